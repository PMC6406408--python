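import numpy as np
import pytest

from cnloss.io import CnvSegment, CountMatrix, GeneLocus, PipelineConfig
from cnloss.partition import parse_inactivation_spec
from cnloss.simulate import SimulationParams, simulate_cohort


@pytest.fixture(scope="session")
def tp53_locus():
    return GeneLocus("TARGET", "chr17", 7_565_097, 7_590_856)


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig(target_gene="TARGET", seed=0)


@pytest.fixture(scope="session")
def planted_cohort():
    """Default-condition synthetic cohort with planted deletion signature."""
    return simulate_cohort(SimulationParams(seed=42))


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort for fast end-to-end runs."""
    params = SimulationParams(seed=3, n_samples=60, n_genes=400,
                              n_deleted=8, n_mutated=0,
                              n_signature_genes=10)
    return simulate_cohort(params)


@pytest.fixture
def cohort_files(tmp_path, small_cohort):
    paths = small_cohort.write(tmp_path / "cohort")
    from cnloss.simulate import write_inactivation_list
    lst = tmp_path / "cohort" / "inactivating.txt"
    write_inactivation_list(small_cohort.params, lst)
    paths["inactivation_list"] = lst
    return paths


@pytest.fixture(scope="session")
def default_spec():
    return parse_inactivation_spec(["Arg175His", "Arg273Cys", "STOP 300"])


def make_counts(values, gene_ids=None, sample_ids=None):
    values = np.asarray(values)
    g, n = values.shape
    return CountMatrix(
        gene_ids=gene_ids or [f"G{i}" for i in range(g)],
        sample_ids=sample_ids or [f"S{j}" for j in range(n)],
        counts=values,
    )


def seg(sample, chrom, start, end, score):
    return CnvSegment(sample, chrom, start, end, score)
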