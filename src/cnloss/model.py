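"""Model/results interface over the full gene-loss signature workflow.

:class:`GeneLossSignatureModel` is built from the cohort data (counts,
copy-number segments, mutations, gene loci) plus a :class:`PipelineConfig`;
``fit()`` runs the partition, the gating, the expression filter, the
precision-weighted moderated-t differential expression and the
random-forest ranking, and returns a :class:`GeneLossSignatureResults`
carrying every table and diagnostic.  A gate failure is a valid fit
outcome, not an exception: the results object then holds the partition and
gate report only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, expression, forest
from .io import (CnvSegment, CountMatrix, GeneLocus, MutationRecord,
                 PipelineConfig, read_counts, read_gene_loci, read_mutations,
                 read_seg, write_de_table, write_rf_table)
from .partition import (CohortPartition, InactivationSpec, build_partition,
                        parse_inactivation_spec)


class GeneLossSignatureModel:
    """Two-group gene-loss signature model for one target gene in one cohort.

    Parameters
    ----------
    counts
        Raw RNA-seq counts over the cohort (genes x samples).
    segments, mutations
        Copy-number segments and somatic mutations over the cohort.
    loci
        gene_id -> :class:`GeneLocus`; must contain the configured target.
    config
        All thresholds; see :class:`PipelineConfig`.
    inactivation_spec
        Optional parsed inactivating-mutation list; without it the mutation
        route is inactive.
    """

    def __init__(self, counts: CountMatrix, segments: list[CnvSegment],
                 mutations: list[MutationRecord],
                 loci: dict[str, GeneLocus], config: PipelineConfig,
                 inactivation_spec: InactivationSpec | None = None):
        if config.target_gene not in loci:
            raise KeyError(f"target gene {config.target_gene!r} not in locus table")
        trunc = config.normalize_sample_id
        if config.barcode_truncate is not None:
            counts = CountMatrix(counts.gene_ids,
                                 [trunc(s) for s in counts.sample_ids],
                                 counts.counts, counts.lib_sizes)
            segments = [replace(s, sample_id=trunc(s.sample_id)) for s in segments]
            mutations = [replace(m, sample_id=trunc(m.sample_id)) for m in mutations]
        self.counts = counts
        self.segments = segments
        self.mutations = mutations
        self.loci = loci
        self.config = config
        self.inactivation_spec = inactivation_spec or InactivationSpec.empty()

    @classmethod
    def from_files(cls, counts_path, seg_path, mutations_path, loci_path,
                   config: PipelineConfig, inactivation_list_path=None,
                   loci_coords: str = "one-based") -> "GeneLossSignatureModel":
        counts = read_counts(counts_path)
        segments = read_seg(seg_path)
        mutations = read_mutations(mutations_path) if mutations_path else []
        loci = read_gene_loci(loci_path, coords=loci_coords)
        spec = None
        if inactivation_list_path:
            lines = Path(inactivation_list_path).read_text().splitlines()
            spec = parse_inactivation_spec(lines)
        return cls(counts, segments, mutations, loci, config, spec)

    @property
    def target_locus(self) -> GeneLocus:
        return self.loci[self.config.target_gene]

    def partition(self) -> CohortPartition:
        """Build the inactivated/control partition and gate decision."""
        cnv_samples = {s.sample_id for s in self.segments}
        return build_partition(self.segments, self.mutations,
                               self.target_locus, self.inactivation_spec,
                               self.config, cnv_samples,
                               set(self.counts.sample_ids))

    def fit(self, compute_mda: bool = True) -> "GeneLossSignatureResults":
        """Run the full workflow; downstream stages only when gates pass."""
        cfg = self.config
        part = self.partition()
        res = GeneLossSignatureResults(model=self, partition=part)
        if not part.gates_passed:
            return res
        ordered = part.inactivated_ids + part.control_ids
        sub = self.counts.subset_samples(ordered)
        filtered = expression.filter_genes(sub, cfg.cpm_threshold,
                                           cfg.cpm_min_samples)
        res.n_genes_total = sub.n_genes
        res.n_genes_filtered = filtered.n_genes
        de, prior = diffexpr.de_table(filtered, len(part.inactivated),
                                      len(part.control))
        res.de_ = de
        res.prior = prior
        labels = np.array([1] * len(part.inactivated) + [0] * len(part.control))
        x = expression.log_cpm(filtered).values.T    # samples x genes
        ens = forest.train_forest(x, labels, n_trees=cfg.rf_trees,
                                  seed=cfg.seed)
        mda = forest.mda_importance(ens, x, labels, seed=cfg.seed) \
            if compute_mda else None
        res.rf_ = forest.gini_ranking(ens, filtered.gene_ids, mda=mda)
        res.oob_accuracy = ens.oob_accuracy
        res.overlap_, res.comparison_ = forest.de_rf_comparison(res.de_, res.rf_)
        return res


@dataclass
class GeneLossSignatureResults:
    """Fit results: partition, gate report, DE and RF tables, diagnostics."""

    model: GeneLossSignatureModel
    partition: CohortPartition
    de_: pd.DataFrame | None = None
    rf_: pd.DataFrame | None = None
    comparison_: pd.DataFrame | None = None
    overlap_: int | None = None
    prior: "diffexpr.ModerationPrior | None" = None
    oob_accuracy: float = float("nan")
    n_genes_total: int | None = None
    n_genes_filtered: int | None = None

    @property
    def gates_passed(self) -> bool:
        return self.partition.gates_passed

    def target_row(self) -> pd.Series | None:
        """DE statistics of the target gene itself, if it survived filtering."""
        if self.de_ is None:
            return None
        rows = self.de_[self.de_["gene"] == self.model.config.target_gene]
        return rows.iloc[0] if len(rows) else None

    def run_summary(self) -> dict:
        gate = self.partition.gate_report
        d = {
            "target_gene": self.model.config.target_gene,
            "dataset_label": self.model.config.dataset_label,
            "strategy": self.model.config.strategy,
            "n_inactivated": gate.n_inactivated,
            "n_control": gate.n_control,
            "ratio": gate.ratio,
            "gates_passed": gate.passed,
            "gate_reasons": list(gate.reasons),
            "genes_total": self.n_genes_total,
            "genes_tested": self.n_genes_filtered,
        }
        if self.prior is not None:
            d["d0"] = self.prior.df_prior
            d["s0_squared"] = self.prior.s2_prior
        if self.de_ is not None:
            d["n_significant_q05"] = int((self.de_["q"] < 0.05).sum())
            d["oob_accuracy"] = self.oob_accuracy
            d["top100_rf_significant_in_de"] = self.overlap_
        return d

    def summary(self) -> str:
        """Human-readable fit summary."""
        s = self.run_summary()
        lines = [
            "Gene-loss signature fit",
            "=" * 47,
            f"target gene         : {s['target_gene']}",
            f"cohort              : {s['dataset_label'] or '-'}",
            f"strategy            : {s['strategy']}",
            f"inactivated samples : {s['n_inactivated']}",
            f"control samples     : {s['n_control']}",
            f"inactivated/control : {s['ratio']:.4f}",
            f"gates               : {'passed' if s['gates_passed'] else 'FAILED (' + ', '.join(s['gate_reasons']) + ')'}",
        ]
        if self.de_ is not None:
            lines += [
                f"genes tested        : {s['genes_tested']} of {s['genes_total']}",
                f"prior df (d0)       : {s['d0']:.4g}",
                f"prior variance s0^2 : {s['s0_squared']:.4g}",
                f"genes with q < 0.05 : {s['n_significant_q05']}",
                f"forest OOB accuracy : {s['oob_accuracy']:.3f}",
                f"top-100 RF in DE    : {s['top100_rf_significant_in_de']}",
            ]
            tr = self.target_row()
            if tr is not None:
                lines.append(
                    f"target gene DE      : logFC {tr['logFC']:+.3f}, "
                    f"q {tr['q']:.3g}")
        return "\n".join(lines)

    def save(self, outdir) -> dict[str, Path]:
        """Write partition, DE, RF and comparison TSVs into a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"partition": outdir / "partition.tsv"}
        self.partition.to_frame().to_csv(paths["partition"], sep="\t",
                                         index=False)
        if self.de_ is not None:
            paths["de"] = outdir / "de.tsv"
            write_de_table(self.de_, paths["de"])
        if self.rf_ is not None:
            paths["rf"] = outdir / "rf.tsv"
            write_rf_table(self.rf_, paths["rf"])
        if self.comparison_ is not None:
            paths["comparison"] = outdir / "de_rf_comparison.tsv"
            self.comparison_.to_csv(paths["comparison"], sep="\t",
                                    index=False, float_format="%.6g")
        return paths
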