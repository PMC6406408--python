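"""Seeded generator of TCGA-like cohorts for testing every pipeline stage
without any download: per-sample copy-number segments with discrete
GISTIC-like calls, protein-change mutations, and negative-binomial RNA-seq
counts with a planted downregulation of the target gene plus planted
downstream signature genes.

The expression consequence of a deletion is modelled directly as a log2
mean shift of the target gene in inactivated samples (the pipeline only
ever sees counts, so a mechanistic dosage model would add nothing the
analysis could distinguish).  Library sizes are drawn log-normally around
1e7 so CPM scaling is genuinely exercised.  All randomness flows from a
single integer seed through one numpy Generator, so emitted files are
byte-identical across runs and platforms.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (CnvSegment, CountMatrix, GeneLocus, MutationRecord,
                 parse_protein_change, write_counts, write_gene_loci,
                 write_mutations, write_segments)

# chromosome lengths used for background-segment placement (hg19-like scale)
_CHROM_SIZES = {f"chr{i}": size for i, size in enumerate(
    [249_000_000, 243_000_000, 198_000_000, 191_000_000, 180_000_000,
     171_000_000, 159_000_000, 146_000_000, 141_000_000, 135_000_000,
     135_000_000, 133_000_000, 115_000_000, 107_000_000, 102_000_000,
     90_000_000, 81_000_000, 78_000_000, 59_000_000, 63_000_000,
     48_000_000, 51_000_000], start=1)}

DEFAULT_TARGET_LOCUS = GeneLocus("TARGET", "chr17", 7_565_097, 7_590_856)
DEFAULT_INACTIVATING = ("Arg175His", "Arg273Cys", "STOP 300")


@dataclass
class SimulationParams:
    """Study conditions for one synthetic cohort.

    Defaults emulate a mid-sized TCGA tumor cohort with a recurrently
    deleted target gene: 120 samples, 2000 expressed genes, 12 samples with
    a focal deep deletion (score -2, 60 kb) over the target, 3 samples with
    a listed inactivating mutation, one background CNV per sample on average
    (scores +/-1, 10-500 kb, never over the target in intended-control
    samples), negative-binomial counts with dispersion 0.1, a -1.5 log2
    shift of the target gene in inactivated samples and a 20-gene
    downstream signature at +/-1.5 log2.
    """

    n_samples: int = 120
    n_genes: int = 2000
    target_locus: GeneLocus = DEFAULT_TARGET_LOCUS
    n_deleted: int = 12
    n_mutated: int = 3
    deletion_score: float = -2.0
    deletion_size: int = 60_000
    background_cnv_rate: float = 1.0
    background_size_range: tuple[int, int] = (10_000, 500_000)
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    nb_dispersion: float = 0.1
    lib_size_mean: float = 1e7
    lib_size_log_sd: float = 0.2     # sd of ln(library size)
    target_effect: float = -1.5
    signature: list[tuple[str, float]] = field(default_factory=list)
    n_signature_genes: int = 20
    signature_effect: float = 1.5
    inactivating_mutations: tuple[str, ...] = DEFAULT_INACTIVATING
    n_target_passenger_mut: int = 2  # target mutations NOT in the list
    n_cnv_only: int = 0              # samples with CNV but no mRNA data
    n_mrna_only: int = 0             # samples with mRNA but no CNV data
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_deleted + self.n_mutated > self.n_samples:
            raise ValueError("n_deleted + n_mutated exceeds n_samples")
        if self.deletion_size < self.target_locus.length:
            raise ValueError(
                "deletion_size smaller than the target locus; the planted "
                "deletion could not span it")
        for name in ("background_cnv_rate", "nb_dispersion", "lib_size_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery scoring."""

    target_gene: str
    inactivated: list[str]           # intended inactivated sample ids
    control_eligible: list[str]      # intended control-eligible ids
    true_log2fc: dict[str, float]    # per-gene planted effect (0 if absent)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SimulatedCohort:
    segments: list[CnvSegment]
    mutations: list[MutationRecord]
    counts: CountMatrix
    loci: dict[str, GeneLocus]
    truth: GroundTruth
    params: SimulationParams

    def write(self, outdir) -> dict[str, Path]:
        """Emit the four input files plus the truth JSON into a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "seg": outdir / "segments.seg.tsv",
            "mutations": outdir / "mutations.tsv",
            "counts": outdir / "counts.tsv",
            "loci": outdir / "loci.tsv",
            "truth": outdir / "truth.json",
        }
        write_segments(self.segments, paths["seg"])
        write_mutations(self.mutations, paths["mutations"])
        write_counts(self.counts, paths["counts"])
        write_gene_loci(self.loci, paths["loci"], coords="one-based")
        self.truth.to_json(paths["truth"])
        return paths


def _random_interval(rng: np.random.Generator, size: int,
                     avoid: GeneLocus | None) -> tuple[str, int, int]:
    """Place a segment of ``size`` bp uniformly, optionally avoiding a locus."""
    chroms = sorted(_CHROM_SIZES)
    for _ in range(100):
        chrom = chroms[rng.integers(0, len(chroms))]
        limit = _CHROM_SIZES[chrom] - size
        start = int(rng.integers(1, max(limit, 2)))
        end = start + size - 1
        if avoid is not None and chrom == avoid.chrom \
                and start <= avoid.end and end >= avoid.start:
            continue
        return chrom, start, end
    raise RuntimeError("could not place a background segment")  # pragma: no cover


def simulate_cohort(params: SimulationParams) -> SimulatedCohort:
    """Generate one cohort: segments, mutations, counts, loci, ground truth."""
    rng = np.random.default_rng(params.seed)
    n, g = params.n_samples, params.n_genes
    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]
    target = params.target_locus
    gene_ids = [target.gene_id] + [f"G{i:04d}" for i in range(1, g)]

    # gene loci: the target at its stated locus, the rest tiled elsewhere
    loci = {target.gene_id: target}
    chroms = sorted(c for c in _CHROM_SIZES if c != target.chrom)
    for i, gid in enumerate(gene_ids[1:]):
        chrom = chroms[i % len(chroms)]
        start = 1_000_000 + (i // len(chroms)) * 100_000
        loci[gid] = GeneLocus(gid, chrom, start, start + 20_000)

    # sample roles
    order = rng.permutation(n)
    deleted = [sample_ids[i] for i in sorted(order[:params.n_deleted])]
    mutated = [sample_ids[i] for i in
               sorted(order[params.n_deleted:params.n_deleted + params.n_mutated])]
    inactivated = sorted(deleted + mutated)
    rest = [s for s in sample_ids if s not in set(inactivated)]
    passengers = [rest[i] for i in
                  sorted(rng.permutation(len(rest))[:params.n_target_passenger_mut])]
    control_eligible = sorted(set(rest) - set(passengers))

    # --- copy-number segments -------------------------------------------
    segments: list[CnvSegment] = []
    for sid in deleted:
        slack = params.deletion_size - target.length
        lead = int(rng.integers(0, slack + 1))
        start = max(1, target.start - lead)
        segments.append(CnvSegment(sid, target.chrom, start,
                                   start + params.deletion_size - 1,
                                   params.deletion_score))
    lo, hi = params.background_size_range
    for sid in sample_ids:
        # every profiled sample carries at least one (copy-neutral) segment,
        # as genome-wide segmentation output does
        segments.append(CnvSegment(sid, "chr1", 1, 50_000_000, 0.0))
        avoid = target if sid not in set(deleted) else None
        n_bg = rng.poisson(params.background_cnv_rate)
        for _ in range(n_bg):
            size = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            chrom, start, end = _random_interval(rng, size, avoid)
            score = float(rng.choice([-1.0, 1.0]))
            segments.append(CnvSegment(sid, chrom, start, end, score))
    segments.sort(key=lambda s: (s.sample_id, s.chrom, s.start))

    # --- mutations -------------------------------------------------------
    listed = [m for m in params.inactivating_mutations
              if not m.upper().startswith("STOP")]
    stop_bounds = [int(m.split()[1]) for m in params.inactivating_mutations
                   if m.upper().startswith("STOP")]
    mutations: list[MutationRecord] = []

    def _mk(sid: str, gene: str, raw: str) -> MutationRecord:
        ref, pos, alt = parse_protein_change(raw)
        return MutationRecord(sid, gene, ref, pos, alt, raw)

    for sid in mutated:
        if listed and (not stop_bounds or rng.random() < 0.5):
            raw = listed[int(rng.integers(0, len(listed)))]
        else:
            pos = int(rng.integers(1, stop_bounds[0] + 1))
            raw = f"p.Trp{pos}Ter"
        mutations.append(_mk(sid, target.gene_id, raw))
    for sid in passengers:
        # a target mutation absent from the list: excludes from control only
        pos = int(rng.integers(400, 500))
        mutations.append(_mk(sid, target.gene_id, f"p.Ala{pos}Val"))
    # background mutations on non-target genes
    for sid in sample_ids:
        for _ in range(rng.poisson(0.5)):
            gid = gene_ids[int(rng.integers(1, len(gene_ids)))]
            pos = int(rng.integers(1, 400))
            mutations.append(_mk(sid, gid, f"p.Gly{pos}Asp"))
    mutations.sort(key=lambda m: (m.sample_id, m.gene_id, m.raw_text))

    # --- counts ----------------------------------------------------------
    signature = list(params.signature)
    if not signature and params.n_signature_genes > 0:
        sig_genes = gene_ids[1:1 + params.n_signature_genes]
        signs = np.where(np.arange(len(sig_genes)) % 2 == 0, -1.0, 1.0)
        signature = [(gid, float(s * params.signature_effect))
                     for gid, s in zip(sig_genes, signs)]
    true_lfc = {gid: 0.0 for gid in gene_ids}
    true_lfc[target.gene_id] = params.target_effect
    for gid, eff in signature:
        true_lfc[gid] = eff

    baseline = rng.normal(params.baseline_log2_mean, params.baseline_log2_sd, g)
    effect = np.zeros((g, n))
    inact_mask = np.array([s in set(inactivated) for s in sample_ids])
    gene_pos = {gid: i for i, gid in enumerate(gene_ids)}
    for gid, eff in true_lfc.items():
        if eff != 0.0:
            effect[gene_pos[gid], inact_mask] = eff
    lib_sizes = params.lib_size_mean * np.exp(
        rng.normal(0.0, params.lib_size_log_sd, n)
        - params.lib_size_log_sd ** 2 / 2)
    rel = 2.0 ** (baseline[:, None] + effect)
    mu = rel / rel.sum(axis=0, keepdims=True) * lib_sizes[None, :]
    phi = params.nb_dispersion
    if phi > 0:
        nb_n = 1.0 / phi
        nb_p = nb_n / (nb_n + mu)
        counts = rng.negative_binomial(nb_n, nb_p)
    else:
        counts = rng.poisson(mu)

    # platform-membership tweaks: drop mRNA columns / add CNV-only samples
    mrna_samples = list(sample_ids)
    if params.n_cnv_only > 0:
        drop = [s for s in control_eligible[-params.n_cnv_only:]]
        mrna_samples = [s for s in sample_ids if s not in set(drop)]
        control_eligible = [s for s in control_eligible if s not in set(drop)]
        keep = [sample_ids.index(s) for s in mrna_samples]
        counts = counts[:, keep]
        lib_sizes = lib_sizes[keep]
    if params.n_mrna_only > 0:
        extra = [f"X{i:04d}" for i in range(1, params.n_mrna_only + 1)]
        mrna_samples = mrna_samples + extra
        mu_x = rel[:, :1] / rel[:, :1].sum(axis=0, keepdims=True) \
            * params.lib_size_mean
        extra_counts = rng.poisson(np.repeat(mu_x, params.n_mrna_only, axis=1))
        counts = np.hstack([counts, extra_counts])

    cm = CountMatrix(gene_ids=gene_ids, sample_ids=mrna_samples,
                     counts=counts.astype(np.int64))
    truth = GroundTruth(target_gene=target.gene_id,
                        inactivated=inactivated,
                        control_eligible=sorted(control_eligible),
                        true_log2fc=true_lfc)
    return SimulatedCohort(segments=segments, mutations=mutations, counts=cm,
                           loci=loci, truth=truth, params=params)


def write_inactivation_list(params: SimulationParams, path) -> None:
    Path(path).write_text("\n".join(params.inactivating_mutations) + "\n")


def truth_report(truth: GroundTruth, de: pd.DataFrame,
                 rf: pd.DataFrame | None = None, alpha: float = 0.05,
                 top_k: int = 50) -> dict:
    """Recovery metrics of the planted signal from the result tables.

    Reports logFC bias and RMSE over planted genes, sensitivity and
    specificity at ``q < alpha``, and (when an RF table is given) how many
    planted genes sit in the top ``top_k`` by Gini share.  With an empty
    signature, sensitivity is not applicable and reported as None.
    """
    de = de.set_index("gene")
    tested = set(de.index)
    unknown = tested - set(truth.true_log2fc)
    if unknown:
        raise ValueError(f"genes absent from ground truth: {sorted(unknown)[:5]}")
    planted = [gid for gid, eff in truth.true_log2fc.items()
               if eff != 0.0 and gid in tested]
    nulls = [gid for gid in tested if truth.true_log2fc[gid] == 0.0]
    report: dict = {"n_planted_tested": len(planted), "n_null_tested": len(nulls)}
    if planted:
        err = np.array([de.loc[gid, "logFC"] - truth.true_log2fc[gid]
                        for gid in planted])
        report["logfc_bias"] = float(err.mean())
        report["logfc_rmse"] = float(np.sqrt((err ** 2).mean()))
        report["sensitivity"] = float(
            np.mean([de.loc[gid, "q"] < alpha for gid in planted]))
    else:
        report["logfc_bias"] = report["logfc_rmse"] = None
        report["sensitivity"] = None
    fpr = (float(np.mean([de.loc[gid, "q"] < alpha for gid in nulls]))
           if nulls else None)
    report["false_positive_rate"] = fpr
    report["specificity"] = None if fpr is None else 1.0 - fpr
    if rf is not None:
        top = set(rf.sort_values("rank").head(top_k)["gene"])
        report["planted_in_top_rf"] = int(len(top & set(planted)))
        report["rf_top_k"] = top_k
    return report
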