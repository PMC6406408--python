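"""Domain types and readers/writers for the file formats the pipeline touches.

All genomic coordinates are held 1-based inclusive internally (the native
convention of SEG segment files and MAF mutation tables); BED input is
converted at the boundary.  Sample-id matching across files is exact string
match, optionally after truncating barcodes to a fixed length (TCGA aliquot
barcodes carry suffixes that per-platform files may or may not include).
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import protein_letters_3to1

logger = logging.getLogger(__name__)

#: Marker for a stop codon in a parsed protein change.
STOP = "*"
#: Marker for a protein change that could not be parsed (fails closed:
#: never matches an inactivating-mutation list).
UNKNOWN = "?"

_AA3TO1 = {k.upper(): v for k, v in protein_letters_3to1.items()}
_AA3TO1["TER"] = STOP
_AA1 = set(_AA3TO1.values()) - {STOP}


class FormatError(ValueError):
    """A malformed input file (missing column, bad cell, duplicate id...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneLocus:
    """Genomic interval of a gene, 1-based inclusive on both ends."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError(f"{self.gene_id}: empty chromosome")
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CnvSegment:
    """A per-sample copy-number segment with a numeric GISTIC-like score.

    ``score`` may be a discrete thresholded call (-2..+2, where -2 is a deep
    deletion and +2 a high-level amplification) or a continuous value.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    score: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"segment {self.sample_id} {self.chrom}:{self.start}-{self.end}: "
                "start > end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class MutationRecord:
    """A somatic mutation with its protein change parsed into components.

    ``ref_aa``/``alt_aa`` are 1-letter amino-acid codes, ``"*"`` for a stop
    codon, or ``"?"`` when the change could not be parsed (such records never
    match an inactivation list).
    """

    sample_id: str
    gene_id: str
    ref_aa: str
    position: int | None
    alt_aa: str
    raw_text: str

    @property
    def is_parsed(self) -> bool:
        return self.position is not None and UNKNOWN not in (self.ref_aa, self.alt_aa)

    @property
    def is_stop_gain(self) -> bool:
        return self.is_parsed and self.alt_aa == STOP

    @property
    def is_missense(self) -> bool:
        return self.is_parsed and self.alt_aa != STOP


@dataclass
class CountMatrix:
    """Raw RNA-seq counts, genes x samples, with frozen library sizes.

    ``lib_sizes`` are the column sums at construction time; after gene
    filtering they are deliberately *not* recomputed (filtering must not
    change the CPM scale).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    lib_sizes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids in count matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids in count matrix")
        if np.any(self.counts < 0):
            raise FormatError("negative counts")
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.lib_sizes = np.asarray(self.lib_sizes, dtype=float)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_genes(self, keep: Sequence[bool] | np.ndarray) -> "CountMatrix":
        """Row-subset; library sizes are carried over unchanged."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return CountMatrix(
            gene_ids=[self.gene_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            counts=self.counts[idx, :],
            lib_sizes=self.lib_sizes.copy(),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        """Column-subset in the given order; library sizes follow the columns."""
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in count matrix: {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return CountMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(sample_ids),
            counts=self.counts[:, idx],
            lib_sizes=self.lib_sizes[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class PipelineConfig:
    """All tunable thresholds of the partition and signature steps.

    Defaults follow the published workflow: a deletion call is a GISTIC-like
    score strictly below -1 on a segment overlapping the target gene; control
    samples must be free of non-neutral CNVs larger than 1 Mb; the analysis
    proceeds only with >= 5 inactivated samples and an inactivated/control
    ratio strictly above 0.05; genes are kept when CPM > 5 in >= 5 samples.
    """

    target_gene: str
    dataset_label: str = ""
    strategy: str = "deletions_and_mutations"
    gistic_threshold: float = -1.0
    min_deletion_size: int = 0       # bp; 0 disables the optional size filter
    control_max_cnv_size: int = 1_000_000
    min_inactivated: int = 5
    min_ratio: float = 0.05
    cpm_threshold: float = 5.0
    cpm_min_samples: int = 5
    rf_trees: int = 500
    seed: int = 0
    barcode_truncate: int | None = None

    STRATEGIES = ("deletions_and_mutations", "mutations_only")

    def __post_init__(self) -> None:
        if self.strategy not in self.STRATEGIES:
            raise ValueError(
                f"unknown strategy {self.strategy!r}; expected one of {self.STRATEGIES}"
            )
        for name in ("gistic_threshold", "min_deletion_size", "control_max_cnv_size",
                     "min_ratio", "cpm_threshold"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.min_inactivated < 1:
            raise ValueError("min_inactivated must be >= 1")
        if not 0 < self.min_ratio < 1:
            raise ValueError(f"min_ratio must be in (0, 1), got {self.min_ratio}")

    def normalize_sample_id(self, sample_id: str) -> str:
        if self.barcode_truncate is not None:
            return sample_id[: self.barcode_truncate]
        return sample_id


# ---------------------------------------------------------------------------
# protein-change parsing
# ---------------------------------------------------------------------------

_PC_RE = re.compile(
    r"^(?:p\.)?\(?"
    r"(?P<ref>[A-Za-z]{3}|[A-Za-z])"
    r"(?P<pos>\d+)"
    r"(?P<alt>[A-Za-z]{3}|[A-Za-z]|\*)"
    r"\)?$"
)


def _normalize_aa(token: str) -> str | None:
    """One amino-acid token (1- or 3-letter, Ter/X/*) -> 1-letter or stop."""
    if token == STOP:
        return STOP
    up = token.upper()
    if len(up) == 3:
        return _AA3TO1.get(up)
    if len(up) == 1:
        if up == "X":  # 'X' is a stop in some MAF dialects
            return STOP
        return up if up in _AA1 else None
    return None


def parse_protein_change(text: str) -> tuple[str, int | None, str]:
    """Parse an HGVS-like or bare protein change into (ref, position, alt).

    Accepts ``p.C28S``, ``p.Cys28Ser``, ``Cys28Ser``, ``p.R130*``,
    ``p.Arg130Ter``.  Anything else — frameshifts, splice notation, ``p.?`` —
    returns the unknown marker triple and is never treated as inactivating.
    """
    m = _PC_RE.match(text.strip())
    if not m:
        return (UNKNOWN, None, UNKNOWN)
    ref = _normalize_aa(m.group("ref"))
    alt = _normalize_aa(m.group("alt"))
    if ref is None or ref == STOP or alt is None:
        return (UNKNOWN, None, UNKNOWN)
    return (ref, int(m.group("pos")), alt)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

SEG_COLUMNS = {"sample": "sample", "chrom": "chrom", "start": "start",
               "end": "end", "score": "score"}
MUT_COLUMNS = {"sample": "sample", "gene": "gene",
               "protein_change": "protein_change"}


def _require_columns(df: pd.DataFrame, needed: Iterable[str], path) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_seg(path, columns: Mapping[str, str] | None = None,
             on_bad_score: str = "raise") -> list[CnvSegment]:
    """Read a SEG-style TSV of per-sample copy-number segments.

    ``columns`` maps the logical names (sample/chrom/start/end/score) to the
    header names used in the file.  Rows whose score is not numeric raise a
    :class:`FormatError` naming the row, or are skipped with a log message
    when ``on_bad_score="skip"``.
    """
    cols = dict(SEG_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, cols.values(), path)
    segments: list[CnvSegment] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        try:
            score = float(rec[cols["score"]])
        except (TypeError, ValueError):
            if on_bad_score == "skip":
                logger.warning("%s row %d: non-numeric score %r, skipped",
                               path, i, rec[cols["score"]])
                continue
            raise FormatError(
                f"{path} row {i}: non-numeric score {rec[cols['score']]!r}"
            ) from None
        try:
            seg = CnvSegment(
                sample_id=str(rec[cols["sample"]]),
                chrom=str(rec[cols["chrom"]]),
                start=int(str(rec[cols["start"]]).replace(",", "")),
                end=int(str(rec[cols["end"]]).replace(",", "")),
                score=score,
            )
        except ValueError as exc:
            raise FormatError(f"{path} row {i}: {exc}") from None
        segments.append(seg)
    return segments


def read_mutations(path, columns: Mapping[str, str] | None = None
                   ) -> list[MutationRecord]:
    """Read a MAF-style TSV keeping only sample, gene and protein change."""
    cols = dict(MUT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, cols.values(), path)
    records: list[MutationRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        raw = str(rec[cols["protein_change"]])
        ref, pos, alt = parse_protein_change(raw)
        if pos is None:
            logger.info("%s row %d: unparseable protein change %r "
                        "(kept, never inactivating)", path, i, raw)
        records.append(MutationRecord(
            sample_id=str(rec[cols["sample"]]),
            gene_id=str(rec[cols["gene"]]),
            ref_aa=ref, position=pos, alt_aa=alt, raw_text=raw,
        ))
    return records


def read_counts(path) -> CountMatrix:
    """Read a genes x samples TSV of raw integer counts.

    First column: gene ids; remaining columns: one sample each.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    try:
        values = df.to_numpy().astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from None
    bad = ~np.isfinite(values) | (values % 1 != 0) | (values < 0)
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: non-integer or negative count at gene "
            f"{df.index[g]!r}, sample {df.columns[s]!r}"
        )
    return CountMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        counts=values.astype(np.int64),
    )


def write_counts(cm: CountMatrix, path) -> None:
    cm.to_frame().to_csv(path, sep="\t", index_label="gene")


def read_gene_loci(path, coords: str = "bed") -> dict[str, GeneLocus]:
    """Read a gene-locus table (chrom/start/end/gene TSV).

    ``coords="bed"`` declares 0-based half-open input (converted to 1-based
    inclusive); ``coords="one-based"`` takes the coordinates as written.
    """
    if coords not in ("bed", "one-based"):
        raise ValueError(f"coords must be 'bed' or 'one-based', got {coords!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ["chrom", "start", "end", "gene"], path)
    loci: dict[str, GeneLocus] = {}
    for i, rec in enumerate(df.to_dict("records"), start=2):
        gene = str(rec["gene"])
        if gene in loci:
            raise FormatError(f"{path} row {i}: duplicate gene id {gene!r}")
        start, end = int(rec["start"]), int(rec["end"])
        if coords == "bed":
            if end <= start:
                raise FormatError(
                    f"{path} row {i}: empty or inverted BED interval "
                    f"[{start}, {end})"
                )
            start, end = start + 1, end
        try:
            loci[gene] = GeneLocus(gene, str(rec["chrom"]), start, end)
        except ValueError as exc:
            raise FormatError(f"{path} row {i}: {exc}") from None
    return loci


def write_gene_loci(loci: Mapping[str, GeneLocus], path,
                    coords: str = "one-based") -> None:
    rows = []
    for g in sorted(loci):
        loc = loci[g]
        start, end = loc.start, loc.end
        if coords == "bed":
            start, end = start - 1, end
        rows.append({"chrom": loc.chrom, "start": start, "end": end, "gene": g})
    pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# result-table writers (fixed headers consumed downstream)
# ---------------------------------------------------------------------------

DE_COLUMNS = ["gene", "logFC", "AveExpr", "t", "p", "q",
              "median_cpm_inactivated", "median_cpm_control"]
RF_COLUMNS = ["gene", "mdg_percent", "mda", "rank"]


def write_de_table(results: pd.DataFrame, path) -> None:
    """Write the differential-expression table (6 significant digits)."""
    results = results.loc[:, DE_COLUMNS]
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_rf_table(results: pd.DataFrame, path) -> None:
    """Write the forest-importance table sorted by decreasing Gini share."""
    results = results.loc[:, RF_COLUMNS].sort_values(
        ["mdg_percent", "gene"], ascending=[False, True], kind="mergesort")
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_segments(segments: Iterable[CnvSegment], path) -> None:
    rows = [dataclasses.asdict(s) for s in segments]
    df = pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "score"])
    df.columns = ["sample", "chrom", "start", "end", "score"]
    df.to_csv(path, sep="\t", index=False)


def write_mutations(records: Iterable[MutationRecord], path) -> None:
    rows = [{"sample": r.sample_id, "gene": r.gene_id,
             "protein_change": r.raw_text} for r in records]
    pd.DataFrame(rows, columns=["sample", "gene", "protein_change"]).to_csv(
        path, sep="\t", index=False)
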