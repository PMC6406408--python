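"""Cohort partitioning: inactivated vs control sample sets.

A sample enters the *inactivated* set when the target gene is deleted
(a CNV segment overlapping the gene locus with a GISTIC-like score strictly
below the deletion threshold, by default -1, and optionally longer than a
minimum size) or carries a mutation matching the user-supplied inactivating
list.  A sample enters the *control* set only when it is structurally quiet:
copy-neutral at the target locus, free of non-neutral CNVs larger than a
size threshold (default 1 Mb) anywhere in the genome, and free of any
mutation record on the target gene.  Downstream analysis is gated on the
inactivated set reaching a minimum size and a minimum ratio to the control
set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import (STOP, CnvSegment, GeneLocus, MutationRecord, PipelineConfig,
                 parse_protein_change)


class InactivationSpecError(ValueError):
    """Malformed inactivating-mutation list."""


# Exclusion / inclusion reason strings used in reports.
REASON_DELETION = "deletion"
REASON_MUTATION = "mutation"
EXCL_NO_CNV = "no-cnv-data"
EXCL_NO_MRNA = "no-mrna-data"
EXCL_CNV_ON_TARGET = "cnv-on-target"
EXCL_LARGE_CNV = "large-cnv"
EXCL_MUT_ON_TARGET = "mutation-on-target"
EXCL_UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class InactivationSpec:
    """Parsed inactivating-mutation list.

    ``missense_entries`` holds (ref_aa, position, alt_aa) triples in 1-letter
    code; ``stop_max_position`` (from a ``STOP N`` line) is the rightmost
    stop-gain position still considered inactivating, or ``None`` when
    stop-gains are not accepted.
    """

    missense_entries: frozenset[tuple[str, int, str]] = frozenset()
    stop_max_position: int | None = None

    def __post_init__(self) -> None:
        if self.stop_max_position is not None and self.stop_max_position < 1:
            raise InactivationSpecError(
                f"STOP position must be >= 1, got {self.stop_max_position}")

    @classmethod
    def empty(cls) -> "InactivationSpec":
        return cls()


def parse_inactivation_spec(lines: Iterable[str]) -> InactivationSpec:
    """Parse the plain-text inactivating-mutation list.

    One protein substitution per line (``Cys28Ser`` / ``C28S`` / ``p.C28S``);
    blank lines and ``#`` comments are ignored; at most one ``STOP N`` line
    sets the stop-gain position bound.
    """
    missense: set[tuple[str, int, str]] = set()
    stop_max: int | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        if tokens[0].upper() == "STOP":
            if len(tokens) != 2 or not tokens[1].isdigit() or int(tokens[1]) < 1:
                raise InactivationSpecError(
                    f"line {lineno}: malformed STOP line {raw.strip()!r}")
            n = int(tokens[1])
            if stop_max is not None and stop_max != n:
                raise InactivationSpecError(
                    f"line {lineno}: conflicting STOP bounds {stop_max} and {n}")
            stop_max = n
            continue
        if len(tokens) != 1:
            raise InactivationSpecError(
                f"line {lineno}: malformed entry {raw.strip()!r}")
        ref, pos, alt = parse_protein_change(tokens[0])
        if pos is None or alt == STOP:
            raise InactivationSpecError(
                f"line {lineno}: malformed substitution {tokens[0]!r} "
                "(use e.g. Cys28Ser, or 'STOP N' for stop-gains)")
        missense.add((ref, pos, alt))
    return InactivationSpec(frozenset(missense), stop_max)


def segment_overlaps_locus(seg: CnvSegment, locus: GeneLocus) -> bool:
    """True iff the segment shares >= 1 bp with the locus (same chromosome)."""
    return (seg.chrom == locus.chrom
            and seg.start <= locus.end
            and seg.end >= locus.start)


def mutation_matches(record: MutationRecord, spec: InactivationSpec) -> bool:
    """True iff the record is in the missense list or an in-bound stop-gain.

    Unparseable records never match (fail closed).
    """
    if not record.is_parsed:
        return False
    if record.is_missense:
        return (record.ref_aa, record.position, record.alt_aa) in spec.missense_entries
    # stop-gain
    return (spec.stop_max_position is not None
            and record.position <= spec.stop_max_position)


def select_inactivated(segments: Sequence[CnvSegment],
                       mutations: Sequence[MutationRecord],
                       locus: GeneLocus,
                       spec: InactivationSpec,
                       config: PipelineConfig,
                       candidates: Iterable[str]) -> dict[str, str]:
    """Pick inactivated samples among ``candidates``; returns id -> reason.

    Under ``deletions_and_mutations`` a candidate qualifies through a deletion
    call (overlapping segment, score strictly below ``gistic_threshold``,
    length strictly above ``min_deletion_size`` when that filter is set) or
    through a matching inactivating mutation on the target gene; under
    ``mutations_only`` the mutation route alone applies.
    """
    if config.strategy not in PipelineConfig.STRATEGIES:  # pragma: no cover
        raise ValueError(f"unknown strategy {config.strategy!r}")
    candidates = set(candidates)
    out: dict[str, str] = {}
    if config.strategy == "deletions_and_mutations":
        for seg in segments:
            if seg.sample_id not in candidates or seg.sample_id in out:
                continue
            if (segment_overlaps_locus(seg, locus)
                    and seg.score < config.gistic_threshold
                    and seg.length > config.min_deletion_size):
                out[seg.sample_id] = REASON_DELETION
    for rec in mutations:
        if (rec.sample_id in candidates and rec.sample_id not in out
                and rec.gene_id == locus.gene_id
                and mutation_matches(rec, spec)):
            out[rec.sample_id] = REASON_MUTATION
    return out


def select_control(segments: Sequence[CnvSegment],
                   mutations: Sequence[MutationRecord],
                   locus: GeneLocus,
                   config: PipelineConfig,
                   candidates: Iterable[str]
                   ) -> tuple[set[str], dict[str, str]]:
    """Split ``candidates`` into (control set, excluded id -> reason).

    Exclusions, in priority order when several apply: a non-neutral segment
    overlapping the target locus; a non-neutral segment anywhere longer than
    ``control_max_cnv_size``; any mutation record on the target gene.
    """
    candidates = set(candidates)
    excluded: dict[str, str] = {}
    by_sample: dict[str, list[CnvSegment]] = {}
    for seg in segments:
        if seg.sample_id in candidates:
            by_sample.setdefault(seg.sample_id, []).append(seg)
    mutated = {rec.sample_id for rec in mutations
               if rec.sample_id in candidates and rec.gene_id == locus.gene_id}
    for sid in candidates:
        segs = by_sample.get(sid, [])
        if any(seg.score != 0 and segment_overlaps_locus(seg, locus)
               for seg in segs):
            excluded[sid] = EXCL_CNV_ON_TARGET
        elif any(seg.score != 0 and seg.length > config.control_max_cnv_size
                 for seg in segs):
            excluded[sid] = EXCL_LARGE_CNV
        elif sid in mutated:
            excluded[sid] = EXCL_MUT_ON_TARGET
    control = candidates - set(excluded)
    return control, excluded


@dataclass
class GateReport:
    n_inactivated: int
    n_control: int
    ratio: float
    passed: bool
    reasons: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"n_inactivated": self.n_inactivated,
                "n_control": self.n_control,
                "ratio": self.ratio,
                "passed": self.passed,
                "reasons": list(self.reasons)}


@dataclass
class CohortPartition:
    """The partition outcome: sample sets, exclusion reasons, gate decision."""

    inactivated: dict[str, str]          # sample_id -> deletion | mutation
    control: set[str]
    excluded: dict[str, str]             # sample_id -> exclusion reason
    gate_report: GateReport | None = None

    @property
    def gates_passed(self) -> bool:
        return self.gate_report is not None and self.gate_report.passed

    @property
    def inactivated_ids(self) -> list[str]:
        return sorted(self.inactivated)

    @property
    def control_ids(self) -> list[str]:
        return sorted(self.control)

    def to_frame(self) -> pd.DataFrame:
        """Per-sample assignment table, sorted by sample id."""
        rows = []
        for sid in self.inactivated_ids:
            rows.append({"sample_id": sid, "assignment": "inactivated",
                         "reason": self.inactivated[sid]})
        for sid in self.control_ids:
            rows.append({"sample_id": sid, "assignment": "control",
                         "reason": ""})
        for sid in sorted(self.excluded):
            rows.append({"sample_id": sid, "assignment": "excluded",
                         "reason": self.excluded[sid]})
        return (pd.DataFrame(rows, columns=["sample_id", "assignment", "reason"])
                .sort_values("sample_id", kind="mergesort")
                .reset_index(drop=True))


def check_gates(n_inactivated: int, n_control: int,
                config: PipelineConfig) -> GateReport:
    """Apply the downstream-analysis gates.

    Passing requires at least ``min_inactivated`` inactivated samples, a
    non-empty control set, and an inactivated/control ratio *strictly* above
    ``min_ratio``.  Failing is a reported outcome, not an error.
    """
    reasons = []
    if n_inactivated < config.min_inactivated:
        reasons.append("min-inactivated")
    if n_control == 0:
        reasons.append("no-control")
        ratio = float("nan")
    else:
        ratio = n_inactivated / n_control
        if not ratio > config.min_ratio:
            reasons.append("ratio")
    return GateReport(n_inactivated=n_inactivated, n_control=n_control,
                      ratio=ratio, passed=not reasons, reasons=reasons)


def build_partition(segments: Sequence[CnvSegment],
                    mutations: Sequence[MutationRecord],
                    locus: GeneLocus,
                    spec: InactivationSpec | None,
                    config: PipelineConfig,
                    cnv_samples: Iterable[str],
                    mrna_samples: Iterable[str]) -> CohortPartition:
    """Run the full partition: intersection, selection, control, gates.

    ``cnv_samples`` / ``mrna_samples`` are the sample universes of the two
    platforms; only their intersection is a candidate.  Samples present on
    one platform only are recorded as excluded with the missing-data reason.
    When no inactivation list is given the mutation route is simply inactive
    (an empty spec matches nothing).
    """
    spec = spec or InactivationSpec.empty()
    cnv_samples, mrna_samples = set(cnv_samples), set(mrna_samples)
    candidates = cnv_samples & mrna_samples
    excluded: dict[str, str] = {}
    for sid in mrna_samples - cnv_samples:
        excluded[sid] = EXCL_NO_CNV
    for sid in cnv_samples - mrna_samples:
        excluded[sid] = EXCL_NO_MRNA
    inactivated = select_inactivated(segments, mutations, locus, spec,
                                     config, candidates)
    control, ctrl_excluded = select_control(
        segments, mutations, locus, config, candidates - set(inactivated))
    excluded.update(ctrl_excluded)
    gate = check_gates(len(inactivated), len(control), config)
    return CohortPartition(inactivated=inactivated, control=control,
                           excluded=excluded, gate_report=gate)
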