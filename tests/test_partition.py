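"""Partition rules, gates, and equivalence with a brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnloss.io import CnvSegment, GeneLocus, MutationRecord, PipelineConfig
from cnloss.partition import (CohortPartition, InactivationSpec,
                              InactivationSpecError, build_partition,
                              check_gates, mutation_matches,
                              parse_inactivation_spec, segment_overlaps_locus,
                              select_control, select_inactivated)

from conftest import seg

LOCUS = GeneLocus("TARGET", "chr17", 200, 300)


def mut(sample, gene, raw):
    from cnloss.io import parse_protein_change
    ref, pos, alt = parse_protein_change(raw)
    return MutationRecord(sample, gene, ref, pos, alt, raw)


def cfg(**kw):
    kw.setdefault("target_gene", "TARGET")
    return PipelineConfig(**kw)


class TestInactivationSpec:
    def test_missense_entry(self):
        spec = parse_inactivation_spec(["Cys28Ser"])
        assert spec.missense_entries == frozenset({("C", 28, "S")})
        assert spec.stop_max_position is None

    def test_stop_bound(self):
        assert parse_inactivation_spec(["STOP 300"]).stop_max_position == 300

    def test_empty_spec_matches_nothing(self):
        spec = parse_inactivation_spec([])
        assert not mutation_matches(mut("S", "TARGET", "p.C28S"), spec)
        assert not mutation_matches(mut("S", "TARGET", "p.R10*"), spec)

    def test_comments_and_blanks_ignored(self):
        spec = parse_inactivation_spec(["# note", "", "C28S  # inline"])
        assert spec.missense_entries == frozenset({("C", 28, "S")})

    def test_malformed_line_reports_number(self):
        with pytest.raises(InactivationSpecError, match="line 2"):
            parse_inactivation_spec(["C28S", "not a mutation line"])

    def test_conflicting_stop_lines_error(self):
        with pytest.raises(InactivationSpecError, match="conflicting"):
            parse_inactivation_spec(["STOP 300", "STOP 200"])


class TestOverlap:
    def test_one_bp_overlap_counts(self):
        assert segment_overlaps_locus(seg("S", "chr17", 100, 200, -2), LOCUS)

    def test_adjacent_is_disjoint(self):
        assert not segment_overlaps_locus(seg("S", "chr17", 100, 199, -2), LOCUS)

    def test_other_chromosome_never_overlaps(self):
        assert not segment_overlaps_locus(seg("S", "chr1", 200, 300, -2), LOCUS)


class TestMutationMatches:
    SPEC = InactivationSpec(frozenset({("C", 28, "S")}), 300)

    def test_listed_missense_matches(self):
        assert mutation_matches(mut("S", "TARGET", "p.C28S"), self.SPEC)

    def test_stop_gain_bound_is_inclusive(self):
        assert mutation_matches(mut("S", "TARGET", "p.R250*"), self.SPEC)
        assert not mutation_matches(mut("S", "TARGET", "p.R301*"), self.SPEC)

    def test_unknown_marker_fails_closed(self):
        assert not mutation_matches(mut("S", "TARGET", "p.?"), self.SPEC)


class TestSelectInactivated:
    def test_deep_deletion_included(self):
        got = select_inactivated([seg("S1", "chr17", 100, 400, -2)], [],
                                 LOCUS, InactivationSpec(), cfg(), {"S1"})
        assert got == {"S1": "deletion"}

    def test_boundary_score_excluded(self):
        # "lower than -1" is strict: a score of exactly -1 is not a deletion
        got = select_inactivated([seg("S1", "chr17", 100, 400, -1)], [],
                                 LOCUS, InactivationSpec(), cfg(), {"S1"})
        assert got == {}

    def test_min_deletion_size_filter(self):
        s = seg("S1", "chr17", 250, 8249, -2)  # 8 kb deletion over the locus
        conf = cfg(min_deletion_size=10_000)
        assert select_inactivated([s], [], LOCUS, InactivationSpec(),
                                  conf, {"S1"}) == {}
        assert select_inactivated([s], [], LOCUS, InactivationSpec(),
                                  cfg(), {"S1"}) == {"S1": "deletion"}

    def test_mutations_only_ignores_deletions(self):
        spec = InactivationSpec(frozenset({("C", 28, "S")}), None)
        segs = [seg("S1", "chr17", 100, 400, -2)]
        muts = [mut("S2", "TARGET", "p.C28S")]
        got = select_inactivated(segs, muts, LOCUS, spec,
                                 cfg(strategy="mutations_only"), {"S1", "S2"})
        assert got == {"S2": "mutation"}

    def test_candidates_only(self):
        got = select_inactivated([seg("S1", "chr17", 100, 400, -2)], [],
                                 LOCUS, InactivationSpec(), cfg(), set())
        assert got == {}


class TestSelectControl:
    def test_large_cnv_anywhere_excludes(self):
        control, excl = select_control(
            [seg("S1", "chr3", 1, 2_000_000, -1)], [], LOCUS, cfg(), {"S1"})
        assert excl == {"S1": "large-cnv"}
        assert control == set()

    def test_neutral_segments_are_harmless(self):
        control, excl = select_control(
            [seg("S1", "chr17", 1, 50_000_000, 0.0),
             seg("S1", "chr3", 1, 5_000_000, 0.0)], [], LOCUS, cfg(), {"S1"})
        assert control == {"S1"} and excl == {}

    def test_any_target_mutation_excludes(self):
        # even an unparseable/synonymous-looking record on the target gene
        control, excl = select_control([], [mut("S1", "TARGET", "p.?")],
                                       LOCUS, cfg(), {"S1"})
        assert excl == {"S1": "mutation-on-target"}

    def test_cnv_on_target_excludes(self):
        control, excl = select_control(
            [seg("S1", "chr17", 290, 80_000, 1.0)], [], LOCUS, cfg(), {"S1"})
        assert excl == {"S1": "cnv-on-target"}

    def test_small_offtarget_cnv_allowed(self):
        control, _ = select_control(
            [seg("S1", "chr3", 1, 500_000, -1)], [], LOCUS, cfg(), {"S1"})
        assert control == {"S1"}


class TestGates:
    @pytest.mark.parametrize("n_inact,n_ctrl,passed,reason", [
        (5, 50, True, None),
        (4, 10, False, "min-inactivated"),
        (5, 99, True, None),
        (5, 100, False, "ratio"),     # 0.05 is not > 0.05 (strict)
        (5, 120, False, "ratio"),
    ])
    def test_boundaries(self, n_inact, n_ctrl, passed, reason):
        report = check_gates(n_inact, n_ctrl, cfg())
        assert report.passed is passed
        if reason:
            assert reason in report.reasons

    def test_empty_control_fails_without_exception(self):
        report = check_gates(10, 0, cfg())
        assert not report.passed and "no-control" in report.reasons


# ---------------------------------------------------------------------------
# brute-force oracle equivalence on randomized mini-cohorts
# ---------------------------------------------------------------------------

def brute_force_partition(segments, mutations, locus, spec, config,
                          cnv_samples, mrna_samples):
    """Literal per-sample re-evaluation of the partition rules."""
    inactivated, control, excluded = {}, set(), {}
    candidates = set(cnv_samples) & set(mrna_samples)
    for sid in set(mrna_samples) - set(cnv_samples):
        excluded[sid] = "no-cnv-data"
    for sid in set(cnv_samples) - set(mrna_samples):
        excluded[sid] = "no-mrna-data"
    for sid in candidates:
        segs = [s for s in segments if s.sample_id == sid]
        muts = [m for m in mutations
                if m.sample_id == sid and m.gene_id == locus.gene_id]
        has_del = any(
            s.chrom == locus.chrom and s.start <= locus.end
            and s.end >= locus.start and s.score < config.gistic_threshold
            and (s.end - s.start + 1) > config.min_deletion_size
            for s in segs)
        has_inact_mut = any(mutation_matches(m, spec) for m in muts)
        if config.strategy == "deletions_and_mutations":
            is_inact = has_del or has_inact_mut
        else:
            is_inact = has_inact_mut
        if is_inact:
            inactivated[sid] = "deletion" if (
                config.strategy == "deletions_and_mutations" and has_del) \
                else "mutation"
            continue
        if any(s.score != 0 and s.chrom == locus.chrom
               and s.start <= locus.end and s.end >= locus.start for s in segs):
            excluded[sid] = "cnv-on-target"
        elif any(s.score != 0
                 and (s.end - s.start + 1) > config.control_max_cnv_size
                 for s in segs):
            excluded[sid] = "large-cnv"
        elif muts:
            excluded[sid] = "mutation-on-target"
        else:
            control.add(sid)
    return inactivated, control, excluded


def random_mini_cohort(rng):
    n = int(rng.integers(2, 21))
    samples = [f"S{i}" for i in range(n)]
    locus = GeneLocus("TARGET", "chr17", 200, 300)
    segments = []
    for sid in samples:
        for _ in range(int(rng.integers(0, 11))):
            chrom = str(rng.choice(["chr17", "chr3"]))
            start = int(rng.integers(1, 500))
            length = int(rng.choice([10, 100, 150, 2_000_000]))
            score = float(rng.choice([-2, -1, 0, 1, 2]))
            segments.append(CnvSegment(sid, chrom, start, start + length - 1,
                                       score))
    mutations = []
    for sid in samples:
        if rng.random() < 0.4:
            raw = str(rng.choice(["p.C28S", "p.R250*", "p.R301*", "p.?",
                                  "p.A77V"]))
            mutations.append(mut(sid, str(rng.choice(["TARGET", "OTHER"])), raw))
    spec = InactivationSpec(frozenset({("C", 28, "S")}),
                            300 if rng.random() < 0.7 else None)
    config = cfg(
        strategy=str(rng.choice(["deletions_and_mutations", "mutations_only"])),
        gistic_threshold=float(rng.choice([-1.0, -1.5])),
        min_deletion_size=int(rng.choice([0, 120])),
        control_max_cnv_size=int(rng.choice([1_000_000, 100])),
    )
    cnv = {s for s in samples if rng.random() < 0.9}
    mrna = {s for s in samples if rng.random() < 0.9}
    return segments, mutations, locus, spec, config, cnv, mrna


N_ORACLE_COHORTS = 200


def test_brute_force_oracle_equivalence():
    """Set membership matches an exhaustive re-evaluation of the rules."""
    rng = np.random.default_rng(20240901)
    for _ in range(N_ORACLE_COHORTS):
        args = random_mini_cohort(rng)
        part = build_partition(*args)
        inact, control, excluded = brute_force_partition(*args)
        assert set(part.inactivated) == set(inact)
        assert part.control == control
        assert set(part.excluded) == set(excluded)
        assert part.excluded == excluded  # reasons match too


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_partition_invariants(seed):
    """Disjointness, closure and one-primary-reason hold for any input."""
    rng = np.random.default_rng(seed)
    args = random_mini_cohort(rng)
    segments, mutations, locus, spec, config, cnv, mrna = args
    part = build_partition(*args)
    candidates = cnv & mrna
    inact, ctrl = set(part.inactivated), part.control
    assert inact.isdisjoint(ctrl)
    excl_cand = {s for s in part.excluded if s in candidates}
    assert inact | ctrl | excl_cand == candidates
    assert part.to_frame()["sample_id"].is_unique


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_partition_monotonicity(seed):
    """Looser control-size threshold never shrinks the control set; a more
    negative deletion threshold never grows the inactivated set; the
    mutations-only set is contained in the deletions-and-mutations set."""
    rng = np.random.default_rng(seed)
    segments, mutations, locus, spec, config, cnv, mrna = random_mini_cohort(rng)
    base_cfg = cfg(strategy="deletions_and_mutations",
                   gistic_threshold=-1.0, control_max_cnv_size=1_000)
    base = build_partition(segments, mutations, locus, spec, base_cfg, cnv, mrna)
    looser = build_partition(segments, mutations, locus, spec,
                             cfg(control_max_cnv_size=2_000_000), cnv, mrna)
    assert base.control <= looser.control
    stricter = build_partition(segments, mutations, locus, spec,
                               cfg(gistic_threshold=-1.9), cnv, mrna)
    assert set(stricter.inactivated) <= set(base.inactivated)
    mut_only = build_partition(segments, mutations, locus, spec,
                               cfg(strategy="mutations_only"), cnv, mrna)
    assert set(mut_only.inactivated) <= set(base.inactivated)


def test_build_partition_records_platform_exclusions():
    part = build_partition([seg("S1", "chr17", 100, 400, -2)], [], LOCUS,
                           None, cfg(), cnv_samples={"S1", "S2"},
                           mrna_samples={"S1", "S3"})
    assert part.excluded["S2"] == "no-mrna-data"
    assert part.excluded["S3"] == "no-cnv-data"
    assert part.inactivated == {"S1": "deletion"}
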