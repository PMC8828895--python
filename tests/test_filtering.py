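"""Unit and property tests for the confidence cascade.

The randomized oracle test re-derives each decision case-by-case from the
filtering rules written out longhand, independent of the cascade's
dispatch logic.
"""
import random
from collections import Counter

import pytest

from baitnet import filtering
from baitnet.types import (
    APMS,
    BIOID,
    ControlRun,
    CrapomeEntry,
    FilterThresholds,
    PurificationRun,
    RULE_APMS_FOLD,
    RULE_BIOID_FREQ,
    RULE_BIOID_MIDBAND,
    RULE_PASS,
    RULE_SAINT_FAIL,
    ScoredInteraction,
    ValidationError,
)

T = FilterThresholds()


def si(method=BIOID, avg=5.0, score=0.9, bait="B1", prey="P1"):
    return ScoredInteraction(bait, prey, method, avg, score)


def ce(n_detected, avg=0.0, n=716):
    return CrapomeEntry("P1", n_detected, n, avg)


class TestAverageSpectralCounts:
    def test_mean_over_runs(self):
        runs = [PurificationRun("B", BIOID, 1, 1, {"P1": 4}),
                PurificationRun("B", BIOID, 2, 1, {"P1": 2})]
        assert filtering.average_spectral_counts(runs) == {"P1": 3.0}

    def test_zero_substituted_for_absent_prey(self):
        runs = [PurificationRun("B", BIOID, 1, 1, {"P2": 6}),
                PurificationRun("B", BIOID, 2, 1, {})]
        assert filtering.average_spectral_counts(runs) == {"P2": 3.0}

    def test_single_run_identity(self):
        runs = [PurificationRun("B", BIOID, 1, 1, {"P3": 7})]
        assert filtering.average_spectral_counts(runs) == {"P3": 7.0}

    def test_empty_and_mixed_inputs_rejected(self):
        with pytest.raises(ValidationError):
            filtering.average_spectral_counts([])
        mixed = [PurificationRun("B", BIOID, 1, 1, {"P": 1}),
                 PurificationRun("C", BIOID, 1, 1, {"P": 1})]
        with pytest.raises(ValidationError):
            filtering.average_spectral_counts(mixed)


class TestSaintThreshold:
    @pytest.mark.parametrize("score,kept", [
        (0.74, True),    # cutoff is inclusive
        (0.7399, False),
        (1.0, True),
        (0.0, False),
    ])
    def test_boundary(self, score, kept):
        kept_list, decisions = filtering.apply_saint_threshold([si(score=score)], T)
        assert (len(kept_list) == 1) is kept
        if not kept:
            assert decisions[0].rule == RULE_SAINT_FAIL

    def test_empty_input(self):
        assert filtering.apply_saint_threshold([], T) == ([], [])


class TestBioidCrapomeRule:
    def test_high_frequency_dropped_regardless_of_counts(self):
        d = filtering.crapome_decision_bioid(si(avg=999), ce(400, avg=0.1), T)
        assert d.rule == RULE_BIOID_FREQ and not d.kept

    def test_exactly_half_dropped(self):
        assert filtering.crapome_decision_bioid(si(), ce(358), T).rule == \
            RULE_BIOID_FREQ

    def test_midband_dropped_when_repository_counts_higher(self):
        d = filtering.crapome_decision_bioid(si(avg=5), ce(200, avg=10), T)
        assert d.rule == RULE_BIOID_MIDBAND

    def test_midband_kept_when_study_counts_higher(self):
        d = filtering.crapome_decision_bioid(si(avg=5), ce(200, avg=2), T)
        assert d.kept and d.rule == RULE_PASS

    def test_below_midband_counts_irrelevant(self):
        d = filtering.crapome_decision_bioid(si(avg=1), ce(100, avg=50), T)
        assert d.kept

    def test_method_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            filtering.crapome_decision_bioid(si(method=APMS), ce(0), T)


class TestApmsCrapomeRule:
    def test_high_frequency_with_sufficient_fold_kept(self):
        d = filtering.crapome_decision_apms(
            si(method=APMS, avg=30), ce(400, avg=5), T)
        assert d.kept

    def test_high_frequency_below_fold_dropped(self):
        d = filtering.crapome_decision_apms(
            si(method=APMS, avg=10), ce(400, avg=5), T)
        assert d.rule == RULE_APMS_FOLD

    def test_frequency_not_above_half_exempt_from_fold(self):
        d = filtering.crapome_decision_apms(
            si(method=APMS, avg=1), ce(300, avg=100), T)
        assert d.kept

    def test_zero_repository_average_passes_trivially(self):
        d = filtering.crapome_decision_apms(
            si(method=APMS, avg=0.0), ce(400, avg=0.0), T)
        assert d.kept

    def test_method_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            filtering.crapome_decision_apms(si(method=BIOID), ce(0), T)


class TestDistill:
    def test_hand_enumerated_cascade(self):
        scored = [
            si(score=0.9, prey="A"),
            si(score=0.5, prey="B"),
            si(score=0.9, prey="C"),
        ]
        crapome = {"C": CrapomeEntry("C", 430)}  # 430/716 = 0.60
        table, decisions = filtering.distill_interactome(scored, crapome, T)
        assert len(table) == 1 and table.iloc[0]["prey"] == "A"
        assert [d.rule for d in decisions] == \
            [RULE_PASS, RULE_SAINT_FAIL, RULE_BIOID_FREQ]

    def test_all_pass_input_preserved(self):
        scored = [si(prey=f"P{i}") for i in range(10)]
        table, _ = filtering.distill_interactome(scored, {}, T)
        assert len(table) == 10

    def test_deterministic(self, sim_default):
        scored = filtering.score_interactions(sim_default.runs,
                                              sim_default.controls)
        t1, d1 = filtering.distill_interactome(scored, sim_default.crapome, T)
        t2, d2 = filtering.distill_interactome(scored, sim_default.crapome, T)
        assert t1.equals(t2) and d1 == d2

    def test_missing_crapome_prey_treated_as_zero_frequency(self):
        table, _ = filtering.distill_interactome([si(prey="UNSEEN")], {}, T)
        assert len(table) == 1


class TestSurrogateScore:
    def run(self, counts):
        return [PurificationRun("B", BIOID, 1, 1, counts)]

    def test_absent_from_controls_high_count_scores_high(self, toy_controls):
        scores = filtering.surrogate_score(self.run({"NEW": 20}), toy_controls)
        assert scores["NEW"] >= 0.9

    def test_bait_at_control_level_scores_low(self):
        controls = [ControlRun("G1", "GFP", BIOID, {"C1": 5})]
        scores = filtering.surrogate_score(self.run({"C1": 5}), controls)
        assert scores["C1"] <= 0.5

    def test_zero_bait_average_scores_zero(self, toy_controls):
        runs = [PurificationRun("B", BIOID, 1, 1, {"X": 0})]
        assert filtering.surrogate_score(runs, toy_controls)["X"] == 0.0

    def test_no_controls_is_an_error(self):
        with pytest.raises(ValidationError, match="read_saint_output"):
            filtering.surrogate_score(self.run({"X": 1}), [])

    def test_monotone_in_bait_and_control_counts(self):
        controls = [ControlRun("G1", "GFP", BIOID, {"P": 4})]
        lo = filtering.surrogate_score(self.run({"P": 3}), controls)["P"]
        hi = filtering.surrogate_score(self.run({"P": 9}), controls)["P"]
        assert hi > lo
        worse_ctrl = [ControlRun("G1", "GFP", BIOID, {"P": 20})]
        assert filtering.surrogate_score(self.run({"P": 9}), worse_ctrl)["P"] < hi


# --- properties -----------------------------------------------------------

def oracle_decision(score, method, study_avg, n_detected, crapome_avg, n=716):
    """The filtering rules spelled out case-by-case, longhand."""
    if score < 0.74:
        return RULE_SAINT_FAIL
    f = n_detected / n
    if method == BIOID:
        # only prey with frequency lower than 50% allowed
        if not f < 0.50:
            return RULE_BIOID_FREQ
        # 25-50% band with higher repository average removed
        if 0.25 <= f < 0.50 and crapome_avg > study_avg:
            return RULE_BIOID_MIDBAND
        return RULE_PASS
    # AP-MS: frequency higher than 50% requires threefold study excess
    if f > 0.50 and not study_avg >= 3 * crapome_avg:
        return RULE_APMS_FOLD
    return RULE_PASS


def test_cascade_matches_longhand_oracle_on_randomized_inputs():
    rng = random.Random(20240917)
    for case in range(1500):
        method = rng.choice([BIOID, APMS])
        score = rng.choice([rng.random(), 0.74, 0.7399, 0.75])
        study_avg = rng.choice([0.0, rng.uniform(0, 30), 3.0])
        n_detected = rng.choice(
            [0, 178, 179, 357, 358, 359, 716, rng.randrange(0, 717)])
        crapome_avg = rng.choice([0.0, rng.uniform(0, 30), 1.0])
        interaction = si(method=method, avg=study_avg, score=score)
        crapome = {"P1": ce(n_detected, avg=crapome_avg)}
        _, decisions = filtering.distill_interactome([interaction], crapome, T)
        expected = oracle_decision(score, method, study_avg, n_detected,
                                   crapome_avg)
        assert decisions[0].rule == expected, (
            f"case {case}: {method} score={score} f={n_detected}/716 "
            f"study={study_avg} crapome={crapome_avg}")


def test_decisions_exhaustive_and_mutually_exclusive(sim_default):
    scored = filtering.score_interactions(sim_default.runs, sim_default.controls)
    table, decisions = filtering.distill_interactome(scored,
                                                     sim_default.crapome, T)
    assert len(decisions) == len(scored)
    assert Counter(d.interaction for d in decisions) == Counter(scored)
    assert len(table) == sum(d.kept for d in decisions)


def test_monotone_shrinkage_and_cutoff_monotonicity(sim_default):
    scored = filtering.score_interactions(sim_default.runs, sim_default.controls)
    kept_saint, _ = filtering.apply_saint_threshold(scored, T)
    table, _ = filtering.distill_interactome(scored, sim_default.crapome, T)
    distilled = set(zip(table["bait"], table["prey"], table["method"]))
    saint_set = {(s.bait_id, s.prey_id, s.method) for s in kept_saint}
    full_set = {(s.bait_id, s.prey_id, s.method) for s in scored}
    assert distilled <= saint_set <= full_set

    previous = None
    for cutoff in (0.0, 0.5, 0.74, 0.9, 1.0):
        t = FilterThresholds(saint_cutoff=cutoff)
        tab, _ = filtering.distill_interactome(scored, sim_default.crapome, t)
        current = set(zip(tab["bait"], tab["prey"], tab["method"]))
        if previous is not None:
            assert current <= previous  # raising the cutoff never adds
        previous = current
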