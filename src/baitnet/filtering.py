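"""The confidence cascade that distills a high-confidence interactome.

Candidate bait-prey interactions carry a 0-1 confidence (SAINT-style)
score and an average spectral count. The cascade applies, in order:

1. a confidence cutoff (default: keep score >= 0.74);
2. method-specific contaminant-repository rules:
   * BioID: prey detected in >= 50% of repository control experiments are
     removed outright; prey in the 25-50% frequency band are removed when
     the repository's average spectral count exceeds the study's;
   * AP-MS: prey detected in more than 50% of control experiments must
     show at least a threefold higher study average spectral count than
     the repository average.

Every input interaction receives exactly one :class:`FilterDecision`, so
the cascade is auditable: the distilled table is exactly the set of
decisions whose rule is ``pass``.
"""
from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import INTERACTION_COLUMNS
from .types import (
    APMS,
    BIOID,
    ControlRun,
    CrapomeEntry,
    FilterDecision,
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

DEFAULT_THRESHOLDS = FilterThresholds()


def average_spectral_counts(runs: Sequence[PurificationRun]) -> dict[str, float]:
    """Mean spectral count per prey across all runs of one bait+method.

    Pools biological and technical replicates; a prey absent from a run
    contributes a zero to the mean (absence is informative in count data).
    """
    if not runs:
        raise ValidationError("average_spectral_counts requires >= 1 run")
    baits = {r.bait_id for r in runs}
    methods = {r.method for r in runs}
    if len(baits) > 1 or len(methods) > 1:
        raise ValidationError(
            f"runs must share one bait and method; got baits={sorted(baits)}, "
            f"methods={sorted(methods)}"
        )
    totals: dict[str, float] = defaultdict(float)
    for run in runs:
        for prey, c in run.counts.items():
            totals[prey] += c
    n = len(runs)
    return {prey: total / n for prey, total in totals.items()}


def surrogate_score(runs: Sequence[PurificationRun],
                    controls: Sequence[ControlRun]) -> dict[str, float]:
    """Monotone bait-vs-control confidence score in [0, 1].

    Stands in for an external SAINT-style scorer when its output table is
    unavailable. For each prey, with b the bait-side average count and c
    the maximum count seen for that prey in any control run::

        score = b**2 / (b**2 + (c + 1)**2)

    Properties: a prey absent from all controls with a sizeable bait
    average approaches 1; a prey no higher than control levels stays below
    0.5; b = 0 gives exactly 0. The score increases in b and decreases in c.
    """
    if not controls:
        raise ValidationError(
            "surrogate_score requires >= 1 control run; for externally scored "
            "data use read_saint_output instead"
        )
    avg = average_spectral_counts(runs)
    control_max: dict[str, int] = defaultdict(int)
    for ctrl in controls:
        for prey, c in ctrl.counts.items():
            control_max[prey] = max(control_max[prey], c)
    scores = {}
    for prey, b in avg.items():
        c = control_max.get(prey, 0)
        scores[prey] = b * b / (b * b + (c + 1.0) ** 2)
    return scores


def score_interactions(runs: Sequence[PurificationRun],
                       controls: Sequence[ControlRun]) -> list[ScoredInteraction]:
    """Score every bait's preys with :func:`surrogate_score`.

    Runs are grouped by (bait, method); controls are matched by method.
    """
    by_bait: dict[tuple[str, str], list[PurificationRun]] = defaultdict(list)
    for run in runs:
        by_bait[(run.bait_id, run.method)].append(run)
    out: list[ScoredInteraction] = []
    for (bait, method), bait_runs in sorted(by_bait.items()):
        method_controls = [c for c in controls if c.method == method]
        scores = surrogate_score(bait_runs, method_controls)
        avg = average_spectral_counts(bait_runs)
        for prey in sorted(scores):
            out.append(ScoredInteraction(
                bait_id=bait, prey_id=prey, method=method,
                avg_spectral_count=avg[prey], saint_score=scores[prey],
            ))
    return out


def apply_saint_threshold(
    interactions: Iterable[ScoredInteraction],
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
) -> tuple[list[ScoredInteraction], list[FilterDecision]]:
    """Stage 1: confidence cutoff. Returns (kept, decisions-for-dropped)."""
    kept: list[ScoredInteraction] = []
    decisions: list[FilterDecision] = []
    for si in interactions:
        if _passes_saint(si.saint_score, thresholds):
            kept.append(si)
        else:
            decisions.append(FilterDecision(si, kept=False, rule=RULE_SAINT_FAIL))
    return kept, decisions


def _passes_saint(score: float, t: FilterThresholds) -> bool:
    return score >= t.saint_cutoff if t.saint_inclusive else score > t.saint_cutoff


def crapome_decision_bioid(
    si: ScoredInteraction,
    ce: CrapomeEntry,
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
) -> FilterDecision:
    """Contaminant rule for BioID prey that already passed the score cutoff."""
    if si.method != BIOID:
        raise ValidationError(f"crapome_decision_bioid got method {si.method!r}")
    f = ce.frequency
    t = thresholds
    high = f >= t.freq_high if t.bioid_drop_at_freq_high else f > t.freq_high
    if high:
        return FilterDecision(si, kept=False, rule=RULE_BIOID_FREQ)
    if t.freq_mid <= f and ce.avg_spectral_count > si.avg_spectral_count:
        return FilterDecision(si, kept=False, rule=RULE_BIOID_MIDBAND)
    return FilterDecision(si, kept=True, rule=RULE_PASS)


def crapome_decision_apms(
    si: ScoredInteraction,
    ce: CrapomeEntry,
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
) -> FilterDecision:
    """Contaminant rule for AP-MS prey that already passed the score cutoff."""
    if si.method != APMS:
        raise ValidationError(f"crapome_decision_apms got method {si.method!r}")
    t = thresholds
    if ce.frequency > t.freq_high:
        required = t.apms_fold * ce.avg_spectral_count
        ok = (si.avg_spectral_count >= required if t.apms_fold_inclusive
              else si.avg_spectral_count > required)
        if not ok:
            return FilterDecision(si, kept=False, rule=RULE_APMS_FOLD)
    return FilterDecision(si, kept=True, rule=RULE_PASS)


def _crapome_lookup(prey: str, crapome: Mapping[str, CrapomeEntry]) -> CrapomeEntry:
    entry = crapome.get(prey)
    if entry is None:
        # implicit zero-frequency entry: never contaminant-filtered
        entry = CrapomeEntry(prey_id=prey, n_detected=0)
    return entry


def distill_interactome(
    scored: Sequence[ScoredInteraction],
    crapome: Mapping[str, CrapomeEntry],
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
) -> tuple[pd.DataFrame, list[FilterDecision]]:
    """Run the full cascade; return the distilled table and every decision.

    The decision list covers every input exactly once; the table holds
    exactly the interactions whose rule is ``pass``.
    """
    decisions: list[FilterDecision] = []
    for si in scored:
        if not _passes_saint(si.saint_score, thresholds):
            decisions.append(FilterDecision(si, kept=False, rule=RULE_SAINT_FAIL))
            continue
        ce = _crapome_lookup(si.prey_id, crapome)
        if si.method == BIOID:
            decisions.append(crapome_decision_bioid(si, ce, thresholds))
        elif si.method == APMS:
            decisions.append(crapome_decision_apms(si, ce, thresholds))
        else:  # pragma: no cover - ScoredInteraction already validates
            raise ValidationError(f"unknown method {si.method!r}")
    kept = [d.interaction for d in decisions if d.kept]
    table = pd.DataFrame(
        [(si.bait_id, si.prey_id, si.method, si.avg_spectral_count,
          si.saint_score) for si in kept],
        columns=INTERACTION_COLUMNS,
    )
    return table, decisions


def decisions_frame(decisions: Sequence[FilterDecision]) -> pd.DataFrame:
    """Tabular audit trail of the cascade, one row per input interaction."""
    return pd.DataFrame(
        [(d.interaction.bait_id, d.interaction.prey_id, d.interaction.method,
          d.interaction.avg_spectral_count, d.interaction.saint_score,
          d.kept, d.rule) for d in decisions],
        columns=["bait", "prey", "method", "avg_spec", "score", "kept", "rule"],
    )
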