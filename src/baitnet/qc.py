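"""Replicate-agreement quality control.

Replicate runs of the same bait+method should show correlated spectral
counts; low Pearson r flags failed purifications or labeling batches.
Vectors span the union of preys seen in either replicate, with zeros
substituted for absences — in count data, absence is informative.
"""
from __future__ import annotations

from collections import defaultdict
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import PurificationRun, ReplicatePair, ValidationError


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation; errors on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValidationError("need at least 2 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    r = stats.pearsonr(x, y).statistic
    return float(r)


def replicate_vectors(run_a: PurificationRun, run_b: PurificationRun,
                      log1p: bool = False) -> tuple[np.ndarray, np.ndarray, int]:
    """Aligned count vectors over the union of the two runs' preys."""
    preys = sorted(set(run_a.counts) | set(run_b.counts))
    x = np.array([run_a.counts.get(p, 0) for p in preys], dtype=float)
    y = np.array([run_b.counts.get(p, 0) for p in preys], dtype=float)
    if log1p:
        x, y = np.log1p(x), np.log1p(y)
    return x, y, len(preys)


def replicate_report(runs: Sequence[PurificationRun],
                     log1p: bool = False) -> list[ReplicatePair]:
    """One :class:`ReplicatePair` per unordered replicate pair per bait+method.

    Baits with a single run contribute no pairs. Pairs whose union vector
    is constant on either side are skipped (uncorrelatable, not an error
    at report level).
    """
    by_group: dict[tuple[str, str], list[PurificationRun]] = defaultdict(list)
    for run in runs:
        by_group[(run.bait_id, run.method)].append(run)
    pairs: list[ReplicatePair] = []
    for key in sorted(by_group):
        group = sorted(by_group[key], key=lambda r: r.key)
        for run_a, run_b in combinations(group, 2):
            x, y, n = replicate_vectors(run_a, run_b, log1p=log1p)
            if n < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            pairs.append(ReplicatePair(run_a=run_a, run_b=run_b,
                                       r=pearson_r(x, y), n_shared=n))
    return pairs


def report_frame(pairs: Sequence[ReplicatePair]) -> pd.DataFrame:
    """Flat TSV-ready report: bait, method, rep_a, rep_b, r, n_preys."""
    rows = []
    for p in pairs:
        rep = lambda r: f"b{r.bio_replicate}t{r.tech_replicate}"
        rows.append((p.run_a.bait_id, p.run_a.method, rep(p.run_a),
                     rep(p.run_b), p.r, p.n_shared))
    return pd.DataFrame(rows, columns=["bait", "method", "rep_a", "rep_b",
                                       "r", "n_preys"])
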