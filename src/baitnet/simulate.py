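"""Synthetic spectral-count experiments with known ground truth.

Emulates the data-generating situation the cascade assumes: each bait has
a set of planted true partners whose counts are drawn from a negative
binomial (spectral counts are overdispersed relative to Poisson), on top
of a frequency-structured contaminant background — each contaminant
carries a per-run detection probability that also governs how often it
appears in negative-control runs and in the contaminant-repository
profile. Optional planted prey modules (disjoint prey groups wired to
disjoint bait groups) provide ground truth for correlation clustering.

Everything is driven by one seed; the same config and seed reproduce the
outputs byte-for-byte.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    APMS,
    BIOID,
    ControlRun,
    CrapomeEntry,
    GFP,
    GFP_NLS,
    PurificationRun,
    ValidationError,
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic interactomics experiment.

    Replicate structure (2 biological x 2 technical), 16 negative-control
    runs and a 716-experiment contaminant repository mirror a typical
    large-scale TF interactomics design; counts use a negative binomial
    with mean ``mean_true_count`` (true partners) or ``mean_contam_count``
    (contaminants) and size parameter ``dispersion`` (smaller = more
    overdispersed; variance = m + m^2/dispersion).
    """

    n_baits: int = 12
    n_preys: int = 150
    n_contaminants: int = 50
    true_edge_prob: float = 0.12
    mean_true_count: float = 15.0
    mean_contam_count: float = 10.0
    dispersion: float = 2.0
    contaminant_freq_range: tuple[float, float] = (0.05, 0.95)
    #: log-normal spread (sigma) of per-edge and per-contaminant latent
    #: abundance multipliers; gives each interaction a stable characteristic
    #: count level, which is what replicate correlation measures.
    abundance_sigma: float = 0.8
    #: probability a planted edge is capturable by each method: proximity
    #: labeling sees transient and stable partners, affinity purification
    #: mostly the stable subset.
    bioid_capture_prob: float = 1.0
    apms_capture_prob: float = 0.35
    n_bio_reps: int = 2
    n_tech_reps: int = 2
    n_controls: int = 16
    n_experiments: int = 716
    methods: tuple[str, ...] = (BIOID, APMS)
    #: disjoint planted prey modules: (n_module_preys, n_module_baits) each;
    #: module preys interact with exactly the module's baits.
    planted_modules: tuple[tuple[int, int], ...] = ()
    allow_contaminant_true_edges: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_baits, self.n_preys, self.n_bio_reps, self.n_tech_reps,
               self.n_controls, self.n_experiments) < 1:
            raise ValidationError("all sizes must be >= 1")
        if self.n_contaminants < 0:
            raise ValidationError("n_contaminants must be >= 0")
        if not 0.0 <= self.true_edge_prob <= 1.0:
            raise ValidationError("true_edge_prob must be in [0, 1]")
        lo, hi = self.contaminant_freq_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValidationError("contaminant_freq_range must be within [0, 1]")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")
        if self.mean_true_count < 0 or self.mean_contam_count < 0:
            raise ValidationError("count means must be >= 0")
        if self.abundance_sigma < 0:
            raise ValidationError("abundance_sigma must be >= 0")
        for p in (self.bioid_capture_prob, self.apms_capture_prob):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("capture probabilities must be in [0, 1]")
        used_p = sum(m[0] for m in self.planted_modules)
        used_b = sum(m[1] for m in self.planted_modules)
        if used_p > self.n_preys or used_b > self.n_baits:
            raise ValidationError("planted modules exceed prey/bait pools")
        if self.n_controls > self.n_experiments:
            raise ValidationError("n_controls cannot exceed n_experiments")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated experiment."""

    planted_edges: frozenset[tuple[str, str]]
    contaminant_set: frozenset[str]
    control_frequency: Mapping[str, float]
    module_of: Mapping[str, str]  # prey -> module id, for planted modules
    #: per-method subsets of planted_edges that the method can capture
    captured: Mapping[str, frozenset[tuple[str, str]]]
    config: SimConfig
    seed: int


@dataclass
class SimData:
    runs: list[PurificationRun]
    controls: list[ControlRun]
    crapome: dict[str, CrapomeEntry]
    truth: SyntheticTruth


def _nb(rng: np.random.Generator, mean: float, size_param: float,
        n: int = 1) -> np.ndarray:
    """Negative binomial draws with the (mean, size) parametrization."""
    if mean == 0:
        return np.zeros(n, dtype=int)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=n)


def generate_experiment(config: SimConfig) -> SimData:
    """Generate bait runs, control runs, a contaminant profile and truth."""
    rng = np.random.default_rng(config.seed)
    baits = [f"BAIT{i:03d}" for i in range(1, config.n_baits + 1)]
    preys = [f"PREY{i:03d}" for i in range(1, config.n_preys + 1)]
    contams = [f"CONT{i:03d}" for i in range(1, config.n_contaminants + 1)]

    # contaminant per-run detection frequencies
    lo, hi = config.contaminant_freq_range
    freqs = dict(zip(contams, rng.uniform(lo, hi, size=len(contams))))

    # planted modules carve disjoint bait and prey blocks off the front
    module_of: dict[str, str] = {}
    module_edges: set[tuple[str, str]] = set()
    p_cursor = b_cursor = 0
    for m_idx, (n_p, n_b) in enumerate(config.planted_modules):
        m_id = f"M{m_idx + 1}"
        m_preys = preys[p_cursor:p_cursor + n_p]
        m_baits = baits[b_cursor:b_cursor + n_b]
        p_cursor += n_p
        b_cursor += n_b
        for p in m_preys:
            module_of[p] = m_id
        module_edges |= {(b, p) for b in m_baits for p in m_preys}
    free_preys = preys[p_cursor:]

    # background planted edges among non-module preys
    planted: set[tuple[str, str]] = set(module_edges)
    for bait in baits:
        hits = rng.random(len(free_preys)) < config.true_edge_prob
        planted |= {(bait, p) for p, h in zip(free_preys, hits) if h}
    if config.allow_contaminant_true_edges and contams:
        for bait in baits:
            hits = rng.random(len(contams)) < config.true_edge_prob
            planted |= {(bait, c) for c, h in zip(contams, hits) if h}

    # latent per-edge and per-contaminant abundance levels, shared across
    # replicates (and methods): the stable "characteristic count" of each
    # interaction, log-normally spread around the configured mean
    def _lognormal_mult(n: int) -> np.ndarray:
        if config.abundance_sigma == 0:
            return np.ones(n)
        s = config.abundance_sigma
        return rng.lognormal(mean=-s * s / 2, sigma=s, size=n)

    sorted_planted = sorted(planted)
    edge_mean = dict(zip(
        sorted_planted,
        config.mean_true_count * _lognormal_mult(len(sorted_planted))))
    contam_mean = dict(zip(
        contams, config.mean_contam_count * _lognormal_mult(len(contams))))

    # each method captures a subset of the planted edges
    capture_prob = {BIOID: config.bioid_capture_prob,
                    APMS: config.apms_capture_prob}
    captured = {}
    for method in config.methods:
        hits = rng.random(len(sorted_planted)) < capture_prob.get(method, 1.0)
        captured[method] = frozenset(
            e for e, h in zip(sorted_planted, hits) if h)

    runs: list[PurificationRun] = []
    for method in config.methods:
        for bait in baits:
            partners = sorted(p for b, p in captured[method] if b == bait)
            for bio in range(1, config.n_bio_reps + 1):
                for tech in range(1, config.n_tech_reps + 1):
                    counts: dict[str, int] = {}
                    for prey in partners:
                        v = _nb(rng, edge_mean[(bait, prey)],
                                config.dispersion)[0]
                        if v > 0:
                            counts[prey] = int(v)
                    present = rng.random(len(contams)) < [freqs[c] for c in contams]
                    for c, is_in in zip(contams, present):
                        if is_in:
                            v = _nb(rng, contam_mean[c], config.dispersion)[0]
                            if v > 0:
                                counts[c] = counts.get(c, 0) + int(v)
                    runs.append(PurificationRun(
                        bait_id=bait, method=method, bio_replicate=bio,
                        tech_replicate=tech, counts=counts))

    controls: list[ControlRun] = []
    detected_in_controls: dict[str, int] = {c: 0 for c in contams}
    control_counts: dict[str, list[int]] = {c: [] for c in contams}
    for method in config.methods:
        for i in range(1, config.n_controls + 1):
            ctype = GFP_NLS if i % 2 == 0 else GFP
            counts = {}
            present = rng.random(len(contams)) < [freqs[c] for c in contams]
            for c, is_in in zip(contams, present):
                if not is_in:
                    continue
                v = int(_nb(rng, contam_mean[c], config.dispersion)[0])
                if v > 0:
                    counts[c] = v
                    detected_in_controls[c] += 1
                    control_counts[c].append(v)
            controls.append(ControlRun(
                control_id=f"{GFP}_{method}_{i:02d}", control_type=ctype,
                method=method, counts=counts))

    # contaminant repository: simulated controls plus pseudo-experiments
    # scaled to n_experiments, so frequency bands are exercised verbatim
    n_sim_controls = config.n_controls * len(config.methods)
    n_pseudo = max(config.n_experiments - n_sim_controls, 0)
    crapome: dict[str, CrapomeEntry] = {}
    for c in contams:
        extra = int(rng.binomial(n_pseudo, freqs[c])) if n_pseudo else 0
        n_detected = min(detected_in_controls[c] + extra, config.n_experiments)
        observed = control_counts[c]
        if extra > 0:
            observed = observed + [int(v) for v in
                                   _nb(rng, contam_mean[c],
                                       config.dispersion, extra)]
        avg = float(np.mean(observed)) if observed else 0.0
        crapome[c] = CrapomeEntry(prey_id=c, n_detected=n_detected,
                                  n_experiments=config.n_experiments,
                                  avg_spectral_count=avg)

    truth = SyntheticTruth(
        planted_edges=frozenset(planted),
        contaminant_set=frozenset(contams),
        control_frequency=dict(sorted(freqs.items())),
        module_of=module_of,
        captured=captured,
        config=config,
        seed=config.seed,
    )
    return SimData(runs=runs, controls=controls, crapome=crapome, truth=truth)


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    return replace(config, seed=seed)


def evaluate_recovery(
    distilled: pd.DataFrame,
    truth: SyntheticTruth,
) -> tuple[float | None, float]:
    """Precision and recall of a distilled table against planted edges.

    Precision is None (not applicable) for an empty table; recall is 0
    with no recovered edges.
    """
    found = set(zip(distilled["bait"], distilled["prey"]))
    planted = set(truth.planted_edges)
    tp = len(found & planted)
    precision = tp / len(found) if found else None
    recall = tp / len(planted) if planted else 0.0
    return precision, recall
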