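"""Core domain types for bait-prey interactomics.

The quantitative unit everywhere is the spectral count: the number of
peptide-spectrum matches (PSMs) assigned to a prey protein in one
purification or proximity-labeling run.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

BIOID = "BioID"
APMS = "AP-MS"
METHODS = (BIOID, APMS)

GFP = "GFP"
GFP_NLS = "GFP-NLS"
CONTROL_TYPES = (GFP, GFP_NLS)


class FormatError(ValueError):
    """A file does not conform to the expected tabular dialect."""


class ValidationError(ValueError):
    """Well-formed input violates a domain invariant."""


def _check_method(method: str) -> str:
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}; expected one of {METHODS}")
    return method


@dataclass(frozen=True)
class PurificationRun:
    """One bait's prey -> spectral-count vector for a single replicate run."""

    bait_id: str
    method: str
    bio_replicate: int
    tech_replicate: int
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        _check_method(self.method)
        if self.bio_replicate < 1 or self.tech_replicate < 1:
            raise ValidationError(
                f"replicate indices must be >= 1 for bait {self.bait_id!r}"
            )
        for prey, c in self.counts.items():
            if c < 0:
                raise ValidationError(
                    f"negative spectral count {c} for prey {prey!r} in bait "
                    f"{self.bait_id!r}"
                )

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.bait_id, self.method, self.bio_replicate, self.tech_replicate)


@dataclass(frozen=True)
class ControlRun:
    """A negative-control (GFP or nuclear GFP-NLS) run."""

    control_id: str
    control_type: str
    method: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        _check_method(self.method)
        if self.control_type not in CONTROL_TYPES:
            raise ValidationError(
                f"unknown control type {self.control_type!r}; "
                f"expected one of {CONTROL_TYPES}"
            )
        for prey, c in self.counts.items():
            if c < 0:
                raise ValidationError(
                    f"negative spectral count {c} for prey {prey!r} in control "
                    f"{self.control_id!r}"
                )


@dataclass(frozen=True)
class BaitRecord:
    """Registry entry for a studied bait (a tagged transcription factor)."""

    bait_id: str
    dbd_family: str = ""
    tag: str = ""


@dataclass(frozen=True)
class CrapomeEntry:
    """Contaminant profile of a prey across negative-control repository runs.

    ``frequency`` is the fraction of control experiments in which the prey
    was detected; frequent preys are likely nonspecific binders.
    """

    prey_id: str
    n_detected: int
    n_experiments: int = 716
    avg_spectral_count: float = 0.0

    def __post_init__(self) -> None:
        if self.n_experiments < 1:
            raise ValidationError("n_experiments must be >= 1")
        if not 0 <= self.n_detected <= self.n_experiments:
            raise ValidationError(
                f"n_detected={self.n_detected} outside [0, {self.n_experiments}] "
                f"for prey {self.prey_id!r}"
            )
        if self.avg_spectral_count < 0:
            raise ValidationError(
                f"negative avg_spectral_count for prey {self.prey_id!r}"
            )

    @property
    def frequency(self) -> float:
        return self.n_detected / self.n_experiments


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (e.g. a GO-BP term) used for enrichment testing."""

    term_id: str
    term_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.term_id!r} has no members")


@dataclass(frozen=True)
class ScoredInteraction:
    """A (bait, prey) candidate with its confidence score and abundance.

    ``avg_spectral_count`` is the mean PSM count over all of the bait's
    replicate runs for this method (zeros substituted where absent);
    ``saint_score`` is a 0-1 probabilistic confidence that the pair is a
    true interaction rather than background.
    """

    bait_id: str
    prey_id: str
    method: str
    avg_spectral_count: float
    saint_score: float

    def __post_init__(self) -> None:
        _check_method(self.method)
        if self.avg_spectral_count < 0:
            raise ValidationError(
                f"negative avg_spectral_count for {self.bait_id}-{self.prey_id}"
            )
        if not 0.0 <= self.saint_score <= 1.0:
            raise ValidationError(
                f"saint_score {self.saint_score} outside [0, 1] for "
                f"{self.bait_id}-{self.prey_id}"
            )


@dataclass(frozen=True)
class FilterThresholds:
    """Constants of the confidence cascade.

    saint_cutoff: minimum confidence score (kept at >= cutoff).
    freq_high:    contaminant-repository frequency at/above which BioID prey
                  are removed outright (and above which AP-MS prey must meet
                  the fold requirement).
    freq_mid:     lower edge of the BioID frequency band in which the
                  repository's average count is compared to the study's.
    apms_fold:    required fold-excess of study over repository average
                  counts for frequent AP-MS prey.
    """

    saint_cutoff: float = 0.74
    freq_high: float = 0.50
    freq_mid: float = 0.25
    apms_fold: float = 3.0
    # Boundary conventions, exposed because prose thresholds are ambiguous
    # at exact equality.
    saint_inclusive: bool = True
    bioid_drop_at_freq_high: bool = True
    apms_fold_inclusive: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.saint_cutoff <= 1.0:
            raise ValidationError("saint_cutoff must be in [0, 1]")
        if not 0.0 <= self.freq_mid < self.freq_high <= 1.0:
            raise ValidationError("need 0 <= freq_mid < freq_high <= 1")
        if self.apms_fold <= 0:
            raise ValidationError("apms_fold must be > 0")


RULE_PASS = "pass"
RULE_SAINT_FAIL = "saint_fail"
RULE_BIOID_FREQ = "bioid_freq_ge_high"
RULE_BIOID_MIDBAND = "bioid_midband_crapome_higher"
RULE_APMS_FOLD = "apms_highfreq_below_fold"
FILTER_RULES = (
    RULE_PASS,
    RULE_SAINT_FAIL,
    RULE_BIOID_FREQ,
    RULE_BIOID_MIDBAND,
    RULE_APMS_FOLD,
)


@dataclass(frozen=True)
class FilterDecision:
    """The single rule that decided an interaction's fate in the cascade."""

    interaction: ScoredInteraction
    kept: bool
    rule: str

    def __post_init__(self) -> None:
        if self.rule not in FILTER_RULES:
            raise ValidationError(f"unknown filter rule {self.rule!r}")
        if self.kept != (self.rule == RULE_PASS):
            raise ValidationError("kept must be True iff rule is 'pass'")


@dataclass(frozen=True)
class ComplexDefinition:
    """A named protein complex and its subunit gene symbols."""

    complex_name: str
    subunits: frozenset[str]

    def __post_init__(self) -> None:
        if not self.subunits:
            raise ValidationError(
                f"complex {self.complex_name!r} has no subunits"
            )


@dataclass(frozen=True)
class ReplicatePair:
    """Pearson agreement between two replicate runs of the same bait+method."""

    run_a: PurificationRun
    run_b: PurificationRun
    r: float
    n_shared: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValidationError(f"correlation {self.r} outside [-1, 1]")
        if self.n_shared < 2:
            raise ValidationError("need at least 2 preys to correlate")


@dataclass
class PreyCluster:
    """A group of preys with correlated bait profiles, plus the baits that
    drive it (ranked by how many cluster members each bait interacts with)."""

    cluster_id: str
    members: list[str]
    driving_baits: list[tuple[str, int]] = field(default_factory=list)
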