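"""Interactome graph construction and network-level summaries.

The distilled interactome is a directed graph: an edge runs from a bait
(a tagged transcription factor) to each prey it captured, with provenance
recording whether the pair was seen by BioID, AP-MS or both. Summaries
computed here: method-overlap counts, known/novel fractions against
reference PPI sets, prey degree (promiscuity), nuclear-localization
fractions, bait-bait (TF-TF) edges, bidirectional pairs, the partition of
baits by their contacts with the NFI transcription-factor family, and
per-bait coverage of annotated protein complexes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .io import normalize_pair
from .types import APMS, BIOID, ComplexDefinition, ValidationError


def percent(numerator: float, denominator: float) -> int:
    """Percentage rounded to the nearest integer, as printed in reports."""
    if denominator == 0:
        raise ValidationError("percentage of a zero denominator")
    return round(100 * numerator / denominator)

logger = logging.getLogger(__name__)

PROVENANCE_BOTH = "both"

NFI_SET = frozenset({"NFIA", "NFIB", "NFIC", "NFIX"})

#: Compartment labels treated as nuclear by :func:`localization_fraction`.
NUCLEAR_TAGS = frozenset({
    "nucleus", "nuclear", "nucleoplasm", "nucleoli", "nucleolus",
    "nuclear bodies", "nuclear speckles", "nuclear membrane",
})


@dataclass
class Network:
    """Directed bait -> prey interactome with per-edge provenance."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges())

    def provenance(self, bait: str, prey: str) -> str:
        return self.graph.edges[bait, prey]["provenance"]

    def preys(self) -> set[str]:
        return {v for _, v in self.graph.edges()}

    def baits(self) -> set[str]:
        return {u for u, _ in self.graph.edges()}


def _pairs(table: pd.DataFrame) -> set[tuple[str, str]]:
    return set(zip(table["bait"], table["prey"]))


def build_network(bioid: pd.DataFrame, apms: pd.DataFrame) -> Network:
    """Merge per-method distilled tables into one provenance-annotated graph."""
    b_pairs, a_pairs = _pairs(bioid), _pairs(apms)
    net = Network()
    avg = {}
    for table in (bioid, apms):
        for row in table.itertuples(index=False):
            avg[(row.bait, row.prey)] = max(
                avg.get((row.bait, row.prey), 0.0), float(row.avg_spec))
    for bait, prey in sorted(b_pairs | a_pairs):
        if (bait, prey) in b_pairs and (bait, prey) in a_pairs:
            prov = PROVENANCE_BOTH
        elif (bait, prey) in b_pairs:
            prov = BIOID
        else:
            prov = APMS
        net.graph.add_edge(bait, prey, provenance=prov,
                           avg_spec=avg[(bait, prey)])
    return net


def method_overlap_counts(bioid: pd.DataFrame,
                          apms: pd.DataFrame) -> tuple[int, int, int]:
    """(n_bioid_only, n_apms_only, n_both) over unique (bait, prey) pairs."""
    b_pairs, a_pairs = _pairs(bioid), _pairs(apms)
    both = b_pairs & a_pairs
    return len(b_pairs - a_pairs), len(a_pairs - b_pairs), len(both)


def annotate_known(
    net: Network,
    references: Mapping[str, set[tuple[str, str]]],
) -> dict[str, float]:
    """Flag edges found in any reference PPI set; return per-method fractions.

    Edge identity is the undirected gene pair — reference databases are
    undirected. An edge with provenance ``both`` counts in both methods'
    denominators. Sets a boolean ``known`` attribute on every edge.
    """
    if not references:
        logger.warning("no reference sets supplied; all edges marked novel")
    universe: set[tuple[str, str]] = set()
    for pairs in references.values():
        universe |= {normalize_pair(a, b) for a, b in pairs}
    counts = {BIOID: [0, 0], APMS: [0, 0]}  # [known, total] per method
    for bait, prey, data in net.graph.edges(data=True):
        known = normalize_pair(bait, prey) in universe
        data["known"] = known
        methods = ([BIOID, APMS] if data["provenance"] == PROVENANCE_BOTH
                   else [data["provenance"]])
        for m in methods:
            counts[m][1] += 1
            counts[m][0] += known
    return {m: (k / n if n else 0.0) for m, (k, n) in counts.items()}


def prey_degree(net: Network) -> dict[str, int]:
    """Number of distinct baits each prey interacts with (methods collapsed)."""
    return {prey: net.graph.in_degree(prey) for prey in net.preys()}


@dataclass(frozen=True)
class LocalizationSummary:
    n_annotated: int
    n_nuclear: int
    n_unannotated: int

    @property
    def nuclear_fraction(self) -> float | None:
        if self.n_annotated == 0:
            return None
        return self.n_nuclear / self.n_annotated


def localization_fraction(
    net: Network,
    loc_map: Mapping[str, set[str]],
    nuclear_tags: frozenset[str] = NUCLEAR_TAGS,
) -> LocalizationSummary:
    """Fraction of annotated preys with any nuclear compartment tag.

    Multi-localized preys count as nuclear if any of their tags is nuclear.
    Preys without annotation are excluded from the denominator and reported
    separately; with no annotated preys the fraction is None.
    """
    preys = net.preys()
    annotated = {p for p in preys if loc_map.get(p)}
    nuclear = {p for p in annotated
               if {t.lower() for t in loc_map[p]} & nuclear_tags}
    return LocalizationSummary(
        n_annotated=len(annotated),
        n_nuclear=len(nuclear),
        n_unannotated=len(preys - annotated),
    )


def bait_bait_edges(net: Network,
                    bait_set: Iterable[str]) -> list[tuple[str, str, str]]:
    """Directed edges whose prey is itself a registered bait.

    Self-edges (a bait detecting itself) are excluded. Returns
    (bait, prey_bait, provenance) triples, sorted.
    """
    baits = set(bait_set)
    out = []
    for bait, prey, data in net.graph.edges(data=True):
        if bait in baits and prey in baits and bait != prey:
            out.append((bait, prey, data["provenance"]))
    return sorted(out)


def bidirectional_pairs(
    edges: Sequence[tuple[str, str, str]],
) -> list[tuple[tuple[str, str], str, str]]:
    """Unordered bait pairs connected in both directions.

    Returns (pair, provenance_forward, provenance_reverse) where forward is
    the direction from the lexicographically smaller bait.
    """
    directed = {(a, b): prov for a, b, prov in edges}
    seen = set()
    out = []
    for (a, b), prov in sorted(directed.items()):
        pair = normalize_pair(a, b)
        if pair in seen:
            continue
        if (b, a) in directed:
            seen.add(pair)
            out.append((pair, directed[pair], directed[(pair[1], pair[0])]))
    return out


@dataclass(frozen=True)
class NfiContact:
    """A non-NFI bait's contacts with the NFI family."""

    bait_id: str
    nfis: frozenset[str]
    direction: str  # "to" | "from" | "both" | "none"


def nfi_partition(
    edges: Sequence[tuple[str, str, str]],
    all_baits: Iterable[str],
    nfi_set: frozenset[str] = NFI_SET,
) -> tuple[list[NfiContact], dict[str, int]]:
    """Partition non-NFI baits by their edges to/from NFI family members.

    Direction classes follow the edge orientation: "to" = the bait captured
    an NFI as prey; "from" = an NFI bait captured it; "both" = both occur.
    Also returns, per NFI, the number of distinct non-NFI baits touching it
    in either direction.
    """
    to_nfi: dict[str, set[str]] = {}
    from_nfi: dict[str, set[str]] = {}
    for a, b, _prov in edges:
        if a not in nfi_set and b in nfi_set:
            to_nfi.setdefault(a, set()).add(b)
        if a in nfi_set and b not in nfi_set:
            from_nfi.setdefault(b, set()).add(a)
    contacts = []
    per_nfi: dict[str, set[str]] = {nfi: set() for nfi in sorted(nfi_set)}
    for bait in sorted(set(all_baits) - nfi_set):
        t, f = to_nfi.get(bait, set()), from_nfi.get(bait, set())
        if t and f:
            direction = "both"
        elif t:
            direction = "to"
        elif f:
            direction = "from"
        else:
            direction = "none"
        for nfi in t | f:
            per_nfi[nfi].add(bait)
        contacts.append(NfiContact(bait_id=bait, nfis=frozenset(t | f),
                                   direction=direction))
    return contacts, {nfi: len(b) for nfi, b in per_nfi.items()}


def complex_coverage(
    net: Network,
    complexes: Sequence[ComplexDefinition],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-bait counts of complex subunits captured as prey.

    The denominator for each complex is the number of its subunits detected
    anywhere in the network's prey set (subunits never observed cannot be
    covered). Complexes with denominator 0 yield an all-zero column and a
    0 denominator; coverage there is not applicable.
    """
    all_preys = net.preys()
    denominators = {c.complex_name: len(c.subunits & all_preys)
                    for c in complexes}
    baits = sorted(net.baits())
    data = {}
    for c in complexes:
        identified = c.subunits & all_preys
        data[c.complex_name] = [
            len(identified & set(net.graph.successors(bait))) for bait in baits
        ]
    frame = pd.DataFrame(data, index=pd.Index(baits, name="bait"))
    return frame, denominators
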