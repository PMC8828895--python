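"""Gene-set enrichment with an explicit custom background.

Over-representation of annotation terms in an interactome subset is
tested with the upper-tail hypergeometric distribution: with a background
of N genes of which K carry the term, and a query of n genes of which k
carry it, p = P(X >= k) for X ~ Hypergeometric(N, K, n). Multiple testing
is controlled with Benjamini-Hochberg. The background is explicit — e.g.
all preys identified in a study — and all counts are conditioned on it.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import GeneSet, ValidationError

logger = logging.getLogger(__name__)


def hypergeometric_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(n, K)):
        raise ValidationError(f"need 0 <= k <= min(n, K); got k={k}, n={n}, K={K}")
    if n > N or K > N:
        raise ValidationError(f"need n, K <= N; got n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    for p in p_values:
        if not 0.0 < p <= 1.0:
            raise ValidationError(f"p value {p} outside (0, 1]")
    if len(p_values) == 0:
        return []
    _, adjusted, _, _ = multipletests(p_values, method="fdr_bh")
    return [float(q) for q in adjusted]


@dataclass(frozen=True)
class EnrichmentRecord:
    term_id: str
    term_name: str
    k: int  # overlap of query with the term (within background)
    n: int  # query size (within background)
    K: int  # term size within background
    N: int  # background size
    p_value: float
    fdr: float
    overlap_genes: frozenset[str]


def enrich(
    query: Iterable[str],
    background: Iterable[str],
    sets: Sequence[GeneSet],
) -> list[EnrichmentRecord]:
    """Test each gene set for over-representation in the query.

    Query genes outside the background are dropped with a warning; each
    term's members are intersected with the background before counting.
    Terms with no background member are skipped. Results sorted by p.
    """
    bg = set(background)
    q = set(query)
    outside = q - bg
    if outside:
        logger.warning("%d query genes outside background dropped: %s",
                       len(outside), sorted(outside)[:5])
        q &= bg
    N, n = len(bg), len(q)
    rows = []
    for gs in sets:
        members = gs.members & bg
        if not members:
            continue
        overlap = members & q
        p = hypergeometric_upper_tail(len(overlap), n, len(members), N)
        rows.append((gs, overlap, p))
    fdrs = bh_fdr([p for _, _, p in rows])
    records = [
        EnrichmentRecord(
            term_id=gs.term_id, term_name=gs.term_name,
            k=len(overlap), n=n, K=len(gs.members & bg), N=N,
            p_value=p, fdr=fdr, overlap_genes=frozenset(overlap),
        )
        for (gs, overlap, p), fdr in zip(rows, fdrs)
    ]
    records.sort(key=lambda r: (r.p_value, r.term_id))
    return records
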