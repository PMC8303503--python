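"""Over-representation analysis with Benjamini-Hochberg FDR control.

Terms are flat gene sets (GMT input; no ontology-graph propagation). The
enrichment p-value for a term is the hypergeometric upper tail of the
overlap between the query set and the term, both restricted to the
screened universe — the background must match the pool of candidates the
screen could have selected from.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io_formats import PathwayCollection, ValidationError


@dataclass
class EnrichmentResult:
    term_id: str
    term_size: int  # within the universe
    query_size: int
    overlap: int
    p_value: float
    q_value: float = np.nan


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    q_i = min over j >= i (rank order) of p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def hypergeometric_enrichment(
    query: Iterable[str], terms: PathwayCollection, universe: Iterable[str]
) -> list[EnrichmentResult]:
    """One-sided over-representation p per term, with BH q-values attached."""
    universe = set(universe)
    query = set(query)
    offenders = query - universe
    if offenders:
        raise ValidationError(f"query features outside the universe: {sorted(offenders)[:10]}")
    n_universe = len(universe)
    n_query = len(query)
    results: list[EnrichmentResult] = []
    for term in terms:
        members = set(term.members) & universe
        overlap = len(members & query)
        # P(X >= overlap), X ~ Hypergeom(N=|U|, K=|term|, n=|query|)
        p = float(stats.hypergeom.sf(overlap - 1, n_universe, len(members), n_query))
        results.append(
            EnrichmentResult(
                term_id=term.pathway_id,
                term_size=len(members),
                query_size=n_query,
                overlap=overlap,
                p_value=min(p, 1.0),
            )
        )
    if results:
        q = bh_adjust([r.p_value for r in results])
        for r, qv in zip(results, q):
            r.q_value = float(qv)
    return results


def significant_terms(
    results: Sequence[EnrichmentResult], threshold: float = 0.05
) -> list[EnrichmentResult]:
    """Terms with q < threshold, sorted by (q, p) ascending."""
    kept = [r for r in results if r.q_value < threshold]
    return sorted(kept, key=lambda r: (r.q_value, r.p_value))
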