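"""Over-representation analysis of gene sets by the exact hypergeometric test.

For a study set of ``n`` genes drawn from a background universe of ``N``
genes, a term annotating ``K`` background genes and ``k`` study genes is
scored by the upper-tail hypergeometric probability

    p_raw = P(X ≥ k),   X ~ Hypergeom(N, K, n),

i.e. the chance of observing at least ``k`` annotated genes in a random
study set of the same size.  Only over-representation is tested.  Raw
p-values are corrected across all tested terms by Benjamini–Hochberg
(default) or Bonferroni.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core_io import AnnotationSet

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "fisher_enrichment", "filter_significant"]


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's 2×2 counts and raw/adjusted p-values."""

    term_id: str
    description: str
    k: int  # study genes annotated to the term
    K: int  # background genes annotated to the term
    n: int  # effective study-set size (restricted to background)
    N: int  # background size
    p_raw: float
    p_adj: float

    def __post_init__(self) -> None:
        assert self.k <= min(self.n, self.K) and self.K <= self.N and self.n <= self.N
        assert self.p_adj >= self.p_raw - 1e-15


def fisher_enrichment(
    study: set[str], ann: AnnotationSet, correction: str = "bh"
) -> list[EnrichmentResult]:
    """Exact over-representation test of ``study`` against every term.

    Study genes outside the background are dropped (count logged).  Terms
    with no study gene are excluded from the output, but every term still
    counts toward the multiple-testing correction.  Results are sorted by
    adjusted p-value, then term id.
    """
    if correction not in ("bh", "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")
    effective = study & ann.background
    dropped = len(study) - len(effective)
    if dropped:
        logger.info("dropped %d study genes outside the background", dropped)
    if not effective:
        raise ValueError("study set has no genes in the background universe")

    N = len(ann.background)
    n = len(effective)
    term_ids = sorted(ann.terms)
    raw: list[float] = []
    counts: list[tuple[int, int]] = []
    for term_id in term_ids:
        _, genes = ann.terms[term_id]
        K = len(genes)
        k = len(effective & genes)
        counts.append((k, K))
        # survival function at k-1 gives the inclusive upper tail P(X >= k)
        raw.append(float(hypergeom.sf(k - 1, N, K, n)))

    method = "fdr_bh" if correction == "bh" else "bonferroni"
    _, adjusted, _, _ = multipletests(raw, method=method)

    results = [
        EnrichmentResult(
            term_id=term_id,
            description=ann.terms[term_id][0],
            k=k,
            K=K,
            n=n,
            N=N,
            p_raw=p,
            p_adj=min(1.0, float(q)),
        )
        for term_id, (k, K), p, q in zip(term_ids, counts, raw, adjusted)
        if k >= 1
    ]
    results.sort(key=lambda r: (r.p_adj, r.term_id))
    return results


def filter_significant(results: list[EnrichmentResult], alpha: float) -> list[EnrichmentResult]:
    """Keep results with adjusted p strictly below ``alpha``, order preserved."""
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    return [r for r in results if r.p_adj < alpha]
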