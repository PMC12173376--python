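"""Hypergeometric over-representation analysis and pathway enrichment.

Significance of an overlap of size k between a query of size n and a category
of size K inside a universe of size N is the upper tail P(X >= k) of
X ~ Hypergeometric(N, K, n).  One-sided enrichment only; depletion is never
tested.  Multiple-testing adjustment is Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .annotation_io import DiseaseGeneSet, GeneUniverse

logger = logging.getLogger("proteosig.enrichment")


@dataclass(frozen=True)
class EnrichmentRow:
    """One over-representation test: overlap k of query n with category K in universe N."""

    set_id: str
    category: str
    k: int
    K: int
    n: int
    N: int
    p: float
    fdr: Optional[float] = None

    def __post_init__(self):
        if not (0 <= self.k <= min(self.n, self.K) and self.K <= self.N and self.n <= self.N):
            raise ValueError(f"inconsistent counts k={self.k} K={self.K} n={self.n} N={self.N}")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p out of range: {self.p}")
        if self.fdr is not None and self.fdr < self.p - 1e-15:
            raise ValueError("fdr below raw p")

    @property
    def neg_log10_p(self) -> float:
        return float(-np.log10(self.p))


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n) via the survival function.

    ``K`` is the category size, ``n`` the query size, ``N`` the universe size.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K,n <= N; got K={K} n={n} N={N}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"need 0 <= k <= min(n, K); got k={k} K={K} n={n}")
    # sf(k-1) = P(X > k-1) = P(X >= k); exact in scipy for modest N
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def overrepresentation_table(
    query_sets: Sequence[DiseaseGeneSet],
    categories: Mapping[str, frozenset[str] | set[str]],
    universe: GeneUniverse,
) -> list[EnrichmentRow]:
    """One row per (query set, category), counting only genes inside the universe.

    Queries and categories are intersected with the universe before counting;
    a query entirely outside the universe signals a symbol-space mismatch and
    raises.  Genes dropped from a query are logged.
    """
    uni = set(universe.genes)
    N = len(uni)
    cat_in = {name: set(members) & uni for name, members in categories.items()}
    rows: list[EnrichmentRow] = []
    for qs in query_sets:
        q = qs.gene_set() & uni
        if not q:
            raise ValueError(f"query set {qs.disease_id!r} is disjoint from the universe")
        dropped = len(qs.gene_set()) - len(q)
        if dropped:
            logger.warning("%s: %d gene(s) outside the universe dropped", qs.disease_id, dropped)
        for name, members in cat_in.items():
            k = len(q & members)
            rows.append(EnrichmentRow(
                set_id=qs.disease_id, category=name, k=k, K=len(members),
                n=len(q), N=N, p=hypergeom_upper_tail(k, len(members), len(q), N)))
    return rows


def rows_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    """Serialize enrichment rows to a DataFrame with a -log10(p) column."""
    return pd.DataFrame([{
        "set_id": r.set_id, "category": r.category, "k": r.k, "K": r.K,
        "n": r.n, "N": r.N, "p": r.p, "fdr": r.fdr,
        "neg_log10_p": r.neg_log10_p} for r in rows])


def pathway_enrichment(
    up_genes: set[str] | frozenset[str],
    down_genes: set[str] | frozenset[str],
    pathway_db: Mapping[str, frozenset[str] | set[str]],
    universe: GeneUniverse,
    fdr_cut: float = 0.05,
    min_genes: int = 3,
    top_m: int = 10,
) -> tuple[list[EnrichmentRow], list[EnrichmentRow]]:
    """Direction-split pathway enrichment of a signed query.

    Per direction: hypergeometric p per pathway, BH across pathways, keep
    pathways with FDR < ``fdr_cut`` AND overlap >= ``min_genes`` (more than
    two genes), return up to ``top_m`` ranked by (fdr, p, name).
    """
    if not pathway_db:
        raise ValueError("pathway_db is empty")
    uni = set(universe.genes)
    N = len(uni)
    cats = {name: set(m) & uni for name, m in pathway_db.items()}

    def one_direction(genes, tag):
        q = set(genes) & uni
        n = len(q)
        if n == 0:
            return []
        names = list(cats)
        raw = []
        ks = []
        for name in names:
            k = len(q & cats[name])
            ks.append(k)
            raw.append(hypergeom_upper_tail(k, len(cats[name]), n, N))
        fdr = bh_adjust(raw)
        kept = [EnrichmentRow(set_id=tag, category=name, k=k, K=len(cats[name]),
                              n=n, N=N, p=p, fdr=f)
                for name, k, p, f in zip(names, ks, raw, fdr)
                if f < fdr_cut and k >= min_genes]
        kept.sort(key=lambda r: (r.fdr, r.p, r.category))
        return kept[:top_m]

    return one_direction(up_genes, "up"), one_direction(down_genes, "down")
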