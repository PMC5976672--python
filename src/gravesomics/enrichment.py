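"""Hypergeometric pathway over-representation analysis.

For a query gene list of size n drawn from a universe of N annotated genes,
a pathway with M member genes and k overlapping query genes is scored by
the upper-tail hypergeometric probability

    p = 1 - sum_{i=0}^{k-1} C(M,i) C(N-M, n-i) / C(N, n)

i.e. the chance of at least k hits under random assignment. k = 0 gives
p = 1 exactly (the empty-sum convention). Raw p-values are reported by
default (Benjamini-Hochberg adjustment optional).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import PathwayAnnotation, ValidationError


@dataclass
class EnrichmentResult:
    pathway_id: str
    description: str
    N: int   # universe size
    M: int   # pathway size within the universe
    n: int   # query size
    k: int   # overlap
    p_value: float

    def __post_init__(self) -> None:
        if self.k > min(self.M, self.n):
            raise ValidationError("overlap cannot exceed pathway or query size")
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError("p-value must lie in (0, 1]")


def hypergeom_pvalue(N: int, M: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N, M, n); k = 0 gives 1."""
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, M, n))


def hypergeom_enrich(query_genes: set[str],
                     annotation: list[PathwayAnnotation],
                     universe: set[str] | None = None,
                     adjust: bool = False) -> list[EnrichmentResult]:
    """Score every pathway against the query; results sorted by p ascending.

    The universe defaults to the union of all annotated genes. Query genes
    outside the universe are dropped with a warning; pathway gene sets are
    intersected with the universe before M is counted.
    """
    if universe is None:
        universe = set().union(*(p.gene_symbols for p in annotation))
    if not universe:
        raise ValidationError("empty gene universe")
    stray = set(query_genes) - universe
    if stray:
        warnings.warn(
            f"{len(stray)} query genes absent from the universe were dropped",
            stacklevel=2,
        )
    query = set(query_genes) & universe
    N, n = len(universe), len(query)
    results = []
    for pw in annotation:
        members = pw.gene_symbols & universe
        if not members:
            continue
        k = len(query & members)
        results.append(EnrichmentResult(pw.pathway_id, pw.description, N,
                                        len(members), n, k,
                                        hypergeom_pvalue(N, len(members), n,
                                                         k)))
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    if adjust and results:
        adj = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, q in zip(results, adj):
            r.p_value = float(min(max(q, r.p_value), 1.0))
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "pathway_id": r.pathway_id, "description": r.description,
        "universe_N": r.N, "pathway_M": r.M, "query_n": r.n, "overlap_k": r.k,
        "p_value": r.p_value,
    } for r in results])
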