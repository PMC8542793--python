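"""Expression signatures and gene-set statistics.

A per-sample cell-cycle index from an eight-gene signature (mean z-score),
ECDF/KS comparisons of index values between time points, a classic
unweighted running-sum enrichment score with a permutation p-value, and the
hypergeometric over-representation test against GMT gene-set collections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .core_io import ExpressionMatrix
from .popde import KSResult, bh_fdr, ks_compare

__all__ = [
    "CELL_CYCLE_SIGNATURE",
    "SignatureIndex",
    "EnrichmentScore",
    "cellcycle_index",
    "ecdf_ks",
    "enrichment_score",
    "ora_test",
]

#: Eight-gene cell-cycle expression signature (mouse symbols).
CELL_CYCLE_SIGNATURE = ("Mki67", "Rb1", "Hist1h2ae", "Ccnb1", "Cbx3", "Gapdh", "Ccnb2", "E2f1")


@dataclass
class SignatureIndex:
    """Per-sample signature index (z-score units) with bookkeeping of the
    signature genes that were present, and those that were missing, in the
    expression matrix."""

    index: pd.Series
    signature_genes: list[str]
    present_genes: list[str]
    missing_genes: list[str]


@dataclass
class EnrichmentScore:
    es: float
    p: float
    n_hits: int
    n_perm: int


def cellcycle_index(
    em: ExpressionMatrix, signature: Sequence[str] = CELL_CYCLE_SIGNATURE
) -> SignatureIndex:
    """Mean z-score of the signature genes, per sample.

    Every present signature gene is z-scored across samples (sample standard
    deviation, n−1); the index is the per-sample mean of the z-scores.
    Genes with zero variance contribute 0; missing genes are reported, never
    silently dropped.  Matching is case-insensitive.
    """
    lower = {}
    for g in em.gene_ids:
        lower.setdefault(str(g).lower(), g)
    present, missing = [], []
    for g in signature:
        (present if str(g).lower() in lower else missing).append(g)
    if not present:
        raise ValueError("no signature gene is present in the expression matrix")
    rows = em.values.loc[[lower[str(g).lower()] for g in present]].to_numpy(dtype=float)
    means = rows.mean(axis=1, keepdims=True)
    sds = rows.std(axis=1, ddof=1, keepdims=True)
    z = np.where(sds > 0, (rows - means) / np.where(sds > 0, sds, 1.0), 0.0)
    index = pd.Series(z.mean(axis=0), index=em.sample_ids, name="cellcycle_index")
    return SignatureIndex(
        index=index, signature_genes=list(signature), present_genes=present, missing_genes=missing
    )


#: Directional two-sample KS comparison (shared with the DE module).
ecdf_ks = ks_compare


def running_sum(ranked_gene_ids: Sequence[str], gene_set: Iterable[str]) -> np.ndarray:
    """Unweighted enrichment running sum along a ranked gene list.

    Hits increment by ``1/m`` and misses decrement by ``1/(N - m)`` where
    ``m`` is the number of hits in the list of length ``N``.
    """
    ranked = list(ranked_gene_ids)
    if len(set(ranked)) != len(ranked):
        raise ValueError("ranked gene list contains duplicates")
    hits = np.array([g in set(gene_set) for g in ranked], dtype=bool)
    m = int(hits.sum())
    n_total = len(ranked)
    if m == 0:
        raise ValueError("the gene set does not overlap the ranked list")
    if m == n_total:
        # degenerate: every gene is a hit; the sum climbs straight to 1
        return np.cumsum(np.full(n_total, 1.0 / m))
    steps = np.where(hits, 1.0 / m, -1.0 / (n_total - m))
    return np.cumsum(steps)


def enrichment_score(
    ranked_gene_ids: Sequence[str],
    gene_set: Iterable[str],
    n_perm: int = 999,
    seed: int = 0,
) -> EnrichmentScore:
    """Signed maximum deviation of the unweighted running sum.

    The score equals the signed sup-difference between the ECDFs of the hit
    and non-hit rank positions (a two-sample KS-type statistic).  The
    p-value is from gene-label permutations: random hit sets of the same
    size, two-sided on |ES|, with the add-one correction
    ``(1 + #{|ES_perm| >= |ES|}) / (n_perm + 1)``.
    """
    ranked = list(ranked_gene_ids)
    rs = running_sum(ranked, gene_set)
    es = float(rs[np.argmax(np.abs(rs))])
    m = int(sum(g in set(gene_set) for g in ranked))
    n_total = len(ranked)
    if m == n_total:
        return EnrichmentScore(es=1.0, p=1.0, n_hits=m, n_perm=0)
    rng = np.random.default_rng(seed)
    inc, dec = 1.0 / m, -1.0 / (n_total - m)
    count = 0
    for _ in range(n_perm):
        hit_pos = rng.choice(n_total, size=m, replace=False)
        steps = np.full(n_total, dec)
        steps[hit_pos] = inc
        perm_rs = np.cumsum(steps)
        if np.max(np.abs(perm_rs)) >= abs(es) - 1e-12:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return EnrichmentScore(es=es, p=p, n_hits=m, n_perm=n_perm)


def ora_test(
    query_genes: Iterable[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe: Iterable[str],
    min_count: int = 3,
    max_fdr: float = 0.2,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in each gene set.

    For each set, the overlap ``k`` of the query (size ``n``) with the
    set-within-universe (size ``K``, universe size ``N``) is tested with the
    upper-tail hypergeometric probability ``P(X >= k)``; the expectation by
    chance is ``n K / N``.  P-values are BH-adjusted across sets, and the
    reporting filter (``overlap_count >= min_count`` and ``fdr < max_fdr``)
    is emitted as a boolean column — no row is dropped.
    """
    uni = set(universe)
    query = set(query_genes)
    offenders = sorted(query - uni)
    if offenders:
        raise ValueError(f"query genes outside the universe: {offenders[:10]}")
    n = len(query)
    n_uni = len(uni)
    rows = []
    for term, members in gene_sets.items():
        inset = set(members) & uni
        overlap = sorted(query & inset)
        k = len(overlap)
        big_k = len(inset)
        p = float(hypergeom.sf(k - 1, n_uni, big_k, n)) if big_k else 1.0
        rows.append(
            {
                "term": term,
                "set_size": big_k,
                "overlap_count": k,
                "expected": n * big_k / n_uni if n_uni else 0.0,
                "p": min(p, 1.0),
                "overlap_genes": ";".join(overlap),
            }
        )
    result = pd.DataFrame(rows)
    if len(result):
        result["fdr"] = bh_fdr(result["p"].to_numpy())
        result["flagged"] = (result["overlap_count"] >= min_count) & (result["fdr"] < max_fdr)
        result = result.sort_values("p", kind="mergesort").reset_index(drop=True)
    return result
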