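"""Differential expression at the mixture and sub-population level.

Mixture-level contrasts use a per-gene two-group linear model (ordinary,
unmoderated t-statistics).  Population-specific contrasts follow the
reference-signal regression idea of population-specific expression analysis
(PSEA): a per-population reference signal is built from that population's
marker genes, and each gene is regressed on the reference plus its
interaction with the treatment indicator — the interaction coefficient is
the population-specific treatment effect.  Fold-change distributions across
contrasts are compared with two-sample Kolmogorov–Smirnov statistics, and
treatment responses with Pearson correlations of the log fold-changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix, linear_values
from .cam_deconv import MarkerSet, _marker_gene_map

__all__ = [
    "DEResult",
    "ReferenceSignals",
    "KSResult",
    "bh_fdr",
    "mixture_de",
    "psea_reference",
    "psea_de",
    "ks_compare",
    "response_correlation",
    "topn_foldchange_ks",
]


@dataclass
class DEResult:
    """Per-gene differential-expression table for one contrast.

    ``table`` columns: ``log_fc`` (log2), ``t_stat``, ``p``, ``fdr`` and,
    for population-scope results, ``lfc_defined`` flagging genes whose
    fold-change could be expressed on the log scale.  ``scope`` is
    ``"mixture"`` or the population label.
    """

    table: pd.DataFrame
    contrast: tuple[str, str]
    scope: str

    @property
    def log_fc(self) -> pd.Series:
        return self.table["log_fc"]


@dataclass
class ReferenceSignals:
    """Samples × K per-population reference signals built from markers."""

    values: pd.DataFrame
    built_from: MarkerSet


class KSResult(NamedTuple):
    d_plus: float   # sup_t F_x(t) - F_y(t)
    d_minus: float  # sup_t F_y(t) - F_x(t)
    d: float
    p: float        # asymptotic two-sided p for D
    p_plus: float   # one-sided p for D+
    p_minus: float  # one-sided p for D-


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _two_level_groups(
    group: Sequence[str], treatment: str | None, control: str | None
) -> tuple[np.ndarray, str, str]:
    labels = np.asarray(list(group))
    levels = pd.unique(labels)
    if treatment is None or control is None:
        if len(levels) != 2:
            raise ValueError(
                f"group must have exactly two levels when treatment/control are not named, got {list(levels)}"
            )
        control, treatment = levels[0], levels[1]
    mask = np.isin(labels, [treatment, control])
    if not mask.all():
        raise ValueError(f"samples with labels outside the contrast: {set(labels[~mask])}")
    return labels == treatment, str(treatment), str(control)


def mixture_de(
    em: ExpressionMatrix,
    group: Sequence[str],
    treatment: str | None = None,
    control: str | None = None,
) -> DEResult:
    """Per-gene two-group contrast on the mixture expression.

    Ordinary least squares of expression on a treatment indicator, which for
    a two-level factor is the pooled-variance two-sample t-test:
    ``log_fc`` is the group-mean difference (log2 units when the input is on
    a log2 scale), the t-statistic uses the residual degrees of freedom, and
    p-values are BH-adjusted across genes.  Genes with zero residual
    variance get t = 0, p = 1 when the means agree.
    """
    tmask, treatment, control = _two_level_groups(group, treatment, control)
    n1, n0 = int(tmask.sum()), int((~tmask).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError(f"need >= 2 samples per group, got {n1} treated / {n0} control")
    V = em.values.to_numpy(dtype=float)
    x1, x0 = V[:, tmask], V[:, ~tmask]
    m1, m0 = x1.mean(axis=1), x0.mean(axis=1)
    v1, v0 = x1.var(axis=1, ddof=1), x0.var(axis=1, ddof=1)
    df = n1 + n0 - 2
    sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    lfc = m1 - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), np.where(lfc == 0, 0.0, np.inf * np.sign(lfc)))
    p = np.where(np.isinf(t), 0.0, 2.0 * t_dist.sf(np.abs(np.where(np.isinf(t), 0.0, t)), df))
    table = pd.DataFrame(
        {"log_fc": lfc, "t_stat": t, "p": p, "fdr": bh_fdr(p)}, index=em.values.index
    )
    return DEResult(table=table, contrast=(treatment, control), scope="mixture")


def psea_reference(em: ExpressionMatrix, markers: MarkerSet) -> ReferenceSignals:
    """Build per-population reference signals from marker expression.

    Each marker gene's linear-scale expression is scaled to unit mean across
    samples; the population reference is the per-sample mean of its scaled
    markers.  The reference is therefore invariant to rescaling any single
    marker and equals 1 for markers constant across samples.
    """
    X = linear_values(em)
    cols = {}
    for pop in markers.populations:
        genes = markers.genes(pop)
        matched = _marker_gene_map(em, genes)
        rows = [matched[g] for g in genes if g in matched]
        if not rows:
            raise ValueError(f"population {pop!r} has no marker present in the matrix")
        M = X.loc[rows].to_numpy(dtype=float)
        means = M.mean(axis=1)
        ok = means > 0
        if not ok.any():
            raise ValueError(f"population {pop!r} markers are all zero")
        cols[pop] = (M[ok] / means[ok, None]).mean(axis=0)
    values = pd.DataFrame(cols, index=em.sample_ids)
    return ReferenceSignals(values=values, built_from=markers)


def psea_de(
    em: ExpressionMatrix,
    refs: ReferenceSignals,
    group: Sequence[str],
    population: str,
    treatment: str | None = None,
    control: str | None = None,
) -> DEResult:
    """Population-specific contrast via reference-signal regression.

    Per gene, ordinary least squares of
    ``y = intercept + β ref_p + γ (ref_p × treated)``; the reported
    statistic is the t-test on the interaction γ (the population-specific
    treatment effect) with ``n - 3`` residual degrees of freedom.
    ``log_fc = log2((β + γ) / β)`` when both β and β + γ are positive;
    otherwise the fold-change is flagged undefined (``lfc_defined`` False).
    """
    if population not in refs.values.columns:
        raise ValueError(f"unknown population {population!r}")
    r = refs.values.loc[list(em.sample_ids), population].to_numpy(dtype=float)
    tmask, treatment, control = _two_level_groups(group, treatment, control)
    if np.ptp(r[tmask]) == 0 or np.ptp(r[~tmask]) == 0:
        raise ValueError(
            f"reference signal of {population!r} is constant within a group; "
            "the interaction is not identifiable"
        )
    n = r.shape[0]
    X = np.column_stack([np.ones(n), r, r * tmask])
    if np.linalg.cond(X) > 1e10:
        raise ValueError("design matrix is numerically singular")
    Y = em.values.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # 3 × genes
    resid = Y.T - X @ coef
    dof = n - 3
    s2 = (resid ** 2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se_gamma = np.sqrt(s2 * xtx_inv[2, 2])
    beta, gamma = coef[1], coef[2]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se_gamma > 0, gamma / np.where(se_gamma > 0, se_gamma, 1.0),
                     np.where(gamma == 0, 0.0, np.inf * np.sign(gamma)))
    p = np.where(np.isinf(t), 0.0, 2.0 * t_dist.sf(np.abs(np.where(np.isinf(t), 0.0, t)), dof))
    defined = (beta > 0) & (beta + gamma > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.where(defined, np.log2(np.where(defined, (beta + gamma) / np.where(beta > 0, beta, 1.0), 1.0)), np.nan)
    table = pd.DataFrame(
        {
            "log_fc": lfc,
            "beta": beta,
            "gamma": gamma,
            "t_stat": t,
            "p": p,
            "fdr": bh_fdr(p),
            "lfc_defined": defined,
        },
        index=em.values.index,
    )
    return DEResult(table=table, contrast=(treatment, control), scope=population)


def ks_compare(x: Sequence[float], y: Sequence[float]) -> KSResult:
    """Directional two-sample Kolmogorov–Smirnov comparison.

    ``D⁺ = sup_t (F_x - F_y)``, ``D⁻ = sup_t (F_y - F_x)``,
    ``D = max(D⁺, D⁻)``.  The two-sided p-value is the asymptotic
    Kolmogorov distribution at ``√(nm/(n+m)) D``; the one-sided p-values use
    the exponential tail ``exp(-2 (nm/(n+m)) D_dir²)``.
    """
    xa = np.sort(np.asarray(x, dtype=float))
    ya = np.sort(np.asarray(y, dtype=float))
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.concatenate([xa, ya])
    fx = np.searchsorted(xa, grid, side="right") / xa.size
    fy = np.searchsorted(ya, grid, side="right") / ya.size
    d_plus = float(np.max(fx - fy))
    d_minus = float(np.max(fy - fx))
    d = max(d_plus, d_minus, 0.0)
    en = np.sqrt(xa.size * ya.size / (xa.size + ya.size))
    from scipy.stats import ks_2samp

    p = float(ks_2samp(xa, ya, method="asymp").pvalue)
    p_plus = float(np.exp(-2.0 * en ** 2 * max(d_plus, 0.0) ** 2))
    p_minus = float(np.exp(-2.0 * en ** 2 * max(d_minus, 0.0) ** 2))
    return KSResult(d_plus=d_plus, d_minus=d_minus, d=d, p=p, p_plus=p_plus, p_minus=p_minus)


def response_correlation(
    de_results: Sequence[DEResult], labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pearson correlation matrix of log fold-changes across contrasts.

    Results are aligned on their shared gene universe (at least 3 genes).
    """
    if len(de_results) < 2:
        raise ValueError("need at least two DE results")
    if labels is None:
        labels = [f"{r.contrast[0]}|{r.scope}" for r in de_results]
    shared = de_results[0].table.index
    for r in de_results[1:]:
        shared = shared.intersection(r.table.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need at least 3")
    mat = pd.DataFrame(
        {lab: r.table.loc[shared, "log_fc"] for lab, r in zip(labels, de_results)}
    )
    return mat.corr(method="pearson")


def topn_foldchange_ks(
    mixture: DEResult, other: DEResult, top_n: int = 500
) -> KSResult:
    """KS comparison of fold-changes over the top mixture-ranked genes.

    The ``top_n`` genes with the smallest mixture p-values define the gene
    list; the other contrast's log fold-changes (x) are compared with the
    mixture's (y), so ``D⁻`` measures how much the other contrast's
    fold-changes exceed the mixture's in distribution.
    """
    ranked = mixture.table.sort_values("p").index[:top_n]
    ranked = [g for g in ranked if g in other.table.index]
    return ks_compare(
        other.table.loc[ranked, "log_fc"].to_numpy(),
        mixture.table.loc[ranked, "log_fc"].to_numpy(),
    )
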