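"""Stability and cross-dataset validation of the deconvolution.

Marker resampling quantifies how sensitive the fraction estimates are to the
particular marker genes used: random marker subsets of a fixed size are
drawn repeatedly, fractions are re-estimated, and the per-(sample,
population) coefficient of variation and bias against the full-set estimate
are reported.  Cross-dataset agreement is measured by Spearman correlation
between population profiles on shared genes, with an optimal population
matching utility for comparisons against a known truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import spearmanr

from .core_io import ExpressionMatrix
from .cam_deconv import FractionMatrix, MarkerSet, PopulationProfiles, estimate_fractions

__all__ = [
    "ResampleResult",
    "resample_markers",
    "profile_correlation",
    "match_columns",
    "fraction_mae",
]


@dataclass
class ResampleResult:
    """Per-(sample, population) stability of resampled fraction estimates.

    ``per_pair`` has columns ``sample_id, population, full_fraction,
    mean_fraction, cv_percent, bias``.  ``cv_percent`` is the standard
    deviation over iterations divided by the mean, as a percentage;
    ``bias`` is the iteration mean minus the full-marker-set estimate.
    """

    per_pair: pd.DataFrame
    full: FractionMatrix
    set_size: int
    n_iter: int
    seed: int

    @property
    def median_cv_percent(self) -> float:
        return float(self.per_pair["cv_percent"].median())

    @property
    def max_abs_bias(self) -> float:
        return float(self.per_pair["bias"].abs().max())


def resample_markers(
    em: ExpressionMatrix,
    markers: MarkerSet,
    set_size: int | str = "smallest",
    n_iter: int = 100,
    seed: int = 0,
) -> ResampleResult:
    """Re-estimate fractions with random marker subsets of a fixed size.

    Each iteration draws ``set_size`` markers per population without
    replacement and re-runs the standardized-averaging fraction estimate.
    ``set_size="smallest"`` resolves to the smallest population's marker
    count, isolating the effect of marker set size and of outlying markers.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be at least 2 (variance is undefined otherwise)")
    counts = markers.counts()
    if set_size == "smallest":
        size = min(counts.values())
    else:
        size = int(set_size)
    too_small = [pop for pop, c in counts.items() if c < size]
    if too_small:
        raise ValueError(f"set_size={size} exceeds the marker count of population(s) {too_small}")
    full = estimate_fractions(em, markers)
    rng = np.random.default_rng(seed)
    pops = markers.populations
    draws = np.empty((n_iter, full.values.shape[0], full.values.shape[1]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # subsets inherit any missing-marker warnings
        for it in range(n_iter):
            subset = {
                pop: list(rng.choice(markers.genes(pop), size=size, replace=False))
                for pop in pops
            }
            draws[it] = estimate_fractions(em, markers.subset(subset)).values.to_numpy()
    means = draws.mean(axis=0)
    sds = draws.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(sds == 0, 0.0, sds / np.where(means > 0, means, np.nan))
    bias = means - full.values.to_numpy()
    rows = []
    for i, sid in enumerate(full.sample_ids):
        for j, pop in enumerate(full.population_labels):
            rows.append(
                {
                    "sample_id": sid,
                    "population": pop,
                    "full_fraction": full.values.iloc[i, j],
                    "mean_fraction": means[i, j],
                    "cv_percent": 100.0 * cv[i, j],
                    "bias": bias[i, j],
                }
            )
    return ResampleResult(
        per_pair=pd.DataFrame(rows), full=full, set_size=size, n_iter=n_iter, seed=seed
    )


def profile_correlation(
    a: PopulationProfiles, b: PopulationProfiles
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman correlation of population profiles on the shared genes.

    Returns the K_a × K_b correlation matrix and the matching two-sided
    p-value matrix (t-approximation).  At least 10 shared genes are
    required.
    """
    shared = [g for g in a.values.index if g in set(b.values.index)]
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared genes; need at least 10")
    av = a.values.loc[shared]
    bv = b.values.loc[shared]
    r = pd.DataFrame(index=av.columns, columns=bv.columns, dtype=float)
    p = r.copy()
    for ca in av.columns:
        for cb in bv.columns:
            res = spearmanr(av[ca], bv[cb])
            r.loc[ca, cb] = float(res.statistic)
            p.loc[ca, cb] = float(res.pvalue)
    return r, p


def match_columns(a: pd.DataFrame, b: pd.DataFrame, method: str = "pearson") -> dict[str, str]:
    """Optimal one-to-one column matching by maximum total correlation.

    Hungarian assignment on the pairwise column correlations of the two
    frames (aligned on their shared index).  Used to resolve the label
    permutation between an estimated decomposition and a ground truth.
    """
    shared = a.index.intersection(b.index)
    corr = pd.DataFrame(index=a.columns, columns=b.columns, dtype=float)
    for ca in a.columns:
        for cb in b.columns:
            corr.loc[ca, cb] = a.loc[shared, ca].corr(b.loc[shared, cb], method=method)
    cost = -corr.to_numpy(dtype=float)
    cost = np.nan_to_num(cost, nan=1.0)
    ai, bi = linear_sum_assignment(cost)
    return {str(a.columns[i]): str(b.columns[j]) for i, j in zip(ai, bi)}


def fraction_mae(
    estimated: FractionMatrix, truth: FractionMatrix, mapping: dict[str, str] | None = None
) -> float:
    """Mean absolute error between fraction matrices after label matching."""
    if mapping is None:
        mapping = match_columns(estimated.values, truth.values)
    est = estimated.values[list(mapping)].to_numpy(dtype=float)
    tru = truth.values.loc[estimated.sample_ids, [mapping[c] for c in mapping]].to_numpy(dtype=float)
    return float(np.abs(est - tru).mean())
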