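"""Sample-level dissimilarity analysis.

Euclidean distances between samples on the transformed expression scale,
classical (Torgerson) multidimensional scaling with an explicit
goodness-of-fit statistic, and a Welch t-test comparing within-stage to
between-stage pairwise distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import ttest_ind

from .core_io import ExpressionMatrix

__all__ = ["Ordination", "StageTest", "sample_distances", "classical_mds", "stage_distance_test"]


@dataclass
class Ordination:
    """A k-dimensional metric embedding of the samples.

    ``goodness_of_fit`` is the sum of the k largest eigenvalues of the
    double-centred squared-distance matrix divided by the sum of the
    absolute values of all eigenvalues (negative eigenvalues count with
    their magnitude in the denominator).
    """

    coordinates: pd.DataFrame  # samples × k
    eigenvalues: np.ndarray  # all eigenvalues, descending
    goodness_of_fit: float
    k: int


class StageTest(NamedTuple):
    t: float
    p: float
    n_within: int
    n_between: int


def sample_distances(em: ExpressionMatrix) -> pd.DataFrame:
    """Euclidean distances between samples over the gene dimensions.

    Expects transformed values (log expression or intensities); raw counts
    should be log-CPM transformed first.
    """
    if em.value_scale == "counts":
        raise ValueError("sample_distances expects log_expr or intensity values, not raw counts")
    if em.n_samples < 2:
        raise ValueError("need at least two samples")
    D = squareform(pdist(em.values.to_numpy(dtype=float).T, metric="euclidean"))
    return pd.DataFrame(D, index=em.sample_ids, columns=em.sample_ids)


def classical_mds(d: pd.DataFrame | np.ndarray, k: int = 2) -> Ordination:
    """Torgerson scaling of a distance matrix.

    Eigendecomposition of ``B = -J D² J / 2`` (``J`` the centring matrix);
    coordinates are the top-k eigenvectors scaled by the square roots of
    their eigenvalues, so pairwise distances of the embedding approximate
    ``d``.
    """
    frame = d if isinstance(d, pd.DataFrame) else pd.DataFrame(np.asarray(d, dtype=float))
    D = frame.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise ValueError("distance matrix must have a zero diagonal")
    if k < 1:
        raise ValueError("k must be at least 1")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals[0]), 1.0) * 1e-12
    n_pos = int((evals > tol).sum())
    if k > n_pos:
        raise ValueError(f"k={k} exceeds the number of positive eigenvalues ({n_pos})")
    coords = evecs[:, :k] * np.sqrt(evals[:k])[None, :]
    gof = float(evals[:k].sum() / np.abs(evals).sum())
    coordinates = pd.DataFrame(
        coords, index=frame.index, columns=[f"dim{i + 1}" for i in range(k)]
    )
    return Ordination(coordinates=coordinates, eigenvalues=evals, goodness_of_fit=gof, k=k)


def stage_distance_test(
    d: pd.DataFrame,
    stages: Sequence[str],
    focal: str,
    other: str,
) -> StageTest:
    """Welch t-test of within-focal vs focal-to-other pairwise distances.

    Pairwise distances are treated as independent observations.  Positive t
    means the within-focal distances are larger than the focal-to-other
    distances.
    """
    labels = np.asarray(list(stages))
    if labels.shape[0] != d.shape[0]:
        raise ValueError("one stage label per sample is required")
    D = d.to_numpy(dtype=float)
    fi = np.flatnonzero(labels == focal)
    oi = np.flatnonzero(labels == other)
    within = [D[i, j] for a, i in enumerate(fi) for j in fi[a + 1:]]
    between = [D[i, j] for i in fi for j in oi]
    if len(within) < 2 or len(between) < 2:
        raise ValueError(
            f"need >= 2 within-focal and >= 2 focal-to-other pairs, got {len(within)} and {len(between)}"
        )
    if np.var(within) == 0 and np.var(between) == 0:
        # degenerate but well-defined: identical constants compare as equal
        t = 0.0 if np.mean(within) == np.mean(between) else np.inf * np.sign(
            np.mean(within) - np.mean(between))
        p = 1.0 if t == 0 else 0.0
        return StageTest(t=float(t), p=float(p), n_within=len(within), n_between=len(between))
    res = ttest_ind(within, between, equal_var=False)
    return StageTest(t=float(res.statistic), p=float(res.pvalue),
                     n_within=len(within), n_between=len(between))
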