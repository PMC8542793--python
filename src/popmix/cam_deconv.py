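"""Convex-analysis-of-mixtures deconvolution of bulk expression.

The mixing model is ``X = S · Aᵀ`` on the linear expression scale: ``X`` is
the observed genes × samples matrix, ``S`` the non-negative genes × K
population-specific profiles and ``A`` the samples × K mixing fractions on
the probability simplex.  When each gene's expression vector is scaled to
unit sum across samples, the scatter of the scaled vectors is a rotated and
compressed simplex whose corners are occupied by genes expressed in a single
sub-population — the population markers.  The pipeline therefore

1. row-normalizes the expressed genes (:func:`project_simplex`),
2. locates K simplex corners among k-means cluster centres
   (:func:`find_corners`),
3. scores genes by the one-vs-everyone fold-change and keeps those whose
   bootstrap lower confidence bound is positive (:func:`ove_fold_change`,
   :func:`select_markers`),
4. estimates mixing fractions from the markers by standardized averaging
   (:func:`estimate_fractions`), and
5. recovers population profiles per gene by non-negative least squares
   (:func:`estimate_profiles`).

:func:`deconvolve` chains the stages; given a precomputed marker set it runs
in supervised mode (fractions and profiles only), which is how markers
learned on one dataset are transferred to another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.cluster import KMeans

from .core_io import ExpressionMatrix, linear_values

__all__ = [
    "FractionMatrix",
    "PopulationProfiles",
    "MarkerRecord",
    "MarkerSet",
    "SimplexProjection",
    "CornerResult",
    "DeconvolutionResult",
    "project_simplex",
    "find_corners",
    "corner_candidates",
    "ove_fold_change",
    "select_markers",
    "estimate_fractions",
    "estimate_profiles",
    "deconvolve",
    "reconstruction_error",
    "elbow_report",
]

DEFAULT_PSEUDOCOUNT = 1e-8
ROW_SUM_TOL = 1e-9


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FractionMatrix:
    """Samples × K mixing fractions; every row lies on the probability simplex."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if (vals < -ROW_SUM_TOL).any() or (vals > 1 + ROW_SUM_TOL).any():
            raise ValueError("fractions must lie in [0, 1]")
        if not np.allclose(vals.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("fraction rows must sum to 1")

    @property
    def population_labels(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class PopulationProfiles:
    """Genes × K non-negative population-specific expression profiles."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValueError("profiles must be non-negative")
        if (vals.sum(axis=0) == 0).any():
            dead = [c for c, s in zip(self.values.columns, vals.sum(axis=0)) if s == 0]
            raise ValueError(f"all-zero population column(s): {dead}")

    @property
    def population_labels(self) -> list[str]:
        return list(self.values.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass(frozen=True)
class MarkerRecord:
    """A marker gene with its one-vs-everyone fold-change and the lower
    bootstrap confidence bound of its log fold-change (``None`` for marker
    lists supplied without statistics)."""

    gene: str
    ove_fc: float | None = None
    ci_lower: float | None = None


@dataclass
class MarkerSet:
    """Disjoint per-population marker gene lists."""

    assignments: dict[str, list[MarkerRecord]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for pop, records in self.assignments.items():
            for rec in records:
                if rec.gene in seen:
                    raise ValueError(
                        f"gene {rec.gene!r} assigned to both {seen[rec.gene]!r} and {pop!r}"
                    )
                seen[rec.gene] = pop
                if rec.ove_fc is not None and rec.ove_fc <= 1:
                    raise ValueError(f"marker {rec.gene!r} has OVE fold-change <= 1")
                if rec.ci_lower is not None and rec.ci_lower <= 0:
                    raise ValueError(f"marker {rec.gene!r} has non-positive CI lower bound")

    @property
    def populations(self) -> list[str]:
        return list(self.assignments)

    def genes(self, population: str) -> list[str]:
        return [rec.gene for rec in self.assignments[population]]

    def counts(self) -> dict[str, int]:
        return {pop: len(recs) for pop, recs in self.assignments.items()}

    def subset(self, genes_by_pop: Mapping[str, Sequence[str]]) -> "MarkerSet":
        keep = {pop: set(genes) for pop, genes in genes_by_pop.items()}
        return MarkerSet(
            {
                pop: [rec for rec in recs if rec.gene in keep.get(pop, set())]
                for pop, recs in self.assignments.items()
            }
        )

    @classmethod
    def from_lists(cls, genes_by_pop: Mapping[str, Sequence[str]]) -> "MarkerSet":
        return cls({pop: [MarkerRecord(g) for g in genes] for pop, genes in genes_by_pop.items()})

    # -- tabular round trip ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"population": pop, "gene": r.gene, "ove_fc": r.ove_fc, "ci_lower": r.ci_lower}
            for pop, recs in self.assignments.items()
            for r in recs
        ]
        return pd.DataFrame(rows, columns=["population", "gene", "ove_fc", "ci_lower"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MarkerSet":
        assignments: dict[str, list[MarkerRecord]] = {}
        has_stats = "ove_fc" in frame.columns
        for _, row in frame.iterrows():
            rec = MarkerRecord(
                gene=str(row["gene"]),
                ove_fc=float(row["ove_fc"]) if has_stats and pd.notna(row.get("ove_fc")) else None,
                ci_lower=float(row["ci_lower"]) if has_stats and pd.notna(row.get("ci_lower")) else None,
            )
            assignments.setdefault(str(row["population"]), []).append(rec)
        return cls(assignments)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "MarkerSet":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass
class SimplexProjection:
    """Row-normalized expressed genes: each kept gene's vector sums to one."""

    normalized: pd.DataFrame
    kept_gene_ids: list[str]
    filter_floor: float


@dataclass
class CornerResult:
    """Outcome of the simplex corner search."""

    corner_genes: dict[str, list[str]]
    corner_expression: pd.DataFrame  # samples × K mean linear expression of corner genes
    cluster_labels: pd.Series
    cluster_centers: np.ndarray
    selected_clusters: tuple[int, ...]
    score: float
    subset_scores: dict[tuple[int, ...], float] = field(default_factory=dict)


@dataclass
class DeconvolutionResult:
    fractions: FractionMatrix
    profiles: PopulationProfiles
    markers: MarkerSet
    corners: CornerResult | None
    reconstruction_error: float


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def project_simplex(em: ExpressionMatrix, floor: float | None = None) -> SimplexProjection:
    """Filter weakly expressed genes and scale each gene's vector to unit sum.

    Genes whose maximum linear expression across samples falls below
    ``floor`` are dropped; by default the floor is the 20th percentile of the
    per-gene maxima.  The remaining rows are divided by their sums, placing
    every gene on the sample simplex — the geometry in which population
    markers sit at the corners.
    """
    X = linear_values(em)
    maxima = X.max(axis=1)
    if floor is None:
        floor = float(np.percentile(maxima.to_numpy(), 20))
    kept = X.loc[maxima >= floor]
    if kept.shape[0] == 0:
        raise ValueError(f"expression floor {floor} removed every gene")
    sums = kept.sum(axis=1)
    positive = sums > 0
    if not positive.all():
        kept = kept.loc[positive]
        sums = sums.loc[positive]
    normalized = kept.div(sums, axis=0)
    return SimplexProjection(
        normalized=normalized, kept_gene_ids=list(normalized.index), filter_floor=float(floor)
    )


def _simplex_lstsq_residual(B: np.ndarray, c: np.ndarray, rho: float = 1e4) -> float:
    """Squared distance from point ``c`` to the convex hull of the columns of ``B``.

    Solved as non-negative least squares with the unit-sum constraint imposed
    through a heavily weighted auxiliary row (a standard NNLS device).
    """
    d, k = B.shape
    Baug = np.vstack([B, rho * np.ones((1, k))])
    caug = np.concatenate([c, [rho]])
    w, _ = nnls(Baug, caug)
    resid = c - B @ w
    return float(resid @ resid)


def find_corners(
    sp: SimplexProjection,
    k: int,
    n_clusters: int = 20,
    seed: int = 0,
    raw: pd.DataFrame | None = None,
) -> CornerResult:
    """Locate the K simplex corners among k-means cluster centres.

    The scaled gene vectors are grouped into ``n_clusters`` k-means clusters;
    every K-subset of the cluster centres is then scored by the total squared
    residual of projecting *all* centres onto the convex hull of the subset,
    and the minimizing subset is returned as the corner set.  Interior
    centres project onto the hull with zero residual only when the subset
    spans the simplex, which is what singles out the true corners.

    Parameters
    ----------
    raw
        Optional linear-scale expression of the kept genes, used to report
        each corner's mean raw expression per sample (seeds the first
        fraction estimate).  Defaults to the normalized vectors.
    """
    R = sp.normalized.to_numpy(dtype=float)
    n_genes = R.shape[0]
    if not (k <= n_clusters <= n_genes):
        raise ValueError(f"need K <= n_clusters <= kept genes, got {k}, {n_clusters}, {n_genes}")
    km = None
    for attempt in (seed, seed + 1):
        cand = KMeans(n_clusters=n_clusters, n_init=10, random_state=attempt).fit(R)
        if len(np.unique(cand.labels_)) == n_clusters:
            km = cand
            break
    if km is None:
        raise RuntimeError("k-means produced an empty cluster on two seeds")
    centers = km.cluster_centers_
    best_score = np.inf
    best_subset: tuple[int, ...] | None = None
    subset_scores: dict[tuple[int, ...], float] = {}
    for subset in combinations(range(n_clusters), k):
        B = centers[list(subset)].T
        score = sum(_simplex_lstsq_residual(B, centers[j]) for j in range(n_clusters))
        subset_scores[subset] = score
        if score < best_score:
            best_score = score
            best_subset = subset
    assert best_subset is not None
    labels = pd.Series(km.labels_, index=sp.normalized.index, name="cluster")
    raw_frame = raw if raw is not None else sp.normalized
    corner_genes: dict[str, list[str]] = {}
    corner_cols = {}
    for i, cluster in enumerate(best_subset):
        pop = f"C{i + 1}"
        members = list(labels.index[labels == cluster])
        corner_genes[pop] = members
        corner_cols[pop] = raw_frame.loc[members].mean(axis=0)
    corner_expression = pd.DataFrame(corner_cols)
    return CornerResult(
        corner_genes=corner_genes,
        corner_expression=corner_expression,
        cluster_labels=labels,
        cluster_centers=centers,
        selected_clusters=best_subset,
        score=best_score,
        subset_scores=subset_scores,
    )


def corner_candidates(
    sp: SimplexProjection, corners: CornerResult, dominance: float = 0.75
) -> dict[str, list[str]]:
    """Genes residing at the simplex extremities, per corner.

    Every kept gene's normalized vector is decomposed as a convex
    combination of the K corner centres (simplex-constrained least squares);
    a gene is a candidate marker of corner ``p`` when that corner dominates
    the decomposition (weight >= ``dominance``, i.e. all other populations
    together explain at most ``1 - dominance`` of the vector).  Genes in the
    simplex interior — shared genes, whose weights mirror the average mixing
    fractions — are excluded.  The default dominance of 0.75 assumes no
    population averages more than three quarters of the mixture across the
    sampled course.
    """
    B = corners.cluster_centers[list(corners.selected_clusters)].T
    rho = 1e4
    Baug = np.vstack([B, rho * np.ones((1, B.shape[1]))])
    labels = list(corners.corner_genes)
    out: dict[str, list[str]] = {pop: [] for pop in labels}
    R = sp.normalized.to_numpy(dtype=float)
    for gene, vec in zip(sp.normalized.index, R):
        w, _ = nnls(Baug, np.concatenate([vec, [rho]]))
        total = w.sum()
        if total <= 0:
            continue
        w = w / total
        p = int(np.argmax(w))
        if w[p] >= dominance:
            out[labels[p]].append(gene)
    return out


def ove_fold_change(
    profiles: PopulationProfiles | pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame:
    """One-vs-everyone fold-change of every gene in every population.

    ``OVE[g, p] = (S[g, p] + c) / (max_{q != p} S[g, q] + c)`` with
    pseudocount ``c`` guarding the exclusive-marker division by zero.  At
    most one population per gene can exceed 1.
    """
    frame = profiles.values if isinstance(profiles, PopulationProfiles) else profiles
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    S = frame.to_numpy(dtype=float)
    if S.shape[1] < 2:
        raise ValueError("OVE fold-change needs at least two populations")
    ove = _ove_array(S, pseudocount)
    return pd.DataFrame(ove, index=frame.index, columns=frame.columns)


def _ove_array(S: np.ndarray, pseudocount: float) -> np.ndarray:
    k = S.shape[1]
    ove = np.empty_like(S, dtype=float)
    for p in range(k):
        others = np.delete(S, p, axis=1).max(axis=1)
        ove[:, p] = (S[:, p] + pseudocount) / (others + pseudocount)
    return ove


def _nnls_profiles(A: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Row-wise non-negative least squares ``min_{s>=0} ||X[g] - A s||``.

    The unconstrained least-squares solution is computed for all genes at
    once; only rows with negative coefficients are re-solved with NNLS.
    """
    sol, *_ = np.linalg.lstsq(A, X.T, rcond=None)
    S = sol.T
    bad = np.flatnonzero((S < -1e-12).any(axis=1))
    for g in bad:
        S[g], _ = nnls(A, X[g])
    return np.clip(S, 0.0, None)


def estimate_profiles(em: ExpressionMatrix, fractions: FractionMatrix) -> PopulationProfiles:
    """Recover population profiles gene by gene with non-negative least squares.

    On the linear scale, each gene's expression across samples is regressed
    on the mixing fractions under a non-negativity constraint:
    ``min_{s >= 0} sum_s (X[g, s] - sum_p s_p A[s, p])²``.
    """
    X = linear_values(em)
    A = fractions.values.loc[list(X.columns)].to_numpy(dtype=float)
    n, k = A.shape
    if n < k:
        raise ValueError(f"need at least K={k} samples, got {n}")
    if np.linalg.matrix_rank(A) < k:
        raise ValueError("fraction matrix is rank deficient; profiles are not identifiable")
    S = _nnls_profiles(A, X.to_numpy(dtype=float))
    return PopulationProfiles(
        values=pd.DataFrame(S, index=X.index, columns=fractions.values.columns)
    )


def _marker_gene_map(em: ExpressionMatrix, genes: Sequence[str]) -> dict[str, str]:
    """Case-insensitive gene symbol lookup: marker id -> matrix row id."""
    lower = {}
    for g in em.gene_ids:
        lower.setdefault(str(g).lower(), g)
    return {g: lower[str(g).lower()] for g in genes if str(g).lower() in lower}


def estimate_fractions(
    em: ExpressionMatrix, markers: MarkerSet | Mapping[str, Sequence[str]]
) -> FractionMatrix:
    """Estimate mixing fractions from marker expression by standardized averaging.

    Per marker gene the linear-scale expression vector is scaled to unit sum
    across samples (this is the standardization that makes markers of very
    different magnitudes comparable); the scaled vectors are averaged within
    each population.  The per-gene scaling leaves each population's signal
    determined only up to a column scale, so the scales are resolved by
    non-negative least squares against the simplex constraint (choose
    ``c >= 0`` minimizing ``||R c - 1||``, i.e. make the per-sample totals as
    close to one as possible — for exclusive markers of a noiseless mixture
    this recovers the true fractions exactly); finally each sample's K
    signals are normalized to sum to one.  Marker genes absent from the
    matrix are dropped with a warning (matching is case-insensitive to allow
    cross-species symbol transfer); a population losing all its markers is
    an error.
    """
    if not isinstance(markers, MarkerSet):
        markers = MarkerSet.from_lists(markers)
    X = linear_values(em).to_numpy(dtype=float)
    index = {g: i for i, g in enumerate(em.gene_ids)}
    signals = {}
    for pop in markers.populations:
        genes = markers.genes(pop)
        matched = _marker_gene_map(em, genes)
        missing = [g for g in genes if g not in matched]
        if missing:
            warnings.warn(
                f"{len(missing)} marker(s) of population {pop!r} absent from the matrix"
            )
        rows = [index[matched[g]] for g in genes if g in matched]
        if not rows:
            raise ValueError(f"population {pop!r} has no marker present in the matrix")
        M = X[rows]
        sums = M.sum(axis=1)
        ok = sums > 0
        if not ok.all():
            warnings.warn(f"dropping {int((~ok).sum())} all-zero marker(s) of {pop!r}")
            M, sums = M[ok], sums[ok]
            if M.shape[0] == 0:
                raise ValueError(f"population {pop!r} has only all-zero markers")
        signals[pop] = (M / sums[:, None]).mean(axis=0)
    R = np.column_stack([signals[p] for p in markers.populations])
    # resolve the per-population scale left over from the unit-sum gene scaling
    scale, _ = nnls(R, np.ones(R.shape[0]))
    scale[scale == 0] = 1.0
    raw = R * scale[None, :]
    totals = raw.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} sample(s) with zero marker signal set to uniform")
        raw[zero] = 1.0 / raw.shape[1]
        totals[zero] = 1.0
    values = pd.DataFrame(
        raw / totals[:, None], index=em.sample_ids, columns=markers.populations
    )
    return FractionMatrix(values=values)


def select_markers(
    em: ExpressionMatrix,
    fractions: FractionMatrix,
    fc_threshold: float = 1.0,
    n_boot: int = 100,
    ci_level: float = 0.95,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    seed: int = 0,
    candidate_genes: Sequence[str] | None = None,
) -> MarkerSet:
    """Select population markers by OVE fold-change with a bootstrap guard.

    Profiles are estimated on the full data and on ``n_boot`` datasets built
    by resampling samples with replacement (re-using the matching fraction
    rows).  A gene becomes a marker of its argmax population ``p`` when the
    full-data ``OVE[g, p]`` exceeds ``fc_threshold`` *and* the
    ``(1 - ci_level)`` lower percentile of the bootstrap ``log OVE[g, p]``
    is positive.  A population ending up with zero markers raises an error
    advising lower thresholds.

    ``candidate_genes`` optionally restricts the tested genes; the
    unsupervised pipeline passes the simplex-extremity genes of
    :func:`corner_candidates` here, because the fold-change/CI filter alone
    controls only its nominal per-gene error rate and would admit a few
    percent of interior genes on a genome-wide candidate set.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    X = linear_values(em).to_numpy(dtype=float)
    A = fractions.values.loc[list(em.sample_ids)].to_numpy(dtype=float)
    n, k = A.shape
    S_full = _nnls_profiles(A, X)
    ove_full = _ove_array(S_full, pseudocount)
    rng = np.random.default_rng(seed)
    boot_log = np.empty((n_boot, X.shape[0], k), dtype=float)
    for b in range(n_boot):
        for _ in range(20):
            idx = rng.integers(0, n, size=n)
            Ab = A[idx]
            if np.linalg.matrix_rank(Ab) == k:
                break
        else:
            raise RuntimeError("could not draw a full-rank bootstrap design")
        Sb = _nnls_profiles(Ab, X[:, idx])
        boot_log[b] = np.log(_ove_array(Sb, pseudocount))
    lower = np.percentile(boot_log, (1.0 - ci_level) * 100.0, axis=0)
    argmax = ove_full.argmax(axis=1)
    pops = fractions.population_labels
    assignments: dict[str, list[MarkerRecord]] = {pop: [] for pop in pops}
    gene_ids = em.gene_ids
    allowed = None if candidate_genes is None else set(candidate_genes)
    for g in range(X.shape[0]):
        if allowed is not None and gene_ids[g] not in allowed:
            continue
        p = argmax[g]
        if ove_full[g, p] > fc_threshold and lower[g, p] > 0:
            assignments[pops[p]].append(
                MarkerRecord(gene=gene_ids[g], ove_fc=float(ove_full[g, p]), ci_lower=float(lower[g, p]))
            )
    empty = [pop for pop, recs in assignments.items() if not recs]
    if empty:
        raise ValueError(
            f"no marker passed the thresholds for population(s) {empty}; "
            "consider lowering fc_threshold or ci_level"
        )
    for pop in assignments:
        assignments[pop].sort(key=lambda r: -r.ove_fc)
    return MarkerSet(assignments)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def reconstruction_error(
    em: ExpressionMatrix, fractions: FractionMatrix, profiles: PopulationProfiles
) -> float:
    """Relative Frobenius reconstruction error ``||X - S Aᵀ||_F / ||X||_F``."""
    X = linear_values(em).to_numpy(dtype=float)
    A = fractions.values.to_numpy(dtype=float)
    S = profiles.values.to_numpy(dtype=float)
    return float(np.linalg.norm(X - S @ A.T) / np.linalg.norm(X))


def _order_populations(fractions: FractionMatrix, times: pd.Series) -> list[str]:
    """Stable population labels: the population dominant at the earliest time
    comes first; the remaining ones are ordered by their mean fraction at the
    latest time, descending (the riser before the minor population)."""
    vals = fractions.values
    t = times.loc[vals.index]
    first = vals.loc[t == t.min()].mean(axis=0)
    last = vals.loc[t == t.max()].mean(axis=0)
    lead = first.idxmax()
    rest = sorted((c for c in vals.columns if c != lead), key=lambda c: -last[c])
    return [lead, *rest]


def deconvolve(
    em: ExpressionMatrix,
    k: int = 3,
    markers: MarkerSet | None = None,
    floor: float | None = None,
    n_clusters: int = 20,
    n_boot: int = 100,
    fc_threshold: float = 1.0,
    ci_level: float = 0.95,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    seed: int = 0,
    relabel_by_time: bool = True,
) -> DeconvolutionResult:
    """Run the full deconvolution chain, or its supervised tail.

    Unsupervised (``markers is None``): simplex projection → corner search →
    initial fractions from the corner genes → bootstrap marker selection →
    fractions by standardized averaging → profiles by NNLS.  Supervised: the
    given marker set drives fraction and profile estimation directly.

    When the sample metadata carries ``time_h`` and ``relabel_by_time`` is
    set, populations are renamed P1..PK with P1 the population dominant at
    the earliest time and P2 the one largest at the latest time among the
    rest, mirroring the usual narrative ordering of a differentiation course.
    """
    if k < 2:
        raise ValueError("need at least two populations")
    corners: CornerResult | None = None
    if markers is None:
        X = linear_values(em)
        sp = project_simplex(em, floor=floor)
        corners = find_corners(sp, k, n_clusters=n_clusters, seed=seed, raw=X.loc[sp.kept_gene_ids])
        a0 = estimate_fractions(em, corners.corner_genes)
        candidates = corner_candidates(sp, corners)
        markers = select_markers(
            em,
            a0,
            fc_threshold=fc_threshold,
            n_boot=n_boot,
            ci_level=ci_level,
            pseudocount=pseudocount,
            seed=seed,
            candidate_genes=[g for genes in candidates.values() for g in genes],
        )
    fractions = estimate_fractions(em, markers)
    if relabel_by_time and "time_h" in em.samples.columns:
        order = _order_populations(fractions, em.samples["time_h"])
        rename = {old: f"P{i + 1}" for i, old in enumerate(order)}
        fractions = FractionMatrix(values=fractions.values[order].rename(columns=rename))
        markers = MarkerSet(
            {rename[pop]: markers.assignments[pop] for pop in order if pop in markers.assignments}
        )
    profiles = estimate_profiles(em, fractions)
    err = reconstruction_error(em, fractions, profiles)
    return DeconvolutionResult(
        fractions=fractions,
        profiles=profiles,
        markers=markers,
        corners=corners,
        reconstruction_error=err,
    )


def elbow_report(
    em: ExpressionMatrix,
    ks: Sequence[int] = (2, 3, 4, 5),
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Reconstruction error as a function of the number of populations.

    A diagnostic only — the report never auto-selects K.
    """
    rows = []
    for k in ks:
        res = deconvolve(em, k=k, seed=seed, relabel_by_time=False, **kwargs)
        rows.append({"k": k, "reconstruction_error": res.reconstruction_error,
                     "n_markers": sum(res.markers.counts().values())})
    return pd.DataFrame(rows)
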