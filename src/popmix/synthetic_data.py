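"""Ground-truth mixture simulator for the deconvolution pipeline.

Emulates the statistical structure of a differentiating pre-adipocyte time
course: K latent sub-populations with planted exclusive marker genes, mixing
fractions that shift over ~0–240 h (a dominant population P1 that starts
above 95% and falls below 40%, a responder P2 that rises above 60%, and a
minor transient P3), multiplicative log-normal measurement noise, and
optional per-batch location offsets.  Observed expression follows the exact
mixing model ``X[g, s] = (Σ_p S[g, p] A[s, p]) · exp(ε)`` with
``ε ~ Normal(0, noise_sd²)``, so every downstream stage has a known truth to
be checked against.

Defaults (2000 genes, K = 3, 40 markers per population, 10 time points × 3
replicates, noise_sd = 0.1) define the reference simulation used throughout
the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, concat_samples, stage_for_time
from .cam_deconv import FractionMatrix, MarkerSet, PopulationProfiles

__all__ = [
    "GroundTruth",
    "SimulationResult",
    "DEFAULT_TIMES",
    "DEFAULT_START",
    "DEFAULT_END",
    "make_truth",
    "fraction_trajectory",
    "default_fractions",
    "simulate_mixture",
    "apply_treatment_effect",
    "simulate_two_groups",
]

#: Default sampling times (hours post induction).
DEFAULT_TIMES = (0.0, 12.0, 24.0, 48.0, 72.0, 96.0, 120.0, 144.0, 192.0, 240.0)
#: Initial composition: dominant progenitors, two minor groups.
DEFAULT_START = (0.95, 0.03, 0.02)
#: Late composition: the responder dominates, the progenitor pool shrinks.
DEFAULT_END = (0.35, 0.62, 0.03)
DEFAULT_MIDPOINT_H = 72.0
DEFAULT_STEEPNESS = 0.05  # per hour


@dataclass
class GroundTruth:
    """True profiles, marker labels and noise model of a simulation.

    ``fractions`` is filled in by :func:`simulate_mixture` (one row per
    generated sample); freshly built truths carry ``None`` there.
    """

    profiles: PopulationProfiles
    marker_labels: dict[str, list[str]]
    noise_sd: float
    seed: int
    batch_shifts: dict[str, np.ndarray] | None = None
    fractions: FractionMatrix | None = None

    @property
    def k(self) -> int:
        return self.profiles.values.shape[1]

    @property
    def marker_set(self) -> MarkerSet:
        return MarkerSet.from_lists(self.marker_labels)


@dataclass
class SimulationResult:
    expression: ExpressionMatrix
    fractions: FractionMatrix  # true per-sample fractions
    truth: GroundTruth


def make_truth(
    n_genes: int = 2000,
    k: int = 3,
    markers_per_pop: int = 40,
    seed: int = 0,
    noise_sd: float = 0.1,
    loading_sd: float = 0.05,
    base_logmean: float = 4.0,
    base_logsd: float = 1.0,
    marker_logmean: float = 5.5,
    marker_logsd: float = 0.4,
    batch_shifts: Mapping[str, np.ndarray] | None = None,
) -> GroundTruth:
    """Build true population profiles with planted exclusive markers.

    Each of the ``k`` populations receives ``markers_per_pop`` marker genes
    expressed at a high log-normal level in that population and exactly zero
    elsewhere; markers are drawn bright (about 4-5 fold the shared baseline)
    because a population marker is by definition a strongly, exclusively
    expressed gene — one whose mixture signal clears the expression floor
    even when its population is small.  The remaining genes are shared: a common log-normal baseline
    per gene multiplied by mild population loadings
    (``exp(Normal(0, loading_sd))``), i.e. shared genes differ between
    populations by ~10% at the default, well below any marker contrast.

    Marker rows are scattered at random through the matrix; the planted
    assignment is recorded in ``marker_labels``.
    """
    if k < 2:
        raise ValueError("need at least two populations")
    if n_genes < k * markers_per_pop:
        raise ValueError(
            f"n_genes={n_genes} cannot host {k} x {markers_per_pop} exclusive markers"
        )
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    pops = [f"P{p + 1}" for p in range(k)]
    base = rng.lognormal(base_logmean, base_logsd, size=n_genes)
    loadings = np.exp(rng.normal(0.0, loading_sd, size=(n_genes, k)))
    S = base[:, None] * loadings
    marker_rows = rng.choice(n_genes, size=k * markers_per_pop, replace=False)
    marker_labels: dict[str, list[str]] = {}
    for p, pop in enumerate(pops):
        rows = marker_rows[p * markers_per_pop : (p + 1) * markers_per_pop]
        S[rows] = 0.0
        S[rows, p] = rng.lognormal(marker_logmean, marker_logsd, size=markers_per_pop)
        marker_labels[pop] = sorted(gene_ids[r] for r in rows)
    profiles = PopulationProfiles(values=pd.DataFrame(S, index=gene_ids, columns=pops))
    shifts = {b: np.asarray(v, dtype=float) for b, v in batch_shifts.items()} if batch_shifts else None
    return GroundTruth(
        profiles=profiles,
        marker_labels=marker_labels,
        noise_sd=noise_sd,
        seed=seed,
        batch_shifts=shifts,
    )


def fraction_trajectory(
    times: Sequence[float],
    start: Sequence[float] = DEFAULT_START,
    end: Sequence[float] = DEFAULT_END,
    midpoint_h: float = DEFAULT_MIDPOINT_H,
    steepness: float = DEFAULT_STEEPNESS,
) -> FractionMatrix:
    """Logistic interpolation of mixing fractions between two compositions.

    Per population ``f_p(t) = start_p + (end_p - start_p) σ(steepness (t -
    midpoint_h))``; each row is renormalized to sum to one.  The defaults
    drive the dominant population from 95% below 40% while the responder
    rises above 60% by 240 h.
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    if (start < 0).any() or (end < 0).any():
        raise ValueError("start and end fractions must be non-negative")
    for name, v in (("start", start), ("end", end)):
        if not np.isclose(v.sum(), 1.0, atol=1e-9):
            raise ValueError(f"{name} fractions must sum to 1, got {v.sum()}")
    t = np.asarray(times, dtype=float)
    sig = 1.0 / (1.0 + np.exp(-steepness * (t - midpoint_h)))
    rows = start[None, :] + (end - start)[None, :] * sig[:, None]
    rows /= rows.sum(axis=1, keepdims=True)
    labels = [f"P{p + 1}" for p in range(len(start))]
    index = pd.Index([_time_label(x) for x in t], name="time")
    return FractionMatrix(values=pd.DataFrame(rows, index=index, columns=labels))


def default_fractions(
    times: Sequence[float],
    k: int = 3,
    bump_height: float = 0.3,
    bump_center_h: float = 60.0,
    bump_width_h: float = 60.0,
) -> FractionMatrix:
    """Reference fraction schedule of the simulated differentiation course.

    The logistic schedule of :func:`fraction_trajectory` with, for K = 3, a
    transient Gaussian bump added to the minor population before row
    renormalization: both minor groups respond to the induction initially
    but only P2 keeps growing, so P3 rises to a peak share of ~24% around
    2.5 days and falls back below 5%.  The transient keeps all three
    fraction columns linearly independent — without it every column is an
    affine function of one logistic, the mixing matrix has rank 2 and the
    population profiles are unidentifiable; its breadth and height were set
    so that the least-squares noise amplification of the minor population's
    profile stays within a small factor of the major ones'.  For K != 3 a
    plain logistic hand-off from P1 to P2 is used.
    """
    t = np.asarray(times, dtype=float)
    if k == 3:
        base = fraction_trajectory(t).values.to_numpy()
        bump = bump_height * np.exp(-(((t - bump_center_h) / bump_width_h) ** 2))
        rows = base.copy()
        rows[:, 2] += bump
        rows /= rows.sum(axis=1, keepdims=True)
        labels = ["P1", "P2", "P3"]
    else:
        minor = 0.05 / max(k - 1, 1)
        start = np.full(k, minor)
        start[0] = 0.95
        end = np.full(k, 0.38 / max(k - 1, 1))
        end[0] = 0.35
        end[1] = 1.0 - end[0] - end[2:].sum() if k > 2 else 0.65
        start /= start.sum()
        end /= end.sum()
        return fraction_trajectory(t, start=start, end=end)
    index = pd.Index([_time_label(x) for x in t], name="time")
    return FractionMatrix(values=pd.DataFrame(rows, index=index, columns=labels))


def _time_label(t: float) -> str:
    return f"t{t:g}h"


def simulate_mixture(
    truth: GroundTruth,
    times: Sequence[float] = DEFAULT_TIMES,
    replicates: int = 3,
    seed: int | None = None,
    fractions: FractionMatrix | None = None,
    batch_of_replicate: Mapping[int, str] | None = None,
) -> SimulationResult:
    """Draw a noisy mixed-expression dataset from a ground truth.

    ``X[g, s] = (Σ_p S[g, p] A[s, p]) exp(ε)`` with iid Gaussian ``ε`` on the
    log scale, followed by multiplicative per-batch gene offsets
    (``exp(shift)``) when the truth carries batch effects.  Sample metadata
    records time, stage (via the default stage map), batch and platform.

    Parameters
    ----------
    fractions
        True fractions per time point; defaults to
        :func:`default_fractions` evaluated at ``times``.
    batch_of_replicate
        Optional mapping replicate index (0-based) → batch name; replicates
        default to batch "b1".
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    if seed is None:
        seed = truth.seed + 1
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    if fractions is None:
        fractions = default_fractions(t, k=truth.k)
    A_time = fractions.values.to_numpy(dtype=float)
    if A_time.shape[0] != len(t):
        raise ValueError("fractions must have one row per time point")
    S = truth.profiles.values.to_numpy(dtype=float)
    sample_ids, rows, meta_rows = [], [], []
    for i, time in enumerate(t):
        for r in range(replicates):
            sample_ids.append(f"{_time_label(time)}_r{r + 1}")
            rows.append(A_time[i])
            batch = (batch_of_replicate or {}).get(r, "b1")
            meta_rows.append(
                {
                    "time_h": time,
                    "stage": stage_for_time(time),
                    "batch": batch,
                    "treatment": "none",
                    "platform": "rnaseq",
                }
            )
    A = np.asarray(rows)
    clean = S @ A.T
    noise = np.exp(rng.normal(0.0, truth.noise_sd, size=clean.shape)) if truth.noise_sd > 0 else 1.0
    X = clean * noise
    meta = pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample_id"))
    if truth.batch_shifts:
        for b, shift in truth.batch_shifts.items():
            cols = np.flatnonzero((meta["batch"] == b).to_numpy())
            if cols.size:
                X[:, cols] *= np.exp(np.asarray(shift, dtype=float))[:, None]
    values = pd.DataFrame(X, index=truth.profiles.values.index, columns=sample_ids)
    em = ExpressionMatrix(values=values, samples=meta, value_scale="intensity")
    frac = FractionMatrix(
        values=pd.DataFrame(A, index=pd.Index(sample_ids, name="sample_id"),
                            columns=fractions.values.columns)
    )
    return SimulationResult(expression=em, fractions=frac, truth=replace(truth, fractions=frac))


def apply_treatment_effect(
    truth: GroundTruth,
    population: str,
    log2_fold: float = 1.0,
    n_genes: int = 100,
    gene_ids: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[GroundTruth, list[str]]:
    """Perturb one population's profile to mimic a treatment response.

    Multiplies the chosen population's expression of ``n_genes`` randomly
    picked genes (or the given ``gene_ids``) by ``2**log2_fold`` and returns
    the perturbed truth together with the affected gene list.  All other
    populations keep their profiles, so any downstream differential signal
    is, by construction, specific to ``population``.
    """
    frame = truth.profiles.values.copy()
    if population not in frame.columns:
        raise ValueError(f"unknown population {population!r}")
    if gene_ids is None:
        rng = np.random.default_rng(seed)
        candidates = [g for g in frame.index if frame.loc[g, population] > 0]
        gene_ids = sorted(rng.choice(candidates, size=min(n_genes, len(candidates)), replace=False))
    frame.loc[list(gene_ids), population] *= 2.0 ** log2_fold
    perturbed = replace(truth, profiles=PopulationProfiles(values=frame), fractions=None)
    return perturbed, list(gene_ids)


def simulate_two_groups(
    truth: GroundTruth,
    population: str,
    times: Sequence[float],
    replicates: int = 3,
    log2_fold: float = 1.0,
    n_genes: int = 100,
    treatment: str = "drug",
    control: str = "vehicle",
    seed: int = 0,
) -> tuple[ExpressionMatrix, list[str]]:
    """Simulate a control and a treated dataset differing in one population.

    Returns the column-concatenated expression matrix (treatment recorded in
    the metadata) and the list of genes whose expression in ``population``
    was shifted by ``2**log2_fold`` in the treated arm.
    """
    perturbed, affected = apply_treatment_effect(
        truth, population, log2_fold=log2_fold, n_genes=n_genes, seed=seed
    )
    ctrl = simulate_mixture(truth, times=times, replicates=replicates, seed=seed + 1)
    trt = simulate_mixture(perturbed, times=times, replicates=replicates, seed=seed + 2)
    ctrl_em, trt_em = ctrl.expression, trt.expression
    ctrl_em.samples["treatment"] = control
    trt_em.samples["treatment"] = treatment
    trt_vals = trt_em.values.copy()
    trt_vals.columns = [f"{c}_{treatment}" for c in trt_vals.columns]
    trt_meta = trt_em.samples.copy()
    trt_meta.index = pd.Index(trt_vals.columns, name="sample_id")
    trt_em = ExpressionMatrix(values=trt_vals, samples=trt_meta, value_scale=trt_em.value_scale)
    return concat_samples(ctrl_em, trt_em), affected
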