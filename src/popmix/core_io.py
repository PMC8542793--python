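"""Containers and preprocessing for gene-level expression tables.

The analysis operates on a genes × samples matrix with per-sample metadata
(time in hours, differentiation stage, batch, treatment, platform).  This
module houses the :class:`ExpressionMatrix` container, the tabular readers
and writers (TSV for expression/metadata, GMT for gene sets) and the
preprocessing transforms applied before deconvolution: probe collapsing,
log-CPM transformation, quantile normalization and a location/scale batch
adjustment.

All tables are plain UTF-8 TSV with a header row and "." as the decimal
separator.  Expression tables carry the gene identifier in the first column
and one column per sample; metadata tables carry one row per sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "METADATA_COLUMNS",
    "DEFAULT_STAGE_BOUNDS",
    "stage_for_time",
    "assign_stages",
    "collapse_probes",
    "log_cpm_transform",
    "quantile_normalize",
    "batch_adjust",
    "linear_values",
    "concat_samples",
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "read_gmt",
    "write_gmt",
]

#: Required columns of a sample metadata table.
METADATA_COLUMNS = ("sample_id", "time_h", "stage", "batch", "treatment", "platform")

#: Stage boundaries in hours: S0 for t <= first, S1 for first < t <= second,
#: S2 beyond.  The differentiation course runs from pre-induction (t <= 0)
#: through early (up to day 4) into late differentiation (up to two weeks).
DEFAULT_STAGE_BOUNDS = (0.0, 96.0)

VALUE_SCALES = ("counts", "log_expr", "intensity")


def stage_for_time(time_h: float, bounds: tuple[float, float] = DEFAULT_STAGE_BOUNDS) -> str:
    """Map a time in hours to a differentiation stage label (S0/S1/S2)."""
    lo, hi = bounds
    if time_h <= lo:
        return "S0"
    if time_h <= hi:
        return "S1"
    return "S2"


def assign_stages(metadata: pd.DataFrame, bounds: tuple[float, float] = DEFAULT_STAGE_BOUNDS) -> pd.DataFrame:
    """Return a copy of ``metadata`` with the stage column filled from time_h."""
    out = metadata.copy()
    out["stage"] = [stage_for_time(t, bounds) for t in out["time_h"]]
    return out


@dataclass
class ExpressionMatrix:
    """A genes × samples expression matrix with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by unique gene identifiers, one column per sample.
        All values must be finite; on the ``counts`` scale they must also be
        non-negative.
    samples
        Metadata with one row per sample, indexed by ``sample_id`` and
        carrying the columns ``time_h, stage, batch, treatment, platform``.
        The row order must match the column order of ``values``.
    value_scale
        One of ``counts`` (raw counts), ``log_expr`` (log2(CPM+1) or a
        comparable log scale) or ``intensity`` (linear array intensities).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    value_scale: str = "counts"

    def __post_init__(self) -> None:
        if self.value_scale not in VALUE_SCALES:
            raise ValueError(f"value_scale must be one of {VALUE_SCALES}, got {self.value_scale!r}")
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"gene identifiers are not unique: {dupes[:5]}")
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample metadata rows do not match expression columns")
        vals = self.values.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("expression values must be finite")
        if self.value_scale == "counts" and (vals < 0).any():
            raise ValueError("counts-scale values must be non-negative")

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        return replace(self, values=self.values.loc[list(gene_ids)])

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return replace(self, values=self.values[ids], samples=self.samples.loc[ids])


def linear_values(em: ExpressionMatrix) -> pd.DataFrame:
    """Expression on the linear scale.

    ``log_expr`` values are inverted with ``2**x - 1`` (clipped at zero);
    counts and intensities pass through unchanged.  All mixing algebra in the
    deconvolution works on this scale.
    """
    if em.value_scale == "log_expr":
        return (np.exp2(em.values) - 1.0).clip(lower=0.0)
    return em.values


def concat_samples(a: ExpressionMatrix, b: ExpressionMatrix) -> ExpressionMatrix:
    """Column-concatenate two matrices sharing the same genes and scale."""
    if a.value_scale != b.value_scale:
        raise ValueError("cannot concatenate matrices on different value scales")
    if list(a.values.index) != list(b.values.index):
        raise ValueError("gene identifiers differ between the two matrices")
    overlap = set(a.sample_ids) & set(b.sample_ids)
    if overlap:
        raise ValueError(f"duplicate sample ids: {sorted(overlap)[:5]}")
    return ExpressionMatrix(
        values=pd.concat([a.values, b.values], axis=1),
        samples=pd.concat([a.samples, b.samples], axis=0),
        value_scale=a.value_scale,
    )


# ---------------------------------------------------------------------------
# preprocessing transforms
# ---------------------------------------------------------------------------

def collapse_probes(
    intensities: pd.DataFrame,
    probe_to_gene: Mapping[str, str],
    metadata: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Collapse probe-level intensities to gene level by the maximum average.

    For every gene the single probe with the highest mean intensity across
    samples is retained; its row becomes the gene's row.  Probes without a
    gene assignment are dropped.  Ties on the mean are broken by keeping the
    lexicographically first probe identifier, so the output is deterministic.

    Parameters
    ----------
    intensities
        Probe × sample intensity table indexed by probe id.
    probe_to_gene
        Mapping from probe id to gene symbol.  Probes absent from the mapping
        are ignored; an empty mapping is an error.
    metadata
        Optional sample metadata; a minimal placeholder table is built when
        omitted.
    """
    if not probe_to_gene:
        raise ValueError("probe_to_gene mapping is empty")
    mapped = [p for p in intensities.index if p in probe_to_gene]
    if not mapped:
        raise ValueError("no probe in the intensity table has a gene assignment")
    sub = intensities.loc[mapped]
    means = sub.mean(axis=1)
    frame = pd.DataFrame(
        {"gene": [probe_to_gene[p] for p in mapped], "mean": means.to_numpy()},
        index=sub.index,
    )
    # highest mean first, probe id ascending as tie-break; keep first per gene
    frame = frame.iloc[np.lexsort((frame.index.to_numpy(), -frame["mean"].to_numpy()))]
    winners = frame[~frame["gene"].duplicated()]
    values = sub.loc[winners.index]
    values.index = winners["gene"].to_numpy()
    values = values.sort_index()
    if metadata is None:
        metadata = _placeholder_metadata(values.columns)
    return ExpressionMatrix(values=values, samples=metadata, value_scale="intensity")


def _placeholder_metadata(sample_ids: Iterable[str]) -> pd.DataFrame:
    ids = list(sample_ids)
    meta = pd.DataFrame(
        {
            "time_h": np.zeros(len(ids)),
            "stage": "S0",
            "batch": "b1",
            "treatment": "none",
            "platform": "microarray",
        },
        index=pd.Index(ids, name="sample_id"),
    )
    return meta


def log_cpm_transform(em: ExpressionMatrix) -> ExpressionMatrix:
    """log2(CPM + 1) transform of a counts-scale matrix.

    ``value[g, s] = log2(1e6 * count[g, s] / library_size[s] + 1)`` where the
    library size is the column sum.  A zero library size is an error naming
    the offending sample.
    """
    if em.value_scale != "counts":
        raise ValueError("log_cpm_transform requires a counts-scale matrix")
    libsize = em.values.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    cpm = em.values.div(libsize, axis=1) * 1e6
    return replace(em, values=np.log2(cpm + 1.0), value_scale="log_expr")


def quantile_normalize(em: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common per-rank mean distribution.

    Each column is replaced by the mean sorted profile evaluated at that
    column's ranks (ties receive the average of the tied positions), so all
    columns end up with the same value multiset while within-column order is
    preserved.  The transform is idempotent.
    """
    if em.n_samples < 2:
        warnings.warn("quantile_normalize: single sample, returned unchanged")
        return em
    vals = em.values.to_numpy(dtype=float)
    mean_sorted = np.sort(vals, axis=0).mean(axis=1)
    from scipy.stats import rankdata

    ranks = np.apply_along_axis(rankdata, 0, vals)  # average ranks, 1-based
    grid = np.arange(1, vals.shape[0] + 1, dtype=float)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        out[:, j] = np.interp(ranks[:, j], grid, mean_sorted)
    return replace(em, values=pd.DataFrame(out, index=em.values.index, columns=em.values.columns))


def batch_adjust(em: ExpressionMatrix, batch_key: str = "batch") -> ExpressionMatrix:
    """Remove per-batch location/scale effects gene by gene.

    For every gene, each batch is re-centred to the gene's grand mean and
    rescaled so its within-batch standard deviation equals the pooled
    standard deviation across batches.  Genes with zero variance pass
    through unchanged, as does a batch whose within-gene deviation is zero
    (it is only re-centred).  Every batch needs at least two samples.
    """
    batches = em.samples[batch_key]
    sizes = batches.value_counts()
    singletons = sizes[sizes < 2]
    if len(singletons):
        raise ValueError(f"batch(es) with fewer than 2 samples: {list(singletons.index)}")
    if sizes.shape[0] == 1:
        return replace(em, values=em.values.copy())
    vals = em.values.to_numpy(dtype=float)
    out = vals.copy()
    grand = vals.mean(axis=1)
    groups = [np.flatnonzero((batches == b).to_numpy()) for b in sizes.index]
    bmeans = np.stack([vals[:, idx].mean(axis=1) for idx in groups], axis=1)
    bvars = np.stack([vals[:, idx].var(axis=1, ddof=1) for idx in groups], axis=1)
    dfs = np.array([len(idx) - 1 for idx in groups], dtype=float)
    pooled_sd = np.sqrt((bvars * dfs).sum(axis=1) / dfs.sum())
    zero_var = vals.var(axis=1) == 0
    for k, idx in enumerate(groups):
        bsd = np.sqrt(bvars[:, k])
        scale = np.where(bsd > 0, pooled_sd / np.where(bsd > 0, bsd, 1.0), 1.0)
        out[:, idx] = (vals[:, idx] - bmeans[:, [k]]) * scale[:, None] + grand[:, None]
    out[zero_var] = vals[zero_var]
    return replace(em, values=pd.DataFrame(out, index=em.values.index, columns=em.values.columns))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

FLOAT_FORMAT = "%.10g"


def read_expression(
    path: str | Path,
    metadata: pd.DataFrame | str | Path | None = None,
    value_scale: str = "counts",
) -> ExpressionMatrix:
    """Read an expression TSV (first column gene id, header sample ids)."""
    values = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    values.index = values.index.astype(str)
    if isinstance(metadata, (str, Path)):
        metadata = read_metadata(metadata)
    if metadata is None:
        metadata = _placeholder_metadata(values.columns)
    else:
        missing = [c for c in values.columns if c not in metadata.index]
        if missing:
            raise ValueError(f"metadata is missing sample id(s): {missing}")
        metadata = metadata.loc[list(values.columns)]
    return ExpressionMatrix(values=values, samples=metadata, value_scale=value_scale)


def write_expression(em: ExpressionMatrix, path: str | Path) -> None:
    frame = em.values.copy()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata table is missing column(s): {missing}")
    meta = meta.set_index("sample_id")
    meta["time_h"] = meta["time_h"].astype(float)
    return meta


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    out = metadata.reset_index()
    if "index" in out.columns:
        out = out.rename(columns={"index": "sample_id"})
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need name, description, genes): {line[:80]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path: str | Path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *genes]) for name, genes in gene_sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
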