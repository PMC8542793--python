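"""Shared fixtures: toy matrices and the reference synthetic experiment.

The reference simulation (2000 genes, K=3, 40 markers/pop, 10 time points x
3 replicates, noise_sd 0.1) and its deconvolution are session-scoped so the
expensive stages run once for the whole suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from popmix import cam_deconv, synthetic_data, validation
from popmix.core_io import ExpressionMatrix


def build_em(values, sample_ids=None, gene_ids=None, value_scale="intensity", times=None,
             stages=None, batches=None, treatments=None) -> ExpressionMatrix:
    """Construct an ExpressionMatrix from a plain array with minimal metadata."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = list(gene_ids) if gene_ids is not None else [f"g{i}" for i in range(n_genes)]
    sample_ids = list(sample_ids) if sample_ids is not None else [f"s{j}" for j in range(n_samples)]
    meta = pd.DataFrame(
        {
            "time_h": list(times) if times is not None else np.zeros(n_samples),
            "stage": list(stages) if stages is not None else ["S0"] * n_samples,
            "batch": list(batches) if batches is not None else ["b1"] * n_samples,
            "treatment": list(treatments) if treatments is not None else ["none"] * n_samples,
            "platform": "rnaseq",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    frame = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    return ExpressionMatrix(values=frame, samples=meta, value_scale=value_scale)


@pytest.fixture(scope="session")
def default_truth():
    return synthetic_data.make_truth(seed=7)


@pytest.fixture(scope="session")
def default_sim(default_truth):
    return synthetic_data.simulate_mixture(default_truth, seed=8)


@pytest.fixture(scope="session")
def default_deconv(default_sim):
    return cam_deconv.deconvolve(default_sim.expression, k=3, seed=9)


@pytest.fixture(scope="session")
def default_resample(default_sim, default_deconv):
    return validation.resample_markers(
        default_sim.expression, default_deconv.markers, set_size=35, n_iter=100, seed=11
    )


@pytest.fixture(scope="session")
def noiseless_sim():
    truth = synthetic_data.make_truth(n_genes=300, markers_per_pop=20, seed=3, noise_sd=0.0)
    return synthetic_data.simulate_mixture(truth, seed=4, replicates=1)
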