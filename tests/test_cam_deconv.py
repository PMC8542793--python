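"""The deconvolution core: simplex projection, corner search, OVE marker
statistics, standardized-averaging fractions and NNLS profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from popmix import cam_deconv as cd
from popmix import synthetic_data as sd
from popmix.cam_deconv import (
    FractionMatrix,
    MarkerSet,
    PopulationProfiles,
    deconvolve,
    estimate_fractions,
    estimate_profiles,
    find_corners,
    ove_fold_change,
    project_simplex,
    select_markers,
)
from popmix.validation import fraction_mae, match_columns
from conftest import build_em


class TestProjectSimplex:
    def test_unit_sum_scaling(self):
        em = build_em([[2.0, 6.0]], gene_ids=["g"])
        sp = project_simplex(em, floor=0.0)
        np.testing.assert_allclose(sp.normalized.loc["g"], [0.25, 0.75])

    def test_constant_gene_becomes_uniform(self):
        em = build_em([[5.0] * 4])
        sp = project_simplex(em, floor=0.0)
        np.testing.assert_allclose(sp.normalized.iloc[0], 0.25)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 10, (5, 6))
        a = project_simplex(build_em(vals), floor=0.0)
        b = project_simplex(build_em(vals * np.array([1, 2, 3, 4, 5])[:, None]), floor=0.0)
        np.testing.assert_allclose(a.normalized.to_numpy(), b.normalized.to_numpy())

    def test_floor_drops_weak_genes_and_can_empty(self):
        em = build_em([[1.0, 1.0], [10.0, 10.0]])
        sp = project_simplex(em, floor=5.0)
        assert sp.kept_gene_ids == ["g1"]
        with pytest.raises(ValueError, match="floor"):
            project_simplex(em, floor=100.0)


class TestFindCorners:
    @staticmethod
    def _two_pop_em(n_shared=60, n_excl=15, seed=0):
        rng = np.random.default_rng(seed)
        times = np.linspace(0, 1, 12)
        A = np.column_stack([1 - times, times])  # two populations crossing over
        S = np.zeros((2 * n_excl + n_shared, 2))
        S[:n_excl, 0] = rng.uniform(50, 150, n_excl)
        S[n_excl: 2 * n_excl, 1] = rng.uniform(50, 150, n_excl)
        S[2 * n_excl:, :] = rng.uniform(40, 80, (n_shared, 1))  # 50/50 genes
        X = S @ A.T
        return build_em(X), n_excl

    def test_exclusive_groups_are_the_corners(self):
        em, n_excl = self._two_pop_em()
        sp = project_simplex(em, floor=0.0)
        res = find_corners(sp, k=2, n_clusters=6, seed=1)
        assert res.score == pytest.approx(0.0, abs=1e-10)
        members = {frozenset(g) for g in res.corner_genes.values()}
        expected = {frozenset(f"g{i}" for i in range(n_excl)),
                    frozenset(f"g{i}" for i in range(n_excl, 2 * n_excl))}
        assert members == expected

    def test_k_equals_n_clusters_returns_all(self):
        em, _ = self._two_pop_em()
        sp = project_simplex(em, floor=0.0)
        res = find_corners(sp, k=3, n_clusters=3, seed=1)
        assert res.score == pytest.approx(0.0, abs=1e-9)
        assert res.selected_clusters == (0, 1, 2)

    def test_chosen_subset_minimizes_hull_residual(self, default_sim):
        sp = project_simplex(default_sim.expression)
        res = find_corners(sp, k=3, n_clusters=8, seed=2)
        assert res.score == min(res.subset_scores.values())
        assert res.subset_scores[res.selected_clusters] == res.score


class TestOveFoldChange:
    def test_hand_example(self):
        prof = pd.DataFrame([[6.0, 3.0, 2.0]], columns=["a", "b", "c"])
        ove = ove_fold_change(prof, pseudocount=1e-12)
        np.testing.assert_allclose(ove.iloc[0], [2.0, 0.5, 1.0 / 3.0], rtol=1e-9)

    def test_equal_gene_gives_unity(self):
        prof = pd.DataFrame([[4.0, 4.0, 4.0]])
        np.testing.assert_allclose(ove_fold_change(prof).iloc[0], 1.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(arrays(np.float64, (6, 4), elements=st.floats(0, 1e3, allow_nan=False)))
    def test_at_most_one_population_above_one(self, S):
        ove = ove_fold_change(pd.DataFrame(S), pseudocount=1e-6)
        assert ((ove > 1 + 1e-12).sum(axis=1) <= 1).all()

    def test_requires_two_populations(self):
        with pytest.raises(ValueError):
            ove_fold_change(pd.DataFrame([[1.0]]))


class TestEstimateFractions:
    def test_hand_example_two_markers(self):
        em = build_em([[3.0, 1.0], [1.0, 3.0]], gene_ids=["g1", "g2"])
        frac = estimate_fractions(em, {"A": ["g1"], "B": ["g2"]})
        np.testing.assert_allclose(frac.values.loc["s0"], [0.75, 0.25])
        np.testing.assert_allclose(frac.values.loc["s1"], [0.25, 0.75])

    def test_pure_sample(self):
        em = build_em([[4.0, 2.0], [0.0, 3.0], [0.0, 1.0]], gene_ids=["a", "b", "c"])
        frac = estimate_fractions(em, {"P1": ["a"], "P2": ["b"], "P3": ["c"]})
        np.testing.assert_allclose(frac.values.iloc[0], [1.0, 0.0, 0.0], atol=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(arrays(np.float64, (6, 5), elements=st.floats(0.01, 100, allow_nan=False)))
    def test_rows_always_on_simplex(self, vals):
        em = build_em(vals)
        frac = estimate_fractions(em, {"A": ["g0", "g1"], "B": ["g2", "g3"], "C": ["g4", "g5"]})
        arr = frac.values.to_numpy()
        np.testing.assert_allclose(arr.sum(axis=1), 1.0, atol=1e-9)
        assert ((arr >= -1e-12) & (arr <= 1 + 1e-12)).all()

    def test_missing_markers_warn_then_error(self):
        em = build_em(np.ones((2, 3)) + np.arange(3), gene_ids=["a", "b"])
        with pytest.warns(UserWarning):
            estimate_fractions(em, {"A": ["a", "zz"], "B": ["b"]})
        with pytest.raises(ValueError, match="B"):
            estimate_fractions(em, {"A": ["a"], "B": ["zz"]})

    def test_case_insensitive_symbol_matching(self):
        em = build_em([[3.0, 1.0], [1.0, 3.0]], gene_ids=["Pparg", "Fasn"])
        frac = estimate_fractions(em, {"A": ["PPARG"], "B": ["fasn"]})
        np.testing.assert_allclose(frac.values.iloc[0], [0.75, 0.25])


class TestEstimateProfiles:
    def test_exact_recovery_noiseless(self, noiseless_sim):
        prof = estimate_profiles(noiseless_sim.expression, noiseless_sim.fractions)
        np.testing.assert_allclose(
            prof.values.to_numpy(), noiseless_sim.truth.profiles.values.to_numpy(),
            atol=1e-8,
        )

    def test_single_population_gives_row_means(self):
        vals = np.random.default_rng(3).uniform(1, 9, (4, 5))
        em = build_em(vals)
        ones = FractionMatrix(values=pd.DataFrame(
            np.ones((5, 1)), index=em.sample_ids, columns=["P1"]))
        prof = estimate_profiles(em, ones)
        np.testing.assert_allclose(prof.values["P1"].to_numpy(), vals.mean(axis=1), rtol=1e-9)

    def test_non_negativity(self, default_sim, default_deconv):
        assert (default_deconv.profiles.values.to_numpy() >= 0).all()

    def test_rank_deficient_fractions_rejected(self):
        em = build_em(np.random.default_rng(4).uniform(1, 9, (3, 4)))
        A = np.column_stack([np.full(4, 0.5), np.full(4, 0.3), np.full(4, 0.2)])
        frac = FractionMatrix(values=pd.DataFrame(A, index=em.sample_ids, columns=list("abc")))
        with pytest.raises(ValueError, match="rank"):
            estimate_profiles(em, frac)


class TestSelectMarkers:
    def test_noiseless_planted_markers_selected(self, noiseless_sim):
        ms = select_markers(noiseless_sim.expression, noiseless_sim.fractions, seed=0)
        for pop, genes in noiseless_sim.truth.marker_labels.items():
            assert set(genes) <= set(ms.genes(pop))

    def test_identical_gene_never_selected_noiseless(self):
        # a gene expressed equally in every population has OVE exactly 1
        rng = np.random.default_rng(5)
        A = sd.fraction_trajectory(np.linspace(0, 240, 8)).values.to_numpy()
        A = A + rng.uniform(0, 0.02, A.shape)
        A = A / A.sum(axis=1, keepdims=True)
        S = np.array([[100.0, 0.0, 0.0], [0.0, 80.0, 0.0], [0.0, 0.0, 60.0],
                      [50.0, 50.0, 50.0]])
        em = build_em(S @ A.T, gene_ids=["m1", "m2", "m3", "same"])
        frac = FractionMatrix(values=pd.DataFrame(A, index=em.sample_ids,
                                                  columns=["P1", "P2", "P3"]))
        ms = select_markers(em, frac, seed=0)
        selected = set(g for pop in ms.populations for g in ms.genes(pop))
        assert "same" not in selected
        assert {"m1", "m2", "m3"} <= selected

    def test_requires_minimum_bootstrap(self, noiseless_sim):
        with pytest.raises(ValueError, match="n_boot"):
            select_markers(noiseless_sim.expression, noiseless_sim.fractions, n_boot=10)


class TestDeconvolve:
    def test_recovers_planted_structure(self, default_sim, default_deconv, default_truth):
        mapping = match_columns(default_deconv.fractions.values, default_sim.fractions.values)
        assert fraction_mae(default_deconv.fractions, default_sim.fractions, mapping) < 0.05

    def test_supervised_mode_transfers_markers(self, default_truth, default_deconv):
        second = sd.simulate_mixture(default_truth, seed=100)
        res = deconvolve(second.expression, k=3, markers=default_deconv.markers)
        mapping = match_columns(res.fractions.values, second.fractions.values)
        assert fraction_mae(res.fractions, second.fractions, mapping) < 0.05

    def test_sample_permutation_equivariance(self, default_sim, default_deconv):
        rng = np.random.default_rng(11)
        order = list(rng.permutation(default_sim.expression.sample_ids))
        permuted = default_sim.expression.subset_samples(order)
        res = deconvolve(permuted, k=3, markers=default_deconv.markers)
        base = deconvolve(default_sim.expression, k=3, markers=default_deconv.markers)
        pd.testing.assert_frame_equal(res.fractions.values.loc[base.fractions.values.index],
                                      base.fractions.values)

    def test_population_labels_follow_time_course(self, default_sim, default_deconv):
        frac = default_deconv.fractions.values
        t = default_sim.expression.samples["time_h"]
        early = frac.loc[t == 0].mean()
        late = frac.loc[t == 240].mean()
        assert early.idxmax() == "P1"
        assert late["P2"] > late["P3"]

    def test_elbow_shape_across_k(self, default_sim):
        rep = cd.elbow_report(default_sim.expression, ks=(2, 3, 4), seed=9)
        err = dict(zip(rep["k"], rep["reconstruction_error"]))
        drop23 = (err[2] - err[3]) / err[2]
        drop34 = (err[3] - err[4]) / err[3]
        assert drop23 > 0
        assert drop34 < 0.02
        assert drop23 > 3 * drop34


class TestMarkerSetContainer:
    def test_disjointness_enforced(self):
        with pytest.raises(ValueError, match="assigned to both"):
            MarkerSet.from_lists({"A": ["g1"], "B": ["g1"]})

    def test_tsv_round_trip(self, tmp_path, default_deconv):
        path = tmp_path / "markers.tsv"
        default_deconv.markers.to_tsv(path)
        back = MarkerSet.from_tsv(path)
        assert back.counts() == default_deconv.markers.counts()
        for pop in back.populations:
            assert back.genes(pop) == default_deconv.markers.genes(pop)

    def test_two_column_marker_table(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("population\tgene\nA\tg1\nA\tg2\nB\tg3\n")
        ms = MarkerSet.from_tsv(path)
        assert ms.genes("A") == ["g1", "g2"] and ms.genes("B") == ["g3"]
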