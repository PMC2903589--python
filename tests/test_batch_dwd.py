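"""DWD batch-bias detection and translation-only adjustment."""

import numpy as np
import pandas as pd
import pytest

from pdacsig import dwd_adjust, fit_dwd, pca_project
from pdacsig.batch_dwd import DwdModel


def make_batches(rng, n_genes=40, n_samples=10, shift=None, noise=0.1):
    genes = [f"g{i}" for i in range(n_genes)]
    Xa = pd.DataFrame(
        noise * rng.standard_normal((n_genes, n_samples)),
        index=genes,
        columns=[f"a{i}" for i in range(n_samples)],
    )
    Xb = pd.DataFrame(
        noise * rng.standard_normal((n_genes, n_samples)),
        index=genes,
        columns=[f"b{i}" for i in range(n_samples)],
    )
    if shift is not None:
        Xb = Xb.add(shift, axis=0)
    return Xa, Xb


class TestFitDwd:
    def test_recovers_shift_axis(self, rng):
        shift = pd.Series(0.0, index=[f"g{i}" for i in range(40)])
        shift.iloc[0] = 5.0
        Xa, Xb = make_batches(rng, shift=shift)
        model = fit_dwd(Xa, Xb)
        cosine = abs(model.direction.iloc[0])
        assert cosine > 0.99

    def test_sign_convention_batch_b_higher(self, rng):
        shift = pd.Series(0.0, index=[f"g{i}" for i in range(40)])
        shift.iloc[0] = -5.0  # B shifted down along gene 0
        Xa, Xb = make_batches(rng, shift=shift)
        model = fit_dwd(Xa, Xb)
        assert model.mean_projections["B"] >= model.mean_projections["A"]
        assert np.isclose(np.linalg.norm(model.direction), 1.0, atol=1e-6)

    def test_separable_clouds_classified_by_sign(self, rng):
        genes = ["g0", "g1"]
        Xa = pd.DataFrame(rng.normal(-3, 0.3, (2, 12)), index=genes)
        Xb = pd.DataFrame(rng.normal(3, 0.3, (2, 12)), index=genes)
        Xb.columns = [f"b{i}" for i in range(12)]
        model = fit_dwd(Xa, Xb)
        w = model.direction.to_numpy()
        proj_a = w @ Xa.to_numpy() + model.intercept
        proj_b = w @ Xb.to_numpy() + model.intercept
        assert (proj_a < 0).all() and (proj_b > 0).all()

    def test_identical_batches_within_permutation_null(self, rng):
        # mean-projection gap of statistically identical batches should look
        # like a permuted-label gap, not an outlier
        Xa, Xb = make_batches(rng, n_genes=30, n_samples=8, noise=1.0)
        model = fit_dwd(Xa, Xb)
        w = model.direction.to_numpy()
        gap = abs(
            (w @ Xb.to_numpy()).mean() - (w @ Xa.to_numpy()).mean()
        )
        pooled = np.hstack([Xa.to_numpy(), Xb.to_numpy()])
        gaps = []
        for _ in range(200):
            perm = rng.permutation(16)
            ga = pooled[:, perm[:8]]
            gb = pooled[:, perm[8:]]
            m = fit_dwd(
                pd.DataFrame(ga, index=Xa.index), pd.DataFrame(gb, index=Xa.index)
            )
            wp = m.direction.to_numpy()
            gaps.append(abs((wp @ gb).mean() - (wp @ ga).mean()))
        # observed gap is not extreme relative to the permutation null
        assert gap <= np.quantile(gaps, 0.99)

    def test_sample_order_invariance_up_to_sign(self, rng):
        Xa, Xb = make_batches(rng, shift=pd.Series(rng.standard_normal(40), index=[f"g{i}" for i in range(40)]))
        m1 = fit_dwd(Xa, Xb)
        perm = rng.permutation(Xa.shape[1])
        m2 = fit_dwd(Xa.iloc[:, perm], Xb.iloc[:, perm])
        cos = abs(float(m1.direction @ m2.direction))
        assert cos > 0.999

    def test_gene_list_mismatch_rejected(self, rng):
        Xa, Xb = make_batches(rng)
        Xb.index = [f"h{i}" for i in range(40)]
        with pytest.raises(ValueError, match="gene lists"):
            fit_dwd(Xa, Xb)

    def test_direction_must_be_unit_norm(self):
        with pytest.raises(ValueError, match="unit norm"):
            DwdModel(
                direction=pd.Series([1.0, 1.0]),
                intercept=0.0,
                penalty=1.0,
                mean_projections={},
            )


class TestDwdAdjust:
    def test_mean_projections_zeroed(self, rng):
        Xa, Xb = make_batches(rng, shift=pd.Series(rng.standard_normal(40) * 2, index=[f"g{i}" for i in range(40)]))
        model = fit_dwd(Xa, Xb)
        w = model.direction.to_numpy()
        for adj in dwd_adjust([Xa, Xb], model):
            assert abs((w @ adj.to_numpy()).mean()) < 1e-8

    def test_within_batch_distances_exactly_preserved(self, rng):
        Xa, Xb = make_batches(rng, shift=pd.Series(3.0, index=[f"g{i}" for i in range(40)]))
        model = fit_dwd(Xa, Xb)
        adj_a, adj_b = dwd_adjust([Xa, Xb], model)
        for before, after in ((Xa, adj_a), (Xb, adj_b)):
            b = before.to_numpy()
            a = after.to_numpy()
            d_before = np.linalg.norm(b[:, :, None] - b[:, None, :], axis=0)
            d_after = np.linalg.norm(a[:, :, None] - a[:, None, :], axis=0)
            np.testing.assert_allclose(d_after, d_before, atol=1e-9)

    def test_shift_simulation_gene_means_align(self, rng):
        shift = pd.Series(0.0, index=[f"g{i}" for i in range(40)])
        shift.iloc[0] = 5.0
        Xa, Xb = make_batches(rng, shift=shift, noise=0.05)
        model = fit_dwd(Xa, Xb)
        adj_a, adj_b = dwd_adjust([Xa, Xb], model)
        gap = (adj_b.mean(axis=1) - adj_a.mean(axis=1)).abs().max()
        assert gap < 0.15  # noise-level agreement after removing the delta=5 shift


class TestPcaProject:
    def test_rank_one_matrix_pc1_explains_all(self):
        u = np.arange(1, 6, dtype=float)
        v = np.array([1.0, -2.0, 0.5, 3.0])
        mat = pd.DataFrame(np.outer(u, v))
        proj = pca_project(mat, n_components=2)
        assert proj.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_scores_have_zero_mean(self, small_matrix):
        proj = pca_project(small_matrix, n_components=3)
        np.testing.assert_allclose(proj.scores.mean(axis=0), 0.0, atol=1e-10)

    def test_batch_centroid_distance_decreases_after_adjustment(self, rng):
        shift = pd.Series(rng.standard_normal(40) * 2.0, index=[f"g{i}" for i in range(40)])
        Xa, Xb = make_batches(rng, shift=shift, noise=0.5)
        model = fit_dwd(Xa, Xb)
        adj_a, adj_b = dwd_adjust([Xa, Xb], model)

        def centroid_distance(a, b):
            proj = pca_project(pd.concat([a, b], axis=1), n_components=2)
            sa = proj.scores.iloc[: a.shape[1]].mean(axis=0)
            sb = proj.scores.iloc[a.shape[1]:].mean(axis=0)
            return float(np.linalg.norm(sa - sb))

        assert centroid_distance(adj_a, adj_b) < centroid_distance(Xa, Xb)

    def test_too_many_components_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            pca_project(small_matrix, n_components=9)
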