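"""SAM statistic, fudge factor, permutation FDR, and gene selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pdacsig import SimConfig, compute_s0, sam_two_class, simulate_derivation_sets


@pytest.fixture
def spiked_run(spiked_study, tumor_labels):
    X, labels = tumor_labels(spiked_study)
    return spiked_study, X, labels, sam_two_class(X, labels, n_perm=200, seed=3)


class TestSamStatistic:
    def test_d_matches_moderated_t_by_direct_formula(self, spiked_run):
        """The oracle recomputes d = (m2 - m1)/(s + s0) from group summaries."""
        _, X, labels, res = spiked_run
        labels = np.asarray(labels)
        cls = np.unique(labels)
        x1 = X.loc[:, labels == cls[0]].to_numpy()
        x2 = X.loc[:, labels == cls[1]].to_numpy()
        n1, n2 = x1.shape[1], x2.shape[1]
        r = x2.mean(1) - x1.mean(1)
        pooled = (x1.var(1, ddof=1) * (n1 - 1) + x2.var(1, ddof=1) * (n2 - 1)) / (
            n1 + n2 - 2
        )
        s = np.sqrt((1 / n1 + 1 / n2) * pooled)
        np.testing.assert_allclose(res.s, s, rtol=1e-10)
        np.testing.assert_allclose(res.d, r / (s + res.s0), rtol=1e-10)

    def test_spiked_genes_selected(self, spiked_run):
        study, _, _, res = spiked_run
        assert set(study.de_genes) <= set(res.selected)
        assert res.fdr <= 0.05

    def test_antisymmetry_under_label_swap(self, spiked_run):
        _, X, labels, res = spiked_run
        # metastatic now sorts as the larger class, flipping the d orientation
        swapped = ["B" if l == "metastatic" else "A" for l in labels]
        res_sw = sam_two_class(X, swapped, n_perm=200, seed=3)
        np.testing.assert_allclose(res_sw.d, -res.d, rtol=1e-10)
        assert set(res_sw.selected) == set(res.selected)

    def test_deterministic_under_seed(self, spiked_run):
        _, X, labels, res = spiked_run
        res2 = sam_two_class(X, labels, n_perm=200, seed=3)
        np.testing.assert_array_equal(res.d, res2.d)
        assert res.selected == res2.selected
        assert res.delta == res2.delta

    def test_selection_monotone_in_target_fdr(self, spiked_run):
        _, X, labels, _ = spiked_run
        sizes = [
            len(sam_two_class(X, labels, n_perm=200, seed=3, target_fdr=f).selected)
            for f in (0.25, 0.05, 0.01)
        ]
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_duplicated_design_preserves_ranking(self, rng):
        genes = [f"g{i}" for i in range(60)]
        X = pd.DataFrame(rng.standard_normal((60, 4)), index=genes)
        labels = ["a", "a", "b", "b"]
        X_dup = pd.concat([X, X], axis=1)
        X_dup.columns = range(8)
        res = sam_two_class(X, labels, n_perm=50, seed=0)
        res_dup = sam_two_class(X_dup, labels * 2, n_perm=50, seed=0)
        # duplication rescales the pooled scatter uniformly, so d changes only
        # by a common positive factor (plus the s0 refit): ranking is invariant
        rho = stats.spearmanr(res.d, res_dup.d).statistic
        assert rho == pytest.approx(1.0)

    def test_missing_values_rejected(self, small_matrix):
        holed = small_matrix.copy()
        holed.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            sam_two_class(holed, ["a"] * 4 + ["b"] * 4)

    def test_single_class_rejected(self, small_matrix):
        with pytest.raises(ValueError, match="two classes"):
            sam_two_class(small_matrix, ["a"] * 8)

    def test_q_values_within_unit_interval_and_cover_selected(self, spiked_run):
        _, _, _, res = spiked_run
        assert ((res.q_values >= 0) & (res.q_values <= 1)).all()
        sel = np.array([g in set(res.selected) for g in res.genes])
        assert (res.q_values[sel] <= res.target_fdr).all()


class TestComputeS0:
    def test_equal_scatters_return_that_value(self, rng):
        r = rng.standard_normal(100)
        s = np.full(100, 0.7)
        assert compute_s0(r, s) == pytest.approx(0.7)

    def test_variance_inflation_at_low_scatter_gives_positive_s0(self, rng):
        # genes with tiny scatter get wildly inflated d unless s0 > 0
        n = 500
        s = np.concatenate([np.full(250, 0.01), np.full(250, 1.0)])
        r = s * rng.standard_normal(n) + np.where(s < 0.1, rng.standard_normal(n), 0)
        s0 = compute_s0(r, s)
        assert s0 > 0

        def window_cv(s0_val):
            d = r / (s + s0_val)
            order = np.argsort(s)
            spreads = [
                np.median(np.abs(d[w] - np.median(d[w]))) / 0.64
                for w in np.array_split(order, 50)
            ]
            return np.std(spreads, ddof=1) / np.mean(spreads)

        assert window_cv(s0) < window_cv(0.0)

    def test_scale_equivariant(self, rng):
        r = rng.standard_normal(200)
        s = np.abs(rng.standard_normal(200)) + 0.05
        s0 = compute_s0(r, s)
        s0_scaled = compute_s0(3.0 * r, 3.0 * s)
        assert s0_scaled == pytest.approx(3.0 * s0, rel=1e-9)

    def test_too_few_genes_rejected(self, rng):
        with pytest.raises(ValueError):
            compute_s0(rng.standard_normal(5), np.abs(rng.standard_normal(5)))


class TestPermutationMachinery:
    def test_small_designs_enumerate_all_assignments(self, rng):
        genes = [f"g{i}" for i in range(30)]
        X = pd.DataFrame(rng.standard_normal((30, 6)), index=genes)
        res = sam_two_class(X, ["a"] * 3 + ["b"] * 3, n_perm=1000, seed=0)
        assert res.n_perm == 20  # C(6,3)

    def test_null_replicates_rarely_call_genes(self, tumor_labels):
        calls = []
        for rep in range(8):
            cfg = SimConfig(
                n_genes=500, n_de_genes=0, effect_size=0.0, batch_shift=0.0,
                noise_sd=1.0, missing_rate=0.0, seed=700 + rep,
            )
            X, labels = tumor_labels(simulate_derivation_sets(cfg))
            res = sam_two_class(X, labels, n_perm=100, seed=rep)
            calls.append(len(res.selected))
        assert np.median(calls) == 0
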