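"""VIP scores, cross-validated component choice, permutation FDR and the
selected-gene table."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from plsde import (InvalidParameterError, PLSNipals, VIPSelector,
                   choose_h_cv, compute_vip, cross_val_components,
                   generate_expression, permutation_fdr, pooled_fdr,
                   select_genes, run_vip_selection, nipals_fit, standardize)
from plsde.selection import _null_vip_matrix


def _fit(expr, pheno, h, scale=True):
    data = standardize(expr, pheno, scale_columns=scale)
    return nipals_fit(data, h), data


# ---------------------------------------------------------------------------
# VIP
# ---------------------------------------------------------------------------

class TestVip:
    def test_uniform_weights_give_unit_vip(self, rng):
        p, n = 12, 20
        y = np.array([1.0] * 10 + [0.0] * 10)
        model = PLSNipals(n_components=1)
        model.x_weights_ = np.full((p, 1), 1.0 / np.sqrt(p))
        model.x_scores_ = (y - y.mean() + 0.1 * rng.normal(size=n)).reshape(-1, 1)
        assert np.abs(compute_vip(model, y) - 1.0).max() < 1e-12

    def test_squared_sum_equals_feature_count(self, cohort):
        expr, pheno, _ = cohort
        model, _ = _fit(expr, pheno, 3)
        vip = compute_vip(model, pheno.to_numpy())
        p = model.x_weights_.shape[0]
        assert abs(vip @ vip - p) / p < 1e-6

    def test_matches_brute_force_double_loop(self):
        expr, pheno, _ = generate_expression(30, 12, 8, n_de=5,
                                             effect_size=1.0, noise_sd=1.0,
                                             seed=5)
        model, _ = _fit(expr, pheno, 3)
        y = pheno.to_numpy(dtype=float)
        vip = compute_vip(model, y)
        W, T = model.x_weights_, model.x_scores_
        p, h = W.shape
        r2 = np.array([pearsonr(y, T[:, k]).statistic ** 2 for k in range(h)])
        for j in range(p):
            num = sum(r2[k] * W[j, k] ** 2 for k in range(h))
            expected = np.sqrt(p * num / r2.sum())
            assert abs(vip[j] - expected) < 1e-10

    def test_uncorrelated_scores_are_an_error(self):
        y = np.array([1.0, 1, 0, 0])
        model = PLSNipals(n_components=1)
        model.x_weights_ = np.full((3, 1), 1.0 / np.sqrt(3))
        model.x_scores_ = np.array([1.0, -1, 1, -1]).reshape(-1, 1)
        with pytest.raises(InvalidParameterError):
            compute_vip(model, y)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_planted_vip_increases_with_effect_size(self, seed):
        means = []
        for effect in (0.5, 1.0, 2.0):
            expr, pheno, truth = generate_expression(
                400, 30, 14, n_de=30, effect_size=effect, noise_sd=1.0,
                seed=seed)
            model, data = _fit(expr, pheno, 2)
            vip = pd.Series(compute_vip(model, pheno.to_numpy()),
                            index=data.probe_ids)
            means.append(vip.loc[truth.de_probe_ids].mean())
        assert means[0] < means[1] < means[2]


# ---------------------------------------------------------------------------
# pooled permutation FDR
# ---------------------------------------------------------------------------

class TestPooledFdr:
    def test_hand_enumerated_instance(self):
        """3 probes, 2 permutations, null table written out by hand."""
        vip_obs = np.array([2.0, 1.0, 0.5])
        vip_null = np.array([[1.5, 0.8, 0.3],
                             [2.5, 0.9, 0.1]])
        # exceedances: 1, 2, 4 out of n_perm * p = 6
        expected = np.array([1 / 6, 2 / 6, 4 / 6])
        assert np.array_equal(pooled_fdr(vip_obs, vip_null), expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_double_sum(self, seed):
        rng = np.random.default_rng(seed)
        vip_obs = rng.exponential(size=10)
        vip_null = rng.exponential(size=(20, 10))
        fdr = pooled_fdr(vip_obs, vip_null)
        for i in range(10):
            count = sum(vip_null[j, i2] > vip_obs[i]
                        for j in range(20) for i2 in range(10))
            assert abs(fdr[i] - count / (20 * 10)) < 1e-12

    def test_ties_are_not_exceedances(self):
        fdr = pooled_fdr(np.array([1.0]), np.array([[1.0], [2.0]]))
        assert fdr[0] == 0.5  # only the 2.0 strictly exceeds

    def test_global_maximum_gets_zero(self):
        fdr = pooled_fdr(np.array([9.0, 1.0]), np.full((4, 2), 2.0))
        assert fdr[0] == 0.0 and fdr[1] == 1.0

    def test_conventional_estimator_matches_brute_force(self):
        rng = np.random.default_rng(3)
        vip_obs = rng.exponential(size=8)
        vip_null = rng.exponential(size=(10, 8))
        fdr = pooled_fdr(vip_obs, vip_null, method="conventional")
        for i in range(8):
            exceed = np.sum(vip_null > vip_obs[i])
            disc = np.sum(vip_obs >= vip_obs[i])
            assert abs(fdr[i] - min(1.0, (exceed / 10) / disc)) < 1e-12

    def test_unknown_method_rejected(self):
        with pytest.raises(InvalidParameterError):
            pooled_fdr(np.array([1.0]), np.ones((2, 1)), method="bonferroni")


class TestPermutationFdr:
    def test_deterministic_under_seed(self, cohort):
        expr, pheno, _ = cohort
        a = permutation_fdr(expr, pheno, h=2, n_perm=30, seed=9)
        b = permutation_fdr(expr, pheno, h=2, n_perm=30, seed=9)
        pd.testing.assert_series_equal(a, b)

    def test_invariant_under_joint_sample_reordering(self, cohort):
        """Shuffling expression columns and phenotype rows identically must
        not change VIP-based FDR (label-alignment correctness)."""
        expr, pheno, _ = cohort
        rng = np.random.default_rng(4)
        order = rng.permutation(expr.columns)
        a = permutation_fdr(expr, pheno, h=2, n_perm=25, seed=3)
        b = permutation_fdr(expr[order], pheno.reindex(order), h=2,
                            n_perm=25, seed=3)
        pd.testing.assert_series_equal(a, b)

    def test_vip_identity_holds_inside_every_permutation(self, cohort):
        expr, pheno, _ = cohort
        data = standardize(expr, pheno)
        null, redraws = _null_vip_matrix(data, h=2, n_perm=10, seed=1)
        p = data.X.shape[1]
        assert redraws == 0
        assert np.abs((null ** 2).sum(axis=1) - p).max() / p < 1e-6


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

class TestCrossValidation:
    def test_h_max_one_always_chooses_one(self, cohort):
        expr, pheno, _ = cohort
        curve = choose_h_cv(expr, pheno, h_max=1, seed=0)
        assert curve.chosen_h == 1 and len(curve.accuracy) == 1

    def test_separable_cohort_reaches_perfect_accuracy(self, cohort):
        expr, pheno, _ = cohort
        curve = choose_h_cv(expr, pheno, h_max=4, seed=0)
        assert curve.accuracy.max() == 1.0
        # ties broken toward the smallest h
        assert curve.chosen_h == int(np.argmax(curve.accuracy)) + 1

    def test_null_cohort_accuracy_near_majority_rate(self):
        expr, pheno, _ = generate_expression(500, 63, 20, n_de=0,
                                             effect_size=1.0, noise_sd=1.0,
                                             seed=8)
        curve = choose_h_cv(expr, pheno, h_max=6, seed=8)
        majority = 63 / 83
        sd = np.sqrt(majority * (1 - majority) / 83)
        assert curve.accuracy.max() < majority + 4 * sd

    def test_class_smaller_than_fold_count_is_error(self):
        y = np.array([1.0] * 10 + [0.0] * 2)
        X = np.random.default_rng(0).normal(size=(12, 5))
        with pytest.raises(InvalidParameterError):
            cross_val_components(X, y, h_max=2, n_folds=3)

    def test_folds_are_seeded(self, cohort):
        expr, pheno, _ = cohort
        a = choose_h_cv(expr, pheno, h_max=3, seed=5)
        b = choose_h_cv(expr, pheno, h_max=3, seed=5)
        assert np.array_equal(a.accuracy, b.accuracy)


# ---------------------------------------------------------------------------
# the selected-gene table
# ---------------------------------------------------------------------------

class TestSelectGenes:
    @staticmethod
    def _tiny():
        expr = pd.DataFrame(
            [[5.0, 6.0, 1.0, 1.5], [3.0, 3.1, 7.0, 7.2], [2.0, 2.0, 2.1, 2.2]],
            index=["p1", "p2", "p3"], columns=["c1", "c2", "k1", "k2"])
        pheno = pd.Series([1, 1, 0, 0], index=expr.columns)
        idx = pd.Index(["p1", "p2", "p3"], name="probe_id")
        vip = pd.Series([3.0, 2.0, 0.5], index=idx)
        fdr = pd.Series([0.0, 0.01, 0.5], index=idx)
        return expr, pheno, vip, fdr

    def test_strict_threshold_boundary(self):
        expr, pheno, vip, fdr = self._tiny()
        table = select_genes(expr, pheno, vip, fdr, fdr_threshold=0.01)
        sel = table[table.selected].probe_id.tolist()
        assert sel == ["p1"]  # fdr == 0.01 is NOT selected

    def test_threshold_one_selects_everything(self):
        expr, pheno, vip, fdr = self._tiny()
        table = select_genes(expr, pheno, vip, fdr, fdr_threshold=1.0)
        assert table.selected.all()

    def test_direction_follows_case_control_means(self):
        expr, pheno, vip, fdr = self._tiny()
        table = select_genes(expr, pheno, vip, fdr).set_index("probe_id")
        assert table.loc["p1", "direction"] == "up"
        assert table.loc["p2", "direction"] == "down"

    def test_sorted_by_fdr_then_vip(self):
        expr, pheno, vip, fdr = self._tiny()
        table = select_genes(expr, pheno, vip, fdr)
        assert table.probe_id.tolist() == ["p1", "p2", "p3"]

    def test_invalid_threshold_rejected(self):
        expr, pheno, vip, fdr = self._tiny()
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(InvalidParameterError):
                select_genes(expr, pheno, vip, fdr, fdr_threshold=bad)

    def test_planted_directions_recovered(self):
        expr, pheno, truth = generate_expression(
            300, 30, 14, n_de=21, effect_size=2.5, noise_sd=1.0, seed=13)
        table, _, _ = run_vip_selection(expr, pheno, h=2, n_perm=100, seed=13)
        planted = dict(zip(truth.de_probe_ids, truth.effect_sizes))
        sel = table[table.selected]
        hits = [p for p in sel.probe_id if p in planted]
        assert hits, "no planted probe selected"
        for p, d in zip(sel.probe_id, sel.direction):
            if p in planted:
                assert (planted[p] > 0) == (d == "up")
        # odd n_de with 50/50 split: one extra upregulated probe
        signs = np.sign(truth.effect_sizes)
        assert (signs > 0).sum() == (signs < 0).sum() + 1


# ---------------------------------------------------------------------------
# sklearn-style selector surface
# ---------------------------------------------------------------------------

class TestVIPSelector:
    def test_fit_transform_reduces_to_selected_columns(self, cohort):
        expr, pheno, truth = cohort
        X = expr.to_numpy().T
        y = pheno.to_numpy(dtype=float)
        sel = VIPSelector(n_components=2, n_perm=60, random_state=1).fit(X, y)
        assert sel.get_support().sum() == sel.transform(X).shape[1]
        assert sel.vip_.shape == (X.shape[1],)
        # planted probes dominate the selection
        planted = {int(p[3:]) for p in truth.de_probe_ids}
        chosen = set(np.flatnonzero(sel.get_support()))
        assert len(chosen & planted) / len(planted) > 0.5

    def test_cv_mode_records_curve(self, cohort):
        expr, pheno, _ = cohort
        X, y = expr.to_numpy().T, pheno.to_numpy(dtype=float)
        sel = VIPSelector(n_components="cv", h_max=3, n_perm=20,
                          random_state=0).fit(X, y)
        assert sel.cv_curve_ is not None and sel.h_ == sel.cv_curve_.chosen_h

    def test_requires_binary_labels(self, rng):
        X = rng.normal(size=(10, 5))
        with pytest.raises(InvalidParameterError):
            VIPSelector(n_components=1).fit(X, np.arange(10.0))

    def test_get_set_params_round_trip(self):
        sel = VIPSelector(n_perm=50, fdr_threshold=0.05)
        assert sel.get_params()["n_perm"] == 50
        sel.set_params(n_perm=10)
        assert sel.n_perm == 10
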