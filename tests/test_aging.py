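"""Age matching, parcel volumes, aging regression and FWE correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crossmorph import (
    GMStack,
    fit_aging_model,
    fwe_correct,
    gm_fraction_regression,
    match_age_range,
    parcel_gm_volumes,
)


def make_covariates(n, rng, age_range=(20, 60)):
    return pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(n)],
        "age": rng.uniform(*age_range, n),
        "sex": rng.integers(0, 2, n),
        "tiv": rng.normal(1400, 100, n),
        "field_strength": rng.integers(0, 2, n),
    })


class TestMatchAgeRange:
    def test_chimp_human_cutoff_is_58(self):
        cutoff, kept = match_age_range([30, 50, 58, 58.5, 70], 50, factor=1.15)
        assert cutoff == 58
        assert list(kept) == [0, 1, 2]

    def test_unit_factor_keeps_reference_max(self):
        cutoff, _ = match_age_range([10, 20], 50, factor=1.0)
        assert cutoff == 50

    def test_all_below_cutoff_unchanged(self):
        ages = [10, 20, 30]
        _, kept = match_age_range(ages, 50)
        assert list(kept) == [0, 1, 2]

    def test_empty_result_rejected(self):
        with pytest.raises(ValueError):
            match_age_range([90, 95], 50)


def _stack_from_matrix(data, rng, voxel_mm=2.0):
    m, n = data.shape
    side = int(round(m ** (1 / 3)))
    assert side**3 == m
    mask = np.ones((side, side, side), bool)
    return GMStack(
        data=data, mask=mask, affine=np.diag([voxel_mm] * 3 + [1.0]),
        covariates=make_covariates(n, rng),
    )


class TestParcelGMVolumes:
    def test_constant_map_volume(self):
        rng = np.random.default_rng(0)
        data = np.full((27, 4), 0.5)
        stack = _stack_from_matrix(data, rng)
        labels = np.repeat([1, 2, 3], 9)
        vols = parcel_gm_volumes(stack, labels)
        # 9 voxels x 8 mm^3 x 0.5 / 1000
        assert np.allclose(vols.to_numpy(), 0.5 * 9 * 8 / 1000)

    def test_linearity_in_intensity(self):
        rng = np.random.default_rng(1)
        data = rng.random((27, 5))
        stack = _stack_from_matrix(data, rng)
        stack2 = _stack_from_matrix(2 * data, np.random.default_rng(1))
        labels = np.repeat([1, 2, 3], 9)
        assert np.allclose(2 * parcel_gm_volumes(stack, labels).to_numpy(),
                           parcel_gm_volumes(stack2, labels).to_numpy())

    def test_planted_parcel_means_recovered(self):
        rng = np.random.default_rng(2)
        data = np.zeros((27, 3))
        labels = np.repeat([1, 2], [13, 14])
        data[labels == 1] = 0.4
        data[labels == 2] = 0.8
        stack = _stack_from_matrix(data, rng)
        vols = parcel_gm_volumes(stack, labels)
        assert np.allclose(vols.loc[1], 0.4 * 13 * 8 / 1000)
        assert np.allclose(vols.loc[2], 0.8 * 14 * 8 / 1000)


class TestFitAgingModel:
    def _simulate(self, rng, n=80, n_parcels=6, beta_age=0.0, noise=1.0):
        cov = make_covariates(n, rng)
        base = 50 + beta_age * cov["age"].to_numpy()
        vols = base + noise * rng.standard_normal((n_parcels, n))
        return pd.DataFrame(vols, index=np.arange(1, n_parcels + 1)), cov

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(3)
        vols, cov = self._simulate(rng, beta_age=-0.2)
        table = fit_aging_model(vols, cov)
        X = np.column_stack([
            np.ones(len(cov)), cov["age"], cov["sex"], cov["tiv"],
            cov["field_strength"],
        ])
        XtX_inv = np.linalg.inv(X.T @ X)
        for pid in vols.index:
            y = vols.loc[pid].to_numpy()
            beta = XtX_inv @ X.T @ y
            resid = y - X @ beta
            sigma2 = resid @ resid / (len(y) - X.shape[1])
            se = np.sqrt(sigma2 * XtX_inv[1, 1])
            assert np.isclose(table.loc[pid, "beta_age"], beta[1], rtol=1e-8)
            assert np.isclose(table.loc[pid, "t_age"], beta[1] / se, rtol=1e-8)

    def test_shift_invariance_of_t_statistic(self):
        rng = np.random.default_rng(4)
        vols, cov = self._simulate(rng)
        a = fit_aging_model(vols, cov)
        b = fit_aging_model(vols + 100.0, cov)
        assert np.allclose(a["t_age"], b["t_age"], rtol=1e-10)

    def test_significance_invariant_to_parcel_order(self):
        rng = np.random.default_rng(5)
        vols, cov = self._simulate(rng, beta_age=-0.5, noise=0.5)
        a = fit_aging_model(vols, cov)
        perm = rng.permutation(vols.index)
        b = fit_aging_model(vols.loc[perm], cov)
        assert (a.loc[perm, "significant"].to_numpy()
                == b["significant"].to_numpy()).all()

    def test_decline_metric_modes(self):
        rng = np.random.default_rng(6)
        vols, cov = self._simulate(rng, beta_age=-0.5, noise=0.5)
        absolute = fit_aging_model(vols, cov)
        signed = fit_aging_model(vols, cov, signed=True)
        assert (absolute["decline_metric"] >= 0).all()
        assert np.allclose(absolute["decline_metric"],
                           np.abs(signed["decline_metric"]))

    def test_collinear_design_rejected_with_names(self):
        rng = np.random.default_rng(7)
        vols, cov = self._simulate(rng)
        cov["tiv"] = cov["age"] * 2.0
        with pytest.raises(ValueError, match="collinear"):
            fit_aging_model(vols, cov)


class TestFWECorrect:
    def test_single_test_significant(self):
        p_adj, flags = fwe_correct([0.04])
        assert flags[0]
        assert np.isclose(p_adj[0], 0.04)

    def test_all_ones_none_significant(self):
        _, flags = fwe_correct([1.0] * 10)
        assert not flags.any()

    def test_matches_holm_recursion_oracle(self):
        rng = np.random.default_rng(8)
        p = rng.random(17)
        p_adj, _ = fwe_correct(p)
        # direct step-down recursion
        order = np.argsort(p)
        adj = np.empty(17)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (17 - rank) * p[idx])
            adj[idx] = min(1.0, running)
        assert np.allclose(p_adj, adj)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=25))
    def test_holm_between_bonferroni_and_uncorrected(self, p):
        p = np.asarray(p)
        _, holm = fwe_correct(p, alpha=0.05)
        bonf = p <= 0.05 / p.size
        raw = p <= 0.05
        assert np.all(holm >= bonf)   # Holm rejects a superset of Bonferroni
        assert np.all(raw >= holm)    # and a subset of the uncorrected flags

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            fwe_correct([0.1, np.nan])


class TestGMFractionRegression:
    def test_perfect_linear_decline(self):
        age = np.linspace(20, 60, 30)
        tiv = np.full(30, 1400.0)
        gm = (50 - 0.1 * age) / 100 * tiv
        fit = gm_fraction_regression(gm, tiv, age)
        assert np.isclose(fit.r_squared, 1.0)
        assert np.isclose(fit.slope, -0.1)

    def test_permuted_response_near_zero_r2(self):
        rng = np.random.default_rng(9)
        age = np.linspace(20, 60, 400)
        gm = rng.permutation(700 - 2 * age + rng.normal(0, 5, 400))
        fit = gm_fraction_regression(gm, np.full(400, 1400.0), age)
        assert fit.r_squared < 0.03

    def test_matches_closed_form_sums(self):
        rng = np.random.default_rng(10)
        age = rng.uniform(20, 60, 20)
        tiv = rng.normal(1400, 100, 20)
        gm = 0.45 * tiv - 1.1 * age + rng.normal(0, 10, 20)
        fit = gm_fraction_regression(gm, tiv, age)
        y = 100 * gm / tiv
        yhat = fit.intercept + fit.slope * age
        r2 = 1 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2)
        assert np.isclose(fit.r_squared, r2, rtol=1e-10)

    def test_constant_age_rejected(self):
        with pytest.raises(ValueError):
            gm_fraction_regression([1.0, 2.0], [3.0, 3.0], [5.0, 5.0])
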