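"""VAR estimation and GPDC tests: closed-form, recovery and cross-checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netgranger import (
    CouplingSpec,
    Edge,
    VARModel,
    band_bin_centres,
    build_stable_var,
    fit_var,
    gpdc_spectrum,
    random_coupling_spec,
    select_order_group,
    simulate_timecourses,
    subject_gpdc,
    transfer_spectrum,
)

NEAR_ZERO_HZ = np.array([1e-9])  # lambda ~ 0 (difference to 0 is O(lambda^2))


def bivariate_model():
    return VARModel(np.zeros(2), np.array([[[0.5, 0.0], [0.4, 0.5]]]), np.eye(2))


class TestFitVar:
    def test_recovers_known_var1(self):
        A = np.array([[[0.5, 0.2], [0.1, 0.4]]])
        edges = tuple(Edge(j, i, 1, A[0, i, j]) for i in range(2) for j in range(2))
        model = build_stable_var(CouplingSpec(2, 1, edges), "A")
        tc = simulate_timecourses(model, 1000, seed=5)
        fit = fit_var(tc, 1)
        assert np.allclose(fit.coefficients, A, atol=0.05)

    def test_white_noise_coefficients_near_zero(self):
        rng = np.random.default_rng(0)
        tc = rng.standard_normal((3, 2000))
        fit = fit_var(tc, 1)
        # rough standard error of a VAR coefficient is 1/sqrt(T)
        assert np.all(np.abs(fit.coefficients) < 3.0 / np.sqrt(2000))

    def test_self_consistency_on_noiseless_predictions(self):
        """Refitting on the model's own one-step recursion returns the same
        coefficients."""
        model = build_stable_var(random_coupling_spec(3, 2, seed=2), "A")
        tc = simulate_timecourses(model, 600, seed=3)
        fit = fit_var(tc, 2)
        # roll the fitted deterministic recursion forward from the data
        k, p, T = 3, 2, 600
        pred = tc.copy()
        for t in range(p, T):
            acc = fit.intercept.copy()
            for l in range(1, p + 1):
                acc += fit.coefficients[l - 1] @ tc[:, t - l]
            pred[:, t] = acc
        # regression of predictions on the same lagged data is exact
        n_eff = T - p
        X = np.empty((n_eff, 1 + k * p))
        X[:, 0] = 1.0
        for l in range(1, p + 1):
            X[:, 1 + (l - 1) * k : 1 + l * k] = tc[:, p - l : T - l].T
        B, *_ = np.linalg.lstsq(X, pred[:, p:].T, rcond=None)
        refit = np.stack([B[1 + l * k : 1 + (l + 1) * k].T for l in range(p)])
        assert np.allclose(refit, fit.coefficients, atol=1e-8)

    def test_matches_statsmodels(self):
        from statsmodels.tsa.api import VAR as SMVar

        model = build_stable_var(random_coupling_spec(3, 2, seed=8), "A")
        tc = simulate_timecourses(model, 500, seed=9)
        fit = fit_var(tc, 2)
        sm_res = SMVar(tc.T).fit(maxlags=2, trend="c")
        assert np.allclose(fit.coefficients, sm_res.coefs, atol=1e-8)
        assert np.allclose(fit.intercept, sm_res.params[0], atol=1e-8)

    def test_rank_deficient_rejected(self):
        tc = np.vstack([np.arange(100.0), np.arange(100.0)])  # duplicated channel
        with pytest.raises(np.linalg.LinAlgError):
            fit_var(tc, 1)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            fit_var(np.zeros((4, 20)), 3)


class TestOrderSelection:
    def test_var2_cohort_selects_order_two(self):
        A1 = np.array([[0.2, 0.0], [0.0, 0.2]])
        A2 = np.array([[0.45, 0.0], [0.35, 0.4]])
        edges = tuple(
            Edge(j, i, l + 1, [A1, A2][l][i, j])
            for l in range(2) for i in range(2) for j in range(2)
            if [A1, A2][l][i, j] != 0
        )
        model = build_stable_var(CouplingSpec(2, 2, edges), "A")
        tcs = [simulate_timecourses(model, 512, seed=s) for s in range(10)]
        sel = select_order_group(tcs, p_max=5)
        assert sel.order == 2
        assert sel.table.shape[0] == 5

    def test_white_noise_prefers_smallest_order(self):
        rng = np.random.default_rng(4)
        tcs = [rng.standard_normal((2, 400)) for _ in range(8)]
        assert select_order_group(tcs, p_max=4).order == 1

    def test_single_subject_reduces_to_own_argmin(self):
        model = build_stable_var(random_coupling_spec(2, 1, seed=1), "A")
        tc = simulate_timecourses(model, 400, seed=2)
        sel = select_order_group([tc], p_max=4)
        assert sel.order == sel.table["subject_0"].idxmin()


class TestGPDCSpectrum:
    def test_closed_form_bivariate(self):
        """abar(0) = I - A1; squared GPDC(1->2) = 0.16/0.41; amplitude form
        0.4/sqrt(0.41)."""
        spec = gpdc_spectrum(bivariate_model(), NEAR_ZERO_HZ)
        assert spec.values[0, 1, 0] == pytest.approx(0.16 / 0.41, abs=1e-12)
        amp = gpdc_spectrum(bivariate_model(), NEAR_ZERO_HZ, squared=False)
        assert amp.values[0, 1, 0] == pytest.approx(0.4 / np.sqrt(0.41), abs=1e-12)

    def test_absent_edge_exactly_zero_everywhere(self):
        spec = gpdc_spectrum(bivariate_model(), band_bin_centres())
        assert np.all(spec.path(1, 0) == 0.0)

    def test_diagonal_only_model_decoupled(self):
        m = VARModel(np.zeros(3), np.array([np.diag([0.5, 0.3, 0.7])]), np.eye(3))
        spec = gpdc_spectrum(m, band_bin_centres())
        off = ~np.eye(3, dtype=bool)
        assert np.all(spec.values[:, off] == 0.0)
        assert np.allclose(np.diagonal(spec.values, axis1=1, axis2=2), 1.0)

    def test_transfer_identity_when_coefficients_vanish(self):
        m = VARModel(np.zeros(2), np.zeros((1, 2, 2)), np.eye(2))
        ts = transfer_spectrum(m, band_bin_centres())
        assert np.allclose(ts.abar, np.eye(2)[None], atol=1e-14)

    def test_direct_complex_arithmetic_oracle(self):
        """Independent evaluation of the transfer polynomial and Eq.-style
        normalisation at an arbitrary frequency."""
        model = build_stable_var(random_coupling_spec(3, 2, seed=6), "A")
        f = np.array([0.101])
        lam = f[0] * 2.0
        abar = np.eye(3).astype(complex)
        for l in range(1, 3):
            abar -= model.coefficients[l - 1] * np.exp(-2j * np.pi * lam * l)
        s2 = np.diag(model.residual_covariance)
        expected = np.empty((3, 3))
        for i in range(3):
            for j in range(3):
                num = abs(abar[i, j]) ** 2 / s2[i]
                den = sum(abs(abar[m_, j]) ** 2 / s2[m_] for m_ in range(3))
                expected[i, j] = num / den
        spec = gpdc_spectrum(model, f)
        assert np.allclose(spec.values[0], expected, atol=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_normalisation_and_range_random_models(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 7))
        p = int(rng.integers(1, 6))
        model = build_stable_var(
            random_coupling_spec(k, p, seed=seed, density=0.5, coeff_scale=0.8), "A"
        )
        spec = gpdc_spectrum(model, band_bin_centres())
        assert np.all(spec.values >= 0.0)
        assert np.all(spec.values <= 1.0)
        assert np.allclose(spec.values.sum(axis=1), 1.0, atol=1e-10)

    def test_scale_equivariance(self):
        """Rescaling one channel's data leaves estimated GPDC ~ invariant."""
        model = build_stable_var(random_coupling_spec(3, 1, seed=3), "A")
        tc = simulate_timecourses(model, 4000, seed=4)
        g1 = gpdc_spectrum(fit_var(tc, 1), band_bin_centres())
        tc2 = tc.copy()
        tc2[1] *= 50.0
        g2 = gpdc_spectrum(fit_var(tc2, 1), band_bin_centres())
        assert np.allclose(g1.values, g2.values, atol=1e-6)


class TestSubjectGPDC:
    def test_default_grid_has_fifty_bins(self):
        bins = band_bin_centres()
        assert bins.size == 50
        assert bins[0] == pytest.approx(0.051)
        assert bins[-1] == pytest.approx(0.149)

    def test_independent_channels_low_cross_values(self):
        rng = np.random.default_rng(12)
        vals = []
        for _ in range(20):
            tc = rng.standard_normal((2, 256))
            spec = subject_gpdc(tc, order=1)
            vals.extend([spec.path(0, 1).max(), spec.path(1, 0).max()])
        assert np.quantile(vals, 0.95) < 0.2

    def test_lagged_copy_near_one(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal(600)
        y = np.roll(x, 1) + 1e-6 * rng.standard_normal(600)
        spec = subject_gpdc(np.vstack([x, y]), order=1)
        assert spec.path(0, 1).min() > 0.9

    def test_path_table_long_format(self):
        model = build_stable_var(random_coupling_spec(2, 1, seed=0), "A")
        tc = simulate_timecourses(model, 256, seed=0)
        tab = subject_gpdc(tc, 1).path_table()
        assert set(tab.columns) == {"source", "target", "bin_hz", "value"}
        assert len(tab) == 2 * 50
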