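"""Group-inference tests: KW oracle, cluster rule, windows, reliability."""

import itertools

import numpy as np
import pytest

from netgranger import (
    binwise_cluster_test,
    bonferroni_threshold,
    kruskal_wallis,
    loo_reliability,
    normality_gate,
    window_summary,
)


def kw_oracle(a, b):
    """Independent tie-corrected H from first principles (manual ranking)."""
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(pooled.size)
    i = 0
    sorted_vals = pooled[order]
    while i < pooled.size:
        j = i
        while j < pooled.size and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j + 1)  # average rank of the tie block
        i = j
    n, na = pooled.size, len(a)
    ra, rb = ranks[:na].sum(), ranks[na:].sum()
    h = 12.0 / (n * (n + 1)) * (ra**2 / na + rb**2 / (n - na)) - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction


class TestNormalityGate:
    def test_normal_sample_parametric(self, rng):
        assert normality_gate(rng.standard_normal(1000)) == "parametric"

    def test_heavy_tails_nonparametric(self, rng):
        x = rng.standard_t(df=2, size=2000)
        assert normality_gate(x) == "nonparametric"

    def test_boundary_is_strict(self):
        # engineered sample with |skewness| exactly handled by strict inequality:
        # a symmetric sample has skewness 0 and Pearson kurtosis well below 7
        x = np.concatenate([-np.arange(1, 50.0), np.arange(1, 50.0)])
        assert normality_gate(x) == "parametric"

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="variance"):
            normality_gate(np.ones(10))


class TestKruskalWallis:
    def test_worked_value_separated_triples(self):
        h, p = kruskal_wallis([1, 2, 3], [4, 5, 6])
        assert h == pytest.approx(3.857, abs=5e-4)

    def test_worked_value_pairs(self):
        h, _ = kruskal_wallis([1, 2], [3, 4])
        assert h == pytest.approx(2.4, abs=1e-12)

    def test_identical_samples_h_zero(self):
        h, p = kruskal_wallis([1.0, 2.0, 3.0], [2.0, 1.0, 3.0])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_all_tied_error(self):
        with pytest.raises(ValueError, match="tied"):
            kruskal_wallis([1.0, 1.0], [1.0, 1.0])

    def test_matches_exhaustive_oracle_all_small_splits(self):
        """H equals the independent rank oracle on every two-group split of a
        pooled sample with ties, n_total = 8."""
        pooled = np.array([1.2, 3.4, 3.4, 5.0, 2.0, 8.0, 0.5, 3.4])
        idx = np.arange(8)
        checked = 0
        for na in range(2, 7):
            for subset in itertools.combinations(idx, na):
                sel = np.zeros(8, dtype=bool)
                sel[list(subset)] = True
                a, b = pooled[sel], pooled[~sel]
                if np.ptp(pooled) == 0:
                    continue
                h, _ = kruskal_wallis(a, b)
                assert h == pytest.approx(kw_oracle(a, b), abs=1e-10)
                checked += 1
        assert checked == sum(
            len(list(itertools.combinations(idx, na))) for na in range(2, 7)
        )


class TestBinwiseClusterTest:
    def _spectra(self, rng, n, n_bins=20, k=2, shift=0.0, shift_bins=slice(5, 12)):
        arr = rng.uniform(0.1, 0.3, size=(n, n_bins, k, k))
        arr[:, shift_bins, 1, 0] += shift
        return arr

    def test_constructed_five_bin_run_reported(self, rng):
        bins = np.linspace(0.05, 0.15, 20)
        a = self._spectra(rng, 20, shift=0.3)
        b = self._spectra(rng, 20, shift=0.0)
        results = binwise_cluster_test(a, b, bins)
        bands = [r for r in results if r.significant_band is not None]
        assert any(r.source == 0 and r.target == 1 for r in bands)
        hit = next(r for r in bands if (r.source, r.target) == (0, 1))
        assert hit.direction == "A"
        assert hit.significant_band[0] >= bins[4]

    def test_four_bin_run_not_reported(self, rng):
        bins = np.linspace(0.05, 0.15, 20)
        a = self._spectra(rng, 25, shift=2.0, shift_bins=slice(5, 9))  # 4 bins only
        b = self._spectra(rng, 25, shift=0.0)
        results = binwise_cluster_test(a, b, bins)
        assert all(r.significant_band is None for r in results)

    def test_null_spectra_rarely_flagged(self):
        rng = np.random.default_rng(55)
        flags = 0
        trials = 40
        for _ in range(trials):
            a = self._spectra(rng, 15)
            b = self._spectra(rng, 15)
            res = binwise_cluster_test(a, b, np.linspace(0.05, 0.15, 20))
            flags += sum(r.significant_band is not None for r in res)
        assert flags / (trials * 2) < 0.05  # 2 off-diagonal paths per trial


class TestWindowSummary:
    def test_worked_percentages_and_high_mean(self):
        ws = window_summary([np.array([0.1, 0.25, 0.4, 0.5])])
        assert np.allclose(ws.percentages[0], [25.0, 25.0, 50.0])
        assert ws.means[0, 2] == pytest.approx(0.45)
        assert ws.out_of_range[0] == 0.0

    def test_all_below_low_boundary(self):
        ws = window_summary([np.array([0.01, 0.02, 0.04])])
        assert np.allclose(ws.percentages[0], 0.0)
        assert ws.out_of_range[0] == pytest.approx(100.0)
        assert np.all(np.isnan(ws.means[0]))

    def test_mass_sums_to_100(self, rng):
        vals = [rng.uniform(0, 1, size=200) for _ in range(5)]
        ws = window_summary(vals)
        totals = ws.percentages.sum(axis=1) + ws.out_of_range
        assert np.allclose(totals, 100.0, atol=1e-9)

    def test_boundaries_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            window_summary([np.array([0.1])], boundaries=[0.3, 0.2])


class TestLooReliability:
    def test_overwhelming_difference_fraction_one(self, rng):
        vals = np.concatenate([rng.normal(0, 0.1, 10), rng.normal(5, 0.1, 10)])
        labels = ["A"] * 10 + ["B"] * 10
        res = loo_reliability(kruskal_wallis, vals, labels, alpha=0.05, threshold=0.9917)
        assert res.fraction_significant == 1.0
        assert res.is_reliable

    def test_null_not_reliable(self, rng):
        vals = rng.standard_normal(20)
        labels = ["A"] * 10 + ["B"] * 10
        res = loo_reliability(kruskal_wallis, vals, labels)
        assert not res.is_reliable

    def test_threshold_boundary_strict(self):
        from netgranger.groupcompare import ReliabilityResult

        r = ReliabilityResult("t", 10, fraction_significant=0.9917, threshold=0.9917)
        assert not r.is_reliable  # strictly "more than"

    def test_constant_outcome_fraction_exact(self, rng):
        always_sig = lambda a, b: (0.0, 1e-12)
        vals = rng.standard_normal(12)
        labels = ["A"] * 6 + ["B"] * 6
        res = loo_reliability(always_sig, vals, labels)
        assert res.fraction_significant in (0.0, 1.0)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            loo_reliability(kruskal_wallis, np.arange(5.0), ["A", "A", "B", "B", "B"])


class TestBonferroni:
    def test_printed_thresholds(self):
        alpha6, pct6 = bonferroni_threshold(0.05, 6)
        assert pct6 == 99.17
        alpha4, _ = bonferroni_threshold(0.05, 4)
        assert alpha4 == pytest.approx(0.0125)
        alpha2, _ = bonferroni_threshold(0.05, 2)
        assert alpha2 == pytest.approx(0.025)
        _, pct3 = bonferroni_threshold(0.05, 3)
        assert round(pct3, 1) == 98.3

    def test_identity_at_m_one(self):
        assert bonferroni_threshold(0.05, 1) == (0.05, 95.0)

    def test_m_zero_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
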