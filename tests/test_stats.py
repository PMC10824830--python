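"""Fisher pooling, contrasts, corrected bands, and peak extraction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dyadsync import stats, xcorr
from dyadsync.errors import AlignmentError, ConfigurationError, ParameterError
from dyadsync.xcorr import CrossCorrelationCurve, LagGrid

#: Two-sided standard-normal quantile at 0.975, frozen from tables.
Z_975 = 1.959963984540054


def _curve(rs, ms, grid=None, dyad="d", segment="whole"):
    grid = grid or LagGrid(tuple(range(0, 100 * len(rs), 100)), 120.0)
    return CrossCorrelationCurve(
        grid, np.asarray(rs, dtype=float), np.asarray(ms, dtype=int), dyad, segment
    )


class TestFisherTransform:
    def test_fixed_point_and_known_value(self):
        assert stats.fisher(0.0) == 0.0
        # 0.5 * ln(1.8 / 0.2) = 0.5 * ln 9 = ln 3
        assert stats.fisher(0.8) == pytest.approx(np.log(3.0), abs=1e-12)
        assert stats.fisher_inv(0.5 * np.log(3.0)) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("r", [0.1, 0.3, 0.5, 0.7, 0.9])
    def test_odd_symmetry(self, r):
        assert stats.fisher(-r) == pytest.approx(-stats.fisher(r), abs=1e-15)

    @given(st.floats(min_value=-0.999, max_value=0.999))
    def test_round_trip_identity(self, r):
        assert stats.fisher_inv(stats.fisher(r)) == pytest.approx(r, abs=1e-12)

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            stats.fisher(1.0)

    def test_clamp_pulls_unit_correlations_inside(self):
        with pytest.warns(RuntimeWarning):
            out = stats.clamp_correlation(np.array([1.0, -1.0, 0.5]))
        assert np.all(np.abs(out) < 1.0)
        assert out[2] == 0.5


class TestPool:
    def test_identical_dyads_pool_to_their_value(self):
        curves = [_curve([0.3, -0.2], [50, 40], dyad=f"d{i}") for i in range(5)]
        fc = stats.pool(curves)
        np.testing.assert_allclose(np.tanh(fc.X), [0.3, -0.2], atol=1e-12)

    def test_hand_evaluated_two_dyad_pool(self):
        # atanh(0.8) = ln 3; mean with atanh(0) = (ln 3)/2; tanh((ln 3)/2) = 0.5
        fc = stats.pool([_curve([0.8], [10]), _curve([0.0], [10])])
        assert fc.X[0] == pytest.approx(np.log(3.0) / 2.0, abs=1e-12)
        assert np.tanh(fc.X[0]) == pytest.approx(0.5, abs=1e-12)

    def test_pooled_standard_error(self):
        fc = stats.pool([_curve([0.1], [10]), _curve([0.2], [10])])
        assert fc.se[0] == pytest.approx(1.0 / np.sqrt(20.0), abs=1e-12)
        assert fc.m_total[0] == 20
        assert fc.n_dyads[0] == 2

    def test_permutation_invariant(self, rng):
        curves = [_curve(rng.uniform(-0.5, 0.5, 3), [100, 90, 80], dyad=f"d{i}")
                  for i in range(6)]
        fc1 = stats.pool(curves)
        fc2 = stats.pool(curves[::-1])
        np.testing.assert_allclose(fc1.X, fc2.X, atol=1e-14)
        np.testing.assert_allclose(fc1.se, fc2.se, atol=1e-14)

    def test_adding_mean_dyad_keeps_x_shrinks_se(self):
        curves = [_curve([0.2], [100]), _curve([0.4], [100])]
        fc = stats.pool(curves)
        extra = _curve([np.tanh(fc.X[0])], [100])
        fc2 = stats.pool(curves + [extra])
        assert fc2.X[0] == pytest.approx(fc.X[0], abs=1e-12)
        assert fc2.se[0] < fc.se[0]

    def test_undefined_lags_excluded_from_pooling(self):
        fc = stats.pool([_curve([0.4, np.nan], [50, 40]), _curve([0.2, 0.1], [50, 40])])
        assert fc.n_dyads.tolist() == [2, 1]
        assert fc.X[1] == pytest.approx(np.arctanh(0.1))
        assert fc.m_total[1] == 40  # only the defined dyad's pairs count

    def test_empty_input_rejected(self):
        with pytest.raises(ConfigurationError):
            stats.pool([])

    def test_mismatched_grids_rejected(self):
        a = _curve([0.1], [10], grid=LagGrid((0,), 120.0))
        b = _curve([0.1], [10], grid=LagGrid((100,), 120.0))
        with pytest.raises(AlignmentError):
            stats.pool([a, b])


class TestSubtract:
    def _fc(self, X, se, m=1000):
        grid = LagGrid(tuple(range(0, 100 * len(X), 100)), 120.0)
        n = len(X)
        return stats.FisherCurve(
            grid, np.asarray(X, float), np.asarray(se, float),
            np.full(n, m, float), np.full(n, 10), label="fc"
        )

    def test_self_difference_is_zero(self):
        fc = self._fc([0.3, -0.1], [0.02, 0.02])
        np.testing.assert_allclose(stats.subtract(fc, fc).X, 0.0, atol=1e-15)

    def test_quadrature_of_standard_errors(self):
        d = stats.subtract(self._fc([0.1], [0.03]), self._fc([0.0], [0.04]))
        assert d.se[0] == pytest.approx(0.05, abs=1e-12)

    def test_huge_baseline_leaves_minuend(self):
        a = self._fc([0.25], [0.03])
        zero = self._fc([0.0], [1e-9], m=10**18)
        d = stats.subtract(a, zero)
        assert d.X[0] == pytest.approx(0.25)
        assert d.se[0] == pytest.approx(0.03, rel=1e-9)

    def test_antisymmetric(self, rng):
        a = self._fc(rng.normal(0, 0.2, 4), np.full(4, 0.02))
        b = self._fc(rng.normal(0, 0.2, 4), np.full(4, 0.05))
        np.testing.assert_allclose(
            stats.subtract(a, b).X, -stats.subtract(b, a).X, atol=1e-15
        )


class TestBand:
    def _fc(self, X, se):
        grid = LagGrid(tuple(range(0, 100 * len(X), 100)), 120.0)
        return stats.FisherCurve(
            grid, np.asarray(X, float), np.asarray(se, float),
            np.full(len(X), 1e4), np.full(len(X), 10), label="fc"
        )

    def test_null_center_symmetric_not_significant(self):
        ac = stats.band(self._fc([0.0], [0.05]))
        assert ac.ci_low[0] == pytest.approx(-ac.ci_high[0], abs=1e-12)
        assert not ac.significant[0]
        assert ac.morphology[0] == "none"

    def test_uncorrected_interval_uses_z_1p96(self):
        ac = stats.band(self._fc([0.2], [0.05]), alpha=0.05, n_comparisons=1)
        assert ac.ci_low[0] == pytest.approx(np.tanh(0.2 - Z_975 * 0.05), abs=1e-9)
        assert ac.ci_high[0] == pytest.approx(np.tanh(0.2 + Z_975 * 0.05), abs=1e-9)

    def test_family_wise_defaults_match_printed_correction(self):
        # alpha / n = 0.001 / 41, reported to one significant figure as 0.00002
        p_c = stats.DEFAULT_ALPHA / stats.DEFAULT_N_COMPARISONS
        assert p_c == pytest.approx(2.44e-5, abs=5e-7)
        assert float(f"{p_c:.1g}") == 2e-5

    def test_morphology_labels_follow_interval_sign(self):
        ac = stats.band(self._fc([0.5, -0.5, 0.0], [0.01, 0.01, 0.5]))
        assert list(ac.morphology) == ["symmetric", "asymmetric", "none"]
        assert ac.significant.tolist() == [True, True, False]

    def test_ci_width_shrinks_with_more_pairs(self):
        widths = []
        for m in (100, 1000, 10000):
            ac = stats.band(self._fc([0.1], [1.0 / np.sqrt(m)]))
            widths.append(ac.ci_high[0] - ac.ci_low[0])
        assert widths[0] > widths[1] > widths[2]

    def test_degenerate_se_rejected(self):
        with pytest.raises(ParameterError):
            stats.band(self._fc([0.1], [0.0]))


class TestFindPeaks:
    def _ac(self, R):
        R = np.asarray(R, float)
        n = len(R)
        grid = LagGrid(tuple(range(0, 100 * n, 100)), 120.0)
        return stats.AggregatedCurve(
            grid, R, R - 0.01, R + 0.01, np.arctanh(np.clip(R, -0.99, 0.99)),
            np.full(n, 0.01), np.full(n, 1e4), np.full(n, 10),
            np.zeros(n, bool), np.full(n, "none", object), label="t"
        )

    def test_monotone_curve_peaks_at_endpoint(self):
        peaks = stats.find_peaks(self._ac([0.0, 0.1, 0.2, 0.3]))
        kinds = {(p.lag_ms, p.kind) for p in peaks}
        assert (300, "max") in kinds and (0, "min") in kinds

    def test_injected_interior_maximum_found(self):
        peaks = stats.find_peaks(self._ac([0.0, 0.01, 0.02, 0.01, 0.3, 0.01, 0.0]))
        maxima = [p for p in peaks if p.kind == "max" and p.is_global]
        assert len(maxima) == 1 and maxima[0].lag_ms == 400
        assert maxima[0].morphology == "symmetric"

    def test_matches_exhaustive_scan(self, rng):
        R = rng.uniform(-0.3, 0.3, 16)
        peaks = stats.find_peaks(self._ac(R))
        gmax = [p for p in peaks if p.kind == "max" and p.is_global]
        gmin = [p for p in peaks if p.kind == "min" and p.is_global]
        assert gmax[0].lag_ms == 100 * int(np.argmax(R))
        assert gmin[0].lag_ms == 100 * int(np.argmin(R))
        assert gmax[0].R == pytest.approx(R.max())
        assert gmin[0].R == pytest.approx(R.min())

    def test_signs_label_morphology(self):
        peaks = stats.find_peaks(self._ac([-0.2, 0.1, -0.2]))
        by_lag = {p.lag_ms: p for p in peaks if p.kind == "max"}
        assert by_lag[100].morphology == "symmetric"
        lows = {p.lag_ms: p for p in peaks if p.kind == "min"}
        assert lows[0].morphology == "asymmetric"
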