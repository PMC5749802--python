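"""Weight-at-day fits, growth-coefficient estimation and cohort splitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from planktivore.growth import (
    FitError,
    annual_increment,
    build_weight_trajectory,
    estimate_k,
    feeding_window_diagnostic,
    fit_weight_at_day,
    split_growth,
    window_midpoint,
)


def samples_on_quadratic(a, b, c, group=33, days=None, noise_sd=0.0, seed=0):
    days = np.arange(91, 259) if days is None else np.asarray(days)
    rng = np.random.default_rng(seed)
    w = a * days**2 + b * days + c + rng.normal(0.0, noise_sd, days.size)
    return pd.DataFrame(
        {"doy": days, "length_cm": group + 0.5, "weight_g": w}
    )


class TestFitWeightAtDay:
    def test_noiseless_recovery_exact(self):
        truth = (0.002, -0.3, 250.0)
        fit = fit_weight_at_day(samples_on_quadratic(*truth), 33)
        assert fit.coefficients == pytest.approx(truth, abs=1e-8)

    def test_constant_weights_degenerate_fit(self):
        fit = fit_weight_at_day(samples_on_quadratic(0.0, 0.0, 250.0), 33)
        assert fit.a == pytest.approx(0.0, abs=1e-10)
        assert fit.b == pytest.approx(0.0, abs=1e-8)
        assert fit.c == pytest.approx(250.0, rel=1e-9)

    def test_noisy_recovery_within_three_se(self):
        truth = (0.002, -0.3, 250.0)
        days = np.random.default_rng(3).integers(91, 259, 200)
        fit = fit_weight_at_day(
            samples_on_quadratic(*truth, days=days, noise_sd=5.0, seed=3), 33
        )
        for est, true, se in zip(fit.coefficients, truth, fit.coef_se):
            assert abs(est - true) <= 3 * se

    def test_too_few_points_or_days_rejected(self):
        df = samples_on_quadratic(0.001, 0.0, 200.0).iloc[:2]
        with pytest.raises(FitError):
            fit_weight_at_day(df, 33)
        same_day = pd.DataFrame(
            {"doy": [100, 100, 100, 100], "length_cm": 33.5, "weight_g": [1, 2, 3, 4.0]}
        )
        with pytest.raises(FitError):
            fit_weight_at_day(same_day, 33)

    def test_window_filter_applies(self):
        df = samples_on_quadratic(0.0, 1.0, 0.0)
        fit = fit_weight_at_day(df, 33, window=(100, 150))
        assert fit.n == 51


class TestEstimateK:
    def test_single_age_hand_example(self):
        # 33 -> 33.45 cm against Lmax 36: k = 0.45 / 3 = 0.15
        df = pd.DataFrame(
            {"year": [2005, 2006], "age": [5, 6], "mean_length_cm": [33.0, 33.45]}
        )
        assert estimate_k(df, 36.0)[2005] == pytest.approx(0.15)

    def test_zero_increment_gives_zero_k(self):
        df = pd.DataFrame(
            {"year": [2005, 2006, 2005, 2006], "age": [4, 5, 6, 7],
             "mean_length_cm": [30.0, 30.0, 33.0, 33.0]}
        )
        assert estimate_k(df, 36.0)[2005] == pytest.approx(0.0)

    def test_age_at_lmax_skipped_with_warning(self, caplog):
        df = pd.DataFrame(
            {"year": [2005, 2006, 2005, 2006], "age": [4, 5, 9, 10],
             "mean_length_cm": [30.0, 31.2, 36.5, 36.5]}
        )
        with caplog.at_level("WARNING", logger="planktivore.growth"):
            ks = estimate_k(df, 36.0)
        assert ks[2005] == pytest.approx(1.2 / 6.0)
        assert any("skipped" in r.message for r in caplog.records)

    def test_no_valid_pairs_raises(self):
        df = pd.DataFrame({"year": [2005], "age": [5], "mean_length_cm": [33.0]})
        with pytest.raises(ValueError):
            estimate_k(df, 36.0)

    def test_synthetic_cohort_recovery(self, herring_params):
        # winter means built forward with k=0.24 are recovered exactly
        k_true, lmax = 0.24, herring_params.lmax
        rows = []
        L = {a: 28.0 + 0.8 * a for a in range(4, 10)}
        for a, Ls in L.items():
            rows.append({"year": 2005, "age": a, "mean_length_cm": Ls})
            rows.append(
                {"year": 2006, "age": a + 1, "mean_length_cm": Ls + k_true * (lmax - Ls)}
            )
        assert estimate_k(pd.DataFrame(rows), lmax)[2005] == pytest.approx(
            k_true, abs=1e-12
        )


class TestSplitGrowth:
    @pytest.mark.parametrize(
        "dl, expected",
        [
            (1.3, (1, 2, 0.70, 0.30)),
            (2.0, (2, 2, 1.0, 0.0)),
            (0.72, (0, 1, 0.28, 0.72)),
            (0.0, (0, 0, 1.0, 0.0)),
        ],
    )
    def test_examples(self, dl, expected):
        s = split_growth(dl)
        assert (s.dg_lower, s.dg_upper) == expected[:2]
        assert (s.rdl_lower, s.rdl_upper) == pytest.approx(expected[2:])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            split_growth(-0.1)

    @settings(deadline=None, derandomize=True, max_examples=1000)
    @given(dl=st.floats(min_value=0.0, max_value=3.0))
    def test_expected_increment_identity(self, dl):
        s = split_growth(dl)
        assert s.rdl_lower + s.rdl_upper == pytest.approx(1.0, abs=1e-12)
        assert s.dg_lower * s.rdl_lower + s.dg_upper * s.rdl_upper == pytest.approx(
            dl, abs=1e-9
        )
        assert s.dg_upper - s.dg_lower in (0, 1)

    def test_increment_floors_at_lmax(self):
        assert annual_increment(0.2, 37.0, 36.0) == 0.0
        assert annual_increment(0.15, 33.0, 36.0) == pytest.approx(0.45)


class TestWeightTrajectory:
    @pytest.fixture
    def fits(self):
        out = {}
        for g in (33, 34, 35):
            df = samples_on_quadratic(0.001, 0.1, 50.0 + 10 * g, group=g)
            out[g] = fit_weight_at_day(df, g)
        return out

    def test_herring_midpoint_day(self):
        assert window_midpoint((91, 258)) == 175

    def test_passes_through_three_defining_points(self, fits):
        traj = build_weight_trajectory(33, 2, fits, (91, 258))
        assert traj(91) == pytest.approx(fits[33](91), rel=1e-9)
        assert traj(258) == pytest.approx(fits[35](258), rel=1e-9)
        assert traj(175) == pytest.approx(
            0.5 * (fits[33](175) + fits[35](175)), rel=1e-9
        )

    def test_zero_increment_follows_own_curve_at_nodes(self, fits):
        traj = build_weight_trajectory(34, 0, fits, (91, 258))
        for t in (91, 175, 258):
            assert traj(t) == pytest.approx(fits[34](t), rel=1e-9)

    def test_missing_fit_raises(self, fits):
        with pytest.raises(KeyError):
            build_weight_trajectory(33, 5, fits, (91, 258))


class TestFeedingWindowDiagnostic:
    def test_monotone_growth_gives_monotone_bins(self):
        df = samples_on_quadratic(0.0, 1.0, 100.0, group=32)
        out = feeding_window_diagnostic(df, 32)
        assert (out["mean_weight_g"].diff().dropna() > 0).all()

    def test_absent_bins_not_reported(self):
        df = samples_on_quadratic(0.0, 1.0, 100.0, group=32, days=np.arange(91, 100))
        out = feeding_window_diagnostic(df, 32)
        assert len(out) == 1

    def test_empty_for_missing_group(self):
        df = samples_on_quadratic(0.0, 1.0, 100.0, group=32)
        assert feeding_window_diagnostic(df, 26).empty
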