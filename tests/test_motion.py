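"""Mobility classification, TAMSD, anomalous-exponent and D fitting."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from sptpalm import (
    analyze_tracks,
    classify_mobility,
    filter_alpha,
    fit_anomalous,
    fit_diffusion_coefficient,
    tamsd,
)
from sptpalm.motion import TAMSDCurve
from sptpalm.simulate import simulate_planar_tracks


def brute_force_tamsd(xy_nm, dt):
    """Explicit O(n²) double loop, the definitional oracle."""
    xy = np.asarray(xy_nm) / 1000.0
    n = len(xy)
    lags, vals, pairs = [], [], []
    for k in range(1, n):
        acc = 0.0
        cnt = 0
        for i in range(n - k):
            d = xy[i + k] - xy[i]
            acc += d @ d
            cnt += 1
        lags.append(k * dt)
        vals.append(acc / cnt)
        pairs.append(cnt)
    return np.array(lags), np.array(vals), np.array(pairs)


class TestClassifyMobility:
    def test_confined_track_is_immobile(self, rng):
        xy = rng.uniform(0, 100, (8, 2))  # inside a 100 nm box
        assert classify_mobility(xy) == "immobile"

    def test_track_spanning_beyond_one_pixel_is_mobile(self):
        xy = np.array([[0.0, 0.0], [500.0, 0.0], [250.0, 50.0], [100.0, 20.0]])
        assert classify_mobility(xy) == "mobile"

    def test_identical_positions_immobile(self):
        assert classify_mobility(np.zeros((6, 2))) == "immobile"

    def test_box_boundary_is_exclusive(self):
        xy = np.array([[0.0, 0.0], [160.0, 0.0]])
        assert classify_mobility(xy) == "mobile"
        xy = np.array([[0.0, 0.0], [159.9, 0.0]])
        assert classify_mobility(xy) == "immobile"


class TestTamsd:
    def test_ballistic_closed_form(self):
        # constant speed v along a line: TAMSD(kτ) = (v k τ)² exactly
        v_nm_s, tau = 500.0, 0.1
        t = np.arange(10)
        xy = np.column_stack([v_nm_s * tau * t, np.zeros(10)])
        curve = tamsd(xy, tau)
        expected = (v_nm_s / 1000.0 * curve.lags) ** 2
        np.testing.assert_allclose(curve.values, expected, rtol=1e-12)

    def test_stationary_track_all_zero(self):
        curve = tamsd(np.full((7, 2), 123.0), 0.1)
        assert (curve.values == 0.0).all()

    def test_pair_counts_decrease(self, rng):
        curve = tamsd(rng.normal(0, 100, (12, 2)), 0.1)
        assert (np.diff(curve.n_pairs_per_lag) < 0).all()
        assert curve.n_pairs_per_lag[0] == 11

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        n=st.integers(4, 12),
        seed=st.integers(0, 10_000),
    )
    def test_matches_brute_force_oracle(self, n, seed):
        xy = np.random.default_rng(seed).normal(0, 200, (n, 2))
        curve = tamsd(xy, 0.1)
        lags, vals, pairs = brute_force_tamsd(xy, 0.1)
        np.testing.assert_allclose(curve.lags, lags, rtol=1e-12)
        np.testing.assert_allclose(curve.values, vals, rtol=1e-12)
        np.testing.assert_array_equal(curve.n_pairs_per_lag, pairs)


class TestFitAnomalous:
    def test_pure_brownian_curve(self):
        lags = np.arange(1, 6) * 0.1
        curve = TAMSDCurve(lags, 4 * 0.01 * lags, np.arange(5, 0, -1))
        alpha, D = fit_anomalous(curve)
        assert alpha == pytest.approx(1.0, abs=1e-9)
        assert D == pytest.approx(0.01, rel=1e-9)

    def test_constant_curve_gives_alpha_zero(self):
        lags = np.arange(1, 5) * 0.1
        curve = TAMSDCurve(lags, np.full(4, 0.02), np.arange(4, 0, -1))
        alpha, _ = fit_anomalous(curve)
        assert alpha == pytest.approx(0.0, abs=1e-9)

    def test_too_few_lags_rejected(self):
        lags = np.arange(1, 4) * 0.1
        curve = TAMSDCurve(lags, 4 * 0.01 * lags, np.arange(3, 0, -1))
        with pytest.raises(ValueError):
            fit_anomalous(curve)

    def test_zero_value_rejected(self):
        lags = np.arange(1, 5) * 0.1
        curve = TAMSDCurve(lags, np.array([0.0, 1.0, 2.0, 3.0]), np.arange(4, 0, -1))
        with pytest.raises(ValueError):
            fit_anomalous(curve)

    def test_median_alpha_near_one_for_long_noise_free_tracks(self):
        # 12-frame noise-free Brownian tracks: the short-track sampling
        # distribution of alpha centres near 1
        locs, _ = simulate_planar_tracks(
            2000,
            D=0.0272,
            localization_sigma=1e-9,
            length_range=(12, 12),
            rng=np.random.default_rng(21),
        )
        alphas = []
        for _, g in locs.groupby("track_id"):
            curve = tamsd(g[["x_nm", "y_nm"]].to_numpy(), 0.1)
            alphas.append(fit_anomalous(curve)[0])
        assert 0.85 <= float(np.median(alphas)) <= 1.15

    def test_ballistic_alpha_two_and_excluded(self):
        t = np.arange(8)
        xy = np.column_stack([400.0 * t, np.zeros(8)])
        curve = tamsd(xy, 0.1)
        alpha, _ = fit_anomalous(curve)
        assert alpha == pytest.approx(2.0, abs=1e-9)
        assert not filter_alpha(alpha)


class TestFilterAlpha:
    @pytest.mark.parametrize(
        "alpha,kept",
        [(1.0, True), (0.0, True), (1.5, True), (1.6, False), (-0.2, False)],
    )
    def test_retention_range_inclusive(self, alpha, kept):
        assert filter_alpha(alpha) is kept


class TestFitDiffusionCoefficient:
    def test_exact_brownian_curve(self):
        lags = np.arange(1, 5) * 0.1
        curve = TAMSDCurve(lags, 4 * 0.02 * lags, np.arange(4, 0, -1))
        assert fit_diffusion_coefficient(curve) == pytest.approx(0.02, rel=1e-12)

    def test_free_intercept_absorbs_static_noise_offset(self):
        # constant 4σ² offset (σ = 20 nm → 0.0016 µm²) leaves D unbiased
        lags = np.arange(1, 5) * 0.1
        curve = TAMSDCurve(lags, 4 * 0.02 * lags + 0.0016, np.arange(4, 0, -1))
        assert fit_diffusion_coefficient(curve) == pytest.approx(0.02, rel=1e-12)
        assert fit_diffusion_coefficient(curve, through_origin=True) > 0.02

    def test_too_few_lags_rejected(self):
        curve = TAMSDCurve(np.array([0.1]), np.array([0.01]), np.array([3]))
        with pytest.raises(ValueError):
            fit_diffusion_coefficient(curve)

    def test_ensemble_mean_matches_truth(self):
        # mean per-track D over a 2000-track Brownian ensemble, against the
        # ensemble-averaged MSD regression oracle on the same sample
        locs, _ = simulate_planar_tracks(
            2000, D=0.0272, localization_sigma=20.0, rng=np.random.default_rng(8)
        )
        Ds = []
        curves = []
        for _, g in locs.groupby("track_id"):
            xy = g[["x_nm", "y_nm"]].to_numpy()
            if len(xy) < 5:
                continue
            curve = tamsd(xy, 0.1)
            Ds.append(fit_diffusion_coefficient(curve))
            curves.append(curve.values[:4])
        mean_D = float(np.mean(Ds))
        assert mean_D == pytest.approx(0.0272, rel=0.15)
        # oracle: straight-line fit to the ensemble-averaged first four lags
        ens = np.mean(curves, axis=0)
        slope = np.polyfit(np.arange(1, 5) * 0.1, ens, 1)[0]
        assert mean_D == pytest.approx(slope / 4.0, rel=1e-9)


class TestAnalyzeTracks:
    def _tracks_df(self, locs):
        return locs[["track_id", "frame", "x_nm", "y_nm"]]

    def test_all_stationary_input(self):
        locs, _ = simulate_planar_tracks(
            50, D=0.0272, frac_immobile=1.0, rng=np.random.default_rng(2)
        )
        res = analyze_tracks(self._tracks_df(locs))
        assert (res["mobility"] == "immobile").all()
        assert res["alpha"].isna().all()

    def test_deterministic(self):
        locs, _ = simulate_planar_tracks(100, D=0.0272, rng=np.random.default_rng(3))
        df = self._tracks_df(locs)
        pd.testing.assert_frame_equal(analyze_tracks(df), analyze_tracks(df))

    def test_four_frame_mobile_tracks_excluded_for_lags(self):
        locs, _ = simulate_planar_tracks(
            200, D=0.0272, length_range=(4, 4), rng=np.random.default_rng(4)
        )
        res = analyze_tracks(self._tracks_df(locs))
        mobile_like = res[res["mobility"] != "immobile"]
        assert (mobile_like["mobility"] == "excluded").all()
        assert (mobile_like["exclusion_cause"] == "too_few_lags").all()

    def test_classifier_rates_match_monte_carlo_oracle(self):
        # independent oracle: the bounding-box statistic simulated directly
        # from the displacement distributions under immobile/mobile states
        rng = np.random.default_rng(77)
        dt, D, sig = 0.1, 0.0272, 20.0
        step = math.sqrt(2 * D * dt) * 1000.0
        ks = np.arange(4, 13)
        w = (1 - 1 / 8.0) ** (ks - 1)
        w /= w.sum()

        def oracle_rate(mobile, n_mc=60_000):
            lens = rng.choice(ks, n_mc, p=w)
            out = np.empty(n_mc, dtype=bool)
            for i, m in enumerate(lens):
                if mobile:
                    pos = np.vstack(
                        [np.zeros(2), np.cumsum(rng.normal(0, step, (m - 1, 2)), axis=0)]
                    )
                else:
                    pos = np.zeros((m, 2))
                pos = pos + rng.normal(0, sig, (m, 2))
                out[i] = (np.ptp(pos, axis=0) < 160.0).all()
            return out.mean()

        oracle_false_immobile = oracle_rate(mobile=True)
        oracle_sensitivity = oracle_rate(mobile=False, n_mc=20_000)

        locs_m, _ = simulate_planar_tracks(4000, D=D, rng=np.random.default_rng(10))
        res_m = analyze_tracks(self._tracks_df(locs_m))
        pipeline_false_immobile = (res_m["mobility"] == "immobile").mean()

        locs_i, _ = simulate_planar_tracks(
            3000, D=D, frac_immobile=1.0, rng=np.random.default_rng(11)
        )
        res_i = analyze_tracks(self._tracks_df(locs_i))
        pipeline_sensitivity = (res_i["mobility"] == "immobile").mean()

        assert pipeline_false_immobile == pytest.approx(oracle_false_immobile, abs=0.03)
        assert pipeline_sensitivity == pytest.approx(oracle_sensitivity, abs=0.03)
        assert pipeline_sensitivity >= 0.9

    def test_mixture_recovery_matches_oracle_prediction(self):
        # recovered immobile fraction equals the contamination-adjusted
        # prediction frac*sens + (1-frac)*false_rate, not the raw mixture
        # weight: 4-frame mobile tracks often fit in one pixel by chance
        frac = 0.2
        # rates measured on an independent sample (different seed)
        locs_ref, truth_ref = simulate_planar_tracks(
            4000, D=0.0272, frac_immobile=0.5, rng=np.random.default_rng(99)
        )
        ref = analyze_tracks(self._tracks_df(locs_ref)).merge(truth_ref, on="track_id")
        sens = (ref.loc[ref["state"] == "immobile", "mobility"] == "immobile").mean()
        fr = (ref.loc[ref["state"] == "mobile", "mobility"] == "immobile").mean()
        predicted = frac * sens + (1 - frac) * fr

        locs, _ = simulate_planar_tracks(
            3000, D=0.0272, frac_immobile=frac, rng=np.random.default_rng(12)
        )
        res = analyze_tracks(self._tracks_df(locs))
        recovered = (res["mobility"] == "immobile").mean()
        assert recovered == pytest.approx(predicted, abs=0.03)
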