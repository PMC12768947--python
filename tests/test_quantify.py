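"""Thresholding, calibration curves, LOD and concentration conversion."""

import numpy as np
import pytest

from pahsers.quantify import (
    CalibrationCurve,
    QuantError,
    ThresholdSet,
    choose_threshold,
    classify,
    contributions_to_concentrations,
    estimate_lod,
    fit_calibration_curve,
)


def brute_force_threshold(scores, truth):
    """Exhaustive oracle: try every candidate cutoff, call = score >= t."""
    u = np.unique(scores)
    cands = np.concatenate([[u[0] / 2], (u[:-1] + u[1:]) / 2, [(u[-1] + 1) / 2]])
    best = (-1.0, None)
    for t in cands:
        call = scores >= t
        tp = np.sum(call & truth)
        tn = np.sum(~call & ~truth)
        sens = tp / truth.sum()
        spec = tn / (~truth).sum()
        gm = np.sqrt(sens * spec)
        if gm > best[0] + 1e-15:
            best = (gm, t)
    return best[1], best[0]


class TestChooseThreshold:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.1, 0.2])
        truth = np.array([1, 1, 0, 0])
        t, gm = choose_threshold(scores, truth)
        assert gm == pytest.approx(1.0)
        assert 0.2 < t < 0.8

    def test_identical_scores_pick_better_forced_call(self):
        scores = np.full(10, 0.5)
        truth = np.array([1] * 7 + [0] * 3)
        t, gm = choose_threshold(scores, truth)
        # all-positive gives gm=0, all-negative gives gm=0; both forced calls tie at 0
        assert gm == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 100))
        scores = np.round(rng.random(n), 3)
        truth = rng.random(n) < 0.5
        if truth.all() or not truth.any():
            truth[0] = ~truth[0]
        t, gm = choose_threshold(scores, truth)
        t_o, gm_o = brute_force_threshold(scores, truth)
        assert gm == pytest.approx(gm_o, abs=1e-12)
        assert t == pytest.approx(t_o, abs=1e-12)

    def test_single_class_truth_rejected(self):
        with pytest.raises(QuantError):
            choose_threshold(np.array([0.1, 0.9]), np.array([1, 1]))


class TestClassify:
    def test_score_at_threshold_is_positive(self):
        ts = ThresholdSet(np.full(5, 0.5), np.ones(5))
        calls = classify(np.full((1, 5), 0.5), ts)
        assert np.all(calls == 1)

    def test_zero_scores_all_negative(self):
        ts = ThresholdSet(np.full(5, 0.5), np.ones(5))
        assert np.all(classify(np.zeros((3, 5)), ts) == 0)

    def test_elementwise_oracle(self, rng):
        ts = ThresholdSet(rng.random(5), np.ones(5))
        scores = rng.random((20, 5))
        calls = classify(scores, ts)
        np.testing.assert_array_equal(calls, (scores >= ts.thresholds).astype(int))

    def test_fit_save_load_round_trip(self, rng, tmp_path):
        scores = rng.random((50, 5))
        truth = (rng.random((50, 5)) < 0.5).astype(int)
        truth[0] = 1
        truth[1] = 0
        ts = ThresholdSet.fit(scores, truth)
        assert np.all((ts.thresholds > 0) & (ts.thresholds < 1))
        ts.save(tmp_path / "t.json")
        back = ThresholdSet.load(tmp_path / "t.json")
        np.testing.assert_allclose(back.thresholds, ts.thresholds)


class TestCalibration:
    def test_hill_recovery_from_clean_data(self):
        concs = np.array([0.01, 0.025, 0.05, 0.1, 0.25, 0.5, 1.0])
        heights = 0.9 * concs / (0.3 + concs)
        curve = fit_calibration_curve(concs, heights, form="hill", target="PY")
        h_max, K = curve.params
        assert h_max == pytest.approx(0.9, rel=0.01)
        assert K == pytest.approx(0.3, rel=0.01)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(QuantError):
            fit_calibration_curve(np.array([0.1, 0.5]), np.array([0.1, 0.3]))

    def test_inverse_round_trip(self):
        concs = np.geomspace(0.01, 1.0, 8)
        heights = 0.8 * concs / (0.25 + concs)
        curve = fit_calibration_curve(concs, heights, form="hill")
        for c in np.geomspace(0.02, 0.9, 10):
            rt, flag = curve.inverse(float(curve.predict(c)))
            assert rt == pytest.approx(c, rel=1e-6)
            assert not flag

    def test_poly_log_monotone_fit_and_inverse(self):
        concs = np.geomspace(0.01, 1.0, 8)
        heights = 0.2 + 0.1 * np.log10(concs) + 0.012 * np.log10(concs) ** 2
        curve = fit_calibration_curve(concs, heights, form="poly_log")
        mid = 0.1
        rt, _ = curve.inverse(float(curve.predict(mid)))
        assert rt == pytest.approx(mid, rel=1e-4)

    def test_non_monotone_poly_log_rejected(self):
        concs = np.geomspace(0.01, 1.0, 8)
        heights = np.array([0.5, 0.3, 0.2, 0.15, 0.2, 0.3, 0.45, 0.7])
        with pytest.raises(QuantError):
            fit_calibration_curve(concs, heights, form="poly_log")

    def test_sub_blank_height_reports_zero(self):
        concs = np.geomspace(0.01, 1.0, 8)
        heights = 0.8 * concs / (0.25 + concs)
        curve = fit_calibration_curve(concs, heights, form="hill")
        assert curve.inverse(-0.1) == (0.0, False)
        assert curve.inverse(0.0) == (0.0, False)


class TestLod:
    @staticmethod
    def _linearish_curve():
        # large K makes the Hill curve essentially linear over the range
        concs = np.geomspace(0.01, 1.0, 8)
        heights = 100.0 * concs / (100.0 + concs)
        return fit_calibration_curve(concs, heights, form="hill")

    def test_closed_form_on_linear_curve(self):
        curve = self._linearish_curve()
        sigma = 0.01
        lod = estimate_lod(curve, sigma, snr=3.5)
        h_max, K = curve.params
        expected = K * (3.5 * sigma) / (h_max - 3.5 * sigma)
        assert lod == pytest.approx(expected, rel=1e-9)
        # slope ~ h_max/K ~ 1, so LOD ~ 3.5 sigma
        assert lod == pytest.approx(3.5 * sigma, rel=0.01)

    def test_snr_zero_gives_zero(self):
        assert estimate_lod(self._linearish_curve(), 0.01, snr=0.0) == 0.0

    def test_doubling_blank_sd_doubles_lod(self):
        curve = self._linearish_curve()
        assert estimate_lod(curve, 0.02) == pytest.approx(
            2 * estimate_lod(curve, 0.01), rel=0.01
        )

    def test_monotone_in_blank_sd_and_snr(self):
        curve = self._linearish_curve()
        lods_sd = [estimate_lod(curve, sd) for sd in (0.005, 0.01, 0.02, 0.04)]
        assert np.all(np.diff(lods_sd) > 0)
        lods_snr = [estimate_lod(curve, 0.01, snr=s) for s in (1.0, 2.0, 3.5, 5.0)]
        assert np.all(np.diff(lods_snr) > 0)

    def test_undetectable_height_rejected(self):
        curve = self._linearish_curve()
        with pytest.raises(QuantError):
            estimate_lod(curve, blank_sd=1000.0)


class TestContributionsToConcentrations:
    @staticmethod
    def _curves():
        concs = np.geomspace(0.01, 1.0, 8)
        from pahsers.references import DEFAULT_RESPONSE_MODELS, TARGETS

        return {
            t: fit_calibration_curve(
                concs, DEFAULT_RESPONSE_MODELS[t].height(concs), form="hill", target=t
            )
            for t in TARGETS
        }

    def test_negative_contribution_maps_to_zero(self):
        curves = self._curves()
        pred = np.array([-0.5, 0.2, 0.2, 0.05, 0.05, 1.0])
        out = contributions_to_concentrations(pred, 1.0, curves)
        assert out.concentrations[0] == 0.0
        assert np.all(out.concentrations >= 0)

    def test_scale_invariance_in_l_and_z(self):
        curves = self._curves()
        pred = np.array([0.5, 0.2, 0.1, 0.1, 0.1, 1.3])
        doubled = pred.copy()
        doubled[:5] *= 2
        doubled[5] *= 2
        a = contributions_to_concentrations(pred, 2.0, curves)
        b = contributions_to_concentrations(doubled, 2.0, curves)
        np.testing.assert_allclose(a.concentrations, b.concentrations, rtol=1e-9)

    def test_degenerate_z_rejected(self):
        with pytest.raises(QuantError):
            contributions_to_concentrations(
                np.array([0.2, 0.2, 0.2, 0.2, 0.2, 0.0]), 1.0, self._curves()
            )

    def test_known_mixture_round_trip(self, library, grid, silent_cfg, rng):
        """The 5:2:1:1:1 worked mixture at 1 uM total comes back within 1%."""
        from pahsers.references import DEFAULT_RESPONSE_MODELS, TARGETS, ratio_to_concentrations
        from pahsers.mixtures import compose_mixture
        from pahsers.spectra import Spectrum

        curves = self._curves()
        true_concs = ratio_to_concentrations(1.0, (5, 2, 1, 1, 1))
        heights = np.array(
            [DEFAULT_RESPONSE_MODELS[t].height(c) for t, c in zip(TARGETS, true_concs)]
        )
        S = heights.sum()
        blank = Spectrum(grid, np.zeros(660))
        sample = compose_mixture(
            heights / S, library, blank, silent_cfg, rng, scale_range=(S, S)
        )
        out = contributions_to_concentrations(
            sample.labels.regression_target, sample.raw_max, curves
        )
        np.testing.assert_allclose(out.concentrations, true_concs, rtol=0.01)
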