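"""Model fitting: offset correction, parameter recovery, exclusion rule."""

import numpy as np
import pytest
from scipy import stats

from pdcs import bfi_fit as B
from pdcs import correlator as C
from pdcs.speckle_sim import ProbeGeometry
from pdcs.traces import BfiTrace


GRID = C.DelayGrid(10e-6, 46)


def record_from_g2(g2, delays=None, window_start=0.0, window_length=0.1):
    delays = GRID.delays if delays is None else delays
    return C.CorrelationRecord(
        window_start=window_start, window_length=window_length,
        delays=delays, g2=np.asarray(g2, dtype=float),
        n_pixels_averaged=1024, n_curves_averaged=1, mean_rate=0.05,
    )


class TestModelG2:
    def test_no_flow_plateau(self, props, geom15):
        g2 = B.model_g2(props, geom15, 0.0, 0.3, GRID.delays)
        assert np.allclose(g2, 1.3)

    def test_zero_beta_flat(self, props, geom15):
        g2 = B.model_g2(props, geom15, 1e-8, 0.0, GRID.delays)
        assert np.allclose(g2, 1.0)

    def test_composition_identity_with_simulator_model(self, props, geom15):
        from pdcs.speckle_sim import g1_semi_infinite, g2_from_g1

        direct = B.model_g2(props, geom15, 3e-9, 0.22, GRID.delays)
        composed = g2_from_g1(
            g1_semi_infinite(props, geom15, 3e-9, GRID.delays), 0.22
        )
        assert np.allclose(direct, composed, atol=1e-15)


class TestOffsetCorrection:
    def test_already_anchored_curve_unchanged(self):
        # fully decorrelated tail: offset is zero
        g2 = 1.0 + 0.25 * np.exp(-np.arange(46) / 3.0)
        corrected = B.correct_g2_offset(record_from_g2(g2))
        assert np.allclose(corrected.g2, g2, atol=1e-6)

    def test_constructed_offset_recovered(self):
        g2 = 1.0 + 0.25 * np.exp(-np.arange(46) / 3.0)
        rec = record_from_g2(g2 + 0.02)
        assert B.estimate_g2_offset(rec) == pytest.approx(0.02, abs=1e-6)
        corrected = B.correct_g2_offset(rec)
        assert np.allclose(corrected.g2, g2, atol=1e-6)

    def test_still_decaying_curve_skipped(self, props, geom15):
        # slow decay: tail nowhere near the plateau within this grid
        g2 = B.model_g2(props, geom15, 1e-11, 0.5, GRID.delays)
        rec = record_from_g2(g2)
        corrected = B.correct_g2_offset(rec)
        assert np.array_equal(corrected.g2, rec.g2)

    def test_correction_reduces_fit_bias(self, props, geom15):
        """Short-span records carry a normalization bias; tail anchoring
        brings the fitted BFI closer to truth (paired comparison)."""
        from pdcs.speckle_sim import DetectorSimParams, simulate_speckle_photons

        truth = 6e-9
        det = DetectorSimParams(
            n_pixels=256, exposure=10e-6, n_frames=30_000,
            mean_rate=0.2, seed=13,
        )
        stream = simulate_speckle_photons(props, geom15, truth, det)
        records = C.correlate_stream(stream, GRID, 0.05, span_frames=500,
                                     dtype=np.float32)
        raw = [B.fit_bfi(r, props, geom15).bfi for r in records]
        corrected = [
            B.fit_bfi(B.correct_g2_offset(r), props, geom15).bfi for r in records
        ]
        err_raw = abs(np.median(raw) - truth) / truth
        err_corr = abs(np.median(corrected) - truth) / truth
        assert err_corr < err_raw


class TestFit:
    @pytest.mark.parametrize("bfi, beta", [(6e-9, 0.25), (2e-8, 0.15), (1e-9, 0.5)])
    def test_noiseless_selfconsistency(self, props, geom15, bfi, beta):
        rec = record_from_g2(B.model_g2(props, geom15, bfi, beta, GRID.delays))
        sample = B.fit_bfi(rec, props, geom15)
        assert sample.valid
        assert sample.bfi == pytest.approx(bfi, rel=1e-6)
        assert sample.beta == pytest.approx(beta, rel=1e-6)

    def test_noisy_recovery_within_five_percent(self, props, geom15):
        rng = np.random.default_rng(42)
        truth, beta = 6e-9, 0.25
        model = B.model_g2(props, geom15, truth, beta, GRID.delays)
        fits = []
        for w in range(100):
            rec = record_from_g2(model + rng.normal(0.0, 0.005, GRID.n_delays),
                                 window_start=w * 0.1)
            fits.append(B.fit_bfi(rec, props, geom15).bfi)
        assert np.median(fits) == pytest.approx(truth, rel=0.05)

    def test_flat_curve_flagged_unidentifiable(self, props, geom15):
        sample = B.fit_bfi(record_from_g2(np.ones(46)), props, geom15)
        assert not sample.valid

    def test_deterministic(self, props, geom15):
        rng = np.random.default_rng(1)
        rec = record_from_g2(
            B.model_g2(props, geom15, 6e-9, 0.25, GRID.delays)
            + rng.normal(0, 0.01, 46)
        )
        a = B.fit_bfi(rec, props, geom15)
        b = B.fit_bfi(rec, props, geom15)
        assert a == b

    def test_fitted_bfi_monotone_in_simulated_bfi(self, props, geom15):
        rng = np.random.default_rng(3)
        truths = np.logspace(-9.5, -7.5, 10)
        fitted = []
        for t in truths:
            g2 = B.model_g2(props, geom15, t, 0.25, GRID.delays)
            rec = record_from_g2(g2 + rng.normal(0, 0.002, GRID.n_delays))
            fitted.append(B.fit_bfi(rec, props, geom15).bfi)
        assert np.all(np.diff(fitted) > 0)

    def test_preset_subsets(self):
        assert np.array_equal(B.FitOptions.preset("arm-raw").delay_subset,
                              np.arange(1, 46))
        assert np.array_equal(B.FitOptions.preset("pfc-onboard").delay_subset,
                              np.arange(1, 13))
        with pytest.raises(ValueError):
            B.FitOptions.preset("nope")
        with pytest.raises(ValueError):
            B.FitOptions(delay_subset=np.array([0, 1]))


class TestTraceAssembly:
    def _records(self, n, dt, props, geom):
        model = B.model_g2(props, geom, 6e-9, 0.25, GRID.delays)
        return [
            record_from_g2(model, window_start=i * dt, window_length=dt)
            for i in range(n)
        ]

    def test_arm_preset_duration(self, props, geom15):
        trace = B.trace_from_records(self._records(75, 0.1, props, geom15),
                                     props, geom15)
        assert trace.sample_rate == pytest.approx(10.0)
        assert trace.duration == pytest.approx(7.5)

    def test_pfc_preset_duration(self, props, geom15):
        trace = B.trace_from_records(self._records(120, 0.125, props, geom15),
                                     props, geom15)
        assert trace.sample_rate == pytest.approx(8.0)
        assert trace.duration == pytest.approx(15.0)

    def test_empty_input_rejected(self, props, geom15):
        with pytest.raises(ValueError):
            B.trace_from_records([], props, geom15)

    def test_gap_detected(self, props, geom15):
        records = self._records(10, 0.1, props, geom15)
        del records[4]
        with pytest.raises(ValueError, match="missing"):
            B.trace_from_records(records, props, geom15)


class TestExclusion:
    def _trace(self, residuals):
        n = len(residuals)
        return BfiTrace(
            times=np.arange(n) * 0.1, bfi=np.full(n, 6e-9),
            residual=np.asarray(residuals), sample_rate=10.0,
        )

    def test_low_residual_trial_kept(self):
        kept, excluded, _ = B.exclude_trials({"t1": self._trace([0.01] * 10)})
        assert "t1" in kept and not excluded

    def test_boundary_median_kept(self):
        # median exactly at threshold: strict comparison keeps the trial
        kept, _, reasons = B.exclude_trials(
            {"t1": self._trace([0.01, 0.05] * 5)}
        )
        assert "t1" in kept
        assert "0.03" in reasons["t1"]

    def test_high_residual_trial_excluded(self):
        _, excluded, _ = B.exclude_trials({"t1": self._trace([0.05] * 10)})
        assert "t1" in excluded


class TestEarlySlope:
    def test_exact_line(self):
        delays = GRID.delays
        g2 = 1.25 - 1000.0 * delays
        assert B.early_slope_metric(record_from_g2(g2), 10) == pytest.approx(-1000.0)

    def test_constant_curve_zero_slope(self):
        assert B.early_slope_metric(record_from_g2(np.ones(46)), 10) == pytest.approx(0.0)

    def test_magnitude_tracks_flow(self, props, geom15):
        slopes = [
            B.early_slope_metric(
                record_from_g2(B.model_g2(props, geom15, t, 0.25, GRID.delays)), 5
            )
            for t in np.logspace(-10, -8.5, 10)
        ]
        rho, _ = stats.spearmanr(np.abs(slopes), np.arange(10))
        assert rho == pytest.approx(1.0)

    def test_insufficient_delays_rejected(self):
        with pytest.raises(ValueError):
            B.early_slope_metric(record_from_g2(np.ones(46)), 1)


class TestDepthSensitivity:
    def test_decay_faster_at_larger_separation(self, props):
        """Longer photon paths at larger SDS accumulate more scattering
        events, so g2 decays faster at fixed BFI."""
        shallow = B.halving_rate(props, ProbeGeometry(sds_cm=1.5), 6e-9)
        deep = B.halving_rate(props, ProbeGeometry(sds_cm=4.0), 6e-9, tau_max=2e-4)
        assert deep > shallow
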