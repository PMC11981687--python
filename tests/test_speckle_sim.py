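"""Speckle-matching optics, the semi-infinite g1 model, the pulsatile
waveform generator and the binary photon-stream simulator."""

import math

import numpy as np
import pytest

from pdcs import correlator
from pdcs.speckle_sim import (
    DetectorSimParams,
    ProbeGeometry,
    PulseWaveformParams,
    effective_reflection_coefficient,
    g1_semi_infinite,
    g2_from_g1,
    make_pulsatile_bfi,
    simulate_speckle_photons,
    source_irradiance,
    speckle_spot_distance,
)


class TestSpeckleMatching:
    @pytest.mark.parametrize(
        "wavelength_nm, fiber_um, speckle_um, expected_mm",
        [
            (785.0, 200.0, 6.9, 1.76),  # 32x32 array, 200 um fiber
            (785.0, 1500.0, 6.0, 11.5),  # 500x500 array, 1500 um fiber
        ],
    )
    def test_matched_distance(self, wavelength_nm, fiber_um, speckle_um, expected_mm):
        z = speckle_spot_distance(wavelength_nm, fiber_um, speckle_um)
        assert z == pytest.approx(expected_mm, abs=0.005 * expected_mm)

    def test_distance_linear_in_speckle_diameter(self):
        z1 = speckle_spot_distance(785.0, 200.0, 6.9)
        z2 = speckle_spot_distance(785.0, 200.0, 13.8)
        assert z2 == pytest.approx(2.0 * z1, rel=1e-12)

    @pytest.mark.parametrize("bad", [(0, 200, 6.9), (785, -1, 6.9), (785, 200, 0)])
    def test_nonpositive_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            speckle_spot_distance(*bad)

    def test_irradiance_below_mpe(self):
        # 100 mW over a 4 mm-radius disc stays below the 300 mW/cm^2 skin limit
        irr = source_irradiance(100.0, 4.0)
        assert irr == pytest.approx(100.0 / (math.pi * 0.4**2))
        assert irr <= 300.0


class TestSemiInfiniteG1:
    def test_normalized_at_zero_delay(self, props, geom15):
        taus = np.array([0.0, 1e-6, 1e-5, 1e-4])
        g1 = g1_semi_infinite(props, geom15, 1e-8, taus)
        assert g1[0] == pytest.approx(1.0, abs=1e-14)

    def test_no_flow_means_no_decay(self, props, geom15):
        taus = np.linspace(0.0, 1e-3, 50)
        assert np.allclose(g1_semi_infinite(props, geom15, 0.0, taus), 1.0)

    def test_matches_independent_transcription(self, props, geom15):
        """Second, literal transcription of the extrapolated-boundary
        Green's-function solution, written without reference to the
        implementation."""

        def oracle(mu_a, mu_sp, n, lam_nm, rho, bfi, tau):
            k0 = 2.0 * math.pi * n / (lam_nm * 1e-7)
            z0 = 1.0 / mu_sp
            reff = -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
            zb = 2.0 * (1.0 + reff) / (3.0 * mu_sp * (1.0 - reff))
            r1 = math.sqrt(rho**2 + z0**2)
            rb = math.sqrt(rho**2 + (z0 + 2.0 * zb) ** 2)

            def g(t):
                kd = math.sqrt(3.0 * mu_a * mu_sp + 6.0 * mu_sp**2 * k0**2 * bfi * t)
                return math.exp(-kd * r1) / r1 - math.exp(-kd * rb) / rb

            return g(tau) / g(0.0)

        for tau in (1e-6, 1e-5, 1e-4, 1e-3):
            expected = oracle(0.17, 8.0, 1.4, 785.0, 1.5, 1e-8, tau)
            got = g1_semi_infinite(props, geom15, 1e-8, np.array([tau]))[0]
            assert got == pytest.approx(expected, rel=1e-10)

    def test_strictly_decreasing_in_flow_and_separation(self, props):
        taus = np.array([1e-6, 1e-5, 5e-5, 2e-4])
        bfis = np.logspace(-10, -7, 8)
        geom = ProbeGeometry(sds_cm=1.5)
        curves = np.array([g1_semi_infinite(props, geom, b, taus) for b in bfis])
        assert np.all(np.diff(curves, axis=0) < 0)

        rhos = [1.0, 1.5, 2.5, 4.0]
        curves = np.array([
            g1_semi_infinite(props, ProbeGeometry(sds_cm=r), 1e-8, taus)
            for r in rhos
        ])
        assert np.all(np.diff(curves, axis=0) < 0)

    def test_domain_errors(self, props, geom15):
        with pytest.raises(ValueError):
            g1_semi_infinite(props, geom15, -1e-9, np.array([0.0, 1e-5]))
        with pytest.raises(ValueError):
            g1_semi_infinite(props, geom15, 1e-9, np.array([-1e-6]))

    def test_reflection_coefficient_matches_polynomial(self):
        n = 1.4
        assert effective_reflection_coefficient(n) == pytest.approx(
            -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
        )


class TestSiegert:
    @pytest.mark.parametrize(
        "g1, beta, expected",
        [(1.0, 0.3, 1.3), (0.0, 0.5, 1.0), (0.5, 0.2, 1.05)],
    )
    def test_values(self, g1, beta, expected):
        assert g2_from_g1(np.array([g1]), beta)[0] == pytest.approx(expected)

    @pytest.mark.parametrize("beta", [-0.1, 1.1])
    def test_beta_out_of_range(self, beta):
        with pytest.raises(ValueError):
            g2_from_g1(np.array([0.5]), beta)


class TestPulsatileWaveform:
    def test_zero_amplitude_is_constant_baseline(self):
        params = PulseWaveformParams(systolic_amplitude=0.0)
        gt = make_pulsatile_bfi(params, 10.0, 10.0, seed=0)
        assert np.allclose(gt.trace.bfi, params.bfi_baseline)

    def test_systolic_peak_count_matches_rate(self):
        gt = make_pulsatile_bfi(
            PulseWaveformParams(pulse_rate=1.2, jitter_sd=0.02), 15.0, 10.0, seed=1
        )
        # 1.2 Hz x 15 s = 18 cycles; boundary cycles may lose one peak
        assert abs(gt.markers["sp"].size - 18) <= 2

    def test_waveform_never_below_baseline(self):
        params = PulseWaveformParams()
        gt = make_pulsatile_bfi(params, 12.0, 10.0, seed=3)
        assert np.all(gt.trace.bfi >= params.bfi_baseline * (1.0 - 1e-9))

    def test_audited_markers_are_sample_extrema(self):
        gt = make_pulsatile_bfi(PulseWaveformParams(), 12.0, 10.0, seed=4)
        v = gt.trace.bfi
        for i in gt.markers["sp"]:
            assert v[i] > v[i - 1] and v[i] > v[i + 1]
        for i in gt.markers["dn"]:
            assert v[i] < v[i - 1] and v[i] < v[i + 1]
        for i in gt.markers["dp"]:
            assert v[i] > v[i - 1] and v[i] > v[i + 1]

    def test_out_of_band_rate_warns_but_produces(self):
        with pytest.warns(UserWarning):
            gt = make_pulsatile_bfi(
                PulseWaveformParams(pulse_rate=3.0), 5.0, 20.0, seed=0
            )
        assert len(gt.trace) > 0

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError):
            make_pulsatile_bfi(PulseWaveformParams(pulse_rate=1.0), 1.5, 10.0)


class TestPhotonSimulator:
    def test_identical_seeds_bit_identical(self, props, geom15):
        det = DetectorSimParams(n_pixels=64, n_frames=4000, seed=9)
        a = simulate_speckle_photons(props, geom15, 6e-9, det)
        b = simulate_speckle_photons(props, geom15, 6e-9, det)
        assert np.array_equal(a.counts, b.counts)
        c = simulate_speckle_photons(
            props, geom15, 6e-9, DetectorSimParams(n_pixels=64, n_frames=4000, seed=10)
        )
        assert not np.array_equal(a.counts, c.counts)

    def test_mean_event_rate_matches_configuration(self, static_stream):
        stream, det, _ = static_stream
        target = det.mean_rate + det.dark_rate
        n = stream.counts.size
        se = math.sqrt(target * (1 - target) / n)
        assert abs(stream.counts.mean() - target) < 3 * se

    def test_incoherent_stream_has_flat_g2(self, props, geom15):
        det = DetectorSimParams(
            n_pixels=256, n_frames=20_000, coherent_fraction=0.0,
            mean_rate=0.05, seed=5,
        )
        stream = simulate_speckle_photons(props, geom15, 6e-9, det)
        g2, _ = correlator.per_pixel_window_g2(stream.counts, 16, det.n_frames)
        per_pixel = g2[0, :, 1:]  # nonzero delays
        avg = per_pixel.mean(axis=0)
        se = per_pixel.std(axis=0, ddof=1) / math.sqrt(det.n_pixels)
        assert np.all(np.abs(avg - 1.0) < 3.5 * se)

    def test_pixel_averaged_g2_matches_siegert(self, static_stream, props, geom15):
        """Monte-Carlo photon streams reproduce 1 + beta g1(tau)^2."""
        stream, det, bfi = static_stream
        n_delays = 16
        g2, _ = correlator.per_pixel_window_g2(
            stream.counts, n_delays, stream.n_frames
        )
        per_pixel = g2[0]  # (M, K)
        avg = per_pixel.mean(axis=0)
        se = per_pixel.std(axis=0, ddof=1) / math.sqrt(det.n_pixels)
        delays = np.arange(n_delays) * det.exposure
        model = g2_from_g1(
            g1_semi_infinite(props, geom15, bfi, delays), det.beta_expected
        )
        for k in range(1, n_delays):  # tau = 0 is shot-noise dominated
            assert abs(avg[k] - model[k]) < 3.5 * se[k]

    def test_memory_budget_refused_with_guidance(self, props, geom15):
        det = DetectorSimParams(n_pixels=1024, n_frames=10_000_000)
        with pytest.raises(MemoryError, match="chunk"):
            simulate_speckle_photons(props, geom15, 6e-9, det, max_bytes=10**9)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            DetectorSimParams(mean_rate=0.9, dark_rate=0.2)
        with pytest.raises(ValueError):
            DetectorSimParams(mean_rate=0.0, dark_rate=0.0)
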