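"""Synthetic speckle data for parallelized diffuse correlation spectroscopy.

This module provides the forward model of a PDCS experiment:

* the closed-form semi-infinite correlation-diffusion field autocorrelation
  g1(tau) for a homogeneous tissue half-space (extrapolated-zero boundary),
* the Siegert relation linking g1 to the measured intensity autocorrelation,
* a pulsatile blood-flow-index (BFI) waveform generator with the four
  physiological markers (systolic peak, dicrotic notch, diastolic peak,
  diastolic end) placed at known sample positions, and
* a binary SPAD-array photon-stream simulator whose per-pixel statistics match
  the analytic g1/g2 targets, so every downstream stage of the pipeline can be
  validated against known ground truth.

Each simulated pixel observes an independent, fully developed speckle: a
circular complex Gaussian field with the prescribed autocorrelation, mixed
with a static background to control the correlation amplitude beta, thinned
into binary photon events per frame.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from numpy.random import SeedSequence, default_rng
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .traces import BfiTrace

__all__ = [
    "OpticalProperties",
    "ProbeGeometry",
    "PulseWaveformParams",
    "DetectorSimParams",
    "FrameStream",
    "PulsatileGroundTruth",
    "PULSE_BAND_HZ",
    "speckle_spot_distance",
    "source_irradiance",
    "effective_reflection_coefficient",
    "g1_semi_infinite",
    "g2_from_g1",
    "make_pulsatile_bfi",
    "simulate_speckle_photons",
]

#: Physiological search band for the pulse fundamental, Hz (20-160 bpm).
PULSE_BAND_HZ = (0.33, 2.65)

# Pixel chunk used by the photon simulator.  Fixed (not adaptive) so that a
# given seed always yields a bit-identical stream regardless of memory.
_PIXEL_CHUNK = 256


@dataclass(frozen=True)
class OpticalProperties:
    """Homogeneous tissue optical properties.

    Defaults are literature-typical values for adult forehead tissue at
    785 nm; they are assumptions, never ground truth, and every consumer of
    this type accepts alternatives.
    """

    mu_a: float = 0.17  # absorption coefficient, 1/cm
    mu_s_prime: float = 8.0  # reduced scattering coefficient, 1/cm
    n_tissue: float = 1.4  # refractive index of the medium
    n_outside: float = 1.0  # refractive index outside (air)
    wavelength_nm: float = 785.0  # laser wavelength, nm

    def __post_init__(self) -> None:
        for name in ("mu_a", "mu_s_prime", "n_tissue", "n_outside", "wavelength_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mu_s_prime <= self.mu_a:
            raise ValueError("mu_s_prime must exceed mu_a for the diffusion model")

    @property
    def k0(self) -> float:
        """In-medium wavenumber 2*pi*n/lambda, 1/cm."""
        wavelength_cm = self.wavelength_nm * 1e-7
        return 2.0 * math.pi * self.n_tissue / wavelength_cm


@dataclass(frozen=True)
class ProbeGeometry:
    """Source/detector arrangement of one PDCS channel."""

    sds_cm: float = 4.0  # source-detector separation rho, cm
    fiber_diameter_um: float = 1500.0  # detection fiber core diameter D, um
    pixel_active_diameter_um: float = 6.0  # SPAD active-area diameter, um
    fiber_sensor_distance_mm: float | None = None  # z; None = speckle-matched
    source_radius_mm: float = 4.0  # illumination spot radius, mm
    source_power_mw: float = 100.0  # laser power, mW

    def __post_init__(self) -> None:
        if self.sds_cm <= 0:
            raise ValueError("sds_cm must be positive")
        for name in ("fiber_diameter_um", "pixel_active_diameter_um",
                     "source_radius_mm", "source_power_mw"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def speckle_matched_distance_mm(self, wavelength_nm: float = 785.0) -> float:
        """Fiber-to-sensor distance matching one speckle per pixel."""
        return speckle_spot_distance(
            wavelength_nm, self.fiber_diameter_um, self.pixel_active_diameter_um
        )


def speckle_spot_distance(
    wavelength_nm: float, fiber_diameter_um: float, target_speckle_diameter_um: float
) -> float:
    """Fiber-to-sensor distance z (mm) that produces a given speckle diameter.

    The far-field speckle diameter off a multimode fiber of core diameter D is
    d = lambda * z / D; solving for z gives z = d * D / lambda.  Matching d to
    the SPAD active-area diameter makes each pixel sample a single speckle.
    """
    if wavelength_nm <= 0 or fiber_diameter_um <= 0 or target_speckle_diameter_um <= 0:
        raise ValueError("all speckle-matching inputs must be positive")
    wavelength_um = wavelength_nm * 1e-3
    z_um = target_speckle_diameter_um * fiber_diameter_um / wavelength_um
    return z_um * 1e-3


def source_irradiance(power_mw: float, radius_mm: float) -> float:
    """Average irradiance (mW/cm^2) of the illumination spot.

    Used for the maximal-permissible-exposure check: skin MPE at NIR
    wavelengths is ~300 mW/cm^2, so a 100 mW beam needs a spot radius of a few
    millimetres.
    """
    if power_mw <= 0 or radius_mm <= 0:
        raise ValueError("power and radius must be positive")
    radius_cm = radius_mm * 0.1
    return power_mw / (math.pi * radius_cm**2)


def effective_reflection_coefficient(n_rel: float) -> float:
    """Effective Fresnel reflection coefficient for the extrapolated boundary.

    Standard polynomial approximation in the relative refractive index
    n = n_tissue / n_outside (Groenhuis/Egan-style fit used throughout the
    diffuse-optics literature).
    """
    if n_rel <= 0:
        raise ValueError("relative refractive index must be positive")
    return -1.440 / n_rel**2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel


def g1_semi_infinite(
    props: OpticalProperties,
    geom: ProbeGeometry,
    bfi: float,
    delays: np.ndarray,
) -> np.ndarray:
    """Normalized field autocorrelation g1(tau) for a semi-infinite medium.

    Extrapolated-zero-boundary Green's-function solution of the correlation
    diffusion equation for Brownian red-blood-cell motion::

        G1(rho, tau) ~ exp(-K r1)/r1 - exp(-K rb)/rb
        K(tau)  = sqrt(3 mu_a mu_s' + 6 mu_s'^2 k0^2 * BFI * tau)
        r1 = sqrt(rho^2 + z0^2),  rb = sqrt(rho^2 + (z0 + 2 zb)^2)
        z0 = 1/mu_s',  zb = 2 (1 + Reff) / (3 mu_s' (1 - Reff))

    normalized so g1(0) = 1.  ``bfi`` is the effective diffusion coefficient
    in cm^2/s, ``delays`` in seconds.
    """
    delays = np.asarray(delays, dtype=float)
    if np.any(delays < 0):
        raise ValueError("delays must be non-negative")
    if delays.size > 1 and np.any(np.diff(delays) < 0):
        raise ValueError("delays must be ascending")
    if bfi < 0:
        raise ValueError("bfi must be non-negative")

    mu_a, musp = props.mu_a, props.mu_s_prime
    rho = geom.sds_cm
    z0 = 1.0 / musp
    reff = effective_reflection_coefficient(props.n_tissue / props.n_outside)
    zb = 2.0 * (1.0 + reff) / (3.0 * musp * (1.0 - reff))
    r1 = math.hypot(rho, z0)
    rb = math.hypot(rho, z0 + 2.0 * zb)

    def unnormalized(tau: np.ndarray) -> np.ndarray:
        k = np.sqrt(3.0 * mu_a * musp + 6.0 * musp**2 * props.k0**2 * bfi * tau)
        return np.exp(-k * r1) / r1 - np.exp(-k * rb) / rb

    g0 = unnormalized(np.zeros(1))[0]
    return unnormalized(delays) / g0


def g2_from_g1(g1: np.ndarray, beta: float) -> np.ndarray:
    """Siegert relation: g2(tau) = 1 + beta * |g1(tau)|^2."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    g1 = np.asarray(g1, dtype=float)
    if np.any(g1 < -1e-9) or np.any(g1 > 1.0 + 1e-9):
        raise ValueError("g1 values must lie in [0, 1]")
    return 1.0 + beta * np.abs(g1) ** 2


@dataclass(frozen=True)
class PulseWaveformParams:
    """Shape parameters of the synthetic pulsatile BFI waveform.

    The defaults emulate a resting adult: ~1.1 Hz pulse, baseline BFI of
    6e-9 cm^2/s with a systolic excursion of the same order, a dicrotic notch
    ~0.22 s after the systolic peak, and mild cycle-to-cycle period jitter.
    """

    pulse_rate: float = 1.1  # fundamental frequency, Hz
    bfi_baseline: float = 6e-9  # diastolic-end BFI, cm^2/s
    systolic_amplitude: float = 6e-9  # SP - DE excursion, cm^2/s
    notch_depth: float = 0.5  # fractional dip of the dicrotic notch, 0-1
    notch_delay: float = 0.22  # time from SP to DN, s (< 0.4 s)
    diastolic_peak_height: float = 0.12  # fractional rebound after DN
    jitter_sd: float = 0.02  # cycle period jitter SD, s

    def __post_init__(self) -> None:
        if self.pulse_rate <= 0:
            raise ValueError("pulse_rate must be positive")
        if self.bfi_baseline < 0 or self.systolic_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if not 0.0 <= self.notch_depth <= 1.0:
            raise ValueError("notch_depth must lie in [0, 1]")
        if not 0.0 < self.notch_delay < 0.4:
            raise ValueError("notch_delay must lie in (0, 0.4) s")
        if self.diastolic_peak_height < 0:
            raise ValueError("diastolic_peak_height must be non-negative")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")


@dataclass(frozen=True)
class DetectorSimParams:
    """Parameters of the simulated SPAD array."""

    n_pixels: int = 1024  # number of independent speckle pixels M
    exposure: float = 10e-6  # per-frame exposure = frame period, s
    n_frames: int = 100_000  # frames per simulation
    coherent_fraction: float = 0.5  # dynamic-speckle intensity fraction (beta = f^2)
    mean_rate: float = 0.05  # mean photon detections per pixel per frame
    dark_rate: float = 1e-4  # dark-count probability per frame
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")
        if self.exposure <= 0:
            raise ValueError("exposure must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0.0 <= self.coherent_fraction <= 1.0:
            raise ValueError("coherent_fraction must lie in [0, 1]")
        if not 0.0 < self.mean_rate + self.dark_rate < 1.0:
            raise ValueError("mean_rate + dark_rate must lie in (0, 1)")

    @property
    def beta_expected(self) -> float:
        """Realized correlation amplitude for one polarization mode."""
        return self.coherent_fraction**2


@dataclass
class FrameStream:
    """Binary photon events per pixel per frame plus sensor timing metadata."""

    counts: np.ndarray  # (n_frames, n_pixels) uint8 of 0/1 events
    exposure_s: float
    frame_period_s: float
    sds_cm: float
    wavelength_nm: float
    seed: int | None = None
    n_rows: int | None = None
    config: dict = field(default_factory=dict)
    ground_truth: BfiTrace | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a (frames, pixels) array")

    @property
    def n_frames(self) -> int:
        return self.counts.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.counts.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_period_s

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_period_s


@dataclass
class PulsatileGroundTruth:
    """A generated BFI waveform plus an audit of its sampled extrema.

    ``markers`` maps each marker kind ('sp', 'de', 'dn', 'dp') to the sample
    indices at which it occurs; these are exactly the extrema of the sampled
    waveform, so closed-loop detector tests have an unambiguous reference.
    """

    trace: BfiTrace
    markers: Mapping[str, np.ndarray]
    cycle_starts: np.ndarray
    unresolved_dn_dp: int = 0

    def marker_times(self, kind: str) -> np.ndarray:
        return self.trace.times[self.markers[kind]]


def _cycle_knots(params: PulseWaveformParams, start: float, period: float):
    """Control points (time, value) for one pulse cycle starting at ``start``."""
    base = params.bfi_baseline
    amp = params.systolic_amplitude
    t_sp = start + 0.15 * period
    t_dn = min(t_sp + params.notch_delay, start + 0.75 * period)
    t_dp = min(t_dn + 0.12 * period, start + 0.9 * period)
    v_sp = base + amp
    v_dn = base + amp * (0.5 - 0.35 * params.notch_depth)
    v_dp = min(v_dn + params.diastolic_peak_height * amp, base + 0.9 * amp)
    return [(t_sp, v_sp), (t_dn, v_dn), (t_dp, v_dp), (start + period, base)]


def _audit_markers(values: np.ndarray, sample_rate: float,
                   cycle_starts: np.ndarray, dn_window: float = 0.4):
    """Locate SP/DE/DN/DP as extrema of the sampled waveform, per cycle."""
    n = values.size
    sp: list[int] = []
    for s, e in zip(cycle_starts[:-1], cycle_starts[1:]):
        lo = int(np.ceil(s * sample_rate))
        hi = min(int(np.ceil(e * sample_rate)), n)
        if hi - lo < 1:
            continue
        i = lo + int(np.argmax(values[lo:hi]))
        if 0 < i < n - 1 and values[i] > values[i - 1] and values[i] > values[i + 1]:
            sp.append(i)
    de: list[int] = []
    dn: list[int] = []
    dp: list[int] = []
    unresolved = 0
    win = int(math.floor(dn_window * sample_rate))
    for i, j in zip(sp[:-1], sp[1:]):
        seg = values[i + 1 : j]
        k_de = i + 1 + int(np.argmin(seg))
        de.append(k_de)
        k_dn = _first_local_min(values, i + 1, min(i + win, j - 1))
        if k_dn is None or k_dn >= k_de:
            unresolved += 1
            continue
        k_dp = _first_local_max(values, k_dn + 1, k_de - 1)
        if k_dp is None:
            unresolved += 1
            continue
        dn.append(k_dn)
        dp.append(k_dp)
    markers = {
        "sp": np.asarray(sp, dtype=int),
        "de": np.asarray(de, dtype=int),
        "dn": np.asarray(dn, dtype=int),
        "dp": np.asarray(dp, dtype=int),
    }
    return markers, unresolved


def _first_local_min(v: np.ndarray, lo: int, hi: int) -> int | None:
    """First strict local minimum index in [lo, hi], ties broken early."""
    for k in range(max(lo, 1), min(hi, v.size - 2) + 1):
        if v[k] < v[k - 1] and v[k] < v[k + 1]:
            return k
    return None


def _first_local_max(v: np.ndarray, lo: int, hi: int) -> int | None:
    for k in range(max(lo, 1), min(hi, v.size - 2) + 1):
        if v[k] > v[k - 1] and v[k] > v[k + 1]:
            return k
    return None


def make_pulsatile_bfi(
    params: PulseWaveformParams,
    duration: float,
    sample_rate: float,
    seed: int | None = None,
) -> PulsatileGroundTruth:
    """Generate a ground-truth pulsatile BFI waveform.

    Each cycle is a monotone-piecewise (PCHIP) curve through five control
    points — diastolic end, systolic peak, dicrotic notch, diastolic peak and
    the next diastolic end — so the continuous waveform has exactly one
    extremum of each kind per cycle and never dips below the baseline.  Cycle
    periods are jittered with the given seed.  The returned audit lists the
    sample-level extrema actually present after discretization (a notch
    narrower than the sample spacing is reported as unresolved, mirroring what
    any detector could recover).
    """
    lo, hi = PULSE_BAND_HZ
    if not lo <= params.pulse_rate <= hi:
        warnings.warn(
            f"pulse_rate {params.pulse_rate} Hz is outside the physiological "
            f"band [{lo}, {hi}] Hz; markers will not validate",
            stacklevel=2,
        )
    period = 1.0 / params.pulse_rate
    if duration < 2.0 * period:
        raise ValueError("duration must cover at least two pulse periods")
    rng = default_rng(seed)

    starts = [0.0]
    periods: list[float] = []
    while starts[-1] < duration + period:
        p = period
        if params.jitter_sd > 0:
            p = float(np.clip(period + rng.normal(0.0, params.jitter_sd),
                              0.5 * period, 1.5 * period))
        periods.append(p)
        starts.append(starts[-1] + p)
    cycle_starts = np.asarray(starts)

    times = np.arange(math.floor(duration * sample_rate)) / sample_rate
    if params.systolic_amplitude == 0:
        values = np.full(times.shape, params.bfi_baseline)
    else:
        knots_t = [0.0]
        knots_v = [params.bfi_baseline]
        for s, p in zip(cycle_starts[:-1], periods):
            for t, v in _cycle_knots(params, s, p):
                knots_t.append(t)
                knots_v.append(v)
        values = PchipInterpolator(knots_t, knots_v)(times)

    trace = BfiTrace(times=times, bfi=values, sample_rate=sample_rate)
    markers, unresolved = _audit_markers(values, sample_rate, cycle_starts)
    return PulsatileGroundTruth(
        trace=trace, markers=markers, cycle_starts=cycle_starts,
        unresolved_dn_dp=unresolved,
    )


def _mean_detection_hazard(det: DetectorSimParams) -> tuple[float, float]:
    """Solve for the per-frame hazard mu so the mean event rate is exact.

    With normalized intensity I = f*X + (1-f), X ~ Exp(1), and detection
    probability p = 1 - exp(-(mu I + mu_dark)), the expectation is
    E[p] = 1 - (1-dark_rate) * exp(-mu (1-f)) / (1 + mu f).  mu is chosen so
    that E[p] = mean_rate + dark_rate.
    """
    f = det.coherent_fraction
    target = det.mean_rate + det.dark_rate
    mu_dark = -math.log1p(-det.dark_rate) if det.dark_rate > 0 else 0.0

    def expected(mu: float) -> float:
        return 1.0 - (1.0 - det.dark_rate) * math.exp(-mu * (1.0 - f)) / (1.0 + mu * f)

    if expected(0.0) >= target:
        return 0.0, mu_dark
    hi = 1.0
    while expected(hi) < target and hi < 1e6:
        hi *= 2.0
    mu = brentq(lambda m: expected(m) - target, 0.0, hi, xtol=1e-14, rtol=1e-14)
    return float(mu), mu_dark


def _shaped_field(rng, n: int, n_px: int, spectrum_sqrt: np.ndarray) -> np.ndarray:
    """Circular complex Gaussian field with prescribed autocorrelation."""
    w = (rng.standard_normal((n, n_px)) + 1j * rng.standard_normal((n, n_px)))
    w *= math.sqrt(0.5)
    return np.fft.ifft(np.fft.fft(w, axis=0) * spectrum_sqrt[:, None], axis=0)


def simulate_speckle_photons(
    props: OpticalProperties,
    geom: ProbeGeometry,
    bfi_trace: BfiTrace | float,
    det: DetectorSimParams,
    max_bytes: int = 2_000_000_000,
) -> FrameStream:
    """Simulate a binary SPAD photon stream for a (possibly pulsatile) BFI.

    Each pixel carries an independent circular complex Gaussian field whose
    autocorrelation equals ``g1_semi_infinite`` at the locally constant BFI
    (the trace is treated as piecewise stationary: BFI is held fixed within
    each waveform sample, which is orders of magnitude longer than the speckle
    decorrelation time).  The field is synthesized by spectral shaping: white
    noise filtered by the square root of the circulant spectrum of the target
    g1.  Detected intensity mixes the dynamic speckle with a static background
    (``coherent_fraction``), so the realized Siegert amplitude is
    beta = coherent_fraction**2.  A binary event is drawn per frame with
    probability 1 - exp(-(mu*I + mu_dark)).

    A scalar ``bfi_trace`` is a stationary simulation.  Requests exceeding
    ``max_bytes`` of output are refused with guidance to chunk the stream.
    """
    out_bytes = det.n_frames * det.n_pixels
    if out_bytes > max_bytes:
        raise MemoryError(
            f"requested stream needs {out_bytes / 1e9:.2f} GB of counts "
            f"(> {max_bytes / 1e9:.2f} GB budget); simulate in chunks of "
            "frames and concatenate, or reduce n_pixels/n_frames"
        )
    if isinstance(bfi_trace, (int, float)):
        bfi_trace = BfiTrace(
            times=np.array([0.0]), bfi=np.array([float(bfi_trace)]),
            sample_rate=1.0 / (det.n_frames * det.exposure),
        )

    dt = det.exposure
    frame_times = np.arange(det.n_frames) * dt
    seg_of_frame = np.searchsorted(bfi_trace.times, frame_times, side="right") - 1
    seg_of_frame = np.clip(seg_of_frame, 0, len(bfi_trace) - 1)
    # contiguous runs of frames sharing one BFI value
    boundaries = np.flatnonzero(np.diff(seg_of_frame)) + 1
    seg_slices = np.split(np.arange(det.n_frames), boundaries)

    f = det.coherent_fraction
    mu, mu_dark = _mean_detection_hazard(det)
    counts = np.empty((det.n_frames, det.n_pixels), dtype=np.uint8)

    # Pre-compute sqrt spectra per segment (depends only on length and BFI).
    spectra: list[np.ndarray | None] = []
    for frames in seg_slices:
        n = frames.size
        if f == 0.0:
            spectra.append(None)
            continue
        bfi = float(bfi_trace.bfi[seg_of_frame[frames[0]]])
        lags = np.minimum(np.arange(n), n - np.arange(n)) * dt
        r = g1_semi_infinite(props, geom, bfi, np.sort(np.unique(lags)))
        # map back: lags are already the circulant distances; evaluate directly
        r_circ = np.interp(lags, np.sort(np.unique(lags)), r)
        s = np.fft.fft(r_circ).real
        s = np.clip(s, 0.0, None)
        mean_s = s.mean()
        spectra.append(np.sqrt(s / mean_s) if mean_s > 0 else np.zeros(n))

    ss = SeedSequence(det.seed)
    n_chunks = math.ceil(det.n_pixels / _PIXEL_CHUNK)
    children = ss.spawn(n_chunks)
    for ci in range(n_chunks):
        p0 = ci * _PIXEL_CHUNK
        p1 = min(det.n_pixels, p0 + _PIXEL_CHUNK)
        rng = default_rng(children[ci])
        for frames, sqrt_s in zip(seg_slices, spectra):
            n = frames.size
            if sqrt_s is None:
                intensity = np.ones((n, p1 - p0))
            else:
                field_ = _shaped_field(rng, n, p1 - p0, sqrt_s)
                intensity = f * np.abs(field_) ** 2 + (1.0 - f)
            p_event = 1.0 - np.exp(-(mu * intensity + mu_dark))
            counts[frames[0] : frames[0] + n, p0:p1] = (
                rng.random((n, p1 - p0)) < p_event
            ).astype(np.uint8)

    config = {
        "n_pixels": det.n_pixels,
        "exposure_s": det.exposure,
        "n_frames": det.n_frames,
        "coherent_fraction": det.coherent_fraction,
        "mean_rate": det.mean_rate,
        "dark_rate": det.dark_rate,
        "seed": det.seed,
        "sds_cm": geom.sds_cm,
        "mu_a": props.mu_a,
        "mu_s_prime": props.mu_s_prime,
        "n_tissue": props.n_tissue,
        "wavelength_nm": props.wavelength_nm,
    }
    return FrameStream(
        counts=counts,
        exposure_s=det.exposure,
        frame_period_s=det.exposure,
        sds_cm=geom.sds_cm,
        wavelength_nm=props.wavelength_nm,
        seed=det.seed,
        config=config,
        ground_truth=bfi_trace,
    )
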