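# pdcs — parallelized diffuse correlation spectroscopy

Diffuse correlation spectroscopy (DCS) measures microvascular blood flow by
watching the ultra-fast intensity fluctuations of laser speckle that has
diffused through tissue.  At the source–detector separations (SDS) needed to
reach adult cerebral tissue (≈4 cm) the detected light is so weak that a
single detector's autocorrelation estimate is dominated by noise.
*Parallelized* DCS (PDCS) solves this by imaging the speckle field onto a
single-photon avalanche diode (SPAD) array in which every pixel samples one
independent speckle: averaging the per-pixel intensity autocorrelations over
M pixels reduces the noise by √M, so a 32×32 array buys a 32-fold gain and a
500×500 array far more.

This package implements the full analysis chain for such experiments, plus a
physics-based simulator so every stage can be validated without access to raw
instrument data.  It is aimed at biomedical-optics researchers building or
evaluating multi-speckle blood-flow instruments.

## The model

For each pixel the normalized intensity autocorrelation of the binary photon
stream I(t) is

    g2(τ) = ⟨I(t)·I(t+τ)⟩ / ⟨I(t)⟩²

linked to the electric-field autocorrelation by the Siegert relation
g2 = 1 + β|g1|².  For a homogeneous semi-infinite tissue with absorption μa,
reduced scattering μs′ and an effective red-blood-cell diffusion coefficient
BFI (the blood flow index, cm²/s), the correlation diffusion equation has the
extrapolated-zero-boundary Green's-function solution

    g1(τ) ∝ exp(−K(τ)·r1)/r1 − exp(−K(τ)·rb)/rb,
    K(τ) = sqrt(3·μa·μs′ + 6·μs′²·k0²·BFI·τ)

with r1, rb the distances to the isotropic source and its image across the
extrapolated boundary.  Fitting 1 + β·g1(τ; BFI)² to a measured g2 curve by
bounded least squares yields BFI and β per averaging window; the BFI time
series then supports pulse-marker detection (systolic peak, dicrotic notch,
diastolic peak, diastolic end), the pulsatility index
PI = (⟨BFI⟩_SP − ⟨BFI⟩_DE)/⟨BFI⟩, marker-conditioned noise estimates, and
mixed-effects group contrasts of relative BFI across experimental conditions.

## Worked example

```python
import numpy as np
from pdcs import (
    OpticalProperties, ProbeGeometry, DetectorSimParams, DelayGrid,
    simulate_speckle_photons, correlator, bfi_fit,
)

props = OpticalProperties()           # mu_a=0.17/cm, mu_s'=8/cm, 785 nm
geom = ProbeGeometry(sds_cm=1.5)
det = DetectorSimParams(n_pixels=1024, exposure=10e-6, n_frames=80_000,
                        coherent_fraction=0.5, mean_rate=0.05, seed=11)
stream = simulate_speckle_photons(props, geom, 6e-9, det)   # BFI = 6e-9 cm^2/s

grid = DelayGrid(dt=10e-6, n_delays=46)
records = correlator.correlate_stream(stream, grid, window_length=0.1,
                                      span_frames=10_000, dtype=np.float32)
samples = [bfi_fit.fit_bfi(r, props, geom) for r in records]
print("median BFI %.3g cm^2/s, median beta %.3f"
      % (np.median([s.bfi for s in samples]),
         np.median([s.beta for s in samples])))
```

This prints

```
median BFI 6.2e-09 cm^2/s, median beta 0.226
```

i.e. the fit recovers the simulated flow index of 6e-9 cm²/s to within a few
percent from nothing but the binary photon events.  The fitted β sits just
below the mixing-law value 0.25 (= coherent_fraction²) because photon pile-up
at 0.05 events/frame mildly compresses the measured correlation amplitude —
the flow estimate is unaffected, since β is a free parameter of the fit.

A command-line interface mirrors the library:
`pdcs simulate | correlate | fit | pulse | noise | group`.

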