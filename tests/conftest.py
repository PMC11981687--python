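import numpy as np
import pytest

from pdcs.speckle_sim import (
    DetectorSimParams,
    OpticalProperties,
    ProbeGeometry,
    simulate_speckle_photons,
)


@pytest.fixture(scope="session")
def props():
    return OpticalProperties()


@pytest.fixture(scope="session")
def geom15():
    return ProbeGeometry(sds_cm=1.5, fiber_diameter_um=200.0,
                         pixel_active_diameter_um=6.9)


@pytest.fixture(scope="session")
def geom40():
    return ProbeGeometry(sds_cm=4.0)


@pytest.fixture(scope="session")
def static_stream(props, geom15):
    """Stationary multi-speckle stream at BFI 6e-9 cm^2/s, 512 pixels.

    Low count rate (0.02 events/frame) keeps photon pile-up negligible so
    measured g2 can be compared with the analytic Siegert curve.
    """
    det = DetectorSimParams(
        n_pixels=512, exposure=10e-6, n_frames=150 * 256,
        coherent_fraction=0.5, mean_rate=0.02, dark_rate=1e-4, seed=123,
    )
    return simulate_speckle_photons(props, geom15, 6e-9, det), det, 6e-9


def brute_force_g2(intensity: np.ndarray, n_delays: int) -> np.ndarray:
    """Literal double-loop transcription of the autocorrelation estimator.

    g2(tau_k) = mean over t of I(t) I(t+k) (pairs inside the window) divided
    by the squared window mean.  Deliberately independent of the vectorized
    implementation.
    """
    intensity = np.asarray(intensity, dtype=float)
    n = intensity.size
    mean = intensity.mean()
    out = np.empty(n_delays)
    for k in range(n_delays):
        acc = 0.0
        for t in range(n - k):
            acc += intensity[t] * intensity[t + k]
        out[k] = (acc / (n - k)) / mean**2
    return out
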