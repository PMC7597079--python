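import numpy as np
import pytest

import usentropy as u


@pytest.fixture(scope="session")
def pulse():
    """Clinical default pulse: 3.5 MHz, 2.3 mm PL, 30 MHz sampling."""
    return u.PulseSpec()


@pytest.fixture(scope="session")
def geometry():
    return u.LineGeometry()


@pytest.fixture(scope="session")
def speckle_frame(pulse, geometry):
    """Homogeneous high-density speckle frame (fully developed regime)."""
    rng = np.random.default_rng(11)
    phantom = u.PhantomSpec(
        scatterer_density=12.0,
        axial_extent=512 * pulse.sound_speed / (2 * pulse.sampling_rate),
        lateral_extent=48 * geometry.line_spacing,
    )
    field = u.scatter_field(phantom, u.resolution_cell_area(pulse.pulse_length, geometry.line_spacing), rng=rng)
    return u.synthesize_rf(field, pulse, 512, 48, geometry)


@pytest.fixture(scope="session")
def noise_frame(pulse, geometry):
    """Frame of i.i.d. Gaussian samples (no structure)."""
    rng = np.random.default_rng(5)
    return u.RFFrame(
        samples=rng.normal(size=(300, 32)),
        sampling_rate=pulse.sampling_rate,
        sound_speed=pulse.sound_speed,
        pulse_length=pulse.pulse_length,
        geometry=geometry,
    )


def scalar_window_entropy(samples, n_bins=100, lo=-1.0, hi=1.0):
    """Independent scalar-loop entropy oracle (normalize, bin, sum)."""
    flat = [float(v) for v in np.asarray(samples).ravel()]
    peak = max(abs(v) for v in flat)
    if peak == 0:
        return float("nan")
    counts = [0] * n_bins
    total = 0
    for v in flat:
        x = v / peak
        if x < lo or x > hi:
            continue
        k = int((x - lo) / (hi - lo) * n_bins)
        if k == n_bins:
            k = n_bins - 1
        counts[k] += 1
        total += 1
    h = 0.0
    for c in counts:
        if c > 0:
            w = c / total
            h -= w * np.log2(w)
    return h


def brute_force_auroc(scores, labels):
    """Exhaustive Mann-Whitney pair count (ties count 1/2)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))
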