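import math

import numpy as np
import pytest

from fmsf.signal_processing import (
    DEFAULT_BANDS,
    DEFAULT_PROTOCOL,
    BandDefinition,
    FMSFTrace,
)


@pytest.fixture
def protocol():
    return DEFAULT_PROTOCOL


@pytest.fixture
def bands():
    return DEFAULT_BANDS


@pytest.fixture
def canonical_trace():
    """A flat 540 s trace at 25 Hz (constant 100 a.u.)."""
    n = int(540 * 25)
    return FMSFTrace.from_samples(np.full(n, 100.0), sampling_rate=25.0)


def sinusoid(freq: float, amplitude: float, duration: float, fs: float,
             phase: float = 0.0) -> np.ndarray:
    t = np.arange(int(round(duration * fs))) / fs
    return amplitude * np.sin(2.0 * math.pi * freq * t + phase)


def dft_band_oracle(x: np.ndarray, fs: float,
                    bands: BandDefinition = DEFAULT_BANDS) -> dict[str, float]:
    """Brute-force DFT oracle for the band decomposition.

    Computes each low-frequency bin's mean-square contribution by direct
    correlation with complex exponentials (no FFT), then sums bins into
    bands with the same lower-open/upper-closed assignment.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    k_top = int(math.floor(bands.myogenic_upper * n / fs)) + 1
    t = np.arange(n)
    out = {"endo": 0.0, "neuro": 0.0, "myo": 0.0}
    edges = {
        "endo": (bands.low_cut, bands.endothelial_upper),
        "neuro": (bands.endothelial_upper, bands.neurogenic_upper),
        "myo": (bands.neurogenic_upper, bands.myogenic_upper),
    }
    for k in range(1, k_top + 1):
        f = k * fs / n
        coeff = np.sum(x * np.exp(-2j * math.pi * k * t / n))
        contrib = 2.0 * abs(coeff) ** 2 / n ** 2
        if k == n / 2:  # Nyquist bin has no conjugate partner
            contrib /= 2.0
        for band, (lo, up) in edges.items():
            if lo < f <= up:
                out[band] += contrib
    out["total_low"] = out["endo"] + out["neuro"] + out["myo"]
    return out
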