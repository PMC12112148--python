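"""Phase segmentation, detrending and spectral band decomposition of FMSF traces.

A Flow-Mediated Skin Fluorescence (FMSF) measurement records skin NADH
autofluorescence during a brachial occlusion--release protocol: a resting
baseline, an occlusion phase in which fluorescence rises as the tissue becomes
ischemic, a short hyperemic transient in which fluorescence drops below the
resting level after cuff release, and a reperfusion phase during which it
recovers.  Low-frequency oscillations ("flowmotion") ride on the baseline and
reperfusion phases; their spectral content below 0.15 Hz is attributed to
endothelial (< 0.021 Hz), neurogenic (0.021--0.052 Hz) and myogenic
(0.052--0.15 Hz) regulation of microvascular tone.

This module segments a trace into the four protocol phases, estimates the
resting fluorescence level, removes slow drift from analysis windows, and
integrates a rectangular-window periodogram over the three physiological
bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MeasurementProtocol",
    "BandDefinition",
    "FMSFTrace",
    "Interval",
    "PhaseSegmentation",
    "BandComponents",
    "TruncatedTraceError",
    "WindowTooShortError",
    "SamplingTooSlowError",
    "segment_phases",
    "estimate_baseline",
    "detrend_window",
    "band_decompose",
    "DEFAULT_PROTOCOL",
    "DEFAULT_BANDS",
    "CANONICAL_SAMPLING_RATE",
]

#: Sampling rate of the measurement device, Hz.
CANONICAL_SAMPLING_RATE = 25.0


class TruncatedTraceError(ValueError):
    """Raised when a trace is shorter than the measurement protocol requires."""


class WindowTooShortError(ValueError):
    """Raised when an analysis window cannot resolve the slow oscillations."""


class SamplingTooSlowError(ValueError):
    """Raised when the sampling rate cannot resolve the myogenic band."""


@dataclass(frozen=True)
class MeasurementProtocol:
    """Timing of the occlusion--release protocol.

    Parameters
    ----------
    baseline_duration : float
        Resting recording before cuff inflation, seconds (canonical 180).
    occlusion_duration : float
        Cuff-inflated ischemic phase, seconds (canonical 180).
    post_release_duration : float
        Recording after cuff deflation, seconds (canonical 180).
    hyperemic_window : float
        Initial part of the post-release phase containing the rapid
        hyperemic undershoot, seconds (canonical 30); the remainder of the
        post-release phase is the reperfusion analysis window.
    cuff_overpressure : float
        Cuff pressure above the subject's systolic pressure, mmHg
        (canonical 60).  Recorded for provenance; not used in analysis.
    """

    baseline_duration: float = 180.0
    occlusion_duration: float = 180.0
    post_release_duration: float = 180.0
    hyperemic_window: float = 30.0
    cuff_overpressure: float = 60.0

    def __post_init__(self) -> None:
        for name in ("baseline_duration", "occlusion_duration",
                     "post_release_duration", "hyperemic_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.hyperemic_window > self.post_release_duration:
            raise ValueError("hyperemic_window must not exceed post_release_duration")

    @property
    def total_duration(self) -> float:
        """Full protocol span in seconds."""
        return (self.baseline_duration + self.occlusion_duration
                + self.post_release_duration)


@dataclass(frozen=True)
class BandDefinition:
    """Frequency-band edges (Hz) for the flowmotion decomposition.

    The three bands partition ``(low_cut, myogenic_upper]``; a periodogram bin
    with center frequency ``f`` belongs to a band when ``lower < f <= upper``.
    ``low_cut`` excludes DC and drift slower than the analysis window can
    distinguish from trend.
    """

    low_cut: float = 0.005
    endothelial_upper: float = 0.021
    neurogenic_upper: float = 0.052
    myogenic_upper: float = 0.15

    def __post_init__(self) -> None:
        edges = (self.low_cut, self.endothelial_upper,
                 self.neurogenic_upper, self.myogenic_upper)
        if not (0 < edges[0] < edges[1] < edges[2] < edges[3]):
            raise ValueError(
                "band edges must satisfy 0 < low_cut < endothelial_upper"
                " < neurogenic_upper < myogenic_upper")

    @property
    def min_window_seconds(self) -> float:
        """Shortest admissible analysis window: two cycles at the endothelial
        band's upper edge, so every band contains resolvable oscillations."""
        return 2.0 / self.endothelial_upper


DEFAULT_PROTOCOL = MeasurementProtocol()
DEFAULT_BANDS = BandDefinition()


@dataclass
class FMSFTrace:
    """A uniformly sampled fluorescence time series.

    Attributes
    ----------
    time : ndarray
        Sample times in seconds, strictly increasing with constant step
        ``1/sampling_rate``.
    fluorescence : ndarray
        NADH fluorescence in arbitrary units (a.u.); no missing values.
    sampling_rate : float
        Samples per second (canonical 25).
    """

    time: np.ndarray
    fluorescence: np.ndarray
    sampling_rate: float = CANONICAL_SAMPLING_RATE

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time.ndim != 1 or self.fluorescence.ndim != 1:
            raise ValueError("time and fluorescence must be 1-D")
        if self.time.size != self.fluorescence.size:
            raise ValueError("time and fluorescence lengths differ")
        if self.time.size < 2:
            raise ValueError("trace needs at least two samples")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValueError("fluorescence contains non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        step = 1.0 / self.sampling_rate
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if np.max(np.abs(dt - step)) > 1e-9 * step + 1e-12:
            raise ValueError("time is not uniformly spaced at 1/sampling_rate")

    @classmethod
    def from_samples(cls, fluorescence: np.ndarray,
                     sampling_rate: float = CANONICAL_SAMPLING_RATE,
                     t0: float = 0.0) -> "FMSFTrace":
        """Build a trace from samples alone, synthesising the time axis."""
        fluorescence = np.asarray(fluorescence, dtype=float)
        time = t0 + np.arange(fluorescence.size) / sampling_rate
        return cls(time=time, fluorescence=fluorescence,
                   sampling_rate=sampling_rate)

    @property
    def duration(self) -> float:
        """Trace span in seconds (number of samples over the rate)."""
        return self.fluorescence.size / self.sampling_rate

    def __len__(self) -> int:
        return self.fluorescence.size


@dataclass(frozen=True)
class Interval:
    """Half-open sample-index interval ``[start, stop)``."""

    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.stop < self.start:
            raise ValueError("stop must be >= start")

    @property
    def slice(self) -> slice:
        return slice(self.start, self.stop)

    def __len__(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class PhaseSegmentation:
    """Sample-index boundaries of the four protocol phases.

    The intervals are contiguous, non-overlapping, ordered
    baseline -> occlusion -> hyperemic -> reperfusion, and together cover the
    protocol span exactly.
    """

    baseline: Interval
    occlusion: Interval
    hyperemic: Interval
    reperfusion: Interval

    def __post_init__(self) -> None:
        seq = (self.baseline, self.occlusion, self.hyperemic, self.reperfusion)
        for a, b in zip(seq, seq[1:]):
            if a.stop != b.start:
                raise ValueError("phase intervals must be contiguous")

    @property
    def post_release(self) -> Interval:
        """Hyperemic window plus reperfusion: the whole post-deflation span."""
        return Interval(self.hyperemic.start, self.reperfusion.stop)


@dataclass(frozen=True)
class BandComponents:
    """Band-integrated mean-square oscillatory power of one analysis window.

    ``endo``, ``neuro`` and ``myo`` are the periodogram mean-square
    contributions (a.u.^2) of the endothelial, neurogenic and myogenic bands;
    ``total_power`` is the mean square of the whole residual, so
    ``endo + neuro + myo <= total_power`` up to floating-point error.
    """

    endo: float
    neuro: float
    myo: float
    total_power: float
    window_label: str = "baseline"

    def __post_init__(self) -> None:
        for name in ("endo", "neuro", "myo", "total_power"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def segment_phases(trace: FMSFTrace,
                   protocol: MeasurementProtocol = DEFAULT_PROTOCOL,
                   ) -> PhaseSegmentation:
    """Split a trace into baseline, occlusion, hyperemic and reperfusion phases.

    Boundaries are placed at the protocol's nominal phase-change times; the
    hyperemic interval covers the first ``hyperemic_window`` seconds after
    cuff deflation and the reperfusion interval the remainder of the
    post-release recording.

    Raises
    ------
    TruncatedTraceError
        If the trace is shorter than the protocol span; the message names the
        missing seconds.
    """
    fs = trace.sampling_rate
    needed = int(round(protocol.total_duration * fs))
    if len(trace) < needed:
        missing = (needed - len(trace)) / fs
        raise TruncatedTraceError(
            f"truncated trace: {missing:.2f} s shorter than the "
            f"{protocol.total_duration:.0f} s protocol")
    b = int(round(protocol.baseline_duration * fs))
    o = b + int(round(protocol.occlusion_duration * fs))
    h = o + int(round(protocol.hyperemic_window * fs))
    end = needed
    return PhaseSegmentation(
        baseline=Interval(0, b),
        occlusion=Interval(b, o),
        hyperemic=Interval(o, h),
        reperfusion=Interval(h, end),
    )


def estimate_baseline(trace: FMSFTrace, seg: PhaseSegmentation) -> float:
    """Resting fluorescence level: arithmetic mean over the baseline phase.

    Oscillations average out over the 3-minute window, and a linear drift
    contributes its midpoint value, so the mean is an unbiased estimate of the
    resting level for the signal model assumed here.
    """
    if len(seg.baseline) == 0:
        raise ValueError("empty baseline interval")
    return float(np.mean(trace.fluorescence[seg.baseline.slice]))


def detrend_window(segment: np.ndarray, sampling_rate: float,
                   bands: BandDefinition = DEFAULT_BANDS) -> np.ndarray:
    """Remove the least-squares linear trend from an analysis window.

    Returns the zero-mean oscillatory residual.  Linear detrending removes
    drift slower than the window fundamental, which a rectangular-window
    periodogram could otherwise smear into the endothelial band.  The
    operation is idempotent: detrending the residual again changes nothing.

    Raises
    ------
    WindowTooShortError
        If the window is shorter than ``bands.min_window_seconds`` — too short
        to hold two cycles of the slowest band-resolvable oscillation.
    """
    x = np.asarray(segment, dtype=float)
    if x.ndim != 1:
        raise ValueError("segment must be 1-D")
    duration = x.size / sampling_rate
    if duration < bands.min_window_seconds:
        raise WindowTooShortError(
            f"window too short for low_cut: {duration:.1f} s < "
            f"{bands.min_window_seconds:.1f} s needed to resolve the "
            "endothelial band")
    t = np.arange(x.size, dtype=float)
    coeffs = np.polynomial.polynomial.polyfit(t, x, 1)
    residual = x - np.polynomial.polynomial.polyval(t, coeffs)
    # polyfit leaves a residual mean at floating-point noise level; remove it
    # so the zero-mean contract holds exactly.
    return residual - residual.mean()


def periodogram_mean_square(residual: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sided rectangular-window periodogram in mean-square units.

    Returns ``(freq_fraction, power)`` where ``freq_fraction[k] = k / n`` is
    the bin center in cycles per sample and ``power[k]`` the mean-square
    contribution of that bin, so ``power.sum() == mean(residual**2)`` exactly
    (Parseval).
    """
    x = np.asarray(residual, dtype=float)
    n = x.size
    spectrum = np.fft.rfft(x)
    power = np.abs(spectrum) ** 2 / n ** 2
    # Double every bin that has a conjugate partner (all but DC and, for even
    # n, the Nyquist bin).
    if n % 2 == 0:
        power[1:-1] *= 2.0
    else:
        power[1:] *= 2.0
    freqs = np.arange(power.size, dtype=float) / n
    return freqs, power


def band_decompose(residual: np.ndarray, sampling_rate: float,
                   bands: BandDefinition = DEFAULT_BANDS,
                   window_label: str = "baseline") -> BandComponents:
    """Integrate the periodogram of a detrended window over the three bands.

    A single FFT of the whole window is used (no segment averaging or
    tapering), which makes the Parseval identity exact: the band components
    plus the out-of-band power equal the residual's mean square.  A bin with
    center frequency ``f`` is assigned to the band with ``lower < f <= upper``.

    Raises
    ------
    SamplingTooSlowError
        If ``sampling_rate <= 2 * bands.myogenic_upper`` (myogenic band above
        Nyquist).
    WindowTooShortError
        If the window is shorter than ``bands.min_window_seconds``.
    """
    if sampling_rate <= 2.0 * bands.myogenic_upper:
        raise SamplingTooSlowError(
            f"sampling too slow: {sampling_rate} Hz cannot resolve the "
            f"myogenic band (needs > {2 * bands.myogenic_upper} Hz)")
    x = np.asarray(residual, dtype=float)
    if x.size / sampling_rate < bands.min_window_seconds:
        raise WindowTooShortError(
            f"window too short for low_cut: {x.size / sampling_rate:.1f} s < "
            f"{bands.min_window_seconds:.1f} s")
    freqs, power = periodogram_mean_square(x)
    freqs_hz = freqs * sampling_rate

    def band_sum(lower: float, upper: float) -> float:
        mask = (freqs_hz > lower) & (freqs_hz <= upper)
        return float(power[mask].sum())

    return BandComponents(
        endo=band_sum(bands.low_cut, bands.endothelial_upper),
        neuro=band_sum(bands.endothelial_upper, bands.neurogenic_upper),
        myo=band_sum(bands.neurogenic_upper, bands.myogenic_upper),
        total_power=float(power.sum()),
        window_label=window_label,
    )
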