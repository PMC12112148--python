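"""Per-subject FMSF vascular parameters.

Seven scalar parameters summarise one occlusion--release measurement:

* ``FM`` — flowmotion at baseline: mean-square deviation of the detrended
  baseline signal (a.u.^2), with band components ``ENDO``, ``NEURO``, ``MYO``.
* ``NOI`` — normoxia oscillatory index: percentage of baseline low-frequency
  oscillatory power in the endothelial plus neurogenic bands.
* ``IRmax`` — ischemic response: peak fluorescence rise during occlusion,
  percent of the resting level.  Negative values flag mitochondrial
  dysfunction (the occlusion maximum never exceeded the resting level).
* ``HRmax`` — hyperemic response: maximum fluorescence dip below the resting
  level after cuff release, percent (reported as a positive magnitude).
* ``RHR`` — reactive hyperemia response: the total ischemia-to-hyperemia
  excursion, ``IRmax + HRmax``.
* ``FM_R`` / ``HS`` — flowmotion of the reperfusion window and its myogenic
  band component ("hypoxia sensitivity"), a.u.^2.

``log10`` transforms of the right-skewed magnitudes (FM, NEURO, HS) are also
carried, since group comparisons are performed on the log scale where those
parameters are approximately normal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields

import numpy as np

from .signal_processing import (
    DEFAULT_BANDS,
    DEFAULT_PROTOCOL,
    BandComponents,
    BandDefinition,
    FMSFTrace,
    MeasurementProtocol,
    PhaseSegmentation,
    band_decompose,
    detrend_window,
    estimate_baseline,
    segment_phases,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FMSFParameters",
    "compute_flowmotion",
    "compute_band_parameters",
    "compute_noi",
    "compute_ischemic_response",
    "compute_hyperemic_response",
    "compute_rhr",
    "compute_hypoxia_sensitivity",
    "log_transform",
    "analyze_trace",
    "PARAMETER_NAMES",
]

#: Canonical column order for parameter tables.
PARAMETER_NAMES = ("FM", "ENDO", "NEURO", "MYO", "NOI", "IRmax", "HRmax",
                   "RHR", "FM_R", "HS", "logFM", "logNEURO", "logHS")


@dataclass
class FMSFParameters:
    """The derived scalars of one measurement; ``nan`` marks a missing value."""

    FM: float = math.nan
    ENDO: float = math.nan
    NEURO: float = math.nan
    MYO: float = math.nan
    NOI: float = math.nan
    IRmax: float = math.nan
    HRmax: float = math.nan
    RHR: float = math.nan
    FM_R: float = math.nan
    HS: float = math.nan
    logFM: float = math.nan
    logNEURO: float = math.nan
    logHS: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def compute_flowmotion(residual: np.ndarray) -> float:
    """Flowmotion: mean of the squared detrended samples (a.u.^2)."""
    x = np.asarray(residual, dtype=float)
    if x.size == 0:
        raise ValueError("empty residual")
    return float(np.mean(x ** 2))


def compute_band_parameters(components: BandComponents
                            ) -> tuple[float, float, float]:
    """Name the baseline band components (ENDO, NEURO, MYO)."""
    triple = (components.endo, components.neuro, components.myo)
    if any(v < 0 for v in triple):
        raise ValueError("band components must be >= 0")
    return triple


def compute_noi(endo: float, neuro: float, myo: float) -> float:
    """Normoxia oscillatory index, percent.

    ``NOI = 100 * (ENDO + NEURO) / (ENDO + NEURO + MYO)``; bounded in
    [0, 100].  If all three components are zero the index is undefined and
    ``nan`` is returned with a warning.
    """
    if min(endo, neuro, myo) < 0:
        raise ValueError("band components must be >= 0")
    total = endo + neuro + myo
    if total == 0:
        logger.warning("NOI undefined: all band components are zero")
        return math.nan
    return 100.0 * (endo + neuro) / total


def compute_ischemic_response(trace: FMSFTrace, seg: PhaseSegmentation,
                              baseline_level: float) -> float:
    """IRmax: peak occlusion-phase rise above the resting level, percent.

    Negative when the occlusion maximum stays below the resting level, the
    mitochondrial-dysfunction flag used for subject exclusion.
    """
    if baseline_level <= 0:
        raise ValueError("baseline_level must be > 0")
    if len(seg.occlusion) == 0:
        raise ValueError("empty occlusion interval")
    peak = float(np.max(trace.fluorescence[seg.occlusion.slice]))
    return 100.0 * (peak - baseline_level) / baseline_level


def compute_hyperemic_response(trace: FMSFTrace, seg: PhaseSegmentation,
                               baseline_level: float) -> float:
    """HRmax: maximum post-release dip below the resting level, percent.

    The minimum is taken over the whole post-release span (hyperemic window
    plus reperfusion); physiologically it falls inside the hyperemic window.
    Returns 0 if the signal never dips below the resting level.
    """
    if baseline_level <= 0:
        raise ValueError("baseline_level must be > 0")
    post = seg.post_release
    if len(post) == 0:
        raise ValueError("empty post-release interval")
    trough = float(np.min(trace.fluorescence[post.slice]))
    return max(0.0, 100.0 * (baseline_level - trough) / baseline_level)


def compute_rhr(ir_max: float, hr_max: float) -> float:
    """Reactive hyperemia response: IRmax + HRmax (total excursion)."""
    return ir_max + hr_max


def compute_hypoxia_sensitivity(reperfusion_components: BandComponents
                                ) -> tuple[float, float]:
    """Reperfusion flowmotion ``FM_R`` and hypoxia sensitivity ``HS``.

    ``FM_R`` is the mean-square flowmotion of the reperfusion residual and
    ``HS`` its myogenic band component, both in absolute a.u.^2 (not a
    percentage of ``FM_R``).
    """
    if reperfusion_components.window_label != "reperfusion":
        raise ValueError("components must come from the reperfusion window")
    return reperfusion_components.total_power, reperfusion_components.myo


def log_transform(value: float) -> float:
    """Base-10 logarithm; ``nan`` with a warning for non-positive input."""
    if not value > 0:
        logger.warning("log transform undefined for value %r; marking missing",
                       value)
        return math.nan
    return math.log10(value)


def analyze_trace(trace: FMSFTrace,
                  protocol: MeasurementProtocol = DEFAULT_PROTOCOL,
                  bands: BandDefinition = DEFAULT_BANDS) -> FMSFParameters:
    """Run the full single-subject pipeline on one trace.

    Segments the trace, estimates the resting level, detrends the baseline
    and reperfusion windows, decomposes each into the three frequency bands,
    and assembles all derived parameters.
    """
    seg = segment_phases(trace, protocol)
    level = estimate_baseline(trace, seg)
    fs = trace.sampling_rate

    base_res = detrend_window(trace.fluorescence[seg.baseline.slice], fs, bands)
    base_bands = band_decompose(base_res, fs, bands, window_label="baseline")
    endo, neuro, myo = compute_band_parameters(base_bands)
    fm = compute_flowmotion(base_res)
    noi = compute_noi(endo, neuro, myo)

    rep_res = detrend_window(trace.fluorescence[seg.reperfusion.slice], fs,
                             bands)
    rep_bands = band_decompose(rep_res, fs, bands, window_label="reperfusion")
    fm_r, hs = compute_hypoxia_sensitivity(rep_bands)

    ir_max = compute_ischemic_response(trace, seg, level)
    hr_max = compute_hyperemic_response(trace, seg, level)

    return FMSFParameters(
        FM=fm, ENDO=endo, NEURO=neuro, MYO=myo, NOI=noi,
        IRmax=ir_max, HRmax=hr_max, RHR=compute_rhr(ir_max, hr_max),
        FM_R=fm_r, HS=hs,
        logFM=log_transform(fm), logNEURO=log_transform(neuro),
        logHS=log_transform(hs),
    )
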