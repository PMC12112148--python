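"""Synthetic FMSF traces and cohorts with known ground truth.

Real FMSF recordings from the case--control study this pipeline targets are
not publicly available, so every downstream stage is exercised on simulated
data whose true parameter values are known by construction.

A simulated trace follows the canonical protocol morphology: an oscillating
baseline at a resting level, a saturating-exponential fluorescence rise
during occlusion, a rapid post-release undershoot reaching its minimum
inside the hyperemic window, and an exponential recovery toward the resting
level carrying reperfusion oscillations.  Band oscillations are sums of
discrete sinusoidal tones whose frequencies sit on the DFT grid of the
corresponding analysis window, so the injected per-band mean-square power is
exactly what the spectral decomposition should recover.

Cohort generation draws per-subject parameter targets hierarchically:
log-normal for the positive right-skewed magnitudes (ENDO, NEURO, MYO, HS)
and normal for the excursion percentages (IRmax — which may legitimately go
negative, the exclusion flag — and HRmax).  Group presets encode the study
conditions emulated here: three female groups, patchy alopecia areata
(AA, n=18), alopecia universalis (AU, n=6) and healthy controls (n=17),
with the group-level parameter and demographic summaries listed in
``GROUP_PRESETS``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .signal_processing import (
    CANONICAL_SAMPLING_RATE,
    DEFAULT_BANDS,
    DEFAULT_PROTOCOL,
    BandDefinition,
    FMSFTrace,
    MeasurementProtocol,
)

__all__ = [
    "Tone",
    "TraceSimConfig",
    "GroupSimSpec",
    "simulate_trace",
    "simulate_subject",
    "simulate_cohort",
    "group_presets",
    "GROUP_PRESETS",
]

BAND_NAMES = ("endo", "neuro", "myo")


@dataclass(frozen=True)
class Tone:
    """One sinusoidal oscillation component: ``amplitude * sin(2πft + phase)``.

    ``phase=None`` means "draw uniformly at simulation time".  A tone of
    amplitude A contributes A^2/2 to the mean-square power of its window.
    """

    frequency: float
    amplitude: float
    phase: float | None = None

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


def _band_interval(band: str, bands: BandDefinition) -> tuple[float, float]:
    edges = {
        "endo": (bands.low_cut, bands.endothelial_upper),
        "neuro": (bands.endothelial_upper, bands.neurogenic_upper),
        "myo": (bands.neurogenic_upper, bands.myogenic_upper),
    }
    return edges[band]


@dataclass
class TraceSimConfig:
    """Full parameterisation of one simulated measurement.

    ``band_spec`` (baseline window) and ``reperfusion_band_spec`` map band
    name -> list of :class:`Tone`; every tone frequency must lie inside its
    declared band.  ``ischemic_rise_fraction`` and ``hyperemic_dip_fraction``
    are the target IRmax/100 and HRmax/100; the rise may be negative (the
    mitochondrial-dysfunction phenotype), the dip may not.
    """

    baseline_level: float = 1000.0
    band_spec: dict[str, list[Tone]] = field(default_factory=dict)
    reperfusion_band_spec: dict[str, list[Tone]] = field(default_factory=dict)
    ischemic_rise_fraction: float = 0.12
    hyperemic_dip_fraction: float = 0.16
    occlusion_rise_time_constant: float = 20.0
    dip_time_constant: float = 10.0
    recovery_time_constant: float = 40.0
    noise_sd: float = 0.0
    protocol: MeasurementProtocol = DEFAULT_PROTOCOL
    sampling_rate: float = CANONICAL_SAMPLING_RATE
    bands: BandDefinition = DEFAULT_BANDS
    seed: int | Sequence[int] = 0

    def __post_init__(self) -> None:
        if self.baseline_level <= 0:
            raise ValueError("baseline_level must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.hyperemic_dip_fraction < 0:
            raise ValueError("hyperemic_dip_fraction must be >= 0")
        if self.sampling_rate <= 2 * self.bands.myogenic_upper:
            raise ValueError("sampling_rate cannot resolve the myogenic band")
        for spec in (self.band_spec, self.reperfusion_band_spec):
            for band, tones in spec.items():
                lo, up = _band_interval(band, self.bands)
                for tone in tones:
                    if not (lo < tone.frequency <= up):
                        raise ValueError(
                            f"tone at {tone.frequency} Hz outside the "
                            f"{band} band ({lo}, {up}]")


def _resolve_phases(tones: Sequence[Tone], rng: np.random.Generator
                    ) -> list[Tone]:
    return [t if t.phase is not None
            else replace(t, phase=float(rng.uniform(0.0, 2.0 * math.pi)))
            for t in tones]


def _oscillation(t: np.ndarray, tones: Sequence[Tone]) -> np.ndarray:
    out = np.zeros_like(t)
    for tone in tones:
        out += tone.amplitude * np.sin(2.0 * math.pi * tone.frequency * t
                                       + tone.phase)
    return out


def simulate_trace(config: TraceSimConfig) -> FMSFTrace:
    """Generate one deterministic trace from a fully specified configuration.

    Same configuration and seed give a bit-identical sample vector.  In the
    noiseless case the global maximum lies inside the occlusion phase and the
    global minimum at the end of the hyperemic window, and the extracted
    IRmax/HRmax match ``100 * rise`` / ``100 * dip`` up to the residual of
    the finite exponential time constants (< 0.02 percentage points with the
    canonical protocol).
    """
    p = config.protocol
    fs = config.sampling_rate
    dt = 1.0 / fs
    n = int(round(p.total_duration * fs))
    t = np.arange(n) * dt
    rng = np.random.default_rng(config.seed)

    base_tones = _resolve_phases(
        [tn for b in BAND_NAMES for tn in config.band_spec.get(b, [])], rng)
    rep_tones = _resolve_phases(
        [tn for b in BAND_NAMES
         for tn in config.reperfusion_band_spec.get(b, [])], rng)

    level = config.baseline_level
    rise = config.ischemic_rise_fraction
    dip = config.hyperemic_dip_fraction
    t_b = p.baseline_duration
    t_o = t_b + p.occlusion_duration
    t_h = t_o + p.hyperemic_window

    signal = np.empty(n)
    base_osc = _oscillation(t, base_tones)

    # A negative ischemic response (mitochondrial dysfunction) presents as
    # fluorescence that drifts downward instead of rising under occlusion.
    # It is modelled as a linear baseline decline continuing to the cuff
    # inflation, with the slope calibrated so that the occlusion maximum
    # sits exactly `rise` (< 0) below the baseline-window mean; linear
    # detrending removes the drift, so baseline flowmotion is unaffected.
    if rise < 0:
        gamma = 2.0 * rise * level / (rise * (t_b - dt) - (t_b + dt))
    else:
        gamma = 0.0
    # The resting level the analysis will estimate: mean over the baseline
    # window (drift contributes its midpoint; whole-period tones average 0).
    resting = level - gamma * (t_b - dt) / 2.0

    m_base = t < t_b
    signal[m_base] = level - gamma * t[m_base] + base_osc[m_base]

    # Occlusion: flowmotion ceases when flow is arrested (tones stop at
    # inflation).  A positive response rises saturating-exponentially toward
    # level*(1+rise); a dysfunctional one stays flat at the declined value.
    m_occ = (t >= t_b) & (t < t_o)
    s = t[m_occ] - t_b + dt
    if rise >= 0:
        signal[m_occ] = level * (1.0 + rise * (1.0 - np.exp(
            -s / config.occlusion_rise_time_constant)))
        v_release = level * (1.0 + rise * (1.0 - math.exp(
            -p.occlusion_duration / config.occlusion_rise_time_constant)))
    else:
        signal[m_occ] = level - gamma * t_b
        v_release = level - gamma * t_b

    # Hyperemic undershoot: exponential descent continuing from the last
    # occlusion sample, calibrated to hit resting*(1-dip) exactly at the
    # window's last sample (which is therefore the trace minimum).
    dip_target = resting * (1.0 - dip)
    e_last = math.exp(-p.hyperemic_window / config.dip_time_constant)
    asymptote = (dip_target - v_release * e_last) / (1.0 - e_last)
    m_hyp = (t >= t_o) & (t < t_h)
    s = t[m_hyp] - t_o + dt
    signal[m_hyp] = asymptote + (v_release - asymptote) * np.exp(
        -s / config.dip_time_constant)

    # Reperfusion: exponential recovery toward the resting level, with the
    # reperfusion tones ramped in on the recovery time constant so the trough
    # at the hyperemic-window boundary stays the global minimum.  The ramp
    # envelope is amplitude-compensated so the window's detrended mean-square
    # tone power matches the nominal sum of A^2/2.
    m_rep = t >= t_h
    u = t[m_rep] - t_h + dt
    ramp = 1.0 - np.exp(-u / config.recovery_time_constant)
    depth = resting - dip_target
    recovery = resting - depth * np.exp(-u / config.recovery_time_constant)
    rep_osc = _oscillation(t[m_rep], rep_tones)
    comp = 1.0 / math.sqrt(float(np.mean(ramp ** 2))) if rep_tones else 1.0
    signal[m_rep] = recovery + comp * ramp * rep_osc

    if config.noise_sd > 0:
        signal = signal + rng.normal(0.0, config.noise_sd, size=n)

    return FMSFTrace(time=t, fluorescence=signal, sampling_rate=fs)


# --------------------------------------------------------------------------
# Hierarchical cohort simulation


@dataclass
class GroupSimSpec:
    """Target distributions for one study group.

    ``lognormal_targets`` maps parameter name (ENDO, NEURO, MYO, HS) to the
    target (mean, SD) *on the natural scale*; draws are moment-matched
    log-normals.  ``normal_targets`` maps IRmax / HRmax (percent) to normal
    (mean, SD).  ``demographics`` maps age/bmi/sbp/dbp to (mean, SD) and
    ``flag_rates`` maps comorbidity flag names to prevalences.
    """

    label: str
    n: int
    lognormal_targets: dict[str, tuple[float, float]]
    normal_targets: dict[str, tuple[float, float]]
    demographics: dict[str, tuple[float, float]] = field(default_factory=dict)
    flag_rates: dict[str, float] = field(default_factory=dict)
    baseline_level: float = 1000.0
    noise_sd: float = 5.0
    protocol: MeasurementProtocol = DEFAULT_PROTOCOL
    sampling_rate: float = CANONICAL_SAMPLING_RATE
    bands: BandDefinition = DEFAULT_BANDS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name, (mean, sd) in {**self.lognormal_targets,
                                 **self.normal_targets}.items():
            if sd < 0:
                raise ValueError(f"target SD for {name} must be >= 0")
        for name, (mean, sd) in self.lognormal_targets.items():
            if mean <= 0:
                raise ValueError(
                    f"log-normal target {name} needs mean > 0, got {mean}")


def _lognormal_draw(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Moment-matched log-normal: E[X] = mean and SD[X] = sd exactly."""
    if sd == 0:
        return mean
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return float(math.exp(mu + math.sqrt(sigma2) * rng.standard_normal()))


def _detrend_safe_phase(frequency: float, window_start: float,
                        n_samples: int, sampling_rate: float) -> float:
    """Phase making the tone orthogonal to a linear trend over the window.

    A discrete sinusoid with an integer number of periods in the window is
    orthogonal to the constant but not, in general, to a linear ramp; linear
    detrending would therefore remove part of the tone and smear it across
    the spectrum.  For each frequency there are exactly two phases (pi
    apart) at which the inner product with the centered ramp vanishes, so
    detrending leaves the tone untouched and the injected band power is
    exactly recoverable.
    """
    n = np.arange(n_samples, dtype=float)
    t = window_start + n / sampling_rate
    ramp = n - n.mean()
    arg = 2.0 * math.pi * frequency * t
    s_sin = float(np.dot(ramp, np.sin(arg)))
    s_cos = float(np.dot(ramp, np.cos(arg)))
    return math.atan2(-s_sin, s_cos)


def _grid_tones(rng: np.random.Generator, band: str, bands: BandDefinition,
                window_start: float, window_seconds: float,
                sampling_rate: float, mean_square: float) -> list[Tone]:
    """1--3 tones on the window's DFT grid inside the band, with amplitudes
    splitting the requested mean-square power and detrend-safe phases."""
    if mean_square <= 0:
        return []
    lo, up = _band_interval(band, bands)
    k_min = math.floor(lo * window_seconds) + 1
    k_max = math.ceil(up * window_seconds) - 1
    grid = [k / window_seconds for k in range(k_min, k_max + 1)
            if lo < k / window_seconds < up]
    if not grid:
        raise ValueError(f"analysis window of {window_seconds} s resolves no "
                         f"frequency inside the {band} band")
    n_samples = int(round(window_seconds * sampling_rate))
    n_tones = min(int(rng.integers(1, 4)), len(grid))
    freqs = rng.choice(grid, size=n_tones, replace=False)
    weights = rng.uniform(0.5, 1.5, size=n_tones)
    weights /= weights.sum()
    tones = []
    for f, w in zip(freqs, weights):
        phase = _detrend_safe_phase(float(f), window_start, n_samples,
                                    sampling_rate)
        if rng.uniform() < 0.5:
            phase += math.pi
        tones.append(Tone(frequency=float(f),
                          amplitude=math.sqrt(2.0 * mean_square * w),
                          phase=phase))
    return tones


#: Reperfusion endothelial/neurogenic content as a fraction of the baseline
#: band power (the myogenic reperfusion power is set directly by HS).
REPERFUSION_CARRYOVER = 0.5


def simulate_subject(spec: GroupSimSpec, index: int
                     ) -> tuple[TraceSimConfig, dict[str, float]]:
    """Draw one subject's trace configuration and its ground-truth record.

    Band powers and excursion fractions are drawn from the group's target
    distributions; tone frequencies come from the DFT grid of the relevant
    analysis window so the injected powers are exactly recoverable.
    """
    rng = np.random.default_rng([spec.seed, index])
    truth: dict[str, float] = {}
    for name in ("ENDO", "NEURO", "MYO", "HS"):
        mean, sd = spec.lognormal_targets[name]
        truth[name] = _lognormal_draw(rng, mean, sd)
    for name in ("IRmax", "HRmax"):
        mean, sd = spec.normal_targets[name]
        truth[name] = float(mean + sd * rng.standard_normal())
    # Keep draws inside the region the trace morphology can express: the
    # hyperemic dip must stay positive and, for dysfunction subjects
    # (IRmax < 0), deeper than the baseline decline so the post-release
    # trough remains the excursion minimum.  Clips affect ~0.1% of draws
    # under the group presets and are recorded in the ground truth.
    truth["IRmax"] = max(truth["IRmax"], -8.0)
    truth["HRmax"] = max(truth["HRmax"], 2.0)
    if truth["IRmax"] < 0:
        truth["HRmax"] = max(truth["HRmax"], -truth["IRmax"] + 2.0)
    truth["FM"] = truth["ENDO"] + truth["NEURO"] + truth["MYO"]
    truth["NOI"] = 100.0 * (truth["ENDO"] + truth["NEURO"]) / truth["FM"]
    truth["RHR"] = truth["IRmax"] + truth["HRmax"]
    truth["FM_R"] = (REPERFUSION_CARRYOVER
                     * (truth["ENDO"] + truth["NEURO"]) + truth["HS"])

    p = spec.protocol
    fs = spec.sampling_rate
    base_window = p.baseline_duration
    rep_window = p.post_release_duration - p.hyperemic_window
    rep_start = (p.baseline_duration + p.occlusion_duration
                 + p.hyperemic_window)
    band_spec = {
        band: _grid_tones(rng, band, spec.bands, 0.0, base_window, fs,
                          truth[name])
        for band, name in (("endo", "ENDO"), ("neuro", "NEURO"),
                           ("myo", "MYO"))
    }
    rep_spec = {
        "endo": _grid_tones(rng, "endo", spec.bands, rep_start, rep_window,
                            fs, REPERFUSION_CARRYOVER * truth["ENDO"]),
        "neuro": _grid_tones(rng, "neuro", spec.bands, rep_start, rep_window,
                             fs, REPERFUSION_CARRYOVER * truth["NEURO"]),
        "myo": _grid_tones(rng, "myo", spec.bands, rep_start, rep_window,
                           fs, truth["HS"]),
    }
    config = TraceSimConfig(
        baseline_level=spec.baseline_level,
        band_spec=band_spec,
        reperfusion_band_spec=rep_spec,
        ischemic_rise_fraction=truth["IRmax"] / 100.0,
        hyperemic_dip_fraction=truth["HRmax"] / 100.0,
        noise_sd=spec.noise_sd,
        protocol=p,
        sampling_rate=spec.sampling_rate,
        bands=spec.bands,
        seed=[spec.seed, index, 1],
    )
    return config, truth


def _draw_demographics(spec: GroupSimSpec, rng: np.random.Generator
                       ) -> dict[str, float | int]:
    row: dict[str, float | int] = {}
    for name in ("age", "bmi", "sbp", "dbp"):
        mean, sd = spec.demographics.get(name, (math.nan, 0.0))
        val = mean + sd * rng.standard_normal() if not math.isnan(mean) else mean
        if name == "age" and not math.isnan(val):
            val = max(18.0, val)
        row[name] = round(float(val), 1) if not math.isnan(val) else math.nan
    for flag, rate in spec.flag_rates.items():
        row[flag] = int(rng.uniform() < rate)
    return row


def simulate_cohort(specs: Sequence[GroupSimSpec], master_seed: int
                    ) -> tuple[dict[str, FMSFTrace], pd.DataFrame,
                               dict[str, dict[str, float]]]:
    """Simulate a whole multi-group cohort.

    Per-subject randomness derives deterministically from ``master_seed``
    together with the group index and subject index, so a fixed master seed
    reproduces the cohort exactly.  Returns traces keyed by subject id, a
    metadata table in the cohort CSV layout, and a ground-truth table.
    """
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate group labels")
    traces: dict[str, FMSFTrace] = {}
    truth: dict[str, dict[str, float]] = {}
    rows = []
    for gi, spec in enumerate(specs):
        seeded = replace(spec, seed=int(np.random.default_rng(
            [master_seed, gi]).integers(0, 2 ** 31)))
        for si in range(spec.n):
            subject_id = f"{spec.label}-{si + 1:02d}"
            config, subject_truth = simulate_subject(seeded, si)
            traces[subject_id] = simulate_trace(config)
            truth[subject_id] = subject_truth
            demo_rng = np.random.default_rng([master_seed, gi, si, 2])
            row = {"subject_id": subject_id, "group": spec.label, "sex": "F"}
            row.update(_draw_demographics(spec, demo_rng))
            rows.append(row)
    metadata = pd.DataFrame(rows)
    return traces, metadata, truth


# --------------------------------------------------------------------------
# Study-condition presets

#: Group-level summaries emulated by default: per-parameter mean ± SD for the
#: three groups of the alopecia case--control design (female; AA n=18,
#: AU n=6, controls n=17).  FM/NEURO/NOI/HS/IRmax/HRmax are the observed
#: group summaries; ENDO and MYO targets are derived from FM, NEURO and NOI
#: (ENDO + NEURO = NOI/100 * FM, MYO = FM - ENDO - NEURO), with SDs scaled by
#: the group's FM coefficient of variation.
GROUP_PRESETS: dict[str, dict] = {
    "AA": {
        "n": 18,
        "FM": (55.2, 47.3), "NEURO": (13.2, 11.7), "NOI": 55.5,
        "HS": (62.3, 59.4), "IRmax": (11.6, 6.1), "HRmax": (16.3, 4.1),
        "RHR": (27.8, 7.7),
        "demographics": {"age": (47.0, 16.9), "bmi": (25.6, 4.7),
                         "sbp": (124.8, 16.2), "dbp": (81.5, 8.9)},
        "flag_rates": {"smoking": 0.111, "depression": 0.167,
                       "hashimoto": 0.278, "hypertension": 0.167,
                       "hypercholesterolemia": 0.0, "diabetes": 0.0},
    },
    "AU": {
        "n": 6,
        "FM": (27.1, 25.9), "NEURO": (6.3, 6.4), "NOI": 53.3,
        "HS": (67.6, 74.8), "IRmax": (15.3, 7.8), "HRmax": (15.8, 2.8),
        "RHR": (31.0, 8.9),
        "demographics": {"age": (50.7, 23.4), "bmi": (25.3, 3.9),
                         "sbp": (129.7, 19.4), "dbp": (77.5, 11.6)},
        "flag_rates": {"smoking": 0.333, "depression": 0.333,
                       "hashimoto": 0.333, "hypertension": 0.333,
                       "hypercholesterolemia": 0.167, "diabetes": 0.167},
    },
    "control": {
        "n": 17,
        "FM": (125.2, 101.8), "NEURO": (47.3, 45.0), "NOI": 74.4,
        "HS": (84.3, 78.0), "IRmax": (13.8, 5.6), "HRmax": (20.4, 5.1),
        "RHR": (33.1, 7.9),
        "demographics": {"age": (44.6, 12.0), "bmi": (23.9, 3.2),
                         "sbp": (117.9, 11.6), "dbp": (76.5, 7.4)},
        "flag_rates": {"smoking": 0.059, "depression": 0.0, "hashimoto": 0.0,
                       "hypertension": 0.0, "hypercholesterolemia": 0.0,
                       "diabetes": 0.0},
    },
}


#: Reference pooled-case column (AA + AU combined, n = 24) of the same
#: group-level summary: mean ± SD per parameter.
POOLED_REFERENCE: dict[str, tuple[float, float]] = {
    "FM": (48.2, 44.2), "NEURO": (11.4, 10.9), "NOI": (54.6, 22.9),
    "RHR": (28.6, 7.9), "IRmax": (12.5, 6.6), "HRmax": (16.1, 3.7),
    "HS": (63.6, 61.9),
}


def group_presets(noise_sd: float = 5.0, seed: int = 0,
                  n_override: Mapping[str, int] | None = None
                  ) -> list[GroupSimSpec]:
    """Build the three study-condition :class:`GroupSimSpec` presets."""
    specs = []
    for label, p in GROUP_PRESETS.items():
        fm_mean, fm_sd = p["FM"]
        neuro_mean, neuro_sd = p["NEURO"]
        cv = fm_sd / fm_mean
        en_sum = p["NOI"] / 100.0 * fm_mean
        endo_mean = en_sum - neuro_mean
        myo_mean = fm_mean - en_sum
        if min(endo_mean, myo_mean) <= 0:
            raise ValueError(f"inconsistent preset for group {label}")
        specs.append(GroupSimSpec(
            label=label,
            n=(n_override or {}).get(label, p["n"]),
            lognormal_targets={
                "ENDO": (endo_mean, cv * endo_mean),
                "NEURO": (neuro_mean, neuro_sd),
                "MYO": (myo_mean, cv * myo_mean),
                "HS": p["HS"],
            },
            normal_targets={"IRmax": p["IRmax"], "HRmax": p["HRmax"]},
            demographics=p["demographics"],
            flag_rates=p["flag_rates"],
            noise_sd=noise_sd,
            seed=seed,
        ))
    return specs
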