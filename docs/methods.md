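# Methods

## The measurement and its model

Flow-Mediated Skin Fluorescence (FMSF) records skin NADH autofluorescence
(arbitrary units, 25 Hz) on the forearm during a brachial occlusion–release
protocol: 3 min resting baseline, 3 min arterial occlusion at 60 mmHg above
systolic pressure, and 3 min after cuff release. NADH fluorescence rises
during ischemia (mitochondria cannot reoxidise NADH), drops below the
resting value during post-occlusive reactive hyperemia, and recovers during
reperfusion. Low-frequency "flowmotion" oscillations ride on the baseline
and reperfusion phases; their power below 0.15 Hz is attributed to
endothelial (< 0.021 Hz), neurogenic (0.021–0.052 Hz) and myogenic
(0.052–0.15 Hz) regulation of microvascular tone.

The pipeline computes, per measurement:

- **FM** = mean-square of the detrended baseline signal (a.u.²), with band
  components **ENDO**, **NEURO**, **MYO**;
- **NOI** = 100·(ENDO+NEURO)/(ENDO+NEURO+MYO), percent;
- **IRmax** = 100·(max occlusion fluorescence − resting level)/resting
  level; negative values flag mitochondrial dysfunction;
- **HRmax** = 100·(resting level − min post-release fluorescence)/resting
  level, floored at 0;
- **RHR** = IRmax + HRmax;
- **FM(R)** and **HS**: mean-square flowmotion of the reperfusion window
  and its myogenic band component (absolute a.u.², not a percentage).

Group statistics follow a normality-gated design: Shapiro–Wilk on each
group at α = 0.05, Welch's t-test when both groups pass, Mann–Whitney U
otherwise; Pearson vs Spearman correlation by the same gate. Right-skewed
magnitudes (FM, NEURO, HS) are gated and tested on the log10 scale, where
they are approximately normal. No multiple-testing correction is applied
(seven parameters, unadjusted p-values, noted in every report).

## Numerical choices

**Resting level.** Arithmetic mean of the baseline window. Whole-period
oscillations average to zero and a linear drift contributes its midpoint,
so the estimate is unbiased under the signal model.

**Detrending.** Least-squares linear trend removal per analysis window,
followed by exact mean removal. Linear detrending annihilates ramps, is
idempotent, and removes drift slower than the window fundamental that a
rectangular-window periodogram would otherwise smear into the endothelial
band.

**Spectral estimator.** A single rectangular-window FFT periodogram of the
whole window, in mean-square units, so Parseval's identity is exact: the
band components plus out-of-band power equal the residual's mean square to
floating-point precision. No tapering or segment averaging — those would
trade the exact power bookkeeping for variance reduction the downstream
scalar parameters do not need.

**Band assignment.** A bin with center frequency f belongs to the band
with lower < f ≤ upper; the three bands partition (0.005, 0.15] Hz. The
0.005 Hz low cut excludes DC and drift: a 180 s window resolves ≈ 0.0056 Hz
as its fundamental, so slower content is indistinguishable from trend.

**Minimum analysis window.** Windows shorter than two cycles at the
endothelial upper edge (2/0.021 ≈ 95 s) are rejected. This admits the
canonical 180 s baseline and 150 s reperfusion windows while refusing
windows that cannot attribute slow oscillations to a band. (Two cycles at
the 0.005 Hz low cut itself would demand 400 s and reject the canonical
protocol's own analysis windows; the low cut is a bin-assignment boundary,
not a resolvable-content claim.)

**Windows.** The hyperemic transient window defaults to 30 s after cuff
release (reported transient duration is 20–30 s; configurable). FM(R) and
HS are computed on the reperfusion window *after* the hyperemic transient
(150 s under the canonical protocol), so the rapid undershoot itself does
not enter reperfusion flowmotion; the slower recovery tail does (see
limitations).

**RHR definition.** The instrument literature does not print a formula.
RHR = IRmax + HRmax (total ischemia-to-hyperemia excursion) is adopted
because the pooled-case reference column satisfies 12.5 + 16.1 = 28.6
exactly and the per-group columns agree within rounding. A time-integral
definition cannot be excluded; the peak-sum is recorded explicitly in
every comparison output.

**HS scale.** Absolute myogenic mean-square of the reperfusion window
(a.u.²) rather than a 0–100 proportion of FM(R): reference HS values of
62–84 with SDs up to 78 are incompatible with a bounded percentage. Both
FM(R) and HS are reported, so the proportion is recoverable.

**Missing values.** log10 of a non-positive value and NOI with all-zero
bands yield NaN with a logged warning; subjects are only removed by the
explicit exclusion filter (IRmax < 0, optional sex restriction and
comorbidity flags), and every exclusion is logged with its reason.

**Degenerate comparisons.** Two zero-variance groups with equal means give
p = 1 by convention with a warning; single-subject groups report SD as
missing (sample SD is undefined), and empty group columns are omitted.

**Mann–Whitney p-values.** Exact enumeration for tie-free samples with
n ≤ 8 per side, tie- and continuity-corrected normal approximation
otherwise (scipy), reproducible across implementations at these group
sizes.

## The synthetic-data generator

No FMSF recordings from the case–control study are public, so the
generator produces protocol-shaped traces with known ground truth. Its
defaults encode the emulated study conditions: three female groups —
patchy alopecia areata (AA, n = 18), alopecia universalis (AU, n = 6),
healthy controls (n = 17) — with the group mean ± SD levels in
`fmsf.simulate.GROUP_PRESETS` and demographic/comorbidity rates drawn from
the same study description. ENDO and MYO targets (not reported directly)
are derived from FM, NEURO and NOI via ENDO + NEURO = NOI/100 · FM and
MYO = FM − ENDO − NEURO, with SDs scaled by the group's FM coefficient of
variation. The resting fluorescence level defaults to 1000 a.u., placing
oscillation amplitudes at a realistic 1–2% of the signal.

Per subject, band powers (ENDO, NEURO, MYO, HS) are drawn from
moment-matched log-normals (positive, right-skewed, log-normal — consistent
with log-transformed parameters being normal) and excursions (IRmax,
HRmax, percent) from normals; IRmax may go negative, producing the
dysfunction phenotype the exclusion filter targets. Draws are clipped to
the region the trace morphology can express (IRmax ≥ −8 pp, HRmax ≥ 2 pp
and, for dysfunction subjects, HRmax ≥ |IRmax| + 2 pp; ≈ 0.1% of draws
under the presets).

Trace construction:

- **Baseline:** resting level + 1–3 discrete tones per band + white noise
  (default SD 5 a.u. ≈ 0.5% of the level). Tone frequencies sit on the DFT
  grid of the analysis window, and each tone's phase is chosen (up to a
  random sign) orthogonal to the window's linear-trend subspace, so
  detrending and band integration recover the injected powers *exactly*.
  Frequencies drawn off-grid would leak across band edges (a k = 1
  endothelial tone loses ~60% of its power to the detrend alone), which
  would destroy the ground-truth contract the generator exists for.
- **Occlusion:** tones stop at inflation (flowmotion ceases under arrested
  flow); a saturating-exponential rise toward level·(1 + IRmax/100), time
  constant 20 s. A dysfunction subject (IRmax < 0) instead shows a linear
  baseline decline calibrated so the occlusion maximum sits exactly
  IRmax · level/100 below the baseline-window mean; the drift is linear, so
  detrending removes it and baseline flowmotion is unaffected.
- **Hyperemic window:** exponential descent (time constant 10 s)
  calibrated to reach resting·(1 − HRmax/100) exactly at the window's last
  sample, which is therefore the trace minimum.
- **Reperfusion:** exponential recovery toward the resting level (time
  constant 40 s) carrying reperfusion tones ramped in on the same time
  constant (amplitude-compensated so detrended tone power matches its
  nominal value); the ramp keeps the hyperemic trough the global minimum.

Per-subject randomness derives deterministically from a master seed plus
group and subject indices: identical configuration ⇒ bit-identical traces.

### What the generator does and does not emulate

It reproduces the morphology and the parameter distributions the pipeline
measures, which is exactly what makes recovery testable. It does **not**
contain cardiac or respiratory bands (> 0.15 Hz), correlated (pink) noise,
motion artifacts, continuous band spectra (band content is a small set of
discrete tones), or physiological couplings between parameters beyond the
NOI/FM identities. Passing recovery tests therefore demonstrates the
correctness of the analysis chain on signals satisfying the stated model,
not robustness to every artifact of real recordings.

Known simulator/pipeline interaction: the reperfusion recovery tail has
genuine low-frequency power, so FM(R) includes the transient (by the
window design decision above) and extracted HS carries a small additive
contribution from the transient's myogenic tail (≈ 3.6 a.u.² at the
default 16% dip on a 1000 a.u. level, scaling with (dip·level)²); ground
truth records injected tone power only. Extracted occlusion/post-release
maxima also acquire a positive extreme-value bias under measurement noise
(≈ 3.5 noise SDs over ~4500 samples), common to all subjects and therefore
invisible to rank-based recovery checks.

## Problem sizes used in verification

Closed-form and oracle checks use 600 s single-tone windows at 5 Hz
(every grid frequency completes whole periods, making the decomposition
leakage-free) with a brute-force direct-sum DFT as the independent oracle.
Recovery checks use 20 noiseless subjects per group and a 50-subject
cohort at 2% noise; the gate-then-test procedure is calibrated under the
null with 2000 replicates at the study's group sizes (24 vs 17) and its
power measured with 100 replicates at a 1.5-pooled-SD shift. These sizes
put Monte-Carlo error well below the tolerances being asserted.

## Known limitations

- The device's proprietary preprocessing is undocumented; tapering or
  averaged periodograms before band integration would change absolute band
  powers. The single-FFT choice is an assumption, made for its exact
  Parseval bookkeeping.
- Whether the device's RHR is a peak sum or an area measure is unresolved;
  the peak sum reproduces the reference table's internal arithmetic.
- Sample-SD checks of heavy-tailed log-normal targets need thousands of
  draws to stabilise; at cohort sizes (6–18) simulated group SDs scatter
  widely around their targets, as real ones would.
- The normality gate makes the test choice data-dependent; its measured
  type-I error at the study's group sizes is ≈ 0.049, close to nominal,
  but inference after gating is approximate by construction.
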