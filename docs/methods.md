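# Methods

This note documents the models, estimators, and numerical choices behind
`qeegnorm`, and what the synthetic test bench does and does not establish
about real recordings.

## Signal model and preprocessing

Input is the 19-channel 10–20 scalp EEG in µV (512 Hz in the reference
acquisition; any rate above 60 Hz is accepted). Artifact selection is out of
scope: the pipeline trusts its input segments, mirroring clinical practice
where artifact-free epochs are chosen visually. Concatenated records shorter
than 120 s trigger a warning, since all spectral estimates inherit the
variance of the record length.

Filtering is an overall order-6 Butterworth band-pass, 0.5–30 Hz by default,
applied forward–backward (zero phase) so that the latency and shape of the
posterior dominant rhythm are not distorted. An order-6 *band-pass* places
three poles at each edge; the single-pass response at 50 Hz is ≈0.19, and
the zero-phase application squares it to ≈0.04, comfortably inside the
stop-band. Downsampling to 128 Hz is plain decimation: the 30 Hz cut-off is
itself the anti-alias guard. After filtering, 2 s are trimmed from each end
(capped at 10% of the record per side): the high-pass settle-in otherwise
converts a fraction (~10⁻³) of any strong rhythm into a low-frequency edge
transient, which is negligible for broadband content but material next to
small delta-band areas when the posterior alpha oscillation is large.

The double-banana montage is the fixed 18-channel list of adjacent-electrode
differences. It is linear and invariant under re-referencing; the midline
channels Fz–Cz and Cz–Pz are derived but excluded from all lobe and
hemisphere groupings, which never reference them.

## Spectral estimation

Records are cut into 1-s moving windows with 10% overlap. The window count
is `floor((T − 1)/0.9) + 1`, evaluated in seconds with a small guard against
floating-point representation of 0.9 (at 128 Hz an integer-sample step of
115 samples would yield one extra window at 180 s); window starts are
`round(i·0.9·fs)` samples.

Each window is Hann-tapered (rectangular available via configuration),
zero-padded to twice its length so the frequency grid has 0.5 Hz spacing,
and transformed to a one-sided PSD `|FFT|²/(fs·Σw²)` in µV²/Hz. Every
window's spectrum is then renormalized so that its integral equals that
window's raw mean-square voltage. This makes Parseval's identity hold
exactly per window for any taper — band areas are honestly interpretable as
signal power, and the four bands partition the 0.5–30 Hz area exactly (a bin
on a shared edge belongs to the lower band). Without the renormalization an
amplitude-corrected Hann window overstates broadband power by 3/2. The
delta band starts at 0.5 Hz, matching the high-pass edge.

Band areas are computed per window and averaged over windows *before* the
log transform; logPS is base-10, consistent with the magnitude range of the
published normative tables. Spectral entropy normalizes each window's
spectrum over the 60 in-band bins to a probability distribution and averages
per-window entropies (entropy of the window-mean spectrum is available and
is never smaller, by concavity). Its ceiling is log₂ 60 ≈ 5.907 bits.

Coherence uses the same tapered, padded window FFTs, averaging the
cross-spectrum over windows before taking the magnitude; by Cauchy–Schwarz
the estimate lies in [0, 1], equals 1 for identical channels, and has an
O(1/n) positive bias for independent signals with n windows (≈0.005 at
180 s). Band coherence is the unweighted mean over a band's bins. Grouped
values average all channel pairs of a lobe (3) or hemisphere; the hemisphere
slot list keeps the published duplicate of the posterior temporal-occipital
channel (9 slots, 36 formula pairs, the duplicate's self-pair dropped), with
a deduplicated variant available.

The PDR frequency is the argmax of the window-averaged spectrum of P3–O1 /
P4–O2 inside 8–13 Hz on the 0.5 Hz grid, exact ties breaking toward the
lower frequency; amplitude is the RMS of the full band-limited channel
voltage (an alpha-band-restricted variant is a configuration flag).

## Normative layer

Age groups partition as [0, 20), [20, 50], (50, ∞); the closed upper bound
at 50 follows the group sizes attached to that notation in the source
tables. Band-structure orderings sort group means descending and report
exact ties jointly. The published group tables order rows by the
left-hemisphere means; two right-hemisphere cells (older-group
parieto-occipital, young-group temporal) order differently, and the numeric
cells are treated as ground truth.

The shipped equation bundle contains the PDR cubic, the two amplitude
offset-exponentials, and six SSE cubics, as printed. The amplitude
exponentials are implemented in the decaying form `a + b·e^(−k·years)`:
a growing exponential would contradict the accompanying figure, the text's
description ("negative exponential"), and physiology. The band-power
(logPS) regressions are not shipped; `fit_normative` regenerates analogous
polynomial equations from any cohort, reporting the fit correlation
`r = corr(y, ŷ)`, its one-tailed significance via `t = r√(n−2)/√(1−r²)`
with n−2 degrees of freedom, residual SD, and coefficient confidence
intervals (ordinary least squares on a Vandermonde design).

Paired symmetric-lobe comparisons use a Lilliefors-corrected
Kolmogorov–Smirnov gate at α = 0.05 (mean and SD are estimated from the
sample, so the uncorrected KS critical values would be conservative),
selecting a paired t-test under normality and a Wilcoxon signed-rank test
otherwise; two-sided, no multiple-testing correction by default (a Holm
option exists). Test–retest reliability is the per-feature Pearson r across
matched subjects.

## Synthetic rsEEG generator

The generator emulates eyes-closed rsEEG at the level the pipeline measures:
per-lobe band powers (defaults: 10^logPS of the published per-age-group
means), a posterior alpha oscillator (frequency from the normative cubic,
RMS amplitude from the normative exponential, injected as an O1/O2-localized
scalp source so it appears on both P3–O1 and T5–O1 as a physical occipital
generator would), controllable within-lobe coherence, and a common-mode
signal that cancels in every bipolar derivation.

Two structural facts shape the design. First, both chains of a hemisphere
run from the prefrontal to the occipital electrode, so only 7 of the 8
lateral bipolar signals are free. Shared lobe sources are therefore injected
at the *electrode* level — automatically loop-consistent — with gains solved
per region by weighted least squares: the three lobe channels are pinned to
equal ±A, and the unavoidable boundary-electrode spill lands on neighboring
channels in proportion to their power headroom (a small, deterministic,
volume-conduction-like effect). Channel-private band noise is loop-projected
with the residual spread in proportion to private power, so a fully shared
lobe receives none of it. Second, the spectral estimator itself moves power
between bands (own-band retention ≈0.7–0.9, filter-skirt spill into
neighbors up to ≈10%); the generator measures this band-transfer matrix per
source, solves shared amplitudes and private powers against the *expected
measured* areas, and closes the remaining gap with two additive calibration
stages (raw periodogram, then the real pipeline). Without this, a small band
beside a dominant one — theta next to a strong posterior alpha — would be
unreachable, and coherent bands would be diluted by private top-ups.

`shared_fraction` c is the shared-variance fraction of a lobe channel's band
signal; the magnitude-squared coherence between two such channels is ≈c², so
published coherence values map to c = √coh as defaults. At c = 1 a lobe's
channels become multiples of one source and their coherence approaches 1;
realized band coherence is monotone in c with a floor of a few hundredths
from the deterministic spill.

Ground truth records the post-calibration per-channel band powers, with the
oscillator's full windowed-estimator footprint (a spectral line leaks a
small amount into neighboring bands through 1-s windows) added to the
posterior channels. Pipeline recovery of these targets is within 10%
relative error per channel × band at 180 s; the residual is dominated by the
stochastic cross-term between the oscillator and the background over a
finite record. The published PDR amplitudes and logPS band areas are not
jointly consistent under Parseval for a single record (an amplitude of
~40 µV RMS implies far more alpha area than the printed logPS); the
generator keeps them as independent knobs and documents that posterior alpha
areas exceed the table-derived background accordingly.

Cohorts draw ages uniformly from 10–74 years. Subjects receive persistent
traits: per-lobe × band log₁₀ power offsets (SD 0.3, the between-subject SD
implied by the published SEMs at the group sizes), PDR frequency scatter of
0.5 Hz around the cubic, 20% relative amplitude scatter, shared-fraction
jitter (SD 0.05), and a within-band spectral-tilt trait λ (SD 0.15) that
mixes each band's lower and upper halves. Twin sessions share traits and add
state noise: per-band log-power jitter (SD 0.0375, chosen so logPS
test–retest reliability lands near the published 0.98) and fresh tilt jitter
(SD 0.15, which moves spectral entropy without moving band areas and
reproduces the published pattern of SSE being less reliable than logPS).
Coherence reliability is lowest because its estimation variance at these
record lengths dominates its between-subject variance — the published
ranking logPS > PDR > SSE > coherence emerges rather than being asserted.

What passing tests on this generator shows: the pipeline's estimators are
correct, calibrated, and invertible at the feature level under realistic
spectral structure, coherence structure, and record lengths. What it does
not show: robustness to artifacts (no blinks or EMG are simulated), 1/f
aperiodic dynamics beyond band-level targets, or non-stationarity beyond
session-level state noise.

## Problem sizes and determinism

All randomness flows from explicit integer seeds (NumPy `SeedSequence`;
per-subject, per-session streams are derived from the master seed), and the
same seed reproduces recordings bit for bit. The test suite synthesizes
full recordings at 60–180 s and cohorts of 5–10 subjects for pipeline-level
checks, and uses the 200-subject feature-level cohort for regression
parameter recovery; these sizes give sampling error comfortably inside each
test's tolerance while keeping the suite quick. The acceptance script
evaluates the shipped PDR cubic on a 0.01-year grid over ages 10–74.

## Known limitations

- The generator controls band power and band coherence, not waveform
  morphology; transients (spindles, vertex waves, artifacts) are absent.
- Midline channels carry private noise only and are excluded from
  groupings, so nothing validates midline-specific physiology.
- Coherence defaults reproduce the published *ordering and scale* of
  regional synchronization, but estimator leakage makes the realized values
  run slightly above the targets in bands adjacent to strong rhythms.
- EDF support is 16-bit with one-second records and an integer sampling
  rate; EDF+ annotations are ignored on read.
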