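# Methods

`speechlfp` analyses onset-locked spectral dynamics of local field
potentials (LFP) recorded from DBS lead contacts in the motor thalamus
while participants perform speech tasks of graded motor complexity —
sustained vowel, DDK (/tɑtɑtɑ/ repetition), and sentence repetition. The
package couples the analysis pipeline to a synthetic-cohort generator that
reproduces the statistical structure the analysis assumes, so every stage
can be tested against known ground truth without patient recordings.

## Synthetic cohorts

Each participant-hemisphere session is a continuous multi-contact
recording: independent pink-noise backgrounds per contact
(PSD ∝ 1/f^α, default α = 1, synthesized spectrally and scaled to unit
variance) with interleaved trials of the three tasks. Trial durations are
Gaussian per task (means 0.96 / 1.27 / 1.60 s for vowel / DDK / sentence,
SD 0.15 s); inter-trial intervals are truncated-normal (mean 1.5 s,
SD 0.6 s, bounds 0.8–3.1 s); default 30–50 trials per task
(`trials_per_task`, default 40).

Injected effects emulate the task-graded oscillatory findings: a
delta/theta (1–8 Hz) power increase during speech (0…+1000 ms; defaults
+1 / +2.5 / +3 dB for vowel / DDK / sentence) and a prespeech
(−500…0 ms) beta (13–30 Hz) decrease (−0.5 / −1 / −2 dB). Magnitudes are
free parameters: only their ordering is anchored to the phenomenon being
emulated. A participant-level offset ~ N(0, 0.5 dB) is added to all
non-zero effects so the mixed model's random intercept has variance to
estimate.

Mechanism: each effect is a windowed gain on the band-limited component of
the signal, x → x + (g − 1)·env(t)·bandpass(x) with g = 10^(dB/20). The
raised-cosine ramps (50 ms) sit just outside the window, so the target
gain holds across the whole window; the gain is applied to every contact,
so the dB effect is invariant under linear channel operations (segment
averaging, common-average rereferencing). A purely additive oscillation
was rejected because it cannot realize negative dB (desynchronization);
the gain construction is exact for both signs and is verified against a
bandpass-variance oracle (6 dB ⇒ 4× band variance).

What the simulator does *not* emulate: tremor or movement artifacts, line
noise (by default), volume conduction between contacts, task-correlated
acoustic contamination, and non-stationary background spectra. Passing
tests therefore demonstrate correctness of the *pipeline* under the
model's assumptions, not robustness to every property of operating-room
recordings.

## Preprocessing

Fixed stage order: polyphase resampling to 500 Hz → optional zero-phase
IIR notch at the line frequency and harmonics → averaging of segmented
contacts (2A/2B/2C → 2, 3A/3B/3C → 3) → common-average reference over the
four contacts of a hemisphere → zero-phase 4th-order Butterworth bandpass
1–50 Hz → epoching from −2000 to +1000 ms around each speech onset
(inclusive endpoints, 2 ms step, 1501 samples; t = 0 is the sample nearest
the onset). All filtering is forward–backward so perievent latencies are
unbiased. Epochs whose window leaves the recording are dropped and counted
in a rejection report. Overlapping epochs are extracted independently:
with 3 s epochs and inter-trial intervals as short as 0.8 s, overlap is a
property of realistic designs, and the resulting non-independence of
trials is accepted rather than hidden.

The notch bank stands in for dedicated transient-noise removal: the
contract downstream stages rely on is line-power attenuation (≥ 20 dB at
the targeted harmonic, < 0.5 dB elsewhere in 1–50 Hz), which it meets.
Synthetic data carry no line noise, so the stage is near-identity in most
tests.

## Time-frequency decomposition

Complex Morlet wavelets on a log-spaced frequency axis over 1–50 Hz
(default 50 bins; heavy simulation runs use 16). Cycle counts grow
linearly in log-frequency from 3 at 1 Hz to 10 at 50 Hz. Kernels are
truncated at ±4 Gaussian SDs and normalized to unit energy; per-frequency
gain conventions are immaterial because dB normalization cancels them
(verified against MNE's independent Morlet implementation, which differs
from ours by a constant per-frequency gain only).

Per-trial power is computed by FFT-domain multiplication with adequate
zero padding and agrees with direct time-domain convolution to ≤ 1e-6
relative error (measured ~3e-15). Normalization per trial, contact and
frequency: dB(t) = 10·log10(power(t) / baseline), baseline = mean linear
power over the whole −2000…+1000 ms epoch. Consequences: the mean of
10^(dB/10) over the epoch is exactly 1; dB maps are invariant to global
amplitude scaling; and an injected effect occupying part of the epoch
inflates its own baseline, so measured dB effects are attenuated relative
to injected ones (≈ 1.2 dB for a +3 dB effect occupying one third of the
epoch). The per-trial baseline scope follows from normalizing "each
trial"; an across-trial baseline is available as an option.

Averaging dB across trials is negatively biased for noisy power (Jensen:
for exponentially distributed single-trial power the trial-mean dB sits
≈ −2.5 dB below zero even though the linear mean reconstructs to 1). The
bias is identical at baseline times and across tasks, so surrogate tests
and task contrasts cancel it; absolute values of trial-averaged dB maps
should not be read as percent power change.

Edge handling: wavelet convolution sees zero padding beyond the epoch.
Pixels within 2 Gaussian SDs of an epoch edge are flagged (`edge_mask`);
beyond 2 SDs less than 0.25 % of kernel energy falls outside the data
(< 0.02 dB bias), inside it the negative bias grows to several dB at 1 Hz.
Flagged pixels are carried in all tensors and maps and are excluded from
significance evaluation; band-power summaries use the dB maps directly and
are not masked.

## Surrogate statistics

Null per contact and frequency: repeat 2,241 times — draw one time sample
per trial uniformly from the baseline period (−1000, −500] ms of the
dB-normalized power and average across trials. Observed maps (trial
averages; grand averages across participants for group tests, with the
null pooled by averaging participant-level draws shuffle-by-shuffle) are
compared two-tailed with the add-one convention
p = 2·min((1+#{surr≥obs})/(n+1), (1+#{surr≤obs})/(n+1)); the smallest
attainable p at n = 2,241 is 2/2,242 ≈ 8.9e-4, just below the α = 0.001
threshold, and counts below 2,000 shuffles trigger a resolution warning.
No multiple-comparison correction is applied; evaluation is restricted to
−500…+1000 ms and to non-edge pixels. Between-condition contrasts
subtract unthresholded participant maps first and difference independent
baseline draws per participant for the null.

Known limitation — low-frequency anticonservativeness. The baseline
window is 0.5 s, while a 3-cycle wavelet at 1 Hz has σ_t ≈ 0.48 s, so the
baseline contributes roughly one independent sample per trial there. Two
consequences follow: the surrogate spread (within-trial resampling
variance) collapses toward zero, and the null is centered on the realized
baseline mean, so whole frequency rows can reject together with one sign.
On effect-free cohorts (5 participants, 30 trials/task) the empirical
pixel-wise rejection rate at α = 0.001 measures ≈ 0.17–0.20 per row at
1–2 Hz and ≈ 0.002–0.006 above 20 Hz (≈ 0.055 pooled over 1–50 Hz). This
is a property of the baseline-bootstrap design itself — no surrogate
drawn only from a 0.5 s baseline can reproduce the sampling variability of
a 1 Hz, 3-cycle statistic — and low-frequency significance from this test
family should be read accordingly. The acceptance suite records this
honestly as a failed calibration bound.

## Band power and mixed-effects model

Band-power summaries average dB pixels with frequency in delta/theta
(1–8 Hz) or beta (13–30 Hz), inclusive, and time in prespeech [−500, 0)
or during-speech [0, 1000] ms (t = 0 assigned to during-speech), one row
per participant × hemisphere × contact × task: 104 rows per task per
band × window cell at the full 13-participant design.

Per band × window, the model is
mean_power ~ task · laterality · contact + (1 | participant), fitted by
REML (statsmodels MixedLM). Type-3 F tests use sum-to-zero factor coding
(required for meaningful Type-3 hypotheses) and Satterthwaite denominator
degrees of freedom computed here: for a contrast a,
df = 2(a'Ca)²/Var(a'Ca) with C = (X'V⁻¹X)⁻¹; the variance term combines
the finite-difference gradient of a'Ca with respect to the two variance
components with the asymptotic covariance of their REML estimates (twice
the inverse Hessian of the restricted deviance, also by finite
differences); multi-row terms aggregate per-eigenvector dfs. On a
balanced 13-participant design the task effect carries df = 276, and the
implementation matches R's lmerTest (F, df, variance components) to
≈ 0.1 % on identical tables. Follow-ups are pairwise task contrasts on
marginal means with Bonferroni correction (family of 3). Fits with a
vanishing participant variance are flagged singular and report that
component as 0; a noiseless table short-circuits REML entirely.

## Problem sizes and numerical choices

Simulation-heavy checks (null calibration, effect recovery) run 5
participants × 2 hemispheres, 30 trials/task, synthesized directly at
500 Hz with 16 wavelet frequencies — large enough for stable group
statistics while keeping a full 20-cohort sweep to minutes. The
13-participant design is exercised at the band-power level, where the
row-count and degrees-of-freedom properties live. Determinism: every
stochastic component accepts a seed; cohort and pipeline seeds derive from
a single root via SeedSequence spawning, so identical configs reproduce
identical artifacts byte-for-byte.
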