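# speechlfp

Onset-locked spectral analysis of local field potentials (LFP) recorded
from deep-brain-stimulation (DBS) lead contacts during speech tasks of
graded motor complexity — sustained vowel, diadochokinesis (DDK,
/tɑtɑtɑ/), and sentence repetition. The package is aimed at
intracranial-electrophysiology researchers who want a tested, reusable
implementation of this analysis family: event-related spectral
perturbation (ERSP) with baseline-shuffle surrogate statistics and
mixed-effects band-power modelling, plus a synthetic-cohort simulator so
every stage can be validated against ground truth without patient data.

## What it computes

Given continuous multi-contact recordings and per-trial annotations
(task, onset, offset), the pipeline:

1. **Preprocesses**: resample to 500 Hz → optional line-noise notch →
   average segmented contacts (2A/2B/2C → 2, 3A/3B/3C → 3) →
   common-average reference per hemisphere → zero-phase 1–50 Hz bandpass
   → epoch from −2000 to +1000 ms around each speech onset.
2. **Decomposes** each trial with complex Morlet wavelets, log-spaced over
   1–50 Hz with 3→10 cycles, via FFT-domain convolution, and normalizes
   per trial, contact and frequency:
   `Power(dB) = 10·log10(power_t / power_baseline)`, with the baseline the
   whole-epoch mean power.
3. **Tests** pixels against a surrogate null built by drawing one baseline
   time sample ((−1000, −500] ms) per trial and averaging across trials,
   2,241 shuffles, two-tailed p < 0.001, uncorrected; between-condition
   contrasts subtract unthresholded participant maps first.
4. **Models** band power (delta/theta 1–8 Hz, beta 13–30 Hz; prespeech
   [−500, 0) ms, during-speech [0, 1000] ms) with
   `mean_power ~ task * laterality * contact + (1 | participant)`,
   REML-fitted, Type-3 F tests with Satterthwaite denominator df and
   Bonferroni-corrected pairwise task contrasts.

The simulator (`speechlfp.synth`) generates cohorts of 1/f-background
recordings with task-graded injected effects (post-onset theta increases,
prespeech beta desynchronization) and returns the injected ground truth,
which the test suite uses for end-to-end recovery checks.

## Worked example

```bash
python examples/bandpower_mixed_model.py
```

simulates a 13-participant cohort at the band-power level with injected
task means +1/+2.5/+3 dB (vowel/DDK/sentence), participant SD 0.5 dB,
noise SD 0.5 dB, and fits the during-speech theta model:

```
band-power table: 312 rows (104 per task)

variance components: participant 0.218, residual 0.229

Type-3 ANOVA (Satterthwaite):
                                           term      F  df_num df_den        p
                                   C(task, Sum) 486.85       2  276.0 3.06e-91
                             C(hemisphere, Sum)   1.59       1  276.0    0.208
                                C(contact, Sum)   0.81       3  276.0    0.489
...
pairwise task contrasts (Bonferroni, family of 3):
      contrast estimate     se         df    t    p_raw p_bonferroni
sentence-vowel        2 0.0664 276.001559 30.2 2.22e-89     6.67e-89
     ddk-vowel     1.46 0.0664 276.001559   22 1.35e-62     4.04e-62
  sentence-ddk    0.544 0.0664 276.001559 8.19 9.98e-15        3e-14
```

Reading: 104 band-power values per task (13 participants × 2 hemispheres
× 4 contacts); the balanced design yields the classical denominator df of
276; the task effect dominates while hemisphere/contact terms behave like
noise (none injected); the contrasts recover the injected ordering
sentence > DDK > vowel with estimates close to the injected differences
(2.0 and 1.5 dB). Other examples cover simulation + EDF/TextGrid export,
preprocessing, time-frequency maps, surrogate thresholding, and the
one-call `run_pipeline` orchestration.

## Layout

- `src/speechlfp/` — `synth` (cohort simulator), `preprocess`, `timefreq`,
  `surrogate`, `bandpower` (LME + Satterthwaite), `edf`/`events` (EDF,
  CSV, Praat TextGrid I/O), `pipeline` (config, orchestration, manifest),
  `plotting`.
- `examples/` — one narrative script per capability.
- `docs/methods.md` — model assumptions, parameter choices, numerical
  details, known limitations.
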