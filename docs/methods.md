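# Methods

## Problem and model

Minute-by-minute sleep-apnea detection from single-lead ECG rests on two
physiological signatures. During repetitive apneas the heart rate exhibits a
cyclic brady/tachycardia at the event-recurrence rate (a few events per
minute and slower, i.e. VLF, 0–0.04 Hz), and the R-peak amplitude is
modulated at the same slow rate because chest-movement geometry changes with
the breathing pattern. During normal breathing the same two series instead
carry respiratory sinus arrhythmia and EDR modulation at the breathing rate
(HF, 0.15–0.4 Hz). Minute-level band powers of the RR tachogram and the EDR
series, together with standard time-domain HRV statistics, therefore separate
apneic from normal minutes — imperfectly, because event severity varies and
non-apneic slow variability exists.

The classifier is a one-hidden-layer perceptron over a **moving time window**:
the input for minute k concatenates the normalized features of segments
k−w+1 … k (oldest first, current last), so consecutive inputs differ by one
segment. Apnea episodes persist across many minutes, so the label of minute k
is statistically dependent on its neighbourhood; the window lets a
feed-forward network use that dependence without any distributional
assumptions (unlike an HMM). w = 1 recovers the plain per-segment MLP.

Network: hidden width fixed by the Kolmogorov superposition heuristic
H = 2M+1 for M = 18·w inputs (w = 5 ⇒ M = 90, H = 181); relu hidden
activation; C = 2 linear outputs trained against one-hot targets by
mini-batch gradient descent on the squared error. We minimize the batch
*mean* of the per-sample summed squared error — the same minimizer as the
plain sum, but with a learning rate that does not depend on batch size. The
apnea score used for ranking/AUC is y_apnea − y_normal; the predicted label
is the argmax with ties resolved to normal.

## Pipeline parameters

| parameter | default | rationale |
|---|---|---|
| band-pass | 3–45 Hz FIR, Hamming windowed-sinc, ~1 Hz transitions | removes baseline drift and powerline noise; centred (zero-lag) application keeps R-peak times/amplitudes unbiased |
| QRS detection | Hamilton: \|diff\| → 80 ms centred moving average → adaptive threshold between 8-peak QRS/noise running means (coefficient 0.3125), 200 ms refractory, search-back at 1.5·mean RR with half threshold | the classic open-source recipe; detections refined to the filtered-signal maximum within ±20 ms |
| RR correction | 5-point local median, 20% deviation rule, per recording | replaces physiologically implausible intervals (missed/false beats); window and threshold config-exposed |
| segment validity | ≥ 20 beats/minute | minutes with failed detection are excluded from training and scoring and reported as coverage loss |
| tachogram PSD | cubic spline to a uniform 4 Hz grid, mean removal, Welch with Hann window, 256-point FFT, 50% overlap | the RR/EDR series are unevenly sampled and short (~60 points/minute); 4 Hz comfortably covers the 0.4 Hz band edge |
| band powers | trapezoidal PSD integrals over [0, 0.04), [0.04, 0.15), [0.15, 0.4) Hz | ratios use 0/0 → 0 and x/0 → cap (10⁶) |
| pNN50 | NN50/(N−1) | the 50 ms rule applies to adjacent pairs, of which there are N−1; a config flag selects the N convention |
| normalization | z-score with training-split mean/sd (population sd); sd = 0 → 0 | fitted on valid training segments only, never on test data |
| training | SGD, lr 0.01, momentum 0.9, batch 128, ≤ 200 epochs, 10% validation split with patience 20, seeded shuffling | all config-exposed; identical seeds give bit-identical weights |
| windows | windows touching an invalid segment are dropped; the first w−1 minutes of each recording are not scored; windows never span recordings | dropped minutes are excluded from the predicted-AHI denominator by default (`ahi_t_policy` flag switches to full-recording minutes) |
| diagnosis | AHI = 60/T · (apnea minutes); apneic iff AHI > 5 strictly | the A/B/C severity class (C < 5 ≤ B ≤ 10 < A) is carried as metadata |

The window convention deserves a note: "window = 5" is interpreted as five
segments *including* the current one (M = 90, H = 181). The alternative
reading (5 past + 1 current = 108 inputs) would give H = 217; we keep the
convention consistent with H = 181 and expose w as a run-time parameter.

## Synthetic apnea-ECG generator

The generator produces exactly what the pipeline consumes — R-peak times and
amplitudes on a 100 Hz, 16-bit-quantizable signal — with per-minute labels
and known AHI:

* beat times integrate an instantaneous RR series: baseline 1.0 s modulated
  in apnea minutes by a 0.02 Hz (VLF) oscillation and in normal minutes by a
  0.25 Hz (HF) respiratory oscillation; R amplitudes are co-modulated
  (EDR); each beat is rendered as a raised-cosine spike (40 ms) plus white
  Gaussian noise (sd 0.05 against unit spikes);
* **severity heterogeneity**: each apnea minute draws a severity s ~ U(0, 1)
  that scales the VLF modulation (depth 0.25·s) and *suppresses* the
  respiratory HF modulation proportionally (depth 0.05·(1−s)) — a mild event
  or hypopnea keeps most of its breathing signature. Normal minutes draw a
  respiratory depth scale U(0.3, 1);
* **background variability**: an Ornstein–Uhlenbeck wander (sd 0.06 on RR,
  0.05 on amplitude, correlation time 50 s) runs through *all* minutes,
  giving normal minutes genuine VLF power; a 3% multiplicative white RR
  jitter provides the HRV noise floor;
* **temporal label structure**: per-minute labels come from a two-state
  Markov chain with persistence 0.92 (apnea) / 0.95 (normal) — mean episode
  lengths ≈ 12 and 20 minutes, apnea prevalence ≈ 0.3 — or from an explicit
  pattern / target AHI (one contiguous bout).

The severity/suppression and background-wander terms are what make
single-minute classification imperfect (class-conditional feature overlap);
the Markov persistence is what makes neighbouring minutes informative. Both
are needed for the study's central question — whether windowed context
improves minute-level accuracy — to be non-trivial on synthetic data.

What the generator does **not** emulate: P/QRS/T morphology, ectopy and
arrhythmia, electrode artefacts, sleep-stage structure, obstructive/central
subtypes, and sub-minute event alignment. Passing tests therefore validate
the pipeline's mechanics and the direction of its behaviour, not clinical
performance on real recordings.

## Study conditions for the model-level experiments

The window-benefit and robustness experiments use, per seed, 20 training and
7 test recordings of 100 minutes (≈ 1,900 training segments), one third of
the recordings being near-normal subjects with a fixed low AHI of 3 so both
diagnostic classes occur. This corpus is about an order of magnitude smaller
than a full released/withheld PhysioNet-style split; it is the scale at which
the w = 5 network (90 inputs, ~16k weights) still trains stably, and the
observed effect matches the expected pattern: the w = 5 model beats the w = 1
baseline on per-segment accuracy in ≥ 4 of 5 seeds and consistently on AUC
(typical gains 0.01–0.05 absolute).

The label-shuffle control is evaluated as the *mean* held-out AUC over five
independent shuffles with training run to its full epoch budget. A single
shuffled fit's AUC has an irreducible dispersion of several hundredths at
this sample size — the overfit residual function aligns by chance with
informative feature directions — while the mean is a stable estimate of the
no-leakage expectation 0.5.

## Numerical choices and degeneracies

* Sample slices are half-open and 0-based: minute k covers
  [k·60·fs, (k+1)·60·fs); an RR interval belongs to the minute containing its
  second peak; a trailing partial minute is discarded with a warning.
* Welch nperseg is min(256, series length); band integrals need ≥ 2 PSD bins.
* A segment is invalid if it has < 20 beats, < 4 spectral points, a < 10 s
  span, or any non-finite feature; invalid segments carry NaN sentinels.
* Empty/flat signals yield an empty (flagged) beat series, not an exception.
* Model files are plain JSON; Python float repr round-trips exactly, so
  save/load/predict is bit-reproducible.
* Welch segment/overlap, the pNN50 denominator and the 4 Hz interpolation
  rate are convention choices (config-exposed); results are insensitive to
  them at the effect sizes studied here.

## Known limitations

* The Hamilton detector is tuned for clean, positive-polarity QRS spikes; on
  real ECG with low SNR or inverted leads its parameters (threshold
  coefficient, refractory) may need adjustment.
* AHI approximates events/hour by apnea-labelled minutes/hour, inheriting the
  per-minute annotation granularity.
* No class reweighting or regularization beyond early stopping; heavily
  imbalanced corpora may need both.
* The CSV input dialect is headerless; its sampling rate must be supplied by
  the caller (default 100 Hz).
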