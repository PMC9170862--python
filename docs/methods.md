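# Methods

## Problem and approach

During general anaesthesia the cortical EEG loses complexity: the spectrum
steepens, fast activity is suppressed, and the signal becomes more regular.
`ewtdoa` turns that observation into a scalar depth-of-anaesthesia (DoA)
index on the familiar 0–100 monitor scale (100 = awake), trained against a
reference index (BIS-like, one value per second) recorded alongside the EEG.

The processing chain, applied to a single EEG channel sampled at 128 Hz:

1. **Pre-filter.** Zero-phase 4th-order Butterworth band-pass, 0.1–64 Hz.
   At fs = 128 Hz the upper edge coincides with Nyquist, so the realised
   filter is the 0.1 Hz high-pass alone; the upper edge becomes active for
   any higher sampling rate. Forward–backward application avoids injecting
   group delay ahead of the windowing.
2. **Windowing.** 56-s analysis windows with 55-s overlap (1-s stride), each
   window stamped at its end time so the index is causal. A recording of
   T s yields `T − 56 + 1` windows; reference-track element *k* (the value
   at the end of second *k + 1*) pairs with the window ending at second
   *k + 1*.
3. **Empirical wavelet transform.** Per window, boundaries are detected on
   the log magnitude spectrum with the *locmaxmin* rule: keep the
   `n_bands = 15` largest local maxima, place each boundary at the smallest
   spectral value between consecutive retained maxima. A Meyer-style tight
   frame (raised-cosine transitions, relative half-width γ) is built on the
   boundaries; band-passing the window through filter *k* gives the subband
   coefficient vector, and filtering the coefficients once more gives the
   empirical mode. Modes sum back to the window exactly; coefficient
   energies satisfy Parseval. Only the highest-frequency subband (index 14)
   feeds the features.
4. **Features**, per window, from the highest subband:
   - *median coefficient* — amplitude-scale baseline;
   - *spectral entropy* (SE), in bits: Shannon entropy of the normalised
     power over positive-frequency DFT bins (DC excluded), computed for each
     of the 56 one-second sub-segments and averaged;
   - *SODP statistic*: for each one-second sub-segment, plot successive
     first differences X(n) = x(n+1) − x(n) against Y(n) = x(n+2) − x(n+1);
     with SX, SY the RMS spreads, SXY the cross-term and
     D = √((SX² + SY²)² − 4(SX²SY² − SXY²)), the statistic is
     |ln(3π·√((SX² + SY² + D)(SX² + SY² − D)))|, averaged over the window.
5. **Index regression.** ε-insensitive support-vector regression with a
   linear kernel on the z-scored feature triplet (an ordinary least-squares
   baseline is available). Predictions are clipped to [0, 100] and smoothed
   with a trailing 6-s moving average (5-s overlap).
6. **State rules.** Four anaesthetic states — awake (AW), light (LA),
   moderate (MA) and deep (DA) anaesthesia, conventionally 80–100 / 60–80 /
   40–60 / 0–40 on the reference scale. Rule bounds per state are the
   central 80% interval (10th/90th percentiles) of the smoothed training
   index during that state's stable periods. Classification maps a value
   inside one interval to that state, gap/overlap values to the nearest
   interval with ties to the deeper state, and values beyond [0, 100] to
   UNCLASSIFIED.
7. **Evaluation.** Pearson r, MSE/RMSE and R² between index and reference;
   confusion matrix and Cohen's kappa between predicted and annotated
   states.

## Parameters that matter

| parameter | default | units | why |
| --- | --- | --- | --- |
| `window_s` / `overlap_s` | 56 / 55 | s | the window/overlap pair the method was designed around; 1-s stride matches the 1 Hz reference |
| `n_bands` | 15 | – | number of EWT subbands; features come from band 15 |
| `band` | (0.1, 64) | Hz | broad-spectrum pre-filter; hi ≥ Nyquist degrades gracefully to high-pass |
| `gamma` | auto | – | Meyer transition half-width; auto = 99% of the largest feasible value, keeping the frame tight for any boundary set |
| `cost`, `epsilon` | 1.0, 0.1 | –, index units | conventional SVR defaults on standardised features; the result is insensitive to `cost` over 0.1–100 on the synthetic cohort |
| `smooth_n` | 6 | s | trailing moving-average length |
| `coverage` | 0.80 | – | central interval mass for rule derivation |

## Numerical choices

- **Boundary detection** uses the log spectrum with an additive floor of
  1e-12; local maxima that are pure numerical noise (below 1e-10 of the
  spectral peak) are discarded. If fewer maxima than bands exist, the
  boundaries found are kept and the widest spectral interval is halved
  repeatedly until 14 boundaries exist (logged as a warning). This
  guarantees the model always sees 15 bands.
- **SE of an all-zero segment** is defined as 0 (with a warning) rather than
  an error; flat-line EEG occurs in practice.
- **Degenerate SODP** (zero ellipse area, e.g. constant or perfectly linear
  segments): the log argument is floored at 1e-12, giving a large finite
  value instead of −∞. The SODP cross-term identity
  (SX²+SY²)² − D² = 4(SX²SY² − SXY²) ≥ 0 (Cauchy–Schwarz) makes the area
  term non-negative for the squared-first-term form of D used here; the
  alternative printed form with an unsquared first term can go imaginary
  and is available for comparison via `sodp(..., literal_radical=True)`.
- **SE normalisation** uses power (|X|²), not raw DFT values, so that the
  normalised quantity is a probability distribution; the log is base 2
  (bits). The SODP log is natural.
- **Ties in classification** go to the deeper state — the conservative
  reading for patient safety.
- Pearson r with a zero-variance series is reported as NaN (undefined), not
  0; missing index/reference pairs are pairwise-deleted and counted.

## The synthetic cohort

No clinical recordings ship with the package; the generator in
`ewtdoa.synthetic` fabricates study-shaped data with the one property the
method needs: **EEG complexity monotone in depth**. Two mechanisms encode a
known depth trace d(t) ∈ [0, 100]:

- the spectral slope of the broadband noise floor,
  α(d) = 2.6 − 1.8·d/100 (1/f^α amplitude shaping above 0.5 Hz, realised by
  per-sample interpolation between slope-shaped versions of a single
  white-noise realisation so the slope varies smoothly in time);
- a 32–63 Hz noise component with weight 0.05 + 0.25·d/100.

Both raise the highest subband's spectral entropy and SODP area as the
subject lightens. The slope mechanism deliberately carries most of the
encoding: a dominant, sharply band-limited fast component makes the
adaptive boundaries latch onto its edges and destroys the monotone
SE–depth relationship.

A cohort recording follows a surgery-like profile — awake, induction,
deep plateau, moderate plateau, emergence — with randomised levels and
stage lengths (each stage ≥ 16% of the recording so plateaus outlast the
30-s raised-cosine transition ramps plus one analysis window). The 1 Hz
reference is the depth trace plus Gaussian noise (sd 3 index units,
clipped), emulating monitor jitter. Optional SQI-dropout episodes add a
large low-frequency artifact to the EEG and corrupt the reference.
State annotations label the plateaus (ramps trimmed) via the conventional
depth ranges; a window only counts as "stable" downstream when it lies
entirely inside an annotated interval, since a window whose tail covers a
transition carries a mixture of stages.

What the generator does **not** emulate: burst suppression, spindles,
ocular/cardiac artifacts, drug pharmacokinetics, inter-patient variability
of the depth–complexity relationship, or any disagreement between the
reference index and "true" depth beyond additive noise. Passing the
end-to-end tests therefore shows the pipeline recovers a depth signal that
is encoded the way the method assumes — it is not evidence about clinical
accuracy.

## Problem sizes used in tests and the acceptance script

The study-scale experiment uses 10 training and 5 held-out recordings of
600 s (10 min) each — about 8 000 analysis windows end to end. Exactness
checks use 200 random 7168-sample windows; oracle-equivalence checks use
500 random short segments; boundary placement uses 100 random tone pairs.

## Known limitations

- The EWT boundary fallback (uniform subdivision) is a pragmatic guarantee,
  not part of the locmaxmin rule; spectra with fewer than 15 genuine
  maxima get partly arbitrary high bands.
- With a 1-s stride the per-window features are heavily overlapped, so
  training rows are strongly autocorrelated; the SVR treats them as
  independent.
- Rule derivation requires every state present with ≥ 20 stable windows;
  short or single-stage recordings cannot train a rule set.
- EDF reading requires the optional `mne` dependency; there is no EDF
  writer, so synthetic cohorts are saved as CSV with sidecar tracks.
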