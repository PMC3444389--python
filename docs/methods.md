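# Methods

## The organization measure

Atrial fibrillation (AF) replaces the P wave of the surface ECG with
continuous fibrillatory (f) waves whose waveform stability reflects how
organized the underlying atrial activation is.  `wavectm` quantifies that
stability in three steps:

1. **Atrial activity (AA) extraction.**  The single-lead ECG (lead V1 by
   preference) is resampled to 1024 Hz and the ventricular QRST complexes are
   cancelled, leaving the AA signal `x_AA(k)`.

2. **Dyadic wavelet decomposition.**  A 7-level Mallat pyramid decomposition
   of `x_AA` is computed,

   `C_m(n) = sum_k x_AA(k) psi_m,n(k)`,

   where `psi_m,n` are the dilations/translations of the chosen mother
   wavelet.  The level-`m` detail covers the band `(fs/2^(m+1), fs/2^m)`, so
   at 1024 Hz the **level-7** coefficients cover **4–8 Hz** — the band that
   contains the dominant atrial frequency (DAF) of essentially all AF
   recordings.  The coefficient vector `C_7` (about 240 samples for a 30 s
   record) tracks the time course of the similarity between the f waves and
   the wavelet at the AF scale.

3. **Central tendency measure (CTM).**  From `C_7` the first-differences
   scatter plot is formed — the `N-2` points
   `(C(i+2)-C(i+1), C(i+1)-C(i))` — and the CTM is the fraction of points
   strictly inside a disk of radius `rho` around the origin:

   `CTM = (1/(N-2)) sum_i [ sqrt(d2_i^2 + d1_i^2) < rho ]`.

   The radius is `rho = r * sd(C_7)` with the sample (N−1 denominator)
   standard deviation of the analyzed vector itself, which makes the measure
   exactly invariant to uniform amplitude scaling and constant shifts: only
   the temporal variation pattern of the coefficients matters.  A smoothly
   varying coefficient vector (stable waveform) concentrates near the origin
   (CTM close to 1); rapid coefficient variation disperses the plot and
   lowers the CTM.

Classification is a thresholded univariate rule on the per-record CTM: a
receiver operating characteristic (ROC) sweep over midpoint thresholds
selects the accuracy-maximizing threshold (resubstitution), with the area
under the curve (AROC) by the trapezoid rule and leave-one-out
cross-validation (LOOCV) re-fitting the threshold per held-out record.
Group differences are screened with Shapiro–Wilk (normality) and Levene
(homoscedasticity) and tested with a two-tailed pooled-variance Student's
t-test at p < 0.05.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `target_fs` | 1024 Hz | operating rate; level 7 maps to 4–8 Hz only here |
| `hp_cutoff` | 0.5 Hz | baseline-wander highpass (zero-phase Butterworth, order 5) |
| `lp_cutoff` | 70 Hz | noise lowpass (zero-phase Butterworth, order 5) |
| `notch_freq`, `notch_q` | 50 Hz, 35 | powerline notch (configurable to 60 Hz) |
| `wavelet_family`, `wavelet_order` | biorthogonal (4,4) | analysis basis; all six families (Haar, Daubechies, Coiflet, Biorthogonal, Reverse Biorthogonal, Symlet) are registered and reach the same discriminant ability to within a borderline record |
| `levels`, `analysis_scale` | 7, 7 | decomposition depth and analyzed detail level |
| `rho_multiplier` | 3.3 | radius in units of the coefficient-vector SD; 3.3 for the paroxysmal-AF termination mode, 4.0 for the cardioversion-outcome mode |
| `qrst_pre_ms`, `qrst_post_ms` | 250, 450 ms | cancellation window around each R peak |
| `blend_ms` | 20 ms | raised-cosine taper at template ends |

Records at other sampling rates are resampled (rational polyphase with a
Kaiser anti-imaging filter) before analysis; without that, the seventh scale
does not match the atrial band and the measure loses its meaning.

## Stage order and numerical choices

* **Filters** are applied forward/backward (`sosfiltfilt`) for zero net
  phase; the doubled effective order is intentional.  Records must exceed
  three filter lengths; shorter inputs raise an error rather than returning
  transient-dominated output.
* **Highpass after cancellation.**  In the end-to-end pipeline the 0.5 Hz
  highpass runs *after* QRST cancellation.  The zero-phase highpass spreads
  every QRST complex into slow (~2 s) tails that no practical cancellation
  window can cover; cancelling first and highpassing the residue removes
  both the ventricular waveform and the wander without leaving those tails
  in the AA signal.  The standalone `condition()` helper keeps the
  conventional resample → highpass → lowpass → notch order for general
  conditioning use.
* **R-peak detection** follows the classical derivative → squaring → 150 ms
  moving-window integration → adaptive-threshold recipe with a 200 ms
  refractory period, then refines each detection to the local extremum of
  the 8–26 Hz bandpassed signal.  A record with no QRS-like energy returns
  an empty, flagged beat set instead of raising.
* **QRST cancellation** models the ECG as a superposition of one scaled
  template per beat.  The template is initialized from the rank-1 singular
  mode of the aligned beat matrix and refined by alternating least squares
  (template given gains — a sparse linear solve that fits overlapping
  windows jointly — then gains given template).  Gains are estimated from
  the 8 Hz-highpassed QRS core (±60 ms around R) because the T wave overlaps
  the f-wave band spectrally and raw per-window gains absorb atrial energy.
  Template ends are tapered with a 20 ms raised cosine; samples outside all
  beat windows are returned exactly unchanged.
* **Wavelet boundary handling** uses symmetric (half-sample) extension by
  default, the standard choice for biorthogonal bases; coefficient vectors
  therefore carry a few boundary samples beyond `N/2^m`.  Energy
  conservation for the orthonormal families is exact only under
  periodization, so that property is stated and verified in that mode.
* **CTM conventions**: strict `<` at the disk boundary; the degenerate
  zero-variance input returns CTM = 1 with a flag (the limit of the
  definition) so batch runs survive flat segments; non-finite samples raise.
* **ROC conventions**: candidate thresholds are midpoints of adjacent sorted
  unique scores plus sentinels outside the score range; scores exactly at
  the threshold classify negative; accuracy ties break toward the larger
  Youden index, then toward the candidate nearest the score median.  With
  this candidate set the trapezoid AROC equals the Mann–Whitney U statistic
  normalized by `n_pos * n_neg` (ties counted half), which the tests verify
  to 1e-12.

## The synthetic generator

Real AF archives cannot be redistributed with the package, so every stage is
validated against a synthetic AF-ECG generator with known ground truth.  A
record is the sum of

* **f waves** — a 3-harmonic series at a per-record DAF with (i) a
  waxing-waning amplitude (depth 0.65 at 3.0 Hz), (ii) a slow sinusoidal
  wander of the atrial rate (±0.35 Hz at 0.15 Hz), and (iii) a stochastic
  4–8 Hz turbulence floor at 0.2 of the f-wave amplitude — the
  irregular-envelope, wandering-rate character every real f wave shows;
* **ventricular activity** — a sum-of-Gaussians QRS plus half-sine T placed
  at lognormal RR intervals (mean 0.7 s, CV 0.24; the irregular ventricular
  response of AF), amplitude 1 mV against 0.06 mV f waves;
* **nuisance** — 0.2 Hz baseline wander (0.1 mV), 50 Hz powerline (0.02 mV),
  white noise (0.01 mV RMS).

A single variability parameter `theta` in [0, 1] drives the waveform toward
disorganization: the dominant rhythm fades (factor `1 - 0.8*theta`), its
phase decoheres (random-walk step `0.05*theta` rad/sample), and a persistent
fractionated component near the slow edge of the atrial band (4.1–4.9 Hz,
amplitude `1.8*theta` times the base amplitude) grows.

**Why the slow-edge component.**  The level-7 coefficient sequence is
sampled at 8 Hz, so in-band content at frequency `f` appears in it at the
folded frequency `8 - f`: content near the 4 Hz edge produces near-Nyquist
alternation of the coefficients — exactly the "fast temporal variation"
that disperses the first-differences plot — while content near 8 Hz varies
slowly, and any modulation faster than the ~1 s level-7 filter support is
smoothed away.  A measurable loss of organization must therefore place
sustained, coherent energy toward the slow edge of the band; incoherent
mixtures (noise, many independent components) spread the scatter radii and
paradoxically *raise* the std-normalized CTM.  The generator encodes
disorganization accordingly.  The free amplitudes were fixed once so the
two cohort groups (`theta` 0.1 vs 0.8) reproduce the group CTM ranges
reported for non-terminating versus terminating clinical AF (≈0.95 vs
≈0.79 at radius 3.3 SD), and with them the grid-search optimum radius falls
at 3.3–3.6, inside the clinically reported significant range.

**What passing tests do and do not show.**  The generator reproduces the
measurement-relevant properties — a 4–8 Hz dominant atrial component with
tunable waveform variability, irregular ventricular overlap, realistic
nuisance — but not atrial electrophysiology: `theta` is a synthetic class
variable, the fractionated component is a phenomenological stand-in for
disorganized activation, and QRST morphology is constant within a record.
Green end-to-end tests demonstrate that the pipeline recovers a known
organization contrast through realistic interference; they do not re-certify
the clinical classification performance reported on patient data.

## Problem sizes

Tests and the acceptance script use 30 s records at 1024 Hz (30 720
samples), cohorts of 20 + 20 records, 20 seeded cohort replicates, a
100-point radius grid (0.1–10.0 in 0.1 steps) and 120 random vectors for
the CTM oracle check — sizes at which every quantity the package reports is
recomputed from scratch in well under a minute each on one CPU.

## Known limitations

* Single-lead analysis only; no spatiotemporal (multi-lead) cancellation.
* The WFDB reader covers single-segment format-16 records — sufficient for
  the archives this method targets — not the full format zoo.
* Resubstitution and LOOCV are the only validation schemes, mirroring the
  small-cohort setting the method was designed for; no k-fold machinery.
* The cancellation template is rank-1 per record: strong beat-morphology
  changes (ectopy, alternans) would leave residua; such beats are not
  modelled by the generator.
* CTM degeneracies: a zero-variance coefficient vector returns 1.0 with a
  flag; values exactly on the disk boundary (possible for integer-valued
  fixtures) fall outside by the strict inequality.
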