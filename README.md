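# wavectm

Non-invasive estimation of atrial fibrillation (AF) organization from a
single ECG lead, by combining the discrete wavelet transform with the
central tendency measure (CTM) of the first-differences scatter plot.

## The problem and who this is for

AF is the most common sustained arrhythmia.  Two clinical questions hinge on
how *organized* the fibrillatory (f) waves are: will a paroxysmal AF (PAF)
episode terminate on its own, and will a patient cardioverted out of
persistent AF stay in normal sinus rhythm?  Both can be read, non-invasively,
from the waveform variability of the f waves on lead V1.  This package is for
biomedical-signal researchers who want a tested, scriptable implementation of
that estimator plus the surrounding machinery: preprocessing, ventricular
(QRST) cancellation, classification statistics, and a synthetic AF-ECG
generator that makes every stage verifiable without access to clinical
archives.

## The estimator

For an AA (atrial activity) signal `x_AA` at 1024 Hz, a 7-level dyadic
wavelet decomposition (default basis: biorthogonal (4,4)) gives the level-7
detail coefficients

```
C_7(n) = Σ_k  x_AA(k) · ψ_{7,n}(k),
```

which cover the 4–8 Hz band containing the dominant atrial frequency.  From
the N−2 scatter points `(C(i+2)−C(i+1), C(i+1)−C(i))` the CTM counts the
fraction inside a disk of radius ρ = r·SD(C_7) around the origin:

```
CTM = (1/(N−2)) Σ_i 1[ √((C(i+2)−C(i+1))² + (C(i+1)−C(i))²) < ρ ].
```

Stable f waves give smoothly varying coefficients and CTM near 1;
disorganized f waves disperse the plot and lower the CTM.  A ROC-optimal
threshold on the per-record CTM (r = 3.3 for PAF termination, r = 4.0 for
cardioversion outcome) turns the measure into a classifier, reported with
sensitivity/specificity/accuracy, AROC, leave-one-out cross-validation and a
pooled-variance t-test between groups.  See `docs/methods.md` for the full
account.

## Worked example

```python
from wavectm import SynthConfig, synthesize_ecg, record_ctm, PipelineConfig

for theta in (0.1, 0.8):                      # low / high f-wave variability
    cfg = SynthConfig(seed=7, variability=theta, daf_hz=6.0)
    record, r_times, fwave = synthesize_ecg(cfg)
    res = record_ctm(record, PipelineConfig(rho_multiplier=3.3))
    print(f"theta={theta}: CTM = {res.result.ctm:.3f} "
          f"({res.result.n_inside}/{res.result.n_points} points inside)")
```

prints

```
theta=0.1: CTM = 0.972 (239/246 points inside)
theta=0.8: CTM = 0.846 (208/246 points inside)
```

The organized record (θ = 0.1) keeps nearly all scatter points inside the
3.3 SD radius; the disorganized one (θ = 0.8) loses 15% of them — the
contrast the classifier thresholds on.

The same flow from the shell:

```
wavectm run --n-stable 5 --n-variable 5 --seed 42 --out demo
```

```
{"seed": 42, "threshold": 0.9187, "sensitivity": 1.0, "specificity": 1.0,
 "accuracy": 1.0, "aroc": 1.0, "loocv_accuracy": 1.0,
 "mean_stable": 0.9992, "mean_variable": 0.7756, "p_value": 5.53e-06}
```

i.e. on this 10-record synthetic cohort the CTM threshold 0.9187 separates
the groups perfectly, and the group means differ at p ≈ 6·10⁻⁶.  Individual
stages are available as `wavectm simulate / preprocess / extract-aa / ctm /
classify`; real records are read from WFDB (format 16) or a simple
self-describing CSV.

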