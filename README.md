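# lifttensor

Multiway tensor analysis of bimanual grasp-lift-replace recordings: from
raw per-trial grip/load forces and surface EMG to a non-negative 5-way
tensor, a non-negative canonical polyadic (NCP) decomposition of that
tensor, and factor-based statistics that relate the extracted motor
components to age and manual dexterity.

The package is aimed at motor-control and neuromechanics researchers who
record muscle activity (EMG) together with kinetic variables during
repeated object lifts and want a single decomposition that jointly
describes *which* muscles/forces act together, *when* they act, and *how
strongly* each object condition, participant, and trial recruits them.

## The model

All preprocessed trials are collated into a non-negative 5-way array

    X ∈ R₊^(M×T×J×P×K),   M=12 channels, T=460 samples, J=2 objects,
                           P participants (age-ordered), K=10 trials,

where channels 1–4 are right/left grip and load forces and channels 5–12
are right/left anterior deltoid, extensor carpi radialis, flexor carpi
radialis, and abductor pollicis brevis EMG envelopes.  The NCP model
approximates

    X[m,t,j,p,k] ≈ Σ_{r=1..R} A[m,r] B[t,r] C[j,r] D[p,r] E[k,r],

with every factor entry ≥ 0, fitted by hierarchical alternating least
squares (HALS).  Model adequacy is measured by the variance accounted for,

    VAF = 1 − MSE / var(vec(X)),

and the rank R is the smallest candidate whose mean VAF over 10 random
restarts reaches 60%.  After fitting, the scale ambiguity is fixed by
normalizing A, B, D, E to unit Frobenius norm and absorbing the magnitude
into the object factor C.

The participant factors D feed a leave-one-out linear-SVM age-group
classification (with factor-subset search and permutation importance),
OLS regression and Pearson correlation against age and a Purdue-Pegboard
dexterity score, and the trial factors E are tested for monotone trends
with the Mann-Kendall test.

Because raw laboratory recordings of this kind are not freely
redistributable, the package ships a synthetic-data generator
(`lifttensor.synthdata`) that emulates the study conditions — 13 younger /
16 older adults, 0.2 and 0.4 kg objects, 10 trials per object, 2000 Hz EMG
/ 200 Hz kinematics — with a planted low-rank ground truth, so every stage
is testable end to end.

## Worked example

```python
import numpy as np
import lifttensor as lt

# plant a rank-4 ground truth with an age effect and a trial drift on
# the designated component
truth = lt.generate_planted_model(
    (12, 100, 2, 29, 10), R=4, group_effect_d=2.5, trial_slope=-0.05, seed=0)
mt, metas = lt.generate_tensor_dataset(truth, snr_db=10, seed=0)

model, report = lt.ncp_best_of(mt.X, R=4, n_restarts=5, seed=0)
model = lt.fix_scale(model)
print(f"VAF = {report.vaf:.3f}")

groups = [m.group for m in metas]
best = lt.subset_search(model.D, groups)[0]
print(f"best subset {best.factor_subset}: AUC={best.auc:.2f} Acc={best.acc:.2f}")

# resolve the CP permutation ambiguity to find the drifting component
perm, _ = lt.match_factors(model, truth.planted_model)
drift_col = int(np.flatnonzero(perm == 0)[0])
trend = lt.mann_kendall(model.E[:, drift_col])
print(f"trial trend: S={trend.S} p={trend.p:.4f} ({trend.direction})")
```

prints

```
VAF = 0.935
best subset (0, 3): AUC=0.96 Acc=0.90
trial trend: S=-39 p=0.0007 (decreasing)
```

The fit explains 93.5% of the tensor variance at 10 dB SNR; a pair of
estimated participant factors separates the age groups almost perfectly
(the planted effect is strong, 2.5 pooled SDs), and the trial factor of
the component matched to the planted one shows a significantly
decreasing trend (S < 0, i.e. most later trials are below earlier ones).

A full pipeline run (simulate → preprocess raw signals → decompose →
infer) is available as a library call, `lt.run_pipeline(lt.PipelineConfig())`,
or from the shell:

```sh
lifttensor all --out runs/demo --seed 1
```

With the default configuration this reproduces the full study-scale
analysis (29 simulated participants, 580 raw trials, rank sweep 1..10
with 10 restarts on the 12×460×2×29×10 tensor) and takes on the order of
half an hour on one CPU; pass `--config` with a smaller YAML for a quick
look (see `tests/test_cli.py` for a minimal example).

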