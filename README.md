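# dtialps

Diffusion-tensor analysis along the perivascular space (DTI-ALPS) for
studying glymphatic function, with the cohort statistics used in
sleep-apnea neuroimaging studies and a synthetic DWI phantom / cohort
generator so the whole pipeline is testable without scanner data.

## Who this is for

Researchers analysing single-shell diffusion MRI (e.g. b = 0 and
800 s/mm², 30 directions) who want a reproducible, scriptable route from
raw 4-D DWI volumes to:

1. the six diffusion-tensor component maps D_xx, D_yy, D_zz, D_xy, D_xz,
   D_yz (plus FA and colour-FA),
2. ROI component means over the periventricular projection- and
   association-fiber areas,
3. the per-subject ALPS index, and
4. cohort-level statistics: demographics tables, covariate-adjusted
   (age, sex) group comparisons with Bonferroni correction, and Spearman
   correlations with disease-severity and sleep-symptom measures.

## The index

At the level of the lateral-ventricle body the perivascular space runs
right–left (x-axis), perpendicular to the adjacent projection fibers
(z-axis) and to the association fibers lateral to them (y-axis).  With
D_xx^proj, D_yy^proj measured in the projection-fiber area and
D_xx^assoc, D_zz^assoc in the association-fiber area:

```
         (D_xx^proj + D_xx^assoc) / 2       D_xmean
ALPS = ───────────────────────────────── = ─────────
         (D_yy^proj + D_zz^assoc) / 2       D_yzmean
```

Values near 1 mean minimal diffusion along the perivascular space;
larger values indicate freer perivascular water movement, interpreted as
more active glymphatic transport.  The tensor itself is estimated by a
log-linear weighted least-squares fit of `S = S0·exp(−b·gᵀDg)` (OLS
available by flag), after suppressing non-brain voxels with a background
noise threshold.

## Worked example

Simulate a phantom whose fiber-shell diffusivities are the OSA group
means, add Rician noise at SNR 25, and run the per-subject pipeline:

```python
import dtialps as d

truth = d.build_phantom(d.PhantomSpec())
dwi = d.simulate_dwi(truth, snr=25, seed=0)
res = d.subject_alps(dwi, truth.region_labels)
print(f"true ALPS {truth.true_alps:.4f}  estimated {res.alps_index:.4f}")
print(f"D_xmean {res.d_xmean:.4f}  D_yzmean {res.d_yzmean:.4f}")
```

prints

```
true ALPS 1.3364  estimated 1.3380
D_xmean 0.7146  D_yzmean 0.5341
```

The ground-truth index 1.3364 is `(0.73 + 0.70)/2 ÷ (0.58 + 0.49)/2`,
the ratio of the phantom's fiber-shell x-diffusivities to the
perpendicular ones (units 10⁻³ mm²/s); at SNR 25 the estimate lands
within a fraction of a percent.  At infinite SNR the pipeline recovers
the ground truth to machine precision.

The same flow from the shell, on a full synthetic cohort (59 OSA / 62
control subjects drawn from the built-in group distributions):

```bash
dtialps full-pipeline --out demo --seed 42
```

writes `cohort.csv`, `demographics.csv`, `group_outcomes.csv`, and
`correlations.csv` plus a manifest, and prints the group-outcome table —
for seed 42, an OSA mean ALPS of 1.337 vs control 1.359 with a
covariate-adjusted group effect of −0.021 (raw p = 0.38 for that single
draw; detecting a difference of this size reliably needs the power
analysis in the test suite).  Other subcommands: `simulate-phantom`,
`simulate-cohort`, `fit-tensor`, `compute-alps`, `group-stats`,
`correlate`.

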