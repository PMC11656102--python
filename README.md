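# atlasboot

Subject-level **segmentation precision weights** for multi-atlas
label-fusion (MALF) volumetry, with weighted least squares and weighted
permutation inference.

## Why

Volumetric neuroimaging studies segment a region of interest (e.g. the
hippocampus) in every subject by fusing labels from an atlas pool, then
regress the ROI volumes on group, age and intracranial volume (ICV).
Standard practice treats every subject's volume estimate as equally
reliable.  It isn't: targets that align poorly with the atlases produce
fused segmentations — and hence volumes — that swing with the particular
atlas collection used.  Down-weighting imprecise estimates recovers
statistical power that outliers would otherwise destroy.

`atlasboot` estimates, per subject, the conditional variance of the fused
volume due to the atlas-sampling step, by **bootstrapping the atlas
collection**: resample the pool with replacement, re-fuse, extract the ROI
volume, and take the sample variance over replicates (300 by default).
Under the model

```
Y_i = X_i' beta + eps_i,   Cov(eps | targets) = diag(sigma_1^2 .. sigma_n^2)
```

the Aitken-optimal regression weight is the precision `w_i = 1/sigma_i^2`,
and WLS has the closed form `beta_hat = (X'WX)^{-1} X'WY`.  Because the
weights are estimated, p-values come from the **weighted Collins–Dekker
permutation procedure** (permute the WLS residuals of the predictor of
interest against the nuisance covariates; 999 permutations pooled with the
observed statistic), with weighted Freedman–Lane as a secondary route.

The package is aimed at biostatisticians and imaging researchers who want
precision-weighted group comparisons; the bootstrap layer is
fusion-agnostic (replicate volumes from any external fusion tool can be
supplied as a CSV), and two built-in desk-scale engines — majority vote
and locally weighted vote — make the whole pipeline runnable end to end,
including on synthetic phantoms.

## Worked example

```python
import numpy as np
from atlasboot import (
    SceneConfig, make_phantom_scene, MajorityVote, BootstrapConfig,
    bootstrap_volumes, weight_record, CohortConfig, make_cohort,
    collins_dekker_test,
)

# imaging route: phantom scene -> bootstrap precision weight
scene = SceneConfig(grid_shape=(24, 24, 16), roi_semi_axes=(7, 6, 4.5),
                    n_atlases=35, shift_sd=1.5, seed=11)
target, truth, atlases = make_phantom_scene(scene)
samples = bootstrap_volumes(target, atlases, MajorityVote(), roi_label=1,
                            config=BootstrapConfig(n_replicates=300, seed=11),
                            subject_id="phantom01")
rec = weight_record(samples)
print(f"mean replicate volume: {samples.volumes.mean():.1f} mm^3")
print(f"bootstrap variance:    {rec.boot_variance:.1f} mm^6")
print(f"precision weight:      {rec.precision_weight:.3e} / mm^6")

# statistical route: cohort with a group effect masked by outliers
cohort = make_cohort(CohortConfig(n_per_group=80, group_effect=-300.0,
                                  outlier_rate=(0.0, 0.2), seed=21))
y = cohort.volume_mm3.to_numpy()
x = cohort.group.to_numpy(float)
Z = np.column_stack([np.ones(len(cohort)), cohort.age, cohort.icv])
for name, w in [("precision", cohort.precision_weight.to_numpy()),
                ("identity ", np.ones(len(cohort)))]:
    res = collins_dekker_test(y, x, Z, w, n_perm=999, seed=5)
    print(f"{name}: t = {res.t_observed:+.2f}, p = {res.p_value:.3f}")
```

prints

```
mean replicate volume: 642.6 mm^3
bootstrap variance:    750.9 mm^6
precision weight:      1.332e-03 / mm^6
precision: t = -13.81, p = 0.001
identity : t = -0.93, p = 0.376
```

The phantom's 300 bootstrap replicates spread with variance 750.9 mm^6,
whose reciprocal is that subject's regression weight.  In the cohort, a
modest true volume deficit (-300 mm^3) in the case group is hidden from
ordinary least squares (p = 0.376) by high-volume, low-precision outliers,
while the precision-weighted test detects it decisively (p = 0.001) — the
outliers carry inflated error variance and therefore tiny weights.

## Command line

```sh
atlasboot simulate-scene  --out-dir scene/ --n-atlases 35 --shift-sd 1.5 --seed 1
atlasboot bootstrap-weights --target scene/target.nii.gz --atlas-dir scene/ \
    --out weights.csv --n-replicates 300 --seed 1
atlasboot simulate-cohort --out cohort.csv --n-per-group 80 --group-effect -300 \
    --outlier-rate1 0.2 --seed 1
atlasboot test --cohort cohort.csv --out result.json --scheme precision
atlasboot experiment-type1 --controls cohort.csv --out rates.csv
atlasboot experiment-power --group0 g0.csv --group1 g1.csv --out power.csv
```

Images are NIfTI-1; cohorts, weights and experiment results are CSV;
volumes are mm^3 throughout (`--report-cm3` converts on output).  Every
run writes a provenance JSON with the config hash, seed and package
version.

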