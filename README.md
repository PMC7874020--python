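# epinet

Seed-based mapping of **negatively correlated epilepsy networks** from
resting-state BOLD fMRI, with the cohort-level statistics used to relate
those networks to epilepsy-surgery outcome and cognition.

## The problem and who this is for

In temporal lobe epilepsy, brain regions whose resting BOLD signal is
*anticorrelated* with the hypothesized epileptogenic zone (EZ) form a
network of their own. How tightly that network hangs together
(intraconnectivity) and how far it sprawls from the EZ (spread) are
candidate non-invasive prognostic markers for post-surgical seizure
freedom. `epinet` implements that analysis as a reusable pipeline for
imaging researchers: per-patient network mapping from NIfTI volumes, the
two network summary statistics, and the cohort statistics layer (group
comparisons, rank correlations with multiplicity control, ROC
prognosis). Because patient imaging of this kind is rarely shareable, a
first-class synthetic-data module generates scans with planted networks
and cohorts with controllable effect sizes, so every stage is testable
end to end.

## The model

Given a 4-D BOLD image, a brain mask, and an EZ seed mask (all
co-registered; registration is out of scope):

1. **Preprocess** — smooth each volume with an isotropic-in-mm Gaussian
   (FWHM 8 mm default) and grand-mean scale the in-brain signal to 100.
2. **Map** — extract the seed series as the spatial mean over seed
   voxels, then compute Pearson *r* between every in-brain voxel's
   series and the seed series.
3. **Threshold** — the negatively correlated network is every voxel with
   *r* < −0.4 (strict; seed voxels excluded). A positively correlated
   network uses *r* above the patient's mean correlation.
4. **Summarise** — for a network with voxel series *x₁…x_N*:
   * *intraconnectivity* = mean of all pairwise Pearson correlations
     between distinct member voxels, computed by the closed form
     ( ‖Σᵢ zᵢ‖² − N ) / (N(N−1)) with zᵢ the unit-normalised centred
     series (identical to the explicit all-pairs average);
   * *spread* = median Euclidean distance (mm) of member voxel centers
     from the seed-mask centroid.
5. **Cohort statistics** — pooled two-sample *t*-tests by outcome group,
   Spearman ρ against neuropsychological scores with Bonferroni
   correction, post-minus-pre difference scores, demographics summaries,
   and an ROC analysis of seizure freedom predicted by network
   intraconnectivity (AUC with DeLong 95% CI; Youden, max-sensitivity
   and max-specificity operating thresholds).

A matched-size contiguous random control ROI (907 voxels by default) can
replace the EZ seed to show the mapped network is seed-specific.

## Worked example

```python
import numpy as np
from epinet import NegativeNetworkModel, CohortOutcomeModel, VoxelMask
from epinet.synthetic import default_scan_spec, generate_scan

# synthetic scan: 27-voxel seed, 200-voxel planted anticorrelated
# network with loading -0.7, T = 300
spec = default_scan_spec(n_timepoints=300, rng_seed=1)
img, truth = generate_scan(spec)
brain = VoxelMask(np.ones(spec.grid_shape, bool), spec.affine, "brain")

res = NegativeNetworkModel(img, truth.seed_voxels, brain,
                           smooth_fwhm_mm=None).fit()
print(res.summary())
```

```
Negatively correlated epilepsy network — patient summary
==========================================================
seed voxels:            27
brain voxels:           8000
zero-variance excluded: 0

network     thresh  voxels  intraconn  spread_mm
negative    -0.400     200     0.4542       61.2
positive    -0.010    4401     0.0022       56.4
```

The negative network recovers exactly the 200 planted voxels, and its
intraconnectivity 0.4542 sits near the one-factor expectation
w² = (−0.7)² = 0.49; spread is the median mm distance of those voxels
from the seed centroid.

```python
from epinet.synthetic import generate_cohort, CohortSpec
cohort = CohortOutcomeModel(generate_cohort(CohortSpec(rng_seed=0)),
                            neuropsych_columns=["VR-I_pre"]).fit()
print(cohort.summary())
```

```
Cohort outcome analysis
==========================================================
patients: 19
  seizure free = Yes: 12 (63%)
  seizure free = No: 7 (37%)

intraconnectivity by outcome (pooled t-test):
  t = 7.3000, p = 1.241e-06 (n = 12/7, mean diff = 0.2186)

ROC (higher intraconnectivity => predicts seizure freedom):
  AUC = 1.000 (95% CI 1.000-1.000)
  thresholds: youden = 0.2688, max sens = 0.1103, max spec = 0.2688

Spearman rho vs intraconnectivity (Bonferroni-adjusted):
  VR-I_pre     rho = +0.958, p = 1.214e-10, adj p = 1.214e-10 (n = 19)
```

This simulated 12/7 cohort has a 2-SD group separation, so the group
difference is strongly significant and the in-sample ROC separates
perfectly; the Spearman row reflects the planted linear link between
connectivity and the memory score.

The same steps are available from the shell:

```bash
epinet synth scan --seed 1 --out scan/
epinet run-patient --id P01 --bold scan/bold.nii --brain scan/brain.nii \
    --seed scan/seed.nii --out out/
epinet synth cohort --seed 0 --out cohort.tsv
epinet stats roc --table cohort.tsv
```

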