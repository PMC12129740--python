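# mtlnet

Seed-based medial temporal lobe (MTL) network connectivity pipeline with
synthetic ground truth.

Two functional systems converge on the MTL: the anterior-temporal (AT)
network, hubbed on the perirhinal cortex, and the posterior-medial (PM)
network, hubbed on the parahippocampal cortex.  Their connectivity
changes along both normal ageing and the Alzheimer's continuum, and
disentangling the two requires a pipeline that (i) derives AT/PM network
masks from seed-based resting-state fMRI with permutation inference,
(ii) reduces each scan to interpretable per-participant connectivity
indexes, and (iii) models those indexes longitudinally against age,
clinical stage, biomarkers and time to dementia onset.  `mtlnet`
implements that pipeline end to end and — because the reference cohort
is not publicly deposited — ships a synthetic-data generator whose
planted parameters serve as recoverable ground truth.  It is aimed at
methods researchers who want a fully testable, desk-scale replica of
this class of analysis.

## What it computes

* **Connectivity maps**: Pearson r between a seed's mean BOLD series and
  every grey matter voxel, Fisher-transformed (z = atanh r), after 4 mm
  smoothing, 0.01–0.08 Hz bandpass and WM/CSF/global/motion confound
  regression; scans with > 3 mm translation or > 1.5° mean rotation are
  excluded.
* **Network masks**: one-sample and paired sign-flip permutation t-tests
  with threshold-free cluster enhancement, TFCE(v) = Σ_h e(h,v)^0.5 h² dh,
  and max-statistic FWE correction (P_FWE < 0.05);
  AT = PRC-one-sample ∩ (PRC > PHC), PM = PHC-one-sample ∩ (PHC > PRC).
* **Indexes**: mean of positive Fisher-z values inside participant-specific
  masks (group mask ∧ GM ≥ 0.5, seeds removed), from unsmoothed maps.
* **Models**: REML linear mixed models with by-participant random
  intercepts and Satterthwaite Type II/III F-tests; ranked-group
  penalized-spline smooths (k = 6, REML-selected, effective df = 1 ⇔
  linear); baseline ANCOVA with estimated-marginal-mean contrasts;
  Holm–Bonferroni over the 10-test biomarker/cognition family.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_derive_network_masks.py
python analysis/03_fit_cohort_models.py
python analysis/04_recover_planted_effects.py
```

`02` synthesises 20 subjects' BOLD with seed-network loadings of 0.8,
runs preprocessing, mapping and permutation inference, and prints:

```
recovered AT mask: 3905 voxels (planted 2520), Dice = 0.786
recovered PM mask: 3920 voxels (planted 2520), Dice = 0.785
retained 20/20 subjects after motion QC
mean extracted AT index: 1.212 (Fisher z, positive-voxel mean)
```

The recovered masks are the planted networks plus the ~2-voxel halo
produced by 6.3 mm group smoothing — hence Dice ≈ 0.79 rather than 1.0
(see `docs/methods.md`).  `03` fits the full statistical suite on the
261-participant table-mode cohort:

```
age_AT         beta = +0.00100 [+0.00037, +0.00163]  (planted +0.00030)
age_PM         beta = -0.00089 [-0.00117, -0.00062]  (planted -0.00070)
converter_AT   beta = -0.01408 [-0.01587, -0.01229]  (planted -0.01360)
association family: 4/10 Holm-significant (assoc_AT_amyloid_suvr,
assoc_AT_hippo_z, assoc_AT_mmse, assoc_AT_mdrs)
```

i.e. with every effect planted at once the correlated biomarkers compete
for variance, yet the AT-specific associations and the PM age decline
come out signed correctly and the PM family stays null.  `04` reruns the
clean single-effect recovery benchmarks (each planted coefficient vs the
CI of its matching design).

A `mtlnet` command-line wrapper (`mtlnet simulate|stats|run-all|validate`)
exposes the same stages for shell use.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the coefficient-recovery benchmarks from scratch: it simulates
the targeted single-effect cohorts (200 unimpaired adults for the PM age
slope; 114 older participants for the amyloid, hippocampal-volume and
MMSE associations; 50 replicates of 18 MCI converters for the
delay-to-onset slope), fits the corresponding mixed-model designs, and
writes each recovered coefficient with its sample size as JSON.
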