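# patshortcut

An audit pipeline for **shortcut learning and sex bias in medical image
classifiers**, built around photoacoustic-tomography-style peripheral artery
disease (PAD) diagnosis and exercisable end-to-end on a bundled synthetic
phantom generator.

## The problem

Image classifiers can exploit demographic features that *correlate* with a
diagnosis instead of the physiology that *causes* it. In photoacoustic calf
images, sex manifests superficially (skin/fat layer thickness) while PAD
manifests in vascular features. If a training set over-represents diseased
males, a CNN can learn "thin superficial band ⇒ diseased" — a shortcut that
collapses the moment the deployment population has a different sex-disease
mix, and that systematically underdiagnoses the sex that was underrepresented
among the diseased.

The pipeline quantifies this with four linked experiments, controlled by a
single dial: the **sex-specific prevalence ratio**

```
PR = P(diseased | male) / P(diseased | female),
```

with PR = ∞ meaning every diseased subject is male. Datasets stay sex- and
disease-balanced in total, so for a split of even size *n* the four
sex×disease stratum counts are uniquely determined by
`fd = n / (2(1+PR))`, `fh = n/2 − fd`, `md = PR·fd`, `mh = n/2 − md`
(non-integer solutions are rejected, not rounded).

The audit measures:

1. **Separability** — can an ensemble decode sex at all (and across body
   sites)?
2. **Prevalence shift** — a train-PR × test-PR matrix of PR-stratified
   bootstrap AUROCs (resampling draws fixed per-stratum counts with
   replacement, so every replicate respects the target PR).
3. **Underdiagnosis disparity** — `FN_F/FP_F − FN_M/FP_M` over repeated
   independently trained ensembles on the full test pool; positive values
   mean females are disproportionately missed.
4. **Representations** — frozen-encoder head transfer between the sex and
   disease tasks, and exact 2-D Wasserstein distances between PCA-projected
   subgroup feature clouds of balanced vs extreme-PR models.

Because no clinical photoacoustic cohort is publicly deposited, the package
ships a generator whose sex pathway (superficial band thickness), disease
pathway (vessel-like blobs) and *shared* component (the shortcut dial,
`overlap`) are explicit, so every phenomenon above can be switched on and
off. See `docs/methods.md` for the model details.

## Worked example

```bash
patshortcut rq1 --profile fast --seed 7 --out results/
```

trains sex and disease ensembles at PR = 1 on a synthetic calf cohort
(pools of 86/21/40 subjects), evaluates them with stratified bootstrap
(95 % CIs), and applies the sex ensemble to freshly generated healthy-
volunteer cohorts at three body sites. The written `rq1.json` contains:

```
in_distribution.sex      mean AUROC 0.875  [0.708, 0.983]
in_distribution.disease  mean AUROC 0.863  [0.704, 0.969]
ood_sex.calf             mean AUROC 0.784  [0.601, 0.955]
ood_sex.forearm          mean AUROC 0.753  [0.480, 0.924]
ood_sex.neck             mean AUROC 0.517  [0.309, 0.750]
```

Sex is decodable from the images (CI excludes 0.5) at about the same level
as the disease itself — the precondition for shortcut learning — and the sex
classifier transfers to unseen body sites with site-dependent degradation.
`patshortcut rq2|rq3|rq4` run the remaining experiments; `--profile paper`
uses the full protocol constants (ensembles of 10, 1000 bootstrap
iterations, 1000 representation draws), `--profile fast` is the desk-scale
profile used by the test suite. Every report is a pure function of
(config, `--seed`): reruns are byte-identical.

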