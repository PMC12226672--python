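# Methods

This note documents the models, statistics and design choices behind
`patshortcut`, in the spirit of the methods documentation of simulation and
statistics packages. Nothing here reports an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Synthetic phantom generator (`synthgen`)

Each subject is one multi-channel 2-D intensity image (default 3 channels,
emulating a three-wavelength acquisition via fixed per-channel absorption
weights) plus binary sex (F/M) and disease (H/D) labels. The image is a sum
of four components, clipped to non-negative intensities:

* **Baseline site texture** — a flat site-dependent intensity plus a
  low-frequency Gaussian random field. The three site profiles
  (calf / forearm / neck) differ *only* in baseline statistics, never in how
  the labels manifest, which is what makes the out-of-distribution body-site
  experiment meaningful.
* **Sex pathway** — a bright superficial band whose thickness is
  `H/8 + s·sex_effect·H/32 + N(0, H/18)` rows (`s = +1` for F, `−1` for M),
  with a soft one-pixel lower edge. The jitter scale `H/18` was set so that
  at `sex_effect = 1` a small CNN reaches sex AUROCs in the high-0.7s to
  low-0.9s across seeds — the moderate-separability regime in which sex is a
  usable but not trivial shortcut. (An earlier, tighter jitter made sex
  nearly perfectly decodable; prevalence-biased models then predicted
  *zero* female false positives and the disparity statistic degenerated.)
* **Disease pathway** — vessel-like axis-aligned elliptical blobs below the
  band. Diseased subjects have fewer (`λ = 5(1 − 0.20·d·disease_effect)`,
  count noise sd 0.8), dimmer (amplitude `0.5(1 − 0.25·d·disease_effect)`,
  jitter 0.04) and smaller (size factor `1 − 0.10·d·disease_effect`) blobs,
  emulating reduced perfusion. Blob semi-axes are U(2,4) px at 64-px scale so
  the signal survives 32-px desk-scale images; the count noise is sub-
  Poissonian because raw Poisson counts at λ≈5 drown the class difference.
* **Shared component** — a mid-depth horizontal stripe with amplitude
  `0.05·overlap·(s·sex_effect + d·disease_effect) + overlap·N(0, 0.01)`.
  This is the shortcut dial: it responds to *both* labels, so sex and
  disease encodings become partially interchangeable. The coefficient 0.05
  is a deliberate compromise: at ~0.08 the stripe dominates learning and a
  balanced-trained model loses its robustness to test-PR shifts (the stripe
  cannot distinguish a healthy female from a diseased male); at ~0.03 the
  sharing is too weak for two-member ensembles to show cross-task transfer.

Invariants by construction: `sex_effect = 0` makes F and M images
identically distributed (every sex term carries a factor `sex_effect`);
likewise `disease_effect = 0` for H vs D; `overlap ∈ {0, 1}` are both valid.
One root seed sequence per pool is split per subject by counter, so subject
*i* is reproducible independent of generation order.

**What the generator does not emulate:** photoacoustic wave propagation,
optical fluence, skin tone, realistic vascular anatomy, or covariates such
as age. Passing tests therefore demonstrate that the *pipeline* detects the
audited phenomena when they are present and stays silent when they are
absent — not that any particular clinical dataset exhibits them.

## Sampling design (`sampling`)

The prevalence ratio is attached to counts (`PR = md/fd`), which coincides
with the proportion definition because sex totals are balanced. For split
totals 48/12/24 the solver reproduces the full published design table at
PR ∈ {1, 2, 5, ∞}; infeasible pairs (e.g. total 48 at PR = 4) raise rather
than round, since rounding would silently change the experimental condition.

Pools of 86/21/40 subjects use stratum compositions (24,19,19,24),
(6,5,4,6), (10,10,10,10) — near-even, and chosen so every PR in the grid is
drawable *without* replacement from the train and validation pools (PR = ∞
training needs 24 F-H and 24 M-D). Test-side evaluation resamples *with*
replacement, so 10 per stratum suffices there. `stratified_split` implements
confounder matching for user-supplied cohorts: floor quotas per
stratum×split plus a balance-aware greedy placement of leftovers that keeps
every cell within one subject of exact proportionality.

## Classifier and training (`modeling`)

The backbone is a small convolutional network written directly in numpy
(no neural-network library is required): three 3×3 conv blocks
(8/16/16 channels) with average pooling, pooled into a 256-vector, an affine
layer to a `d_feat = 32` feature vector (ReLU), and a single affine sigmoid
head. Training is minibatch Adam (lr 3·10⁻³, batch 16) on binary
cross-entropy with early stopping on validation loss (best-epoch snapshot
kept). Hyperparameters were tuned manually once on the balanced-PR disease
task and then frozen for all tasks and PRs. Pure-numpy float64 arithmetic on
one CPU makes every run bit-deterministic given its seed.

Ensembles (default 10 members; 2 in the fast profile) give each member its
own PR-preserving draw of training and validation sets and its own
init/batching seed; predictions aggregate by the arithmetic mean of member
probabilities. Transfer analysis (`retrain_head`) freezes the encoder
bit-identically and refits only the affine head — a logistic regression in
feature space — on the new task's labels; same-task refitting is allowed as
a self-consistency control.

## Evaluation (`metrics`)

* **AUROC** is the pairwise probability statistic (ties ½), delegated to
  scikit-learn; an exhaustive pair-enumeration oracle guards it in the tests.
* **Stratified bootstrap**: subject scores are computed once; each of
  `n_iter = 1000` iterations (100 in the fast profile) redraws the target
  PR's per-stratum counts with replacement and recomputes AUROC. Reported:
  mean and percentile 2.5/97.5 bounds. Iterations that happen to contain a
  single class are skipped and counted.
* **Underdiagnosis disparity** = `FN_F/FP_F − FN_M/FP_M` on predictions
  binarized at 0.5 (threshold configurable). When either sex has zero false
  positives the statistic is reported as undefined rather than smoothed —
  the formula has no correction, and silent smoothing would change it; an
  optional epsilon flag exists but is off by default. The disparity
  experiment trains a fresh ensemble per run (default 10 runs; 5 in the fast
  profile) and always evaluates on the entire 40-subject test pool.

## Representation analysis (`representation`)

For a balanced-trained (PR = 1) and an extreme-PR (PR = ∞) disease model —
each the ensemble member with test AUROC closest to the member median, ties
to the lowest index — the experiment draws balanced subsets (7 per stratum,
28 subjects) from the test pool over many runs (default 1000; 50 in the fast
profile), refits a 2-component PCA on each subset's penultimate features
(centered, not variance-scaled; component signs fixed by making the largest
loading positive), and computes the exact order-2 Wasserstein distance
(uniform weights, Euclidean ground metric) between the projected F/M clouds
and H/D clouds. Equal-size sets are solved by linear assignment, unequal
sizes by the transportation LP; the order is configurable. The
representative run is the one whose (w_sex, w_disease) pair is closest to
the geometric median (Weiszfeld with the Vardi–Zhang coincident-point
correction, tolerance 10⁻⁹) of all runs' pairs. A degenerate (rank < 2)
feature cloud is treated as a point mass with zero subgroup distances.

Raw (unscaled) Wasserstein values are only meaningfully comparable across
models that share a feature scale; with from-scratch backbones part of a
cross-model difference can reflect overall feature magnitude. The audit's
directional claim (stronger sex separation in the PR = ∞ model) holds at
the frozen study conditions either way.

## Experiments, profiles and seeds (`experiments`)

`ExperimentConfig` collects every protocol constant and validates the whole
PR grid (integer stratum counts, pool feasibility) before any training.
Two named profiles exist: `paper` (64×64 images, ensembles of 10,
n_iter 1000, 10 disparity runs, 1000 representation runs) and `fast`
(32×32, ensembles of 2, n_iter 100, 5 disparity runs, 50 representation
runs, 30 epochs max). The fast profile is the problem size used by the test
suite and the acceptance script; it was sized so the full suite trains a few
hundred small networks in minutes while leaving every audited phenomenon
detectable.

All randomness derives from one master seed through named stream paths
(generation / sampling / training / bootstrap / subset draws), so reports
are byte-identical across reruns and no two stages share a stream. Reports
are JSON (sorted keys, no timestamps) plus long-form CSVs per figure-analog;
plotting is intentionally out of scope — numbers are the contract.

## Known limitations

* The generator's feature families are statistical stand-ins; absolute
  AUROC or Wasserstein values have no clinical meaning, only their ordering
  and responses to the dials do.
* The disparity statistic is undefined whenever a sex has no false
  positives; with a 40-subject pool and well-calibrated extreme-PR models
  this occurs in a minority of runs and is reported, not imputed.
* Confounders other than sex and disease (age, comorbidities) are neither
  simulated nor matched.
* The fast profile's two-member ensembles make per-seed outcomes noisier
  than the ten-member protocol; the phenomenon tests therefore assert
  majorities over fixed master-seed panels rather than single-run outcomes.
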