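# Methods

## Problem and scope

`plexuq` evaluates *stochastic* voxel-wise segmentation of thin, low-contrast
brain structures — the motivating case is the choroid plexus, a bright
curvilinear structure inside the dark lateral ventricles on T1-weighted MRI.
A deterministic segmentation network gives one mask per subject and no sense
of its own reliability; making inference stochastic (Monte-Carlo dropout
inside each member of a model ensemble) yields a *distribution* of
segmentations whose dispersion can be decomposed, quantified per subject,
and compared across cohorts to detect when a model is being applied to data
unlike what it was trained on.

The package does not train or run segmentation networks.  Its input is
either (a) stacks of per-sample probability volumes in NIfTI, or (b) any
callable `predictor(image, member, seed) -> probability volume` obeying the
determinism contract.  Everything downstream of the network — sampling
orchestration, the uncertainty maps, consensus masks, accuracy metrics,
cohort statistics and QC flagging — is implemented and testable end to end
on synthetic phantoms.

## Stochastic sampling

A sampling scheme is M ensemble members × K dropout realizations per
member, S = M·K samples per subject.  Two presets are provided: the full
scheme 5 × 20 = 100 samples, and a lighter cohort-scale scheme
("abide-light") 5 × 5 = 25 samples.  Per-(m, k) seeds are derived from the
scheme's base seed with numpy `SeedSequence` spawn keys, so results are
independent of execution order and parallelizable without change.

Per-voxel moments are accumulated streamingly — Σp, Σp², ΣH(p) — so memory
stays at three volumes regardless of S, and these three sums are sufficient
statistics for all four uncertainty maps.

## Uncertainty maps and the BALD decomposition

With p̄(v) the mean predicted probability over the S samples and H(·) the
binary entropy in nats:

* total predictive entropy  H_total(v) = H(p̄(v))
* expected per-sample entropy  E_s[H_s](v) = (1/S) Σ_s H(p_s(v))
* mutual information  MI(v) = H_total(v) − E_s[H_s](v)
* predictive standard deviation  σ(v) = sqrt((1/S) Σ_s (p_s − p̄)²)

MI is the BALD disagreement criterion: it is zero when all samples agree
and grows with inter-sample disagreement, and serves as the epistemic
(model-knowledge) component; E_s[H_s] is the aleatoric proxy — the
uncertainty that remains even in the average sample.  The identity
H_total = E_s[H_s] + MI holds exactly by construction and is verified to
1e-12 per voxel in tests.

Each map is aggregated per subject as C = Σ U·b / Σ b over a binary mask b,
by default the subject's own consensus segmentation (mean map thresholded
at 0.5).  An empty aggregation mask is an error, never a silent zero.

Numerical choices:

* Natural log throughout; the entropy ceiling is ln 2 ≈ 0.693.
* 0·ln 0 is handled analytically via `xlogy` (the term contributes 0); we
  deliberately avoid ε-clamping probabilities, which would bias
  near-confident voxels.
* MI is clamped below at 0 after computing the raw difference; negative
  values are analytically impossible and can only arise from round-off.
  Values below −1e−9 trigger a warning because they indicate the two input
  maps did not come from the same sample set.
* σ is computed from streaming moments as sqrt(max(0, Σp²/S − p̄²)).  The
  max(0, ·) guards round-off; note that when all samples are identical the
  cancellation leaves a residue of order sqrt(machine-ε · p²) ≈ 1e-8, so
  "σ = 0" assertions in the noise-free limit are made at 1e-6 in
  probability units rather than exactly.

## Consensus segmentation and accuracy metrics

The probabilistic consensus binarizes the mean map at τ = 0.5 (a voxel
exactly at τ is foreground); the deterministic-ensemble consensus is
majority vote (strictly more than half the members; an even-count tie maps
to background — conservative under-segmentation).  For odd member counts
and binary member masks the two constructions coincide, which the tests
exploit as an oracle.

Accuracy against ground truth: Dice 2|A∩M|/(|A|+|M|) (both masks empty →
1.0 with a warning, exactly one empty → 0.0); symmetric Hausdorff distance
between boundary-voxel centers in world mm (boundary = any 6-neighbor
background; HD95 = 95th percentile of the pooled directed surface
distances); volume similarity 1 − |V_A − V_M|/(V_A + V_M); Pearson
correlation of volumes across subjects.  All distances use the image
affine, so anisotropic voxels are handled correctly.  A threshold sweep
reports Dice(τ) per subject and cohort mean.

## The synthetic phantom and its generative model

A phantom is two dark ellipsoidal "ventricles" (default semi-axes
7×10×12 voxels) in mid-intensity background, each threaded by a thin
bright tube (radius 1.5 voxels) along a curvilinear path held strictly
inside the ellipsoid — reproducing the geometry that makes the real
segmentation hard: a thin target whose boundary voxels dominate its
volume.  Default grid 48³ at 1 mm isotropic; intensities
plexus 160 > background 100 > ventricle 40, additive Gaussian noise SD 5.
These values give a clearly learnable but noisy target, roughly the
contrast ordering of a T1 image.

The parametric stochastic predictor draws logits

    logit p_{m,k}(v) = μ(v) + δ_m(v) + ε_{m,k}(v)

with μ(v) = a·clip(d(v)/(w + 0.5), −1, 1), where d is the signed Euclidean
boundary distance in voxels (positive inside the structure), a is the
confidence (default 4), and w the boundary-softening width (default 1
voxel, modelling partial-volume ambiguity; w = 0 gives a hard ±a step).
δ_m is drawn once per member (SD σ_epi) and held constant across
realizations — this is what makes it register as epistemic, i.e. as
inter-member disagreement and hence mutual information.  ε_{m,k} is drawn
fresh per realization (SD σ_ale) and inflates the per-sample entropy.
Both are Gaussian fields optionally smoothed to a correlation length
(default 1.5 voxels) and rescaled to preserve their marginal SD.
Logit-additive noise was chosen over probability-space noise because it
maps smoothly into [0, 1] without clipping artifacts.

What the simulator does *not* emulate: MRI physics (bias fields, k-space
artifacts), anatomical variability beyond size/contrast scaling, spatially
heterogeneous noise, or any real relationship between image appearance and
predictor behaviour (the parametric predictor reads the truth mask, not
the image).  Passing tests therefore demonstrate that the *estimators*
behave correctly under a known generative model — not that any particular
network is well calibrated on real MRI.

### Regimes of the decomposition-recovery study

The central validation varies σ_epi and σ_ale over the grid
{0.25, 0.75, 1.25, 1.75} (20 subjects per cell, 5×5 sampling) and requires
cohort-mean masked MI to increase strictly with σ_epi at every σ_ale and
cohort-mean E_s[H_s] to increase strictly with σ_ale at every σ_epi
(Spearman ρ = 1 along every slice).  Two regime choices make this
structurally sound rather than accidental:

* The grid maximum combined noise sqrt(1.75² + 1.75²) ≈ 2.47 stays below
  the confidence a = 4.  The curve s ↦ E[H(expit(a + sZ))] increases up to
  s ≈ a − 0.5 and then turns over (noise pushes logits into saturation);
  Gauss–Hermite quadrature of this curve locates the turnover at s ≈ 3.5
  for a = 4.
* The study runs with w = 0 (hard boundary), so every structure voxel
  carries the full signal a.  With softening, shell voxels carry weaker
  signal (μ ≈ 2.7 at the default w) whose entropy response turns over at
  s ≈ 1.9 — inside the grid — which would break monotonicity in the
  high-noise corner for reasons that have nothing to do with the
  estimators under test.

By the same quadrature analysis, MI > E_s[H_s] (epistemic dominance in
absolute terms) requires members that are individually confident but
mutually disagreeing, i.e. σ_epi well above a; the corresponding test uses
(a = 4, σ_epi = 8).  At σ_epi comparable to a, many member logits land
near 0 and per-sample entropy remains the larger term even though MI
responds to σ_epi.

### Cohort presets

Three presets emulate an in-distribution cohort and two progressively
shifted ones: `local-like` (σ_epi = 0.3, σ_ale = 0.4), `shifted-adult`
(σ_epi = 0.9), and `shifted-child` (σ_epi = 1.6, plus contrast scaled to
0.6 and structure size to 0.8 — smaller ventricles with weaker contrast,
the partial-volume-dominated regime).  The presets are illustrative
orderings, not calibrated effect sizes.  Subjects within a group differ by
derived seeds (noise realizations and predictor fields); diagnoses
alternate ASD/CON and sites cycle, so the labels round-trip through the
cohort table without implying any biological claim.

## The toy dropout classifier

To exercise *real* dropout (rather than its parametric emulation), a
one-hidden-layer tanh MLP over four per-voxel features (intensity, two
Gaussian smooths, local SD) is trained by Adam on balanced voxel samples
from two phantoms, with unit-level dropout active during training and
inference.  The dropout mask drops hidden units per forward pass, shared
across voxels — the analogue of channel dropout in a convolutional net —
so each stochastic pass perturbs the segmentation coherently.

The architecture is deliberately small: 4 hidden units and weight decay
0.03.  With a wide, unregularized layer the fitted logits saturate and
unit dropout barely moves the output probabilities; with moderate logits,
the dropout-induced dispersion lands on the scale of the theoretical
"uncertainty floor", which grows like p/(1 − p) for dropout rate p.  At
p = 0.1 on held-out phantoms the model reaches Dice 1.0 with masked C_σ
around 0.06–0.08, inside the loose floor band [0.02, 0.2], and C_σ is
non-decreasing over p ∈ {0.1, 0.25, 0.4, 0.5}.

## Cohort analysis and QC flagging

Group summaries report mean and interquartile range (linear-interpolation
quantiles).  Contrasts use Welch's unequal-variance t-test (group variances
differ materially between shifted and unshifted cohorts), corrected across
contrasts with Benjamini–Hochberg FDR.  Mixed-effects modelling with a
site random intercept is intentionally out of scope; the site label is
carried in the cohort table so users can export to any stats environment.

Two screening heuristics flag prospective subjects against a reference
cohort: Tukey fences Q1 − f·IQR, Q3 + f·IQR on the aggregate (default
f = 1.5; f = 0 reduces to the literal "outside the IQR" rule, which flags
about half of in-distribution subjects and is provided only for
completeness), and the histogram KL divergence D(new ‖ reference) with 32
equal-width bins over the pooled range and additive smoothing 1e-6
(Jensen–Shannon available as a symmetric option).  No default KL rejection
threshold is shipped; it is a statistic, not a calibrated test.  Both are
most meaningful group-wise: the SD of a group-mean aggregate shrinks like
1/√n, verified empirically over group sizes 5 vs 20.

## Problem sizes and determinism

All studies run on 48³ phantoms (32³ where geometry is not the point) with
the 5×5 sampling scheme unless the full 5×20 scheme is itself under test;
the decomposition study uses 20 subjects per grid cell, the cohort study
20 per cohort, and the null calibration 20 replicates of 10 + 10.  Every
random quantity descends from a single seed through `SeedSequence`, so any
run is exactly reproducible; two runs of the same configuration produce
byte-identical CSV outputs.

## Known limitations

* The aleatoric proxy is inferred at the posterior-predictive level; the
  package does not model likelihood-level noise (multi-head or deep-GP
  style), and with a single sample (S = 1) MI and σ are identically zero.
* Hausdorff distances are between boundary-voxel centers, not sub-voxel
  surfaces; on coarse grids this quantizes distances to the voxel lattice.
* The IQR/KL flags are screening heuristics; their operating
  characteristics depend on the reference cohort's size and homogeneity.
* Synthetic cohorts share phantom geometry up to seed-driven noise and
  size/contrast scaling; they do not span realistic anatomical diversity.
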