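# plexuq

Uncertainty quantification for probabilistic ensemble segmentation of thin
brain structures — built around the evaluation problem posed by automated
choroid plexus segmentation, where the target is a thin, bright,
curvilinear structure inside the dark lateral ventricles and ground-truth
labels are scarce.

When a segmentation model runs stochastically — Monte-Carlo dropout inside
each member of a model ensemble, S = M·K stochastic probability maps per
subject — the dispersion of those samples carries information a single mask
cannot: how confident the model is, and *why*.  `plexuq` takes such sample
stacks (or any deterministic-given-seed predictor callable) and computes,
for each subject:

* **Four voxel-wise uncertainty maps** (natural-log units).  With p̄(v) the
  mean predicted probability and H binary entropy:
  * total predictive entropy H_total(v) = H(p̄(v))
  * expected per-sample entropy E_s[H_s](v) = (1/S)·Σ_s H(p_s(v)) — the
    aleatoric (irreducible) proxy
  * mutual information MI(v) = H_total − E_s[H_s] — the epistemic
    component (the BALD disagreement criterion)
  * predictive standard deviation σ(v)
* **A per-subject scalar per map**, C = Σ U·b / Σ b, averaged over the
  subject's consensus segmentation mask b.
* **Consensus masks and accuracy metrics** against ground truth: Dice,
  Hausdorff / HD95 in mm, volume similarity, volume correlation, and a
  Dice-vs-threshold sweep.
* **Cohort comparisons** (Welch t-tests with Benjamini–Hochberg FDR) and
  **out-of-distribution flagging** of new subjects against a reference
  cohort (Tukey IQR fences, KL divergence).

A synthetic-phantom module generates the entire test bed — phantoms with a
plexus-like tube inside ellipsoidal ventricles, a parametric stochastic
predictor with separately tunable epistemic/aleatoric noise, a small
trainable dropout classifier, and in-distribution vs shifted cohorts — so
the whole pipeline runs end to end with no imaging data.

## Worked example

The `demo` subcommand builds three synthetic cohorts — `local-like`
(in-distribution), `shifted-adult` (more inter-member disagreement) and
`shifted-child` (disagreement plus smaller, lower-contrast structures) —
samples each subject with the 5×5 scheme, and compares the masked
uncertainty aggregates:

```bash
plexuq demo --out-dir demo-run --seed 0 --n 8
```

```
group-mean masked uncertainty:
                   c_mi     c_ehs  c_htotal     c_std
cohort
local-like     0.004804  0.215318  0.220122  0.023232
shifted-adult  0.020051  0.228729  0.248779  0.051900
shifted-child  0.064607  0.253903  0.318509  0.107734

mutual-information contrasts (Welch + FDR):
                      contrast   mean_a   mean_b          t        p_adj  reject
   local-like vs shifted-adult 0.004804 0.020051 -22.231354 8.338062e-08    True
   local-like vs shifted-child 0.004804 0.064607 -27.202993 4.733651e-08    True
shifted-adult vs shifted-child 0.020051 0.064607 -19.356955 4.733651e-08    True
```

Reading the table: total entropy (`c_htotal`) inflates as the cohorts
shift from the in-distribution condition, and the decomposition shows why —
the epistemic component (`c_mi`, mutual information) grows 13-fold from
0.005 to 0.065 while the aleatoric proxy (`c_ehs`) moves only ~18%.  The
inflation is model disagreement, not data noise: exactly the signature of
a model applied outside its training domain.  All three pairwise contrasts
survive FDR correction.

The same machinery is available programmatically:

```python
from plexuq import (PhantomSpec, SimulatorSpec, SamplingScheme,
                    generate_phantom, simulate_predictor, run_sampling,
                    binarize, compute_all, dice)

image, truth = generate_phantom(PhantomSpec(seed=0))
predictor = simulate_predictor(truth, SimulatorSpec(sigma_epistemic=0.9))
scheme = SamplingScheme(members=5, realizations=20, base_seed=0)   # S = 100
summary = run_sampling(predictor, image, scheme, retain_stack=False).finalize()
consensus = binarize(summary.mean_volume(), 0.5)
maps, subject = compute_all(summary, consensus)
print(subject.values, dice(consensus, truth))
```

Other subcommands: `simulate` (write phantoms + cohort CSV), `sample`
(draw a stack to NIfTI + manifest), `uncertainty` (maps + aggregates from a
manifest), `evaluate` (accuracy vs truth, optional threshold sweep),
`cohort` (group contrasts on a per-subject table), `flag` (IQR/KL
screening).  See `plexuq --help`.

## Layout

```
src/plexuq/
  grids.py       voxel grids, scalar volumes, binary masks
  volume_io.py   NIfTI read/write, sample manifests
  sampling.py    M x K orchestration, seeding, streaming moments
  uncertainty.py the four maps + masked aggregation
  seg_metrics.py consensus, Dice, Hausdorff, volume metrics, sweeps
  phantom.py     phantoms, parametric simulator, toy dropout classifier, cohorts
  cohort.py      group summaries, Welch + FDR, IQR/KL flagging
  pipeline.py    config-driven end-to-end runs
  studies.py     reference experiments used by tests and the script
  cli.py         the `plexuq` command
docs/methods.md  model, assumptions, parameter choices, limitations
```
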