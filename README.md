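# fateplane

A geometric ("gene-free") model of vulval cell-fate specification in
*Caenorhabditis elegans*, for quantitative developmental biologists who
want to simulate, fit, and interrogate cell-fate decisions without a
molecular network model.

During vulval induction, five equivalent precursor cells (P4.p--P8.p)
read a graded EGF signal from the anchor cell and lateral Notch signals
from each other, and each commits to one of three fates (1°: strongly
EGF-induced; 2°: Notch-induced; 3°: uninduced default) -- the invariant
wild-type pattern 3°2°1°2°3°. `fateplane` represents each cell as a point
**r** in an abstract 2-D *fate plane* evolving by the stochastic equation

    dr/dt = (1/τ) [ σ₁( f(r) + m₀ + l₁ m₁ + l₂ m₂ ) − r ] + η(t)

where `f(r) = 2r + (−2xy, y² − x²)` is a threefold-symmetric flow whose
three attracting valleys are the fates, `σ₁(v) = tanh(‖v‖) v/‖v‖` bounds
the dynamics, `m₁`/`m₂` are the EGF and Notch response vectors weighted by
the received ligand levels `l₁`/`l₂`, and η is white noise
(⟨η_i η_j⟩ = 2D δ_ij δ(t−t′)) accounting for partially penetrant
phenotypes.  Notch ligand production switches on across a line in the
plane, L₂(r) = (1 + tanh 2(n₀ + n₁·r))/2, giving state-dependent lateral
and autocrine signaling.  Experimental perturbations (EGF doses, ectopic
NICD, RNAi, receptor mosaics, anchor-cell ablations, timed pulses) enter
as declarative conditions that modulate `l₁`/`l₂` -- there are no
parameters coupling the two pathways.

The package provides:

* **Simulation** -- vectorized Euler--Maruyama ensembles over the
  competence period, attractor identification, fractional fate scoring.
* **A strain registry** -- the classical genetics and the quantified
  EGF/Notch perturbation lines (JU1107, JU1100, CB1417, JU2039, JU2064,
  crosses, ablation series) with measured or fitted signal levels.
* **Bayesian fitting** -- a variance-normalized chi-square likelihood on
  fate proportions, frozen common random numbers, screened multi-start
  Levenberg--Marquardt, and ensemble MCMC; exposed both as functions and
  as a scikit-learn-style estimator (`GeometricFateModel.fit/predict`).
* **Phase diagrams** -- EGF × Notch grid scans with pattern domains,
  partial-penetrance boundaries, and triple-point detection.
* **Synthetic data** -- multinomial fate-count generation and
  parameter-recovery experiments.

See `docs/methods.md` for the model, priors, numerical choices, and the
calibration of the noise convention.

## Worked example

Simulate the JU2092 cross (2.75× WT EGF with mild ectopic Notch, +0.05):

```python
>>> import fateplane as fp
>>> params = fp.get_preset("main")
>>> props = fp.run_condition(params, fp.build_condition("JU2092"),
...                          n_runs=4000, seed=42)
>>> print(props.pattern())
32123
>>> print((props.p * 100).round(1))
[[  0.5  38.3  61.2]
 [  7.   92.6   0.4]
 [100.    0.    0. ]
 [  7.3  92.4   0.2]
 [  0.7  38.8  60.5]]
```

Rows are P4.p...P8.p, columns the percent of animals adopting the 1°, 2°,
3° fate.  P6.p is always primary, P5/7.p secondary, and -- the epistatic
surprise this line exhibits experimentally -- the outer cells P4/8.p are
partially converted to 2° (38%) even though no neighbor is stably 1°:
excess EGF sends P5/7.p *through* the primary territory, where they
transiently produce Notch ligand that synergizes with the ectopic NICD.

The same model from the command line:

```sh
fateplane simulate --strain JU2092 --n-runs 4000 --seed 42 --out ju2092.tsv
fateplane phase --preset main --grid "0:6:31,0:2:21" --n-runs 300 \
    --out grid.tsv --plot grid.png
```

The `phase` command also prints detected triple points -- dose
combinations where a single cell can adopt all three fates, e.g. the
predicted sensitized point near wild-type EGF and ~0.3× WT Notch where
P5/7.p outcomes split three ways.

Refit the model to the packaged training data and sample the posterior:

```sh
fateplane fit --out fit.json            # screened multi-start LM, a few minutes
fateplane sample --fit-report fit.json --n-steps 300 --out posterior.json
```

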