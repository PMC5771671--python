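# Methods

`fateplane` implements a geometric ("gene-free") model of vulval precursor
cell (VPC) specification in *C. elegans*: five equivalent cells
(P4.p--P8.p; P3.p is excluded as less competent), each described not by
gene-expression levels but by a single point moving in an abstract
two-dimensional **fate plane** whose three attracting valleys are the
terminal fates (1st, induced by anchor-cell EGF; 2nd, induced by lateral
Notch signaling; 3rd, the uninduced default).

## The model

Each cell's state `r = (x, y)` obeys the stochastic differential equation

    dr/dt = (1/tau) [ sigma1( f(r) + m ) - r ] + eta(t)

* `f(r) = 2r + (-2xy, y^2 - x^2)` is a polynomial flow with exact
  threefold symmetry -- the minimal flow with three stable outflow sectors.
* `sigma1(v) = tanh(|v|) v/|v|` bounds the dynamics: together with the
  linear `-r` term it confines trajectories to the unit disk and produces
  three attractors separated by saddles.
* `m = m0 + l1*m1 + l2*m2` tilts the landscape: `m0` is a constant bias
  toward the default fate (angle fixed at 210 deg), and `m1`, `m2` are the
  EGF and Notch response vectors, combined *linearly* in the received
  ligand levels `l1`, `l2`. All nonlinearity lives in `sigma1`; there are
  no parameters coupling the two pathways (but see "Coupling" below).
* `eta` is isotropic white noise with diffusion coefficient `D`
  (`<eta_i(t) eta_j(t')> = 2 D delta_ij delta(t - t')`), the source of
  partial penetrance.

EGF arrives as a fixed exponential gradient `l1 = lambda {g^2, g, 1, g,
g^2}` centered on P6.p (`g = gamma`), plus optional uniform ectopic EGF
`delta_l`. Notch ligand production by a cell is a sigmoidal function of its
own position, `L2(r) = (1 + tanh 2(n0 + n1.r))/2`, rising from 0 to 1
across a line in the fate plane; received Notch is `l2 = scale * [sum of
neighbors' L2 + alpha * own L2] + delta_n`, where `alpha` weights autocrine
signaling, end cells have one in-group neighbor, `scale` encodes
receptor-side knockdown (RNAi, half dose), and `delta_n` uniform ectopic
NICD activity (receptor-independent, hence not scaled).

A simulation covers two units of developmental time: the **competence
period** t in [0, 1] with signals on, then one unit of signal-free
relaxation so each cell settles toward an attractor. Initial states are
drawn from the pre-competence steady state -- the Ornstein--Uhlenbeck
stationary law obtained when the multistabilizing flow `f` and all signals
are removed: Gaussian, mean `sigma1(m0)`, isotropic covariance `D*tau`.
Fates are scored from the final position by a Gaussian kernel of variance
`2*D*tau` around each attractor ("soft" scoring, matching the stationary
spread and making fate proportions differentiable in the parameters), or
by nearest attractor ("hard", ties split equally). Attractors are found by
root-finding `r = sigma1(f(r) + m0)` from a ring of starts, classified by
the Jacobian, and labeled by angular proximity: the attractor nearest the
`m0` direction is the default fate, the one nearest `m1` the EGF-induced
fate, the remainder the Notch-induced fate.

### Coupling variant

The `coupled` preset down-regulates Notch *sensitivity* along the same
line that switches on ligand production -- `m = m0 + l1*m1 +
(1 - L2(r))*l2*m2` -- a parameter-free stand-in for the mutual inhibition
between the EGF and Notch pathways in primary-fated cells. Its parameter
column was fit separately and is shipped as the `coupled` preset.

## Parameters and defaults

The shipped `main` preset (means of the fitted parameter ensemble):

| parameter | meaning | default |
|---|---|---|
| \|m0\| | bias toward default fate (angle fixed 210 deg) | 0.47 |
| m1 | EGF response vector | norm 3.87, angle -21 deg |
| m2 | Notch response vector | norm 6.25, angle 73 deg |
| 1/tau (`rate`) | inverse time scale (competence period = 1) | 2.02 |
| D | noise diffusion coefficient | 0.009 (see below) |
| gamma | EGF gradient decay per cell | 0.23 |
| alpha | autocrine Notch weight | 1.08 |
| n0 | ligand-production threshold offset | -1.20 |
| n1 | threshold normal (norm fixed at 3) | angle -46 deg |

Fitted per-experiment signal levels ship in the strain registry: ectopic
EGF in lin-15 = 0.42, JU1100 EGF dose = 4.18x WT, CB1417 EGF dose = 0.28x,
JU2064 ectopic Notch = 0.05 (JU2060 = 0.26).

### Calibration of the noise convention

The sources that quote this parameter set print the noise row as "2D" with
value 0.12. Read literally through the correlator above (D = 0.06), the
model is far too dispersive: the unperturbed pattern comes out only ~80%
penetrant in P5/7.p, whereas the very data the parameters were fit to show
an invariant wild-type pattern, and the quoted predictions carry
uncertainties of +/-0--1%. We therefore treat the printed noise rows as
code-internal units and convert them by a single factor calibrated once by
least squares against the quantitative *training* proportions (ablation
series, the overexpression lines, the hypomorph/ectopic-Notch lines, and
the invariant classical patterns), with every other parameter held at its
quoted value: `D = 0.075 x printed row`, i.e. D = 0.009 for the main
model (the optimum is broad, rms-flat over 0.008--0.011) and D = 0.0105
for the coupled and alternate columns. Held-out prediction targets (the
epistasis-line percentages and the timed-pulse outcome) were checked only
*after* freezing this value and match within their stated uncertainties.
The literal reading remains available via
`ModelParameters.from_reported_scales(literal_noise=True)`.

## Numerical choices

* **Integrator** -- Euler--Maruyama with dt = 0.005 (production) or 0.01
  (fitting). The drift is smooth and bounded, and all outputs are
  distributional; halving dt moves wild-type proportions by < 1%.
  Divergence (states far outside the unit disk) raises with advice to
  reduce dt.
* **Noise through relaxation** -- the equation is unchanged after t = 1
  (only signals are removed), so noise stays on during relaxation; the
  soft-scoring kernel width 2*D*tau then matches the stationary spread
  around an attractor. Both choices (noise-free relaxation, hard scoring)
  are exposed as flags.
* **sigma1 at 0** -- continuously extended by 0; below |v| = 1e-12 a
  series expansion avoids 0/0.
* **Timed pulses** are rectangular additive windows [t0, t1); outcomes are
  insensitive to pulse shape, so no smoothing is modeled.
* **Tie-breaking** -- pattern labels use argmax over fates ordered
  (1st, 2nd, 3rd), so ties resolve toward the lower fate digit.

## Fitting

The likelihood compares observed and simulated per-cell fate proportions
through `chi2 = (N^2/4) sum (p_exp - p_num)^2 / (N p_num + 1/2)` with
N = 100 for every experiment -- a uniform reference count that weights all
phenotypes equally (actual animal counts are deliberately not used). The
+1/2 regularizer keeps the statistic finite when the model probability
vanishes, and the variance normalization makes missing a small-but-nonzero
observed fraction expensive (the plain quadratic `N sum (dp)^2` form is
retained as `legacy`). The lin-15 phenotype ("alternating" 1st/2nd fates,
no per-cell percentages) is encoded as residuals penalizing residual
default-fate mass in every cell plus the ensemble probability that an
adjacent pair are both primary -- an explicit encoding choice.

Posterior: `log P = log prior - chi2/2`. Free parameters (15 by default)
are reparameterized to an unconstrained scale -- logs of positive scalars,
logit of gamma -- with Gaussian priors there: Normal(0, 5) per Cartesian
component of m1/m2; log-normals of width 0.7 around class values for
|m0| (0.5), rate (2), D (0.01), alpha (1), and the four fitted doses
(lin-15 0.5, JU1100 2, CB1417 0.3, JU2064 0.05); Normal(-1, 1) for n0;
Normal(-45, 45) deg for the threshold angle; logit-Normal around 0.2 for
gamma. All priors are configurable, and every fit report records the
priors used.

Simulated proportions enter the objective under **frozen common random
numbers**: one pre-drawn tensor of standard normals per (condition, run,
step) is replayed at every evaluation, so the objective is a smooth
deterministic function of the parameters. The MAP is found by
Levenberg--Marquardt on the stacked residual vector (data + prior).
Finite-difference steps are deliberately large (relative step 0.05): with
a finite ensemble, proportions move in steep increments of ~1/n_runs
whenever a trajectory flips basins, so tiny steps see plateaus while
steps of a few percent measure the trend. Because the surface has many
poor local optima (e.g. mis-oriented response vectors -- note the flow's
reflection symmetry makes the mirror image of the fitted geometry an
exactly equivalent posterior mode), the search is staged: random prior
draws are *screened* by a single evaluation each, the best few are
polished by LM on a low-fidelity objective (fewer runs, larger time
step -- the same landscape at lower resolution), the incumbent is refined
by perturb-and-repolish restarts, and the top two distinct optima are
finally re-polished at full fidelity -- a budgeted version of launching
many independent LM runs. A Gauss--Newton (Laplace) covariance is
computed at the optimum. The posterior is then explored with an
affine-invariant ensemble sampler (emcee) initialized at the MAP in a
Laplace-scaled ball; reports give means +/- SDs with m1/m2 also in
norm/angle convention.

Default problem sizes (chosen to keep a desk-scale refit in minutes on
one CPU): 100 frozen-noise runs per condition at dt = 0.01 for the
full-fidelity likelihood (30 runs at dt = 0.04 for the screening stage),
2000-4000 runs at dt = 0.005 for reported predictions, ~150 screened
starts with ~6 LM polishes and ~6 refinement restarts.  The canonical
refit (`refit_dataset`) repeats the whole staged search twice with
independent frozen-noise realizations and keeps the result with the
higher posterior under a common validation objective, so a single
unlucky noise tensor or start sequence cannot dictate the answer.

## Phase diagrams

`scan_grid` simulates every node of an (EGF, Notch) lattice (the Notch
axis is multiplicative below 1 and additive-NICD above 1, matching the
experimental dual convention), labels patterns, flags partial penetrance
(any cell's majority fraction below 0.95, configurable), and
`locate_triple_points` reports connected clusters of nodes where one cell
holds at least 15% of each fate -- the operational definition of a triple
point, robust to sampling noise. The noise-free diagram is obtained simply
by setting D = 0.

## Synthetic data and what passing tests show

`synthetic_data.simulate_dataset` draws multinomial fate counts per cell
(default cohort 100 animals, the reference N of the likelihood) from model
proportions at known parameters, for a roster spanning the informative
regimes (ablation time course, dose series in both pathways). It emulates
the *statistical* structure the fit assumes -- multinomial observation
noise around exchangeable-animal proportions -- and nothing else: no
scoring errors, no animal-to-animal covariates, no anterior-posterior
asymmetry (real data show some), no overdispersion. Recovery tests passing
on such data certify the inference machinery (identifiability under the
assumed error model), not the biological adequacy of that error model.

## Known limitations

* P3.p and anchor-cell displacement are outside the model's scope, so
  anterior-posterior asymmetries in the data cannot be reproduced.
* The ligand-production line extends far into the default-fate territory;
  no modeled condition samples that region.
* The effective noise level rests on the calibration described above; all
  conclusions that depend on absolute penetrance widths inherit that
  convention.
* MAP values from the screened multi-start are reproducible under a fixed
  seed but, as in any rugged-landscape fit, only statistically guaranteed
  to be global; posterior SDs from short chains are lower bounds.
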