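"""Synthetic fate-count datasets with the error structure the fit assumes.

Observed data are per-cell fate proportions in a finite cohort of animals.
The generator mirrors that: it computes model fate proportions for a set of
conditions at a known ("truth") parameter vector, then draws multinomial
counts per cell at a stated animal count -- observation noise is multinomial
only, matching the binomial error model implicit in the chi-square
likelihood.  The resulting datasets go through the same reader/writer and
fitting path as real data, which makes parameter recovery testable
end-to-end without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import CELLS, ModelParameters
from .conditions import Condition, build_condition
from .inference import (DEFAULT_FREE, DOSE_LINKS, ExperimentDataset,
                        FrozenNoiseObjective, Prior, Record, fit_map,
                        sample_posterior)
from .simulation import find_fixed_points, run_conditions

__all__ = ["SyntheticDataset", "simulate_dataset", "recovery_experiment",
           "RecoveryReport", "DEFAULT_RECOVERY_CONDITIONS"]

#: Condition roster spanning the informative regimes: the unperturbed
#: pattern, dose series in each pathway, the ablation time course (crucial
#: for constraining the dynamics), and over/under-expression lines.
DEFAULT_RECOVERY_CONDITIONS: Tuple[str, ...] = (
    "WT", "half-dose-EGF", "half-dose-Notch", "Notch-null", "Notch-null-2AC",
    "JU1107", "JU1100", "CB1417", "JU2064", "JU2095",
    "ablation-L2-lethargus", "ablation-early-L3", "ablation-DU-divided",
    "ablation-VU-divided", "ablation-3-divided", "ablation-two-cell",
)

_ABLATION_SCORED = np.array([False, True, True, True, False])


@dataclass
class SyntheticDataset:
    truth_params: ModelParameters
    truth_doses: Dict[str, float]
    dataset: ExperimentDataset
    counts: Dict[str, np.ndarray]       # per condition: (5, 3) integer counts
    n_animals: int
    seed: Optional[int]


def _scored_for(name: str) -> np.ndarray:
    if name.startswith("ablation"):
        return _ABLATION_SCORED.copy()
    return np.ones(len(CELLS), dtype=bool)


def simulate_dataset(truth: ModelParameters,
                     conditions: Sequence = DEFAULT_RECOVERY_CONDITIONS,
                     n_animals: int = 100,
                     n_runs: int = 2000,
                     rng: Optional[np.random.Generator] = None,
                     seed: Optional[int] = None,
                     doses: Optional[Dict[str, float]] = None,
                     dt: float = 0.005) -> SyntheticDataset:
    """Draw a multinomial fate-count dataset from the model at ``truth``.

    ``conditions`` may mix strain names and (name, Condition) pairs.  Doses
    linked to fitting parameters (e.g. the JU1100 EGF level) are taken from
    ``doses`` when given, so truth doses can differ from registry defaults.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    doses = dict(doses or {})
    named: List[Tuple[str, Condition]] = []
    for c in conditions:
        if isinstance(c, str):
            cond = build_condition(c)
            links = DOSE_LINKS.get(c, ())
            if links:
                cond = cond.replace(
                    **{fld: doses[par] for par, fld in links if par in doses})
            named.append((c, cond))
        else:
            named.append((c[0], c[1]))
    fps = find_fixed_points(truth)
    props = run_conditions(truth, [c for _, c in named], n_runs=n_runs,
                           rng=rng, dt=dt, fps=fps)
    records = []
    counts = {}
    for (name, cond), fp in zip(named, props):
        scored = _scored_for(name)
        cnt = np.zeros((len(CELLS), 3), dtype=int)
        for c in range(len(CELLS)):
            cnt[c] = rng.multinomial(n_animals, fp.p[c] / fp.p[c].sum())
        counts[name] = cnt
        obs = cnt / float(n_animals)
        records.append(Record(name=name, condition=cond, proportions=obs,
                              scored=scored, kind="proportions",
                              dose_links=DOSE_LINKS.get(name, ())))
    ds = ExperimentDataset(records, provenance="synthetic")
    return SyntheticDataset(truth_params=truth, truth_doses=doses,
                            dataset=ds, counts=counts,
                            n_animals=n_animals, seed=seed)


@dataclass
class RecoveryReport:
    free: Tuple[str, ...]
    truth: Dict[str, float]
    map_estimate: Dict[str, float]
    posterior_mean: Dict[str, float]
    posterior_sd: Dict[str, float]
    covered: Dict[str, bool]            # truth within central 95% interval
    bias: Dict[str, float]
    n_animals: int
    identifiable: bool                  # False if any posterior is prior-wide
    summary: pd.DataFrame = field(repr=False, default=None)


def recovery_experiment(truth: ModelParameters,
                        conditions: Sequence = DEFAULT_RECOVERY_CONDITIONS,
                        n_animals: int = 100,
                        free: Sequence[str] = DEFAULT_FREE,
                        priors: Optional[Dict[str, Prior]] = None,
                        rng: Optional[np.random.Generator] = None,
                        seed: Optional[int] = None,
                        truth_doses: Optional[Dict[str, float]] = None,
                        n_runs_data: int = 2000,
                        n_runs_fit: int = 100,
                        dt_fit: float = 0.01,
                        n_starts: int = 10,
                        n_screen: int = 150,
                        n_mcmc: int = 200) -> RecoveryReport:
    """Generate synthetic data at ``truth``, refit, and assess recovery.

    Reports per-parameter bias (posterior mean minus truth), posterior SD,
    and coverage of the central 95% credible interval.  Posteriors wider
    than 90% of the corresponding prior SD are flagged as non-identifiable
    (e.g. when the condition roster is uninformative).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    synth = simulate_dataset(truth, conditions, n_animals=n_animals,
                             n_runs=n_runs_data, rng=rng, doses=truth_doses)
    obj = FrozenNoiseObjective(synth.dataset, base_params=truth, free=free,
                               priors=priors, n_runs=n_runs_fit, dt=dt_fit,
                               seed=int(rng.integers(2**31 - 1)))
    coarse = FrozenNoiseObjective(synth.dataset, base_params=truth, free=free,
                                  priors=priors, n_runs=min(30, n_runs_fit),
                                  dt=0.04, seed=int(rng.integers(2**31 - 1)))
    # the recovery objectives are cheap, so the final full-fidelity polish
    # can run deep
    res = fit_map(obj, n_starts=n_starts, n_screen=n_screen, coarse=coarse,
                  max_nfev=100, rng=rng)
    sd0 = res.laplace_sd()
    post = sample_posterior(obj.log_posterior, res.theta, n_mcmc, rng=rng,
                            names=obj.free,
                            init_scale=sd0 if sd0 is not None else 1e-2)
    nat = post.natural()
    truth_nat = {}
    from .inference import _params_to_natural, DEFAULT_DOSES
    all_truth = _params_to_natural(truth, {**DEFAULT_DOSES,
                                           **(truth_doses or {})})
    prior_set = priors if priors is not None else None
    from .inference import default_priors
    prior_set = dict(default_priors() if prior_set is None else prior_set)

    map_nat = {n: v for n, v in zip(
        obj.free, [_inv_nat(n, z) for n, z in zip(obj.free, res.theta)])}
    mean = nat.mean()
    sd = nat.std(ddof=1)
    lo = nat.quantile(0.025)
    hi = nat.quantile(0.975)
    covered, bias, tdict, ident = {}, {}, {}, True
    for n in obj.free:
        t = float(all_truth[n])
        tdict[n] = t
        covered[n] = bool(lo[n] <= t <= hi[n])
        bias[n] = float(mean[n] - t)
        # Identifiability heuristic on the transformed scale.
        z = np.array([_fwd_nat(n, v) for v in nat[n]])
        if z.std(ddof=1) > 0.9 * prior_set[n].width:
            ident = False
    summary = pd.DataFrame({
        "truth": pd.Series(tdict), "MAP": pd.Series(map_nat),
        "post_mean": mean[list(obj.free)], "post_sd": sd[list(obj.free)],
        "bias": pd.Series(bias), "covered95": pd.Series(covered),
    })
    return RecoveryReport(free=obj.free, truth=tdict, map_estimate=map_nat,
                          posterior_mean=mean[list(obj.free)].to_dict(),
                          posterior_sd=sd[list(obj.free)].to_dict(),
                          covered=covered, bias=bias, n_animals=n_animals,
                          identifiable=ident, summary=summary)


def _inv_nat(name, z):
    from .inference import _inv
    return _inv(name, float(z))


def _fwd_nat(name, x):
    from .inference import _fwd
    return _fwd(name, float(x))
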