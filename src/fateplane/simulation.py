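"""Ensemble SDE integration, attractor geometry, and fate scoring.

A simulation run covers two units of competence time.  During t in [0, 1]
(the competence period) cells respond to the EGF and Notch signals resolved
from a :class:`~fateplane.conditions.Condition`; during t in (1, 2] all
signals are off and each cell relaxes toward one of the three attractors of
the signal-free flow.  Noise stays on throughout (the dynamics is unchanged,
only the inputs are removed).  Fates are then scored from the distance of
the final state to the three attractors.

Integration is Euler--Maruyama with default step dt = 0.005; the drift is
smooth and bounded so this is ample for distributional predictions (halving
dt moves WT fate proportions by well under 1%).  A batch integrator runs
many conditions at once, and a frozen-noise mode replays pre-drawn noise so
fate proportions are smooth functions of the parameters (the basis of the
fitting machinery).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import CELLS, FATES, ModelParameters, flow_field, saturate
from .conditions import Condition, notch_matrix

__all__ = [
    "EnsembleResult",
    "FixedPointSet",
    "FateProportions",
    "sample_initial_states",
    "integrate_ensemble",
    "integrate_batch",
    "signal_schedules",
    "find_fixed_points",
    "score_fates",
    "fate_weights",
    "run_condition",
    "run_conditions",
]


@dataclass
class FateProportions:
    """Per-cell fractions of the three fates; rows (cells) sum to one."""

    p: np.ndarray  # shape (5, 3), columns ordered (1deg, 2deg, 3deg)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (len(CELLS), len(FATES)):
            raise ValueError(f"expected shape {(len(CELLS), len(FATES))}")
        if np.any(self.p < -1e-12):
            raise ValueError("fate fractions must be non-negative")
        if np.any(np.abs(self.p.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("fate fractions must sum to 1 per cell")

    def pattern(self) -> str:
        """Five-digit majority-fate string, e.g. '32123' for wild type."""
        return "".join(FATES[j] for j in np.argmax(self.p, axis=1))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.p, index=list(CELLS),
                            columns=[f"p{f}" for f in FATES])


@dataclass
class FixedPointSet:
    """Attractors (labeled by fate) and saddles of the signal-free flow."""

    attractors: Dict[str, np.ndarray]   # fate label -> position
    saddles: List[np.ndarray]

    @property
    def attractor_array(self) -> np.ndarray:
        """(3, 2) array in fate order (1deg, 2deg, 3deg)."""
        return np.stack([self.attractors[f] for f in FATES])


@dataclass
class EnsembleResult:
    final_states: np.ndarray            # (n_runs, 5, 2) at t = 2
    condition: Condition
    params: ModelParameters
    seed: Optional[int]
    dt: float
    trajectories: Optional[np.ndarray] = None   # (n_steps+1, n_runs, 5, 2)
    times: Optional[np.ndarray] = None


def sample_initial_states(params: ModelParameters, n_runs: int,
                          rng: np.random.Generator,
                          n_cells: int = len(CELLS)) -> np.ndarray:
    """Draw initial VPC states from the pre-competence steady state.

    Before competence the multistabilizing flow ``f`` is absent and there is
    no signaling, so each cell obeys an Ornstein--Uhlenbeck process around
    sigma1(m0); its stationary law is Gaussian with mean sigma1(m0) and
    isotropic covariance D*tau.  All cells are i.i.d. (initially equivalent).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    mean = saturate(params.m0)
    std = np.sqrt(params.D * params.tau)
    return mean + std * rng.standard_normal((n_runs, n_cells, 2))


def signal_schedules(cond: Condition, params: ModelParameters,
                     t_grid: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precompute state-independent signal terms on a time grid.

    Returns ``(l1, notch_scale, notch_add)`` with shapes (K, 5), (K,), (K,):
    the received EGF profile, the multiplier on the lateral+autocrine Notch
    term, and the additive (ectopic/pulsed) Notch level, all zero for t >= 1
    (post-competence relaxation).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    K = len(t_grid)
    comp = t_grid < 1.0                       # competence period
    g = params.gamma
    gradient = np.array([g * g, g, 1.0, g, g * g])
    l1 = np.zeros((K, len(CELLS)))
    grad_on = comp if cond.ac_ablation_time is None else (
        comp & (t_grid < cond.ac_ablation_time))
    l1[grad_on] = cond.egf_dose * gradient
    l1[comp] += cond.ectopic_egf
    for mod in cond.modifiers:
        if mod.channel == "EGF":
            sel = comp & (t_grid >= mod.window[0]) & (t_grid < mod.window[1])
            l1[sel] += mod.delta
    if cond.egf_receptor_null_cells:
        from .conditions import _CELL_INDEX
        for cell in cond.egf_receptor_null_cells:
            l1[:, _CELL_INDEX[cell]] = 0.0
    ns = np.where(comp,
                  0.0 if cond.notch_disabled else cond.notch_scale, 0.0)
    na = np.where(comp, cond.ectopic_notch, 0.0)
    for mod in cond.modifiers:
        if mod.channel == "Notch":
            sel = comp & (t_grid >= mod.window[0]) & (t_grid < mod.window[1])
            na[sel] += mod.delta
    return l1, ns, na


def integrate_batch(params: ModelParameters,
                    l1_sched: np.ndarray,      # (C, K, 5)
                    ns_sched: np.ndarray,      # (C, K)
                    na_sched: np.ndarray,      # (C, K)
                    r0: np.ndarray,            # (C, R, 5, 2)
                    dt: float,
                    rng: Optional[np.random.Generator] = None,
                    noise: Optional[np.ndarray] = None,   # (C, K, R, 5, 2)
                    record: bool = False) -> np.ndarray:
    """Euler--Maruyama integration of a batch of conditions.

    Either ``rng`` (fresh noise) or ``noise`` (a frozen tensor of standard
    normals, common-random-numbers mode) must be given.  Returns the final
    states (C, R, 5, 2), or the full trajectory (K+1, C, R, 5, 2) if
    ``record``.
    """
    if (rng is None) == (noise is None):
        raise ValueError("exactly one of rng and noise must be provided")
    r = np.array(r0, dtype=float)
    C, R = r.shape[0], r.shape[1]
    K = l1_sched.shape[1]
    W = notch_matrix(params.alpha)
    m0 = params.m0
    m1 = params.m1
    m2 = params.m2
    n1 = params.n1
    n0 = params.n0
    rate = params.rate
    coupling = params.coupling
    sig = np.sqrt(2.0 * params.D * dt)
    traj = np.empty((K + 1, C, R, len(CELLS), 2)) if record else None
    if record:
        traj[0] = r
    for k in range(K):
        x, y = r[..., 0], r[..., 1]
        # tanh-saturated flow; finiteness is monitored on r below rather
        # than per-operation (hot loop)
        L2 = 0.5 * (1.0 + np.tanh(2.0 * (n0 + r @ n1)))     # (C, R, 5)
        lateral = L2 @ W.T
        l2 = ns_sched[:, k, None, None] * lateral + na_sched[:, k, None, None]
        if coupling:
            l2 = (1.0 - L2) * l2
        v = (l1_sched[:, k, None, :, None] * m1
             + l2[..., None] * m2)                          # (C, R, 5, 2)
        v[..., 0] += m0[0] + 2.0 * x - 2.0 * x * y
        v[..., 1] += m0[1] + 2.0 * y + y * y - x * x
        vn = np.sqrt(np.sum(v * v, axis=-1, keepdims=True))
        np.maximum(vn, 1e-12, out=vn)
        v *= np.tanh(vn) / vn
        if noise is not None:
            xi = np.asarray(noise[:, k], dtype=float)
        else:
            xi = rng.standard_normal(r.shape)
        r = r + rate * (v - r) * dt + sig * xi
        if record:
            traj[k + 1] = r
        if k % 100 == 99 and not np.all(np.abs(r) < 1e3):
            raise FloatingPointError(
                "integration diverged (states far outside the unit disk); "
                "reduce dt")
    if not (np.all(np.isfinite(r)) and np.all(np.abs(r) < 1e3)):
        raise FloatingPointError(
            "integration diverged (states far outside the unit disk); "
            "reduce dt")
    return traj if record else r


def integrate_ensemble(params: ModelParameters, cond: Condition, n_runs: int,
                       rng: Optional[np.random.Generator] = None,
                       dt: float = 0.005,
                       seed: Optional[int] = None,
                       record: bool = False,
                       initial: Optional[np.ndarray] = None,
                       noise: Optional[np.ndarray] = None,
                       t_final: float = 2.0) -> EnsembleResult:
    """Simulate an ensemble of animals under one condition for t in [0, 2]."""
    if rng is None:
        rng = np.random.default_rng(seed)
    K = int(round(t_final / dt))
    if abs(K * dt - t_final) > 1e-9:
        raise ValueError("dt must divide the integration span evenly")
    t_grid = np.arange(K) * dt
    l1, ns, na = signal_schedules(cond, params, t_grid)
    if initial is None:
        initial = sample_initial_states(params, n_runs, rng)
    out = integrate_batch(params, l1[None], ns[None], na[None],
                          initial[None], dt,
                          rng=None if noise is not None else rng,
                          noise=None if noise is None else noise[None],
                          record=record)
    if record:
        traj = out[:, 0]
        return EnsembleResult(final_states=traj[-1], condition=cond,
                              params=params, seed=seed, dt=dt,
                              trajectories=traj,
                              times=np.arange(K + 1) * dt)
    return EnsembleResult(final_states=out[0], condition=cond, params=params,
                          seed=seed, dt=dt)


def _drift_nosignal(r: np.ndarray, params: ModelParameters) -> np.ndarray:
    return saturate(flow_field(r) + params.m0) - r


def _angular_distance(a: float, b: float) -> float:
    d = np.abs((a - b + 180.0) % 360.0 - 180.0)
    return float(d)


def _newton_roots(params: ModelParameters, starts: np.ndarray,
                  n_iter: int = 60, tol: float = 1e-11) -> np.ndarray:
    """Vectorized damped Newton on g(r) = sigma1(f(r) + m0) - r.

    All starting points iterate simultaneously with finite-difference
    Jacobians; non-converged points are dropped.  Orders of magnitude
    faster than looping a general-purpose root finder over starts.
    """
    r = np.array(starts, dtype=float)
    eps = 1e-6
    for _ in range(n_iter):
        g0 = _drift_nosignal(r, params)
        gx = _drift_nosignal(r + [eps, 0.0], params)
        gy = _drift_nosignal(r + [0.0, eps], params)
        # columns of J: (n, 2, 2)
        J = np.stack([(gx - g0) / eps, (gy - g0) / eps], axis=-1)
        det = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        det = np.where(np.abs(det) < 1e-14, np.inf, det)
        dx = (J[:, 1, 1] * g0[:, 0] - J[:, 0, 1] * g0[:, 1]) / det
        dy = (-J[:, 1, 0] * g0[:, 0] + J[:, 0, 0] * g0[:, 1]) / det
        step = np.stack([dx, dy], axis=-1)
        norm = np.linalg.norm(step, axis=-1, keepdims=True)
        step = step * np.minimum(1.0, 0.5 / np.maximum(norm, 1e-300))  # damp
        r = r - step
        r = np.clip(r, -3.0, 3.0)
    ok = np.linalg.norm(_drift_nosignal(r, params), axis=-1) < tol
    return r[ok]


def find_fixed_points(params: ModelParameters,
                      n_angles: int = 24) -> FixedPointSet:
    """Locate and classify the fixed points of the signal-free dynamics.

    Roots of sigma1(f(r) + m0) - r = 0 are found from a ring of starting
    points, deduplicated, and classified by the numerical Jacobian.  The
    attractor closest in angle to the m0 direction is the default 3deg fate,
    the one closest to the m1 direction is 1deg, and the remaining one 2deg.
    """
    def g(x):
        return _drift_nosignal(x, params)

    starts = [np.zeros(2)]
    for radius in (0.3, 0.6, 0.9):
        for a in np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False):
            starts.append(radius * np.array([np.cos(a), np.sin(a)]))
    roots: List[np.ndarray] = []
    for x in _newton_roots(params, np.array(starts)):
        if not any(np.linalg.norm(x - r) < 1e-5 for r in roots):
            roots.append(x)

    attract: List[np.ndarray] = []
    saddles: List[np.ndarray] = []
    eps = 1e-6
    for r in roots:
        J = np.empty((2, 2))
        for j in range(2):
            dp = np.zeros(2)
            dp[j] = eps
            J[:, j] = (g(r + dp) - g(r - dp)) / (2 * eps)
        eig = np.linalg.eigvals(J)
        if np.all(eig.real < 0):
            attract.append(r)
        elif np.sum(eig.real > 0) == 1:
            saddles.append(r)

    if len(attract) != 3:
        raise ValueError(
            f"expected 3 attractors, found {len(attract)} at "
            f"{[np.round(a, 4).tolist() for a in attract]}; "
            "the parameter set does not produce a tristable landscape")

    angles = [np.rad2deg(np.arctan2(a[1], a[0])) for a in attract]
    _, m1_angle = _polar_angle(params.m1)
    idx3 = int(np.argmin([_angular_distance(a, params.m0_angle) for a in angles]))
    rest = [i for i in range(3) if i != idx3]
    idx1 = min(rest, key=lambda i: _angular_distance(angles[i], m1_angle))
    idx2 = next(i for i in rest if i != idx1)
    labeled = {"1": attract[idx1], "2": attract[idx2], "3": attract[idx3]}
    return FixedPointSet(attractors=labeled, saddles=saddles)


def _polar_angle(v: np.ndarray) -> Tuple[float, float]:
    return float(np.hypot(v[0], v[1])), float(np.rad2deg(np.arctan2(v[1], v[0])))


def fate_weights(final_states: np.ndarray, fps: FixedPointSet,
                 params: ModelParameters, mode: str = "soft") -> np.ndarray:
    """Per-run, per-cell fate weights from distance to the attractors.

    Soft mode (default) uses a Gaussian kernel of variance 2*D*tau, matching
    the stationary spread of a cell around an attractor, so weights are a
    smooth function of parameters; with D = 0 it degenerates to hard
    assignment.  Hard mode assigns the nearest attractor, splitting ties
    equally.  Input shape (..., 5, 2) -> output (..., 5, 3).
    """
    A = fps.attractor_array                       # (3, 2)
    diff = np.asarray(final_states)[..., None, :] - A   # (..., 5, 3, 2)
    d2 = np.sum(diff * diff, axis=-1)             # (..., 5, 3)
    if mode == "soft" and params.D > 0:
        w = np.exp(-(d2 - d2.min(axis=-1, keepdims=True)) / (2 * params.D * params.tau))
    elif mode in ("hard", "soft"):
        dmin = d2.min(axis=-1, keepdims=True)
        w = (d2 <= dmin + 1e-9 * (1.0 + dmin)).astype(float)   # ties split
    else:
        raise ValueError("mode must be 'soft' or 'hard'")
    return w / w.sum(axis=-1, keepdims=True)


def score_fates(final_states: np.ndarray, fps: FixedPointSet,
                params: ModelParameters, mode: str = "soft") -> FateProportions:
    """Average fate weights over runs into per-cell fate proportions."""
    w = fate_weights(final_states, fps, params, mode=mode)
    return FateProportions(w.reshape(-1, len(CELLS), len(FATES)).mean(axis=0))


def run_condition(params: ModelParameters, cond: Condition,
                  n_runs: int = 2000,
                  rng: Optional[np.random.Generator] = None,
                  seed: Optional[int] = None,
                  dt: float = 0.005,
                  scoring: str = "soft",
                  fps: Optional[FixedPointSet] = None) -> FateProportions:
    """End-to-end simulation of one condition: initialize, integrate, score."""
    if rng is None:
        rng = np.random.default_rng(seed)
    if fps is None:
        fps = find_fixed_points(params)
    res = integrate_ensemble(params, cond, n_runs, rng=rng, dt=dt, seed=seed)
    return score_fates(res.final_states, fps, params, mode=scoring)


def run_conditions(params: ModelParameters, conds: Sequence[Condition],
                   n_runs: int = 2000,
                   rng: Optional[np.random.Generator] = None,
                   seed: Optional[int] = None,
                   dt: float = 0.005,
                   scoring: str = "soft",
                   fps: Optional[FixedPointSet] = None,
                   chunk: int = 64) -> List[FateProportions]:
    """Batched :func:`run_condition` over many conditions (one RNG stream)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    if fps is None:
        fps = find_fixed_points(params)
    K = int(round(2.0 / dt))
    t_grid = np.arange(K) * dt
    out: List[FateProportions] = []
    for lo in range(0, len(conds), chunk):
        block = conds[lo:lo + chunk]
        l1 = np.empty((len(block), K, len(CELLS)))
        ns = np.empty((len(block), K))
        na = np.empty((len(block), K))
        for i, c in enumerate(block):
            l1[i], ns[i], na[i] = signal_schedules(c, params, t_grid)
        r0 = np.stack([sample_initial_states(params, n_runs, rng)
                       for _ in block])
        final = integrate_batch(params, l1, ns, na, r0, dt, rng=rng)
        for i in range(len(block)):
            out.append(score_fates(final[i], fps, params, mode=scoring))
    return out
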