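"""Experimental perturbations as declarative conditions.

A :class:`Condition` captures how a genetic background or micromanipulation
alters the EGF and Notch signals the five VPCs receive:

* ``egf_dose`` -- multiplicative dose ``lambda`` on the anchor-cell gradient
  ``lambda * {g^2, g, 1, g, g^2}`` (WT P6.p receives 1);
* ``ectopic_egf`` -- a uniform additive EGF level (e.g. a lin-15 mutant),
  independent of the anchor cell;
* ``notch_scale`` -- multiplicative factor on the *received* lateral plus
  autocrine Notch ligand (RNAi knockdown, half dose);
* ``ectopic_notch`` -- uniform additive Notch activity (NICD), receptor
  independent, hence not scaled by ``notch_scale``;
* ``notch_disabled`` -- Notch null: the lateral/autocrine term is removed;
* ``egf_receptor_null_cells`` -- mosaic animals where the named cells carry
  no EGF receptor (their l1 is forced to 0);
* ``ac_ablation_time`` -- anchor-cell ablation: the graded EGF term vanishes
  for t > t_abl (uniform ectopic EGF persists, being AC independent);
* ``modifiers`` -- rectangular timed pulses on either channel.

Signal levels are dimensionless, normalized so WT P6.p EGF input equals 1
and a single cell at full ligand production contributes 1 to its neighbor's
Notch input.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, FrozenSet, Optional, Tuple

import numpy as np

from .core import CELLS, ModelParameters, ligand_production

__all__ = [
    "TimedModifier",
    "Condition",
    "STRAINS",
    "build_condition",
    "known_strains",
    "egf_profile",
    "notch_inputs",
    "notch_matrix",
]

_CELL_INDEX = {name: i for i, name in enumerate(CELLS)}


@dataclass(frozen=True)
class TimedModifier:
    """Uniform additive pulse on one channel during a rectangular window."""

    channel: str                     # "EGF" or "Notch"
    window: Tuple[float, float]      # [t_start, t_end) within [0, 1]
    delta: float

    def __post_init__(self) -> None:
        if self.channel not in ("EGF", "Notch"):
            raise ValueError("channel must be 'EGF' or 'Notch'")
        t0, t1 = self.window
        if not (0.0 <= t0 < t1 <= 1.0):
            raise ValueError("window must satisfy 0 <= t_start < t_end <= 1")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")

    def active(self, t: float) -> bool:
        t0, t1 = self.window
        return t0 <= t < t1


@dataclass(frozen=True)
class Condition:
    egf_dose: float = 1.0
    ectopic_egf: float = 0.0
    notch_scale: float = 1.0
    ectopic_notch: float = 0.0
    notch_disabled: bool = False
    egf_receptor_null_cells: FrozenSet[str] = frozenset()
    ac_ablation_time: Optional[float] = None
    modifiers: Tuple[TimedModifier, ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        for name, val in (("egf_dose", self.egf_dose),
                          ("ectopic_egf", self.ectopic_egf),
                          ("notch_scale", self.notch_scale),
                          ("ectopic_notch", self.ectopic_notch)):
            if val < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.ac_ablation_time is not None and not 0.0 <= self.ac_ablation_time <= 1.0:
            raise ValueError("ac_ablation_time must lie in [0, 1]")
        unknown = set(self.egf_receptor_null_cells) - set(CELLS)
        if unknown:
            raise ValueError(f"unknown cells in mosaic spec: {sorted(unknown)}")
        object.__setattr__(self, "egf_receptor_null_cells",
                           frozenset(self.egf_receptor_null_cells))
        object.__setattr__(self, "modifiers", tuple(self.modifiers))

    def replace(self, **kwargs) -> "Condition":
        return replace(self, **kwargs)


def _ablation(t_abl: float, label: str) -> Condition:
    return Condition(ac_ablation_time=t_abl, label=label)


# Registry of the experimental lines and classical manipulations modeled in
# this package.  Doses marked "fit" are the fitted signal levels shipped as
# defaults (EGF doses are fold WT; ectopic Notch is additive NICD activity).
STRAINS: Dict[str, Condition] = {
    "WT": Condition(label="WT"),
    # EGF perturbation lines
    "CB1417": Condition(egf_dose=0.28, label="CB1417"),          # hypomorph, fit
    "JU2036": Condition(egf_dose=1.25, label="JU2036"),          # measured
    "JU2035": Condition(egf_dose=1.79, label="JU2035"),          # measured
    "JU1107": Condition(egf_dose=2.75, label="JU1107"),          # measured
    "JU1100": Condition(egf_dose=4.18, label="JU1100"),          # fit
    "lin-15": Condition(ectopic_egf=0.42, label="lin-15"),       # ectopic EGF, fit
    "lin-15-no-AC": Condition(egf_dose=0.0, ectopic_egf=0.42, label="lin-15-no-AC"),
    # Notch perturbation lines
    "JU2039": Condition(notch_scale=0.4, label="JU2039"),        # Pn.p RNAi, fit
    "JU2064": Condition(ectopic_notch=0.05, label="JU2064"),     # mild NICD, fit
    "JU2060": Condition(ectopic_notch=0.26, label="JU2060"),     # NICD, fit
    # Crosses
    "JU2113": Condition(egf_dose=1.25, notch_scale=0.4, label="JU2113"),
    "JU2091": Condition(egf_dose=1.25, ectopic_notch=0.05, label="JU2091"),
    "JU2089": Condition(egf_dose=1.79, ectopic_notch=0.05, label="JU2089"),
    "JU2092": Condition(egf_dose=2.75, ectopic_notch=0.05, label="JU2092"),
    "JU2095": Condition(egf_dose=0.28, ectopic_notch=0.05, label="JU2095"),
    # Classical genetics
    "half-dose-EGF": Condition(egf_dose=0.5, label="half-dose-EGF"),
    "half-dose-Notch": Condition(notch_scale=0.5, label="half-dose-Notch"),
    "let-23-mosaic": Condition(egf_receptor_null_cells=frozenset({"P5.p", "P7.p"}),
                               label="let-23-mosaic"),
    "Notch-null": Condition(notch_disabled=True, label="Notch-null"),
    # Notch null animals develop two anchor cells: encoded as doubled EGF.
    "Notch-null-2AC": Condition(egf_dose=2.0, notch_disabled=True,
                                label="Notch-null-2AC"),
    # Anchor-cell ablations at successive stages, mapped to evenly spaced
    # model times within the competence period.
    "ablation-L2-lethargus": _ablation(0.2, "ablation-L2-lethargus"),
    "ablation-early-L3": _ablation(0.32, "ablation-early-L3"),
    "ablation-DU-divided": _ablation(0.44, "ablation-DU-divided"),
    "ablation-VU-divided": _ablation(0.56, "ablation-VU-divided"),
    "ablation-3-divided": _ablation(0.68, "ablation-3-divided"),
    "ablation-two-cell": _ablation(0.8, "ablation-two-cell"),
}


def known_strains() -> Tuple[str, ...]:
    return tuple(STRAINS)


def build_condition(name: str) -> Condition:
    """Look up a registered strain/manipulation by name."""
    try:
        return STRAINS[name]
    except KeyError:
        raise KeyError(
            f"unknown strain {name!r}; known strains: {', '.join(STRAINS)}"
        ) from None


def egf_profile(cond: Condition, params: ModelParameters, t: float) -> np.ndarray:
    """Received EGF level l1 per cell (5-vector) at time t in [0, 1]."""
    g = params.gamma
    lvl = np.zeros(len(CELLS))
    if cond.ac_ablation_time is None or t < cond.ac_ablation_time:
        lvl += cond.egf_dose * np.array([g * g, g, 1.0, g, g * g])
    lvl += cond.ectopic_egf
    for mod in cond.modifiers:
        if mod.channel == "EGF" and mod.active(t):
            lvl += mod.delta
    for cell in cond.egf_receptor_null_cells:
        lvl[_CELL_INDEX[cell]] = 0.0
    return lvl


def notch_matrix(alpha: float) -> np.ndarray:
    """Linear map from per-cell ligand production L2 to received lateral input.

    Row c sums the two in-group neighbors of cell c plus alpha times the
    cell's own production (autocrine).  End cells have a single neighbor.
    """
    n = len(CELLS)
    W = np.zeros((n, n))
    for i in range(n):
        W[i, i] = alpha
        if i > 0:
            W[i, i - 1] = 1.0
        if i < n - 1:
            W[i, i + 1] = 1.0
    return W


def notch_inputs(states: np.ndarray, cond: Condition, params: ModelParameters,
                 t: float, L2: Optional[np.ndarray] = None) -> np.ndarray:
    """Received Notch level l2 per cell at time t, from the cells' states.

    ``states`` has shape (..., 5, 2); ``L2`` may be supplied to reuse a
    precomputed ligand-production array of shape (..., 5).
    """
    if L2 is None:
        L2 = ligand_production(np.asarray(states, dtype=float), params)
    if cond.notch_disabled:
        lateral = np.zeros_like(L2)
    else:
        lateral = L2 @ notch_matrix(params.alpha).T
    l2 = cond.notch_scale * lateral + cond.ectopic_notch
    for mod in cond.modifiers:
        if mod.channel == "Notch" and mod.active(t):
            l2 = l2 + mod.delta
    return l2
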