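"""EGF x Notch phase diagrams: pattern domains, penetrance zones, triple points.

The diagram scans a lattice of signaling doses.  The EGF axis is the fold
change ``lambda`` on the anchor-cell gradient.  The Notch axis ``nu`` uses a
dual convention matching how Notch is manipulated experimentally: values
below one are fold changes of the received lateral/autocrine signal (RNAi
knockdown), while values above one add a uniform ectopic NICD activity of
``nu - 1`` on top of the intact WT signaling (in units of the maximum
ligand production of a single cell).

At each node an ensemble is simulated and the per-cell fate proportions
recorded.  A node's *pattern* is the string of per-cell majority fates
(WT = "32123"); nodes where any cell's majority fraction falls below a
threshold are flagged as partially penetrant (domain boundaries).  *Triple
points* -- dose combinations at which a single cell can adopt all three
fates -- are detected directly from the proportions: nodes where some cell
carries at least ``min_fraction`` of each fate, clustered into connected
components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import CELLS, FATES, ModelParameters
from .conditions import Condition
from .simulation import FateProportions, FixedPointSet, find_fixed_points, run_conditions

__all__ = [
    "PhaseDiagramGrid",
    "TriplePoint",
    "axis_to_condition",
    "scan_grid",
    "classify_pattern",
    "locate_triple_points",
    "write_grid",
    "plot_grid",
]


def axis_to_condition(egf: float, notch: float) -> Condition:
    """Map a phase-diagram node (lambda, nu) to a simulation condition."""
    if egf < 0 or notch < 0:
        raise ValueError("doses must be non-negative")
    if notch <= 1.0:
        return Condition(egf_dose=egf, notch_scale=notch,
                         label=f"egf={egf:g},notch={notch:g}")
    return Condition(egf_dose=egf, notch_scale=1.0, ectopic_notch=notch - 1.0,
                     label=f"egf={egf:g},notch={notch:g}")


def classify_pattern(fp: FateProportions,
                     majority_threshold: float = 0.95) -> Tuple[str, bool]:
    """Majority-fate pattern label and partial-penetrance flag.

    Ties go to the lower fate digit (argmax returns the first maximum, and
    fates are ordered 1, 2, 3).
    """
    label = fp.pattern()
    flagged = bool(np.any(fp.p.max(axis=1) < majority_threshold))
    return label, flagged


@dataclass
class PhaseDiagramGrid:
    egf_axis: np.ndarray
    notch_axis: np.ndarray
    proportions: np.ndarray          # (nE, nN, 5, 3)
    patterns: np.ndarray             # (nE, nN) of str
    penetrance_mask: np.ndarray      # (nE, nN) bool
    params: ModelParameters
    n_runs: int
    seed: Optional[int]
    majority_threshold: float

    def __post_init__(self) -> None:
        self.egf_axis = np.asarray(self.egf_axis, dtype=float)
        self.notch_axis = np.asarray(self.notch_axis, dtype=float)
        for ax in (self.egf_axis, self.notch_axis):
            if len(ax) and np.any(np.diff(ax) <= 0):
                raise ValueError("axes must be strictly increasing")

    def pattern_at(self, egf: float, notch: float) -> str:
        i = int(np.argmin(np.abs(self.egf_axis - egf)))
        j = int(np.argmin(np.abs(self.notch_axis - notch)))
        return str(self.patterns[i, j])


@dataclass
class TriplePoint:
    cell: str
    egf: float
    notch: float
    fractions: np.ndarray            # (3,) fate fractions of that cell

    def __str__(self) -> str:
        f = ", ".join(f"{x:.2f}" for x in self.fractions)
        return (f"TriplePoint({self.cell} at EGF={self.egf:.3g}, "
                f"Notch={self.notch:.3g}; fractions [{f}])")


def scan_grid(params: ModelParameters,
              egf_axis: Sequence[float],
              notch_axis: Sequence[float],
              n_runs: int = 500,
              rng: Optional[np.random.Generator] = None,
              seed: Optional[int] = None,
              dt: float = 0.005,
              scoring: str = "soft",
              majority_threshold: float = 0.95,
              fps: Optional[FixedPointSet] = None,
              chunk: int = 64) -> PhaseDiagramGrid:
    """Simulate every (EGF, Notch) node and classify its pattern.

    Nodes are independent; they are batched through the vectorized
    integrator in chunks.  With a fixed seed the scan is deterministic.
    """
    egf_axis = np.asarray(egf_axis, dtype=float)
    notch_axis = np.asarray(notch_axis, dtype=float)
    if egf_axis.size == 0 or notch_axis.size == 0:
        raise ValueError("axes must be non-empty")
    if rng is None:
        rng = np.random.default_rng(seed)
    if fps is None:
        fps = find_fixed_points(params)
    conds = [axis_to_condition(e, n) for e in egf_axis for n in notch_axis]
    props = run_conditions(params, conds, n_runs=n_runs, rng=rng, dt=dt,
                           scoring=scoring, fps=fps, chunk=chunk)
    nE, nN = len(egf_axis), len(notch_axis)
    P = np.empty((nE, nN, len(CELLS), len(FATES)))
    patterns = np.empty((nE, nN), dtype=object)
    mask = np.zeros((nE, nN), dtype=bool)
    for idx, fp in enumerate(props):
        i, j = divmod(idx, nN)
        P[i, j] = fp.p
        patterns[i, j], mask[i, j] = classify_pattern(fp, majority_threshold)
    return PhaseDiagramGrid(egf_axis=egf_axis, notch_axis=notch_axis,
                            proportions=P, patterns=patterns,
                            penetrance_mask=mask, params=params,
                            n_runs=n_runs, seed=seed,
                            majority_threshold=majority_threshold)


def locate_triple_points(grid: PhaseDiagramGrid,
                         min_fraction: float = 0.15) -> List[TriplePoint]:
    """Find dose combinations where one cell shows all three fates.

    Nodes where a cell's smallest fate fraction is >= ``min_fraction`` are
    clustered into 4-connected components per cell; one centroid triple
    point is reported per component, carrying the fractions of the node
    nearest the centroid.
    """
    import scipy.ndimage

    out: List[TriplePoint] = []
    for c, cell in enumerate(CELLS):
        hit = grid.proportions[:, :, c, :].min(axis=-1) >= min_fraction
        labels, n_comp = scipy.ndimage.label(hit)
        for comp in range(1, n_comp + 1):
            ii, jj = np.nonzero(labels == comp)
            egf = float(grid.egf_axis[ii].mean())
            notch = float(grid.notch_axis[jj].mean())
            k = int(np.argmin((grid.egf_axis[ii] - egf) ** 2
                              + (grid.notch_axis[jj] - notch) ** 2))
            out.append(TriplePoint(
                cell=cell, egf=egf, notch=notch,
                fractions=grid.proportions[ii[k], jj[k], c, :].copy()))
    return out


def write_grid(grid: PhaseDiagramGrid, path) -> None:
    """Long-format table: egf, notch, cell, p1, p2, p3, pattern, flagged."""
    import pandas as pd

    rows = []
    for i, e in enumerate(grid.egf_axis):
        for j, n in enumerate(grid.notch_axis):
            for c, cell in enumerate(CELLS):
                p = grid.proportions[i, j, c]
                rows.append({"egf": e, "notch": n, "cell": cell,
                             "p1": p[0], "p2": p[1], "p3": p[2],
                             "pattern": grid.patterns[i, j],
                             "flagged": int(grid.penetrance_mask[i, j])})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def plot_grid(grid: PhaseDiagramGrid, path=None, ax=None):
    """Raster of the pattern map with penetrance shading."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pats = sorted({str(p) for p in grid.patterns.ravel()})
    index = {p: k for k, p in enumerate(pats)}
    img = np.vectorize(lambda p: index[str(p)])(grid.patterns).T
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    extent = (grid.egf_axis[0], grid.egf_axis[-1],
              grid.notch_axis[0], grid.notch_axis[-1])
    cmap = plt.get_cmap("tab20", len(pats))
    ax.imshow(img, origin="lower", aspect="auto", extent=extent,
              cmap=cmap, interpolation="nearest")
    shade = np.ma.masked_where(~grid.penetrance_mask.T, grid.penetrance_mask.T)
    ax.imshow(shade, origin="lower", aspect="auto", extent=extent,
              cmap="gray", alpha=0.35, interpolation="nearest")
    ax.set_xlabel("EGF dose (fold WT)")
    ax.set_ylabel("Notch level (dual convention)")
    handles = [plt.Rectangle((0, 0), 1, 1, color=cmap(index[p])) for p in pats]
    ax.legend(handles, pats, fontsize=7, loc="upper right", title="pattern")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
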