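"""Path-progress collective variables over milestone conformations.

Given an ordered set of N milestone conformations X_1..X_N (matched atom
lists, typically backbone P atoms) and a configuration X, the two path
collective variables are

    spath = sum_i i exp(-lambda R(X - X_i)) / sum_i exp(-lambda R(X - X_i))
    zpath = -(1/lambda) ln sum_i exp(-lambda R(X - X_i))

with i = 1..N. R is the deviation of X from milestone i after optimal rigid
superposition; the default metric is the mean-squared deviation in Å^2 (the
convention of the PATHMSD-style path CVs), so lambda carries units of Å^-2.
spath tracks progress along the path (1 at the first milestone, N at the
last); zpath measures the distance off the path. Evaluation is numerically
stabilised by a max-shift of the exponent (log-sum-exp); the naive form is
kept for oracle comparisons only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .structures import Selection, Structure, resolve_selection
from .superpose import PairingError, kabsch

__all__ = [
    "PathReference",
    "PathCoordinates",
    "milestone_distance",
    "path_coordinates",
    "calibrate_lambda",
    "build_path_from_ensemble",
]


@dataclass
class PathReference:
    """Ordered milestone coordinate sets plus the lambda smoothing parameter."""

    milestones: list[np.ndarray]
    lam: float
    metric: str = "msd"  # msd (Å^2) or rmsd (Å)
    atom_selection: Optional[Selection] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.milestones = [np.asarray(m, float) for m in self.milestones]
        if len(self.milestones) < 2:
            raise ValueError("a path needs at least 2 milestones")
        shape = self.milestones[0].shape
        if any(m.shape != shape for m in self.milestones):
            raise PairingError("all milestones must share one atom layout")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")

    @property
    def n(self) -> int:
        return len(self.milestones)


@dataclass
class PathCoordinates:
    spath: float
    zpath: float
    per_milestone_R: np.ndarray


def milestone_distance(x: np.ndarray, xi: np.ndarray, metric: str = "msd") -> float:
    """Deviation of configuration x from milestone xi after optimal alignment.

    Kabsch superposition (no rejection) removes rigid-body motion; the
    remaining deviation is returned as mean-squared (Å^2, default) or
    root-mean-squared (Å).
    """
    x = np.asarray(x, float)
    xi = np.asarray(xi, float)
    if x.shape != xi.shape:
        raise PairingError(f"atom-count mismatch: {x.shape} vs {xi.shape}")
    _, _, rmsd = kabsch(x, xi)
    if metric == "msd":
        return rmsd**2
    if metric == "rmsd":
        return rmsd
    raise ValueError(f"unknown metric {metric!r}")


def path_coordinates(x: np.ndarray, ref: PathReference, naive: bool = False) -> PathCoordinates:
    """Evaluate (spath, zpath) for one configuration against a path.

    ``naive=True`` evaluates the sums without log-sum-exp stabilisation, in
    extended precision; it exists for cross-checking and underflows for large
    lambda * R.
    """
    r = np.array([milestone_distance(x, m, ref.metric) for m in ref.milestones])
    idx = np.arange(1, ref.n + 1, dtype=float)
    if naive:
        w = np.exp(-np.longdouble(ref.lam) * np.longdouble(1) * r.astype(np.longdouble))
        total = w.sum()
        spath = float((idx * w).sum() / total)
        zpath = float(-np.log(total) / ref.lam)
    else:
        expo = -ref.lam * r
        shift = expo.max()
        w = np.exp(expo - shift)
        total = w.sum()
        spath = float((idx * w).sum() / total)
        zpath = float(-(shift + np.log(total)) / ref.lam)
    return PathCoordinates(spath=spath, zpath=zpath, per_milestone_R=r)


def calibrate_lambda(milestones: Sequence[np.ndarray], metric: str = "msd") -> float:
    """Standard path-CV heuristic: lambda = 2.3 / mean adjacent-milestone distance."""
    milestones = [np.asarray(m, float) for m in milestones]
    if len(milestones) < 2:
        raise ValueError("need >= 2 milestones")
    gaps = [
        milestone_distance(milestones[i], milestones[i + 1], metric)
        for i in range(len(milestones) - 1)
    ]
    mean_gap = float(np.mean(gaps))
    if mean_gap <= 1e-12:
        raise ValueError("adjacent milestones are identical; cannot calibrate lambda")
    return 2.3 / mean_gap


def _frame_coords(frame: Structure, sel: Optional[Selection]) -> np.ndarray:
    if sel is None:
        return np.array([a.coord for r in frame.residues for a in r.atoms])
    return resolve_selection(frame, sel).coords


def build_path_from_ensemble(
    frames: Sequence[Structure],
    sel: Optional[Selection] = None,
    n_milestones: int = 20,
    metric: str = "msd",
    lam: Optional[float] = None,
) -> PathReference:
    """Build a milestone path from an ordered conformational ensemble.

    Frames are ranked by their RMSD to the final frame (the most-open
    conformation), and ``n_milestones`` frames are picked evenly spaced along
    that coordinate. Milestones are stored after superposing each onto the
    first so the reference is free of global rigid drift. If ``lam`` is not
    given it is calibrated with :func:`calibrate_lambda`.
    """
    if n_milestones < 2:
        raise ValueError("need n_milestones >= 2")
    if len(frames) < n_milestones:
        raise ValueError(f"ensemble of {len(frames)} frames < {n_milestones} milestones")
    coords = [_frame_coords(f, sel) for f in frames]
    shape = coords[0].shape
    if any(c.shape != shape for c in coords):
        raise PairingError("frames have differing atom layouts under the selection")

    last = coords[-1]
    dist_to_end = np.array([milestone_distance(c, last, "rmsd") for c in coords])
    order = np.argsort(-dist_to_end, kind="stable")  # farthest (most closed) first
    sorted_d = dist_to_end[order]
    targets = np.linspace(sorted_d[0], sorted_d[-1], n_milestones)
    chosen: list[int] = []
    for t in targets:
        j = int(np.argmin(np.abs(sorted_d - t)))
        idx = int(order[j])
        if idx not in chosen:
            chosen.append(idx)
    # fill up if nearest-target collisions dropped frames
    for idx in order:
        if len(chosen) >= n_milestones:
            break
        if int(idx) not in chosen:
            chosen.append(int(idx))
    chosen = chosen[:n_milestones]
    chosen.sort(key=lambda i: -dist_to_end[i])

    milestones = [coords[chosen[0]]]
    for idx in chosen[1:]:
        r, t, _ = kabsch(coords[idx], milestones[0])
        milestones.append(coords[idx] @ r.T + t)
    lam_val = lam if lam is not None else calibrate_lambda(milestones, metric)
    return PathReference(
        milestones=milestones,
        lam=lam_val,
        metric=metric,
        atom_selection=sel,
        provenance={
            "n_frames": len(frames),
            "chosen_frames": chosen,
            "lambda_calibrated": lam is None,
        },
    )
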