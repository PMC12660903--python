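"""Per-nucleotide conformational analysis.

Two analyses live here:

* eta/theta pseudo-torsions, the two-angle-per-residue reduction of the RNA
  backbone built on P and C4' atoms:
  eta(i)   = dihedral(C4'(i-1), P(i), C4'(i), P(i+1))
  theta(i) = dihedral(P(i), C4'(i), P(i+1), C4'(i+1))
  Chain termini and residues with missing atoms carry undefined flags rather
  than raising.

* bulged-in / bulged-out classification of a nucleobase relative to its
  helix axis: the perpendicular distance of the base-ring centroid from the
  fitted axis is z-scored against the other residues of the same helix, with
  a hysteresis band (default: > +2 sigma = bulged out, < +1 sigma = bulged
  in, in between = indeterminate) so borderline residues are not forced into
  a label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .geometry import HelixAxis, fit_helix_axis
from .structures import Residue, Selection, Structure

__all__ = [
    "PseudoTorsionRecord",
    "FlipState",
    "DihedralError",
    "PURINE_RING_ATOMS",
    "PYRIMIDINE_RING_ATOMS",
    "dihedral",
    "pseudo_torsions",
    "base_centroid",
    "classify_flip",
]

#: 9-membered purine ring atoms
PURINE_RING_ATOMS = ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
#: 6-membered pyrimidine ring atoms
PYRIMIDINE_RING_ATOMS = ("N1", "C2", "N3", "C4", "C5", "C6")


class DihedralError(ValueError):
    """Raised when three consecutive dihedral points are collinear."""


@dataclass
class PseudoTorsionRecord:
    chain_id: str
    seq_num: int
    res_name: str
    eta: Optional[float]  # degrees in (-180, 180], None when undefined
    theta: Optional[float]

    @property
    def defined(self) -> bool:
        return self.eta is not None and self.theta is not None


@dataclass
class FlipState:
    chain_id: str
    seq_num: int
    axis_distance: float
    reference_distance: float
    reference_sd: float
    zscore: float
    label: str  # bulged_in | bulged_out | indeterminate


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle in degrees, IUPAC convention, in (-180, 180].

    Looking along the p2->p3 bond, the angle is positive for a clockwise
    rotation of p4 relative to p1.
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 * max(1.0, np.linalg.norm(b1) * norm_b2) or \
       np.linalg.norm(n2) < 1e-10 * max(1.0, np.linalg.norm(b3) * norm_b2):
        raise DihedralError("three consecutive points are collinear; dihedral undefined")
    x = float(n1 @ n2)
    y = float(np.cross(n1, n2) @ b2 / norm_b2)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def pseudo_torsions(s: Structure, chain: str) -> list[PseudoTorsionRecord]:
    """eta/theta pseudo-torsions for every residue of one chain.

    Residues at the chain termini, or whose own or neighbouring P/C4' atoms
    are missing, are flagged undefined (``None``) in the affected field.
    """
    residues = [r for r in s.chain(chain) if r.is_nucleic]
    if len(residues) < 3:
        raise ValueError(f"chain {chain!r}: need >= 3 nucleotides for pseudo-torsions")

    def _coords(r: Optional[Residue], name: str) -> Optional[np.ndarray]:
        if r is None:
            return None
        a = r.atom(name)
        return None if a is None else a.coord

    records: list[PseudoTorsionRecord] = []
    for i, r in enumerate(residues):
        prev_r = residues[i - 1] if i > 0 else None
        next_r = residues[i + 1] if i < len(residues) - 1 else None
        # a numbering gap is a strand break: treat as a terminus
        if prev_r is not None and prev_r.seq_num != r.seq_num - 1:
            prev_r = None
        if next_r is not None and next_r.seq_num != r.seq_num + 1:
            next_r = None
        eta = theta = None
        pts_eta = (_coords(prev_r, "C4'"), _coords(r, "P"), _coords(r, "C4'"), _coords(next_r, "P"))
        pts_theta = (_coords(r, "P"), _coords(r, "C4'"), _coords(next_r, "P"), _coords(next_r, "C4'"))
        try:
            if all(p is not None for p in pts_eta):
                eta = dihedral(*pts_eta)
        except DihedralError:
            eta = None
        try:
            if all(p is not None for p in pts_theta):
                theta = dihedral(*pts_theta)
        except DihedralError:
            theta = None
        records.append(PseudoTorsionRecord(r.chain_id, r.seq_num, r.res_name, eta, theta))
    return records


def base_centroid(residue: Residue) -> np.ndarray:
    """Centroid of the base ring atoms (no sugar or backbone contamination).

    Tries the purine 9-ring first, falls back to the pyrimidine 6-ring.
    """
    for ring in (PURINE_RING_ATOMS, PYRIMIDINE_RING_ATOMS):
        atoms = [residue.atom(n) for n in ring]
        coords = [a.coord for a in atoms if a is not None]
        if len(coords) >= 3 and len(coords) == sum(a is not None for a in atoms):
            return np.mean(coords, axis=0)
    # partial ring: accept >= 3 of either template
    coords = [residue.atom(n).coord for n in set(PURINE_RING_ATOMS) | set(PYRIMIDINE_RING_ATOMS)
              if residue.atom(n) is not None]
    if len(coords) < 3:
        raise ValueError(
            f"residue {residue.chain_id}:{residue.seq_num} has < 3 base ring atoms"
        )
    return np.mean(coords, axis=0)


def _axis_distance(point: np.ndarray, axis: HelixAxis) -> float:
    rel = point - axis.anchor
    perp = rel - (rel @ axis.direction) * axis.direction
    return float(np.linalg.norm(perp))


def classify_flip(
    s: Structure,
    residue: tuple[str, int],
    helix: Selection,
    atom_set: Optional[Iterable[str]] = None,
    exclude: Iterable[tuple[str, int]] = (),
    out_threshold: float = 2.0,
    in_threshold: float = 1.0,
) -> FlipState:
    """Classify a nucleobase as bulged in or out of its helix.

    The helix axis is fitted to ``helix`` backbone atoms; the base-centroid
    axis distance of the query residue is z-scored against the distances of
    the helix's other residues (minus any ``exclude``d hinge residues).
    """
    chain_id, seq_num = residue
    axis = fit_helix_axis(s, helix, atom_set)
    query = s.residue(chain_id, seq_num)
    if query is None:
        raise ValueError(f"residue {chain_id}:{seq_num} not in structure {s.id!r}")
    d_query = _axis_distance(base_centroid(query), axis)

    excluded = set(exclude) | {(chain_id, seq_num)}
    ref: list[float] = []
    for r in s.residues:
        if not r.is_nucleic or not helix.contains(r.chain_id, r.seq_num):
            continue
        if (r.chain_id, r.seq_num) in excluded:
            continue
        try:
            ref.append(_axis_distance(base_centroid(r), axis))
        except ValueError:
            continue
    if len(ref) < 3:
        raise ValueError("fewer than 3 reference residues for flip classification")
    mean = float(np.mean(ref))
    sd = float(np.std(ref))
    # floor the spread so perfectly regular (synthetic) helices still give a
    # well-defined, large z for genuinely displaced bases
    z = (d_query - mean) / max(sd, 1e-6)
    if z > out_threshold:
        label = "bulged_out"
    elif z < in_threshold:
        label = "bulged_in"
    else:
        label = "indeterminate"
    return FlipState(
        chain_id=chain_id,
        seq_num=seq_num,
        axis_distance=d_query,
        reference_distance=mean,
        reference_sd=sd,
        zscore=z,
        label=label,
    )
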