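"""Rigid-body superposition, RMSD, and per-residue displacement profiles.

The Kabsch algorithm gives the closed-form least-squares optimal rotation
between two paired point sets. Optional iterative outlier rejection discards
atom pairs whose post-fit residual exceeds a sigma cutoff and re-fits, which
mirrors the behaviour of common structure-alignment programs and makes the
reported RMSD robust to locally displaced regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .structures import Structure

__all__ = [
    "SuperpositionResult",
    "DisplacementProfile",
    "DegenerateFitError",
    "PairingError",
    "kabsch",
    "kabsch_superpose",
    "displacement_profile",
]


class DegenerateFitError(ValueError):
    """Raised when fewer than 3 atom pairs are available for a rigid fit."""


class PairingError(ValueError):
    """Raised when two models share no residues/atoms to pair."""


@dataclass
class SuperpositionResult:
    """Optimal rigid transform mapping mobile onto target: x' = R x + t."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms_used: int
    n_rejected: int = 0
    #: RMSD over all pairs with no rejection, co-reported for auditability
    rmsd_all: float = 0.0
    kept_mask: Optional[np.ndarray] = None

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class DisplacementProfile:
    """Per-residue displacement between two superposed models."""

    entries: list[tuple[str, int, str, float]] = field(default_factory=list)
    atom_used: str = "P"
    omitted: list[tuple[str, int]] = field(default_factory=list)

    @property
    def displacements(self) -> np.ndarray:
        return np.array([e[3] for e in self.entries], dtype=float)

    def top(self, n: int) -> list[tuple[str, int, str, float]]:
        return sorted(self.entries, key=lambda e: -e[3])[:n]


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Closed-form optimal rigid transform (proper rotation) and RMSD.

    Returns (R, t, rmsd) such that ``mobile @ R.T + t`` best matches target.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise PairingError("coordinate arrays must be matching (N, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateFitError(f"need >= 3 atom pairs, got {n}")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    t = ct - r @ cm
    moved = mobile @ r.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return r, t, rmsd


def kabsch_superpose(
    mobile: np.ndarray,
    target: np.ndarray,
    reject_cycles: int = 0,
    reject_sigma: float = 2.0,
) -> SuperpositionResult:
    """Least-squares rigid superposition with optional outlier rejection.

    With ``reject_cycles > 0``, pairs whose residual exceeds ``reject_sigma``
    standard deviations of the residual distribution are discarded and the fit
    repeated, up to the given number of cycles or until no pair is rejected.
    The reported ``rmsd`` covers retained pairs; ``rmsd_all`` covers all pairs
    under the final transform.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if reject_sigma <= 0:
        raise ValueError("reject_sigma must be positive")
    n = mobile.shape[0]
    keep = np.ones(n, dtype=bool)
    r, t, rmsd = kabsch(mobile, target)
    for _ in range(int(reject_cycles)):
        moved = mobile @ r.T + t
        resid = np.linalg.norm(moved - target, axis=1)
        sd = resid[keep].std()
        if sd == 0:
            break
        new_keep = keep & (resid <= resid[keep].mean() + reject_sigma * sd)
        if new_keep.sum() < 3:
            break
        if new_keep.sum() == keep.sum():
            keep = new_keep
            break
        keep = new_keep
        r, t, rmsd = kabsch(mobile[keep], target[keep])
    moved = mobile @ r.T + t
    rmsd_all = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return SuperpositionResult(
        rotation=r,
        translation=t,
        rmsd=rmsd,
        n_atoms_used=int(keep.sum()),
        n_rejected=int(n - keep.sum()),
        rmsd_all=rmsd_all,
        kept_mask=keep,
    )


def _common_atom_arrays(
    a: Structure, b: Structure
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int, str, str]]]:
    """Paired coordinate arrays over (chain, seq, icode, atom-name) keys."""
    ma = a.atom_map()
    mb = b.atom_map()
    keys = [k for k in ma if k in mb]
    if not keys:
        raise PairingError(f"no common atoms between {a.id!r} and {b.id!r}")
    xa = np.array([ma[k] for k in keys])
    xb = np.array([mb[k] for k in keys])
    return xa, xb, keys


def displacement_profile(
    a: Structure,
    b: Structure,
    atom_used: str = "P",
    reject_cycles: int = 5,
    reject_sigma: float = 2.0,
) -> tuple[DisplacementProfile, SuperpositionResult]:
    """Per-residue displacement of ``atom_used`` after all-atom superposition.

    ``a`` is superposed onto ``b`` over all common heavy atoms (identical
    chain/residue-number/atom-name keys; author numbering, no sequence
    alignment). The profile then lists the Euclidean distance between the
    analogous ``atom_used`` atoms for every residue common to both models;
    residues lacking that atom in either model are listed in ``omitted``.
    """
    xa, xb, _ = _common_atom_arrays(a, b)
    sup = kabsch_superpose(xa, xb, reject_cycles=reject_cycles, reject_sigma=reject_sigma)

    keys_a = {r.key: r for r in a.residues if r.is_nucleic}
    keys_b = {r.key: r for r in b.residues if r.is_nucleic}
    common = [k for k in keys_a if k in keys_b]
    if not common:
        raise PairingError("models share no residues")
    profile = DisplacementProfile(atom_used=atom_used)
    for key in common:
        ra, rb = keys_a[key], keys_b[key]
        at_a, at_b = ra.atom(atom_used), rb.atom(atom_used)
        if at_a is None or at_b is None:
            profile.omitted.append((ra.chain_id, ra.seq_num))
            continue
        moved = sup.rotation @ at_a.coord + sup.translation
        d = float(np.linalg.norm(moved - at_b.coord))
        profile.entries.append((ra.chain_id, ra.seq_num, ra.res_name, d))
    profile.entries.sort(key=lambda e: (e[0], e[1]))
    return profile, sup
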