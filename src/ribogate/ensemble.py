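"""Quantification of conformational ensembles.

An :class:`Ensemble` is an ordered list of structures (e.g. the 20 sub-state
models recovered from a 3D-variability series, ordered from "partly open" to
"fully open"). The analyses here reproduce the standard ensemble summaries:
a pairwise RMSD matrix over the atoms common to all frames, a per-frame
descriptor series, per-residue tip displacements between designated frames
after superposition on a core subdomain, and simple trend statistics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .geometry import DescriptorError, DescriptorSet, SubdomainRegistry, compute_descriptors
from .structures import Selection, Structure, read_structure, resolve_selection
from .superpose import kabsch, kabsch_superpose

__all__ = [
    "Ensemble",
    "EnsembleReport",
    "EnsembleError",
    "read_ensemble",
    "pairwise_rmsd_matrix",
    "descriptor_series",
    "tip_displacement",
    "trend_stats",
    "ensemble_report",
]


class EnsembleError(ValueError):
    """Raised for ensembles with unusable or inconsistent frames."""


@dataclass
class Ensemble:
    frames: list[Structure]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise EnsembleError("an ensemble needs at least 2 frames")
        if not self.labels:
            self.labels = [f"sub-state {i + 1}" for i in range(len(self.frames))]
        if len(self.labels) != len(self.frames) or len(set(self.labels)) != len(self.labels):
            raise EnsembleError("labels must be unique and aligned to frames")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class EnsembleReport:
    rmsd_matrix: np.ndarray
    descriptor_series: list[Optional[DescriptorSet]]
    trend_stats: dict[str, dict[str, float]]
    labels: list[str]


def _natural_key(name: str):
    return [int(tok) if tok.isdigit() else tok for tok in re.split(r"(\d+)", name)]


def read_ensemble(source: Path | str, pattern: str = "*.pdb") -> Ensemble:
    """Read an ensemble from a directory of per-frame files (natural sort)
    or from a single multi-model PDB file."""
    source = Path(source)
    if source.is_dir():
        files = sorted(source.glob(pattern), key=lambda p: _natural_key(p.name))
        if len(files) < 2:
            raise EnsembleError(f"{source}: found {len(files)} frame files")
        frames = [read_structure(p) for p in files]
        return Ensemble(frames=frames, labels=[p.stem for p in files])
    # multi-model file
    import gemmi

    st = gemmi.read_structure(str(source))
    st.setup_entities()
    st.remove_alternative_conformations()
    st.remove_hydrogens()
    st.remove_waters()
    frames = []
    from .structures import Atom, Residue

    for model in st:
        residues = []
        for chain in model:
            for res in chain:
                r = Residue(
                    chain_id=chain.name,
                    seq_num=res.seqid.num,
                    res_name=res.name.strip(),
                    insertion_code=(res.seqid.icode.strip() or None),
                )
                for at in res:
                    r.add_atom(
                        Atom(
                            name=at.name,
                            element=at.element.name,
                            coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                            occupancy=at.occ,
                            b_iso=at.b_iso,
                        )
                    )
                if r.atoms:
                    residues.append(r)
        frames.append(Structure(id=f"{source.stem}_m{model.name}", residues=residues))
    if len(frames) < 2:
        raise EnsembleError(f"{source}: multi-model file has {len(frames)} models")
    return Ensemble(frames=frames)


def _common_coords(e: Ensemble, sel: Optional[Selection]) -> list[np.ndarray]:
    """Per-frame coordinate arrays over the atom keys common to all frames."""
    maps = []
    for frame, label in zip(e.frames, e.labels):
        m = frame.atom_map()
        if sel is not None:
            m = {k: v for k, v in m.items() if sel.contains(k[0], k[1])
                 and (sel.atom_names is None or k[3] in sel.atom_names)}
        if not m:
            raise EnsembleError(f"frame {label!r} has no atoms under the selection")
        maps.append(m)
    common = set(maps[0])
    for m in maps[1:]:
        common &= set(m)
    if len(common) < 3:
        raise EnsembleError(f"only {len(common)} atoms common to all frames")
    keys = sorted(common)
    return [np.array([m[k] for k in keys]) for m in maps]


def pairwise_rmsd_matrix(e: Ensemble, sel: Optional[Selection] = None) -> np.ndarray:
    """Symmetric matrix of Kabsch RMSDs (no rejection) over common atoms."""
    coords = _common_coords(e, sel)
    n = len(coords)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, rmsd = kabsch(coords[i], coords[j])
            mat[i, j] = mat[j, i] = rmsd
    return mat


def descriptor_series(
    e: Ensemble, registry: SubdomainRegistry
) -> list[Optional[DescriptorSet]]:
    """One DescriptorSet per frame, frame order preserved.

    A frame on which an axis fit fails yields ``None`` and the series
    continues (sub-state models may lack disordered peripheral residues).
    """
    out: list[Optional[DescriptorSet]] = []
    for frame in e.frames:
        try:
            out.append(compute_descriptors(frame, registry))
        except DescriptorError:
            out.append(None)
    return out


def tip_displacement(
    e: Ensemble,
    frame_i: int,
    frame_j: int,
    subdomain: str,
    registry: SubdomainRegistry,
    core: str = "core_D1c",
    atom_used: str = "P",
) -> tuple[list[tuple[str, int, float]], float]:
    """Per-residue displacement of a subdomain between two frames.

    The two frames are superposed on the registry's core selection, then
    the displacement of every ``atom_used`` atom within ``subdomain`` is
    reported together with its maximum (the "tip" movement).
    """
    a, b = e.frames[frame_i], e.frames[frame_j]
    core_sel = registry.selection(core).with_atoms(registry.backbone_atoms)
    ra = resolve_selection(a, core_sel)
    rb = resolve_selection(b, core_sel)
    keys_a = {(r.chain_id, r.seq_num, at.name): at.coord for r, at in ra.atoms}
    keys_b = {(r.chain_id, r.seq_num, at.name): at.coord for r, at in rb.atoms}
    common = sorted(set(keys_a) & set(keys_b))
    if len(common) < 3:
        raise EnsembleError("fewer than 3 common core atoms for superposition")
    xa = np.array([keys_a[k] for k in common])
    xb = np.array([keys_b[k] for k in common])
    sup = kabsch_superpose(xa, xb)

    sub_sel = registry.selection(subdomain).with_atoms({atom_used})
    sa = resolve_selection(a, sub_sel)
    sb = resolve_selection(b, sub_sel)
    map_b = {(r.chain_id, r.seq_num): at.coord for r, at in sb.atoms}
    entries: list[tuple[str, int, float]] = []
    for r, at in sa.atoms:
        key = (r.chain_id, r.seq_num)
        if key not in map_b:
            continue
        moved = sup.rotation @ at.coord + sup.translation
        entries.append((r.chain_id, r.seq_num, float(np.linalg.norm(moved - map_b[key]))))
    if not entries:
        raise EnsembleError(f"no common {atom_used} atoms in subdomain {subdomain!r}")
    return entries, max(d for _, _, d in entries)


def trend_stats(series: Sequence[float]) -> dict[str, float]:
    """Monotonicity fraction, range, and endpoints of a scalar series."""
    vals = np.asarray([v for v in series if v is not None and np.isfinite(v)], float)
    if len(vals) < 2:
        raise ValueError("need >= 2 values for trend statistics")
    steps = np.diff(vals)
    return {
        "monotone_fraction": float(np.mean(steps >= 0)),
        "min": float(vals.min()),
        "max": float(vals.max()),
        "first": float(vals[0]),
        "last": float(vals[-1]),
    }


def ensemble_report(
    e: Ensemble, registry: SubdomainRegistry, sel: Optional[Selection] = None
) -> EnsembleReport:
    """Full ensemble summary: RMSD matrix, descriptor series, trends."""
    series = descriptor_series(e, registry)
    trends: dict[str, dict[str, float]] = {}
    for field_name in ("angle_A", "angle_B", "angle_C", "angle_D", "gate_distance", "rg"):
        vals = [getattr(d, field_name) if d is not None else None for d in series]
        if sum(v is not None for v in vals) >= 2:
            trends[field_name] = trend_stats(vals)
    return EnsembleReport(
        rmsd_matrix=pairwise_rmsd_matrix(e, sel),
        descriptor_series=series,
        trend_stats=trends,
        labels=list(e.labels),
    )
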