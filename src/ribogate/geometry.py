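"""Inter-helical scaffold descriptors: axis fits, angles A-D, gate distance, Rg.

A subdomain's helical axis is the total-least-squares 3D line through its
sugar-phosphate backbone atoms, i.e. the principal axis of the centred atom
cloud. Four inter-axis angles plus one interatomic "gate" distance summarise
the geometry of a multi-helix RNA scaffold in a single descriptor record, and
the radius of gyration tracks overall compaction.

Angle conventions: the *directed* angle uses the axis directions oriented
5'->3' along each subdomain's first strand, and lies in [0, 180]; the
*undirected* angle folds that into [0, 90]. Both are always computed, and the
registry decides which one a descriptor reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import yaml

from .structures import Selection, SelectionError, Structure, resolve_selection

__all__ = [
    "BACKBONE_ATOMS",
    "SUGAR_RING_ATOMS",
    "HelixAxis",
    "DescriptorSet",
    "SubdomainRegistry",
    "AxisFitError",
    "DescriptorError",
    "fit_helix_axis",
    "angle_between_axes",
    "gate_distance",
    "radius_of_gyration",
    "compute_descriptors",
    "load_registry",
    "default_registry",
]

#: default sugar-phosphate backbone atom set used for axis fits
BACKBONE_ATOMS = frozenset({"P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'"})
#: optional extension adding the sugar-ring atoms
SUGAR_RING_ATOMS = frozenset({"C1'", "C2'", "O4'"})


class AxisFitError(ValueError):
    """Raised when a helical-axis fit is impossible (too few atoms)."""


class DescriptorError(ValueError):
    """Raised when a descriptor cannot be computed for a model."""


@dataclass
class HelixAxis:
    """A fitted helical axis: anchor point, unit direction, fit residual."""

    anchor: np.ndarray
    direction: np.ndarray
    residual_rms: float
    n_atoms: int
    ambiguous: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, float)
        norm = np.linalg.norm(self.direction)
        if not math.isclose(norm, 1.0, abs_tol=1e-9):
            self.direction = self.direction / norm


@dataclass
class DescriptorSet:
    """One model's scaffold descriptors (angles in degrees, distances in Å)."""

    model_id: str
    angle_A: float
    angle_B: float
    angle_C: float
    angle_D: float
    gate_distance: float
    rg: float
    #: undirected [0, 90] variants, co-reported for every angle
    undirected: dict[str, float] = field(default_factory=dict)
    missing_residues: dict[str, int] = field(default_factory=dict)

    def angle(self, label: str) -> float:
        return getattr(self, f"angle_{label}")

    def as_dict(self) -> dict[str, float]:
        return {
            "model_id": self.model_id,
            "angle_A": self.angle_A,
            "angle_B": self.angle_B,
            "angle_C": self.angle_C,
            "angle_D": self.angle_D,
            "gate_distance": self.gate_distance,
            "rg": self.rg,
        }


@dataclass
class SubdomainRegistry:
    """Named subdomain selections, the gate atoms, and angle definitions.

    ``subdomains`` maps a label to a residue-range :class:`Selection`;
    ``angles`` maps an angle label to the pair of subdomain labels whose axes
    it measures; ``gate`` is the pair of (chain, seq_num, atom name) gate
    atoms. ``backbone_atoms`` is the atom set used for every axis fit.
    """

    name: str
    subdomains: dict[str, Selection]
    angles: dict[str, tuple[str, str]]
    gate: tuple[tuple[str, int, str], tuple[str, int, str]]
    backbone_atoms: frozenset[str] = BACKBONE_ATOMS
    rg_selection: Optional[Selection] = None
    angle_convention: str = "directed"
    notes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, (s1, s2) in self.angles.items():
            if s1 not in self.subdomains or s2 not in self.subdomains:
                raise SelectionError(
                    f"angle {label!r} references unregistered subdomains ({s1!r}, {s2!r})"
                )

    def selection(self, label: str) -> Selection:
        try:
            return self.subdomains[label]
        except KeyError:
            raise SelectionError(f"no subdomain {label!r} in registry {self.name!r}") from None


def _load_registry_dict(cfg: dict) -> SubdomainRegistry:
    chain = cfg.get("chain", "A")
    subdomains = {
        label: Selection.from_ranges(chain, ranges, name=label)
        for label, ranges in cfg["subdomains"].items()
    }
    gate_cfg = cfg["gate"]
    gate = tuple((str(c), int(n), str(a)) for c, n, a in gate_cfg)
    backbone = frozenset(cfg.get("backbone_atoms", sorted(BACKBONE_ATOMS)))
    rg_sel = None
    if "rg_ranges" in cfg:
        rg_sel = Selection.from_ranges(chain, cfg["rg_ranges"], name="rg")
    return SubdomainRegistry(
        name=cfg.get("name", "registry"),
        subdomains=subdomains,
        angles={k: tuple(v) for k, v in cfg["angles"].items()},
        gate=gate,  # type: ignore[arg-type]
        backbone_atoms=backbone,
        rg_selection=rg_sel,
        angle_convention=cfg.get("angle_convention", "directed"),
        notes=cfg.get("notes", {}),
    )


def load_registry(path: Path | str) -> SubdomainRegistry:
    """Load a subdomain registry from a YAML configuration file."""
    with open(path) as fh:
        return _load_registry_dict(yaml.safe_load(fh))


def default_registry() -> SubdomainRegistry:
    """The packaged O. iheyensis group II intron D1 registry."""
    ref = resources.files("ribogate").joinpath("data/oiheyensis_d1.yaml")
    return _load_registry_dict(yaml.safe_load(ref.read_text()))


# ---------------------------------------------------------------------------
# axis fitting


def fit_helix_axis(
    s: Structure,
    sel: Selection,
    atom_set: Optional[Iterable[str]] = None,
    min_atoms: int = 6,
) -> HelixAxis:
    """Total-least-squares line fit to a subdomain's backbone atoms.

    The direction is the largest-variance principal axis of the centred atom
    cloud; the residual is the RMS perpendicular distance to the fitted line.
    The direction sign follows the 5'->3' convention along the subdomain's
    first (lowest-numbered) strand segment: the axis points from the centroid
    of that segment's first three residues toward its last three.
    """
    atoms = frozenset(atom_set) if atom_set is not None else BACKBONE_ATOMS
    res = resolve_selection(s, sel.with_atoms(atoms))
    coords = res.coords
    if len(coords) < min_atoms:
        raise AxisFitError(
            f"selection {sel.name or sel.residue_ranges!r} resolves to "
            f"{len(coords)} atoms (< {min_atoms})"
        )
    centroid = coords.mean(axis=0)
    centred = coords - centroid
    # principal axis via SVD of the centred cloud
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    direction = vt[0]
    ambiguous = False
    if len(svals) >= 2 and (svals[0] - svals[1]) / max(svals[0], 1e-12) < 1e-6:
        ambiguous = True
    # orient 5'->3' along the first strand segment
    first_range = min(sel.residue_ranges, key=lambda r: r[1])
    chain, start, end = first_range
    strand_res = sorted(
        {ra[0].seq_num for ra in res.atoms if ra[0].chain_id == chain and start <= ra[0].seq_num <= end}
    )
    if len(sel.residue_ranges) == 1 and len(strand_res) >= 4:
        # single-range selection = hairpin: the 5' strand is the first half,
        # so the axis points from the open end toward the loop
        strand_res = strand_res[: len(strand_res) // 2]
    if len(strand_res) >= 2:
        k = min(3, len(strand_res) // 2) or 1
        head = strand_res[:k]
        tail = strand_res[-k:]
        def _centroid(nums: list[int]) -> np.ndarray:
            pts = [ra[1].coord for ra in res.atoms if ra[0].seq_num in nums and ra[0].chain_id == chain]
            return np.mean(pts, axis=0)
        sense = _centroid(tail) - _centroid(head)
        if float(sense @ direction) < 0:
            direction = -direction
    # residual: RMS perpendicular distance
    proj = centred @ direction
    perp = centred - np.outer(proj, direction)
    residual = float(np.sqrt(np.mean(np.sum(perp**2, axis=1))))
    return HelixAxis(
        anchor=centroid,
        direction=direction,
        residual_rms=residual,
        n_atoms=len(coords),
        ambiguous=ambiguous,
        label=sel.name,
    )


def angle_between_axes(a: HelixAxis, b: HelixAxis, convention: str = "directed") -> float:
    """Angle between two fitted axes, in degrees.

    ``directed`` -> arccos(a.b) in [0, 180] using the 5'->3'-oriented
    directions; ``undirected`` -> folded into [0, 90].
    """
    cosang = float(np.clip(a.direction @ b.direction, -1.0, 1.0))
    theta = math.degrees(math.acos(cosang))
    if convention == "directed":
        return theta
    if convention == "undirected":
        return min(theta, 180.0 - theta)
    raise ValueError(f"unknown angle convention {convention!r}")


def gate_distance(s: Structure, registry: SubdomainRegistry) -> float:
    """Distance in Å between the registry's two gate atoms."""
    coords = []
    for chain, seq, atom_name in registry.gate:
        res = s.residue(chain, seq)
        atom = res.atom(atom_name) if res is not None else None
        if atom is None:
            raise DescriptorError(
                f"gate atom {atom_name} of residue {chain}:{seq} missing from {s.id!r}"
            )
        coords.append(atom.coord)
    return float(np.linalg.norm(coords[0] - coords[1]))


def radius_of_gyration(s: Structure, sel: Optional[Selection] = None) -> float:
    """Mass-unweighted radius of gyration of the selected heavy atoms."""
    if sel is None:
        coords = np.array(
            [a.coord for r in s.residues for a in r.atoms if a.element.upper() not in ("H", "D")]
        )
    else:
        coords = resolve_selection(s, sel).coords
    if len(coords) < 2:
        raise DescriptorError("radius of gyration needs >= 2 atoms")
    centred = coords - coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centred**2, axis=1))))


def compute_descriptors(s: Structure, registry: SubdomainRegistry) -> DescriptorSet:
    """Compute the full descriptor record for one model.

    Fits one axis per subdomain referenced by the registry's angle
    definitions, then reports the four inter-axis angles (directed convention
    by default, undirected co-reported), the gate distance, and Rg.
    """
    axes: dict[str, HelixAxis] = {}
    missing: dict[str, int] = {}
    for label in {lab for pair in registry.angles.values() for lab in pair}:
        sel = registry.selection(label)
        try:
            axes[label] = fit_helix_axis(s, sel, registry.backbone_atoms)
        except AxisFitError as exc:
            raise DescriptorError(f"axis fit failed for subdomain {label!r}: {exc}") from exc
        resolved = resolve_selection(s, sel.with_atoms(registry.backbone_atoms))
        missing[label] = resolved.missing_residues

    angles: dict[str, float] = {}
    undirected: dict[str, float] = {}
    for label, (s1, s2) in registry.angles.items():
        angles[label] = angle_between_axes(axes[s1], axes[s2], registry.angle_convention)
        undirected[label] = angle_between_axes(axes[s1], axes[s2], "undirected")

    return DescriptorSet(
        model_id=s.id,
        angle_A=angles.get("A", float("nan")),
        angle_B=angles.get("B", float("nan")),
        angle_C=angles.get("C", float("nan")),
        angle_D=angles.get("D", float("nan")),
        gate_distance=gate_distance(s, registry),
        rg=radius_of_gyration(s, registry.rg_selection),
        undirected=undirected,
        missing_residues=missing,
    )
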