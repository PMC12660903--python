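"""Synthetic structure and kinetics generators for testing the pipeline.

The generators emulate the data the analysis stages consume, without any
downloaded coordinates:

* idealised A-form-like RNA duplexes (default 32.7 deg/bp twist, 2.81 Å/bp
  rise — canonical fibre-diffraction values) whose least-squares helical axis
  equals the construction axis exactly in the noiseless limit;
* multi-helix constructs mimicking a four-subdomain scaffold, with all
  pairwise inter-axis angles and the gate distance set by construction;
* linear morph paths and descriptor-sweep ensembles emulating an ordered
  series of conformational sub-states;
* noisy time courses from the two-step splicing scheme and rate tables from
  the Michaelis-Menten law.

Atomistic realism is deliberately not attempted: every downstream operation
consumes backbone atoms, C1', and base-ring centroids only, so base "atoms"
are named pseudo-atoms on a ring template at a fixed radial offset. All
generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .conformation import PURINE_RING_ATOMS, PYRIMIDINE_RING_ATOMS
from .ensemble import Ensemble
from .geometry import BACKBONE_ATOMS, DescriptorSet, SubdomainRegistry, fit_helix_axis
from .kinetics import (
    MichaelisMentenParams,
    TimeCourse,
    TwoStepParams,
    two_step_populations,
)
from .structures import Atom, Residue, Selection, Structure
from .superpose import kabsch

__all__ = [
    "HelixSpec",
    "PlacedHelix",
    "GeometryError",
    "make_helix",
    "make_construct",
    "make_d1_construct",
    "d1_mimic_registry",
    "make_morph",
    "make_sweep_ensemble",
    "make_kinetics_timecourse",
    "make_mm_rate_table",
    "displace_base",
]


class GeometryError(ValueError):
    """Raised when a requested construct geometry has no 3D realisation."""


# per-atom cylindrical placement: name -> (radius Å, phase offset deg, z offset Å)
_BACKBONE_TEMPLATE = {
    "P": (8.9, 0.0, 0.0),
    "OP1": (10.1, 4.0, 0.6),
    "OP2": (9.5, -7.0, -0.5),
    "O5'": (8.2, 7.0, -0.7),
    "C5'": (7.9, 14.0, -1.1),
    "C4'": (7.6, 21.0, -1.4),
    "C3'": (7.9, 28.0, -2.1),
    "O3'": (8.3, 33.0, -2.6),
    "C1'": (7.3, 30.0, -0.9),
}

_ELEMENTS = {"P": "P", "OP1": "O", "OP2": "O", "O5'": "O", "O3'": "O", "O4'": "O"}


def _element_of(name: str) -> str:
    if name in _ELEMENTS:
        return _ELEMENTS[name]
    return name[0]


@dataclass
class HelixSpec:
    """Parameters of one idealised duplex."""

    n_bp: int = 10
    twist: float = 32.7  # deg per bp
    rise: float = 2.81  # Å per bp
    chain_ids: tuple[str, str] = ("A", "A")
    start_seq_nums: tuple[int, int] = (1, 101)
    strand1_base: str = "G"  # purine: 9-atom ring
    strand2_base: str = "C"  # pyrimidine: 6-atom ring
    base_radius: float = 4.2  # radial distance of base-ring centre from axis
    ring_radius: float = 1.4
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bp < 4:
            raise ValueError("n_bp must be >= 4")
        if self.rise <= 0 or not (0 < self.twist < 360):
            raise ValueError("rise must be > 0 and twist in (0, 360)")


@dataclass
class PlacedHelix:
    """A helix plus its rigid placement: axis direction through a hinge point."""

    spec: HelixSpec
    direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, float)
        n = np.linalg.norm(self.direction)
        if n == 0:
            raise GeometryError("placement direction must be non-zero")
        self.direction = self.direction / n
        self.origin = np.asarray(self.origin, float)


def _ring_atoms(names: Sequence[str], centre: np.ndarray, radial: np.ndarray,
                tangential: np.ndarray, ring_radius: float) -> list[tuple[str, np.ndarray]]:
    out = []
    for k, name in enumerate(names):
        ang = 2.0 * math.pi * k / len(names)
        pos = centre + ring_radius * (math.cos(ang) * radial + math.sin(ang) * tangential)
        out.append((name, pos))
    return out


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation mapping unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180 deg: rotate about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def make_helix(spec: HelixSpec) -> Structure:
    """Build an idealised antiparallel duplex along +z.

    Strand 1 runs 5'->3' with increasing z; strand 2 is antiparallel and
    numbered so that residue pairing follows duplex convention (first residue
    of strand 1 pairs with the last of strand 2). Every residue carries the
    full backbone atom set, C1', and a base ring of named pseudo-atoms. The
    structure is rigidly corrected after generation so that the least-squares
    axis of the backbone atoms is exactly +z through the origin; isotropic
    Gaussian coordinate noise (if any) is added afterwards.
    """
    residues: list[Residue] = []
    n = spec.n_bp
    purine = PURINE_RING_ATOMS
    pyrimidine = PYRIMIDINE_RING_ATOMS

    def _residue(chain: str, seq: int, res_name: str, phase_deg: float,
                 z: float) -> Residue:
        # strand 2 sits at phase + 180 deg with the same z offsets (a C2
        # rotation about the axis): paired contributions then cancel in the
        # x-z and y-z covariances, so the cloud's least-squares axis is the
        # construction axis exactly
        r = Residue(chain_id=chain, seq_num=seq, res_name=res_name)
        for name, (rad, dphi, dz) in _BACKBONE_TEMPLATE.items():
            ang = math.radians(phase_deg + dphi)
            pos = np.array([rad * math.cos(ang), rad * math.sin(ang), z + dz])
            r.add_atom(Atom(name=name, element=_element_of(name), coord=pos))
        # base ring centred toward the helix interior
        ang0 = math.radians(phase_deg + 25.0)
        radial_in = -np.array([math.cos(ang0), math.sin(ang0), 0.0])
        tangential = np.array([-math.sin(ang0), math.cos(ang0), 0.0])
        centre = np.array(
            [spec.base_radius * math.cos(ang0), spec.base_radius * math.sin(ang0), z]
        )
        ring = purine if res_name in ("A", "G") else pyrimidine
        for name, pos in _ring_atoms(ring, centre, radial_in, tangential, spec.ring_radius):
            r.add_atom(Atom(name=name, element=_element_of(name), coord=pos))
        return r

    for i in range(n):
        residues.append(
            _residue(spec.chain_ids[0], spec.start_seq_nums[0] + i,
                     spec.strand1_base, i * spec.twist, i * spec.rise)
        )
    for j in range(n):
        # strand 2 residue j pairs with strand-1 residue n-1-j and sits
        # diametrically across the axis from it
        i_pair = n - 1 - j
        phase = i_pair * spec.twist + 180.0
        residues.append(
            _residue(spec.chain_ids[1], spec.start_seq_nums[1] + j,
                     spec.strand2_base, phase, i_pair * spec.rise)
        )
    residues.sort(key=lambda r: (r.chain_id, r.seq_num))
    s = Structure(id=f"helix_{spec.n_bp}bp", residues=residues)

    # rigid correction: make the fitted backbone axis exactly +z through 0
    sel = Selection.from_ranges(
        spec.chain_ids[0],
        [(spec.start_seq_nums[0], spec.start_seq_nums[0] + n - 1),
         (spec.start_seq_nums[1], spec.start_seq_nums[1] + n - 1)],
        name="helix",
    ) if spec.chain_ids[0] == spec.chain_ids[1] else Selection(
        residue_ranges=(
            (spec.chain_ids[0], spec.start_seq_nums[0], spec.start_seq_nums[0] + n - 1),
            (spec.chain_ids[1], spec.start_seq_nums[1], spec.start_seq_nums[1] + n - 1),
        ),
        name="helix",
    )
    axis = fit_helix_axis(s, sel, BACKBONE_ATOMS)
    rot = _rotation_between(axis.direction, np.array([0.0, 0.0, 1.0]))
    s = s.transformed(rot, -rot @ axis.anchor)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        for r in s.residues:
            for a in r.atoms:
                a.coord = a.coord + rng.normal(0.0, spec.noise_sigma, 3)
    return s


def make_construct(placements: Sequence[PlacedHelix], construct_id: str = "construct") -> Structure:
    """Rigidly place several helices; atom identifiers must not collide."""
    residues: list[Residue] = []
    for ph in placements:
        helix = make_helix(ph.spec)
        rot = _rotation_between(np.array([0.0, 0.0, 1.0]), ph.direction)
        helix = helix.transformed(rot, ph.origin)
        residues.extend(helix.residues)
    return Structure(id=construct_id, residues=residues)


# ---------------------------------------------------------------------------
# four-helix scaffold mimic


def _d1_specs(noise_sigma: float, seed: int) -> dict[str, HelixSpec]:
    return {
        "core_D1c": HelixSpec(n_bp=10, chain_ids=("A", "A"), start_seq_nums=(66, 112),
                              noise_sigma=noise_sigma, seed=seed),
        "peripheral_D1c": HelixSpec(n_bp=11, chain_ids=("A", "A"), start_seq_nums=(80, 92),
                                    noise_sigma=noise_sigma, seed=seed + 1),
        "D1d1": HelixSpec(n_bp=10, chain_ids=("A", "A"), start_seq_nums=(124, 233),
                          noise_sigma=noise_sigma, seed=seed + 2),
        "i1_i2": HelixSpec(n_bp=18, chain_ids=("A", "A"), start_seq_nums=(6, 250),
                           noise_sigma=noise_sigma, seed=seed + 3),
    }


def _i1i2_direction(angle_a: float, angle_c: float, angle_d: float) -> np.ndarray:
    """Direction with polar angle C from +z and angle D to the D1d1 axis."""
    a, c, d = (math.radians(x) for x in (angle_a, angle_c, angle_d))
    denom = math.sin(a) * math.sin(c)
    if denom < 1e-9:
        raise GeometryError("degenerate angle combination (A or C near 0/180)")
    cos_phi = (math.cos(d) - math.cos(a) * math.cos(c)) / denom
    if abs(cos_phi) > 1.0 + 1e-9:
        raise GeometryError(
            f"angles A={angle_a}, C={angle_c}, D={angle_d} admit no 3D realisation"
        )
    phi = math.acos(max(-1.0, min(1.0, cos_phi)))
    return np.array([math.sin(c) * math.cos(phi), math.sin(c) * math.sin(phi), math.cos(c)])


def make_d1_construct(
    angle_a: float = 62.9,
    angle_b: float = 30.0,
    angle_c: float = 45.0,
    angle_d: float = 60.0,
    gate_dist: Optional[float] = 32.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    construct_id: str = "d1_mimic",
) -> tuple[Structure, DescriptorSet]:
    """Four-helix scaffold mimic with all pairwise angles set by construction.

    The core helix lies along +z; the other three are placed so the directed
    inter-axis angles equal (A, B, C, D). If ``gate_dist`` is given, the
    second helix of the D1d1 pair is translated (angles unchanged) so the
    C1'(75)-C1'(238) distance equals it. Returns the structure and the
    ground-truth descriptor values used for construction.
    """
    specs = _d1_specs(noise_sigma, seed)
    b = math.radians(angle_b)
    az_b = math.radians(200.0)
    dir_core = np.array([0.0, 0.0, 1.0])
    dir_d1d1 = np.array([math.sin(math.radians(angle_a)), 0.0, math.cos(math.radians(angle_a))])
    dir_periph = np.array([math.sin(b) * math.cos(az_b), math.sin(b) * math.sin(az_b), math.cos(b)])
    dir_i1i2 = _i1i2_direction(angle_a, angle_c, angle_d)

    placements = [
        PlacedHelix(specs["core_D1c"], dir_core, np.zeros(3)),
        PlacedHelix(specs["peripheral_D1c"], dir_periph, np.array([-14.0, -8.0, 26.0])),
        PlacedHelix(specs["D1d1"], dir_d1d1, np.array([20.0, 2.0, -6.0])),
        PlacedHelix(specs["i1_i2"], dir_i1i2, np.array([-8.0, 20.0, -14.0])),
    ]
    s = make_construct(placements, construct_id=construct_id)

    if gate_dist is not None:
        a75 = s.residue("A", 75).atom("C1'")
        a238 = s.residue("A", 238).atom("C1'")
        v = a238.coord - a75.coord
        d0 = float(np.linalg.norm(v))
        shift = (gate_dist - d0) * v / d0
        for r in s.residues:
            if 124 <= r.seq_num <= 133 or 230 <= r.seq_num <= 242:
                for a in r.atoms:
                    a.coord = a.coord + shift
        gate_truth = gate_dist
    else:
        a75 = s.residue("A", 75).atom("C1'")
        a238 = s.residue("A", 238).atom("C1'")
        gate_truth = float(np.linalg.norm(a238.coord - a75.coord))

    coords = np.array([a.coord for r in s.residues for a in r.atoms])
    rg = float(np.sqrt(np.mean(np.sum((coords - coords.mean(axis=0)) ** 2, axis=1))))
    truth = DescriptorSet(
        model_id=construct_id,
        angle_A=angle_a,
        angle_B=angle_b,
        angle_C=angle_c,
        angle_D=angle_d,
        gate_distance=gate_truth,
        rg=rg,
    )
    return s, truth


def d1_mimic_registry() -> SubdomainRegistry:
    """Registry matching the residue layout of :func:`make_d1_construct`."""
    from .geometry import default_registry

    return default_registry()


def displace_base(s: Structure, chain: str, seq_num: int, delta_r: float) -> Structure:
    """Return a copy with one residue's base ring pushed radially from +z.

    Utility for constructing bulged-out positives in a helix built along z.
    """
    out = s.copy()
    res = out.residue(chain, seq_num)
    if res is None:
        raise ValueError(f"no residue {chain}:{seq_num}")
    ring_names = set(PURINE_RING_ATOMS) | set(PYRIMIDINE_RING_ATOMS)
    centroid = np.mean(
        [a.coord for a in res.atoms if a.name in ring_names], axis=0
    )
    radial = centroid - np.array([0.0, 0.0, centroid[2]])
    radial = radial / np.linalg.norm(radial)
    for a in res.atoms:
        if a.name in ring_names:
            a.coord = a.coord + delta_r * radial
    return out


# ---------------------------------------------------------------------------
# morphs and sweeps


def make_morph(a: Structure, b: Structure, n_frames: int) -> Ensemble:
    """Linear Cartesian morph from a to b after superposing b onto a."""
    if n_frames < 2:
        raise ValueError("need n_frames >= 2")
    ma = a.atom_map(heavy_only=False)
    mb = b.atom_map(heavy_only=False)
    if set(ma) != set(mb):
        raise ValueError("structures have differing atom layouts")
    keys = sorted(ma)
    xa = np.array([ma[k] for k in keys])
    xb = np.array([mb[k] for k in keys])
    rot, tr, _ = kabsch(xb, xa)
    xb_aligned = xb @ rot.T + tr
    frames = []
    for f in range(n_frames):
        w = f / (n_frames - 1)
        coords = (1 - w) * xa + w * xb_aligned
        frame = a.copy()
        frame.id = f"morph_{f + 1:03d}"
        lookup = dict(zip(keys, coords))
        for r in frame.residues:
            for at in r.atoms:
                at.coord = np.array(lookup[(r.chain_id, r.seq_num, r.insertion_code or "", at.name)])
        frames.append(frame)
    return Ensemble(frames=frames, labels=[f.id for f in frames])


def make_sweep_ensemble(
    descriptor: str,
    values: Sequence[float],
    base_kwargs: Optional[dict] = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[Ensemble, list[float]]:
    """One frame per value, sweeping a single descriptor of the D1 mimic.

    ``descriptor`` is one of angle_A..angle_D or gate_distance; all other
    construction parameters stay fixed, so an angle sweep is a pure rotation
    of the designated helix about its hinge point. Returns the ensemble and
    the ground-truth series.
    """
    kw = dict(base_kwargs or {})
    key_map = {
        "angle_A": "angle_a", "angle_B": "angle_b", "angle_C": "angle_c",
        "angle_D": "angle_d", "gate_distance": "gate_dist",
    }
    if descriptor not in key_map:
        raise ValueError(f"unknown descriptor {descriptor!r}")
    frames = []
    for i, v in enumerate(values):
        kw_i = dict(kw)
        kw_i[key_map[descriptor]] = float(v)
        kw_i.setdefault("noise_sigma", noise_sigma)
        kw_i["seed"] = seed  # same seed: identical noise, pure descriptor change
        s, _ = make_d1_construct(construct_id=f"sweep_{i + 1:03d}", **kw_i)
        frames.append(s)
    return Ensemble(frames=frames, labels=[f.id for f in frames]), [float(v) for v in values]


# ---------------------------------------------------------------------------
# kinetics data


def make_kinetics_timecourse(
    params: TwoStepParams,
    times: Sequence[float],
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> TimeCourse:
    """Noisy species fractions from the two-step scheme, clipped to [0, 1]."""
    t = np.asarray(times, float)
    prec, inter, lin = two_step_populations(params, t)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        prec = np.clip(prec + rng.normal(0, noise_sigma, t.shape), 0, 1)
        inter = np.clip(inter + rng.normal(0, noise_sigma, t.shape), 0, 1)
        lin = np.clip(lin + rng.normal(0, noise_sigma, t.shape), 0, 1)
    return TimeCourse(times=t, precursor=prec, intermediate=inter, product=lin)


def make_mm_rate_table(
    params: MichaelisMentenParams,
    substrate: Sequence[float],
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """(S, v) table from the Michaelis-Menten law with optional noise."""
    s = np.asarray(substrate, float)
    v = params.rate(s)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        v = np.clip(v + rng.normal(0, noise_sigma, s.shape), 0, None)
    return s, v
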