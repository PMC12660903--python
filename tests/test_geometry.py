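"""Helical-axis fits, inter-axis angles, gate distance, Rg, descriptor sets."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from ribogate.geometry import (
    AxisFitError,
    DescriptorError,
    HelixAxis,
    angle_between_axes,
    compute_descriptors,
    fit_helix_axis,
    gate_distance,
    radius_of_gyration,
)
from ribogate.structures import Atom, Residue, Selection, Structure
from ribogate.synthetic import HelixSpec, make_d1_construct, make_helix


def tls_oracle_direction(coords):
    """Numerical total-least-squares line fit (minimise summed squared
    perpendicular distances over spherical direction parameters)."""
    centred = coords - coords.mean(0)

    def cost(angles):
        th, ph = angles
        d = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
        perp = centred - np.outer(centred @ d, d)
        return np.sum(perp**2)

    best = min(
        (minimize(cost, x0, method="Nelder-Mead",
                  options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 10000})
         for x0 in [(0.1, 0.1), (1.0, 2.0), (2.0, -1.0), (1.5, 4.0)]),
        key=lambda r: r.fun,
    )
    th, ph = best.x
    return np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])


def cloud_structure(coords):
    residues = [
        Residue("A", i + 1, "A", None, [Atom("P", "P", c)]) for i, c in enumerate(coords)
    ]
    return Structure(id="cloud", residues=residues)


HELIX_SEL = Selection.from_ranges("A", [(1, 12), (101, 112)], name="helix")


class TestAxisFit:
    def test_ideal_helix_axis_along_z(self, ideal_helix):
        ax = fit_helix_axis(ideal_helix, HELIX_SEL)
        angle = np.degrees(np.arccos(abs(ax.direction @ [0, 0, 1])))
        assert angle < 1.0
        assert ax.direction[2] > 0  # 5'->3' orientation of strand 1

    def test_axis_equivariant_under_rotation(self, ideal_helix):
        rot = Rotation.from_euler("zyx", [0.4, 1.0, -0.7]).as_matrix()
        rotated = ideal_helix.transformed(rot, np.array([3.0, -2.0, 11.0]))
        ax0 = fit_helix_axis(ideal_helix, HELIX_SEL)
        ax1 = fit_helix_axis(rotated, HELIX_SEL)
        assert np.allclose(ax1.direction, rot @ ax0.direction, atol=1e-6)

    @pytest.mark.parametrize("n", [10, 50, 200])
    def test_matches_numerical_tls_oracle(self, n, rng):
        coords = rng.normal(size=(n, 3)) * [10, 2, 1]  # anisotropic cloud
        s = cloud_structure(coords)
        ax = fit_helix_axis(s, Selection.from_ranges("A", [(1, n)]), atom_set={"P"})
        oracle = tls_oracle_direction(coords)
        cosang = abs(ax.direction @ oracle)
        assert cosang == pytest.approx(1.0, abs=1e-6)
        # residual equals the oracle's perpendicular RMS
        centred = coords - coords.mean(0)
        perp = centred - np.outer(centred @ oracle, oracle)
        assert ax.residual_rms == pytest.approx(np.sqrt(np.mean(np.sum(perp**2, 1))), rel=1e-5)

    def test_too_few_atoms_raises(self, ideal_helix):
        with pytest.raises(AxisFitError):
            fit_helix_axis(ideal_helix, Selection.from_ranges("A", [(1, 3)]), atom_set={"P"})


class TestAngles:
    def test_identical_axes_zero(self):
        a = HelixAxis(np.zeros(3), np.array([0, 0, 1.0]), 0.0, 10)
        assert angle_between_axes(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_axes_ninety(self):
        a = HelixAxis(np.zeros(3), np.array([0, 0, 1.0]), 0.0, 10)
        b = HelixAxis(np.zeros(3), np.array([1.0, 0, 0]), 0.0, 10)
        assert angle_between_axes(a, b) == pytest.approx(90.0)
        assert angle_between_axes(a, b, "undirected") == pytest.approx(90.0)

    def test_undirected_folds_into_ninety(self):
        a = HelixAxis(np.zeros(3), np.array([0, 0, 1.0]), 0.0, 10)
        c = np.array([np.sin(np.radians(150)), 0, np.cos(np.radians(150))])
        b = HelixAxis(np.zeros(3), c, 0.0, 10)
        assert angle_between_axes(a, b) == pytest.approx(150.0)
        assert angle_between_axes(a, b, "undirected") == pytest.approx(30.0)

    def test_two_helix_construct_recovers_57_degrees(self):
        h1 = make_helix(HelixSpec(n_bp=10, chain_ids=("A", "A"), start_seq_nums=(1, 101)))
        h2 = make_helix(HelixSpec(n_bp=10, chain_ids=("B", "B"), start_seq_nums=(1, 101)))
        rot = Rotation.from_euler("y", 57, degrees=True).as_matrix()
        h2 = h2.transformed(rot, np.array([25.0, 0.0, 0.0]))
        merged = Structure(id="two", residues=h1.residues + h2.residues)
        ax1 = fit_helix_axis(merged, Selection.from_ranges("A", [(1, 10), (101, 110)]))
        ax2 = fit_helix_axis(merged, Selection.from_ranges("B", [(1, 10), (101, 110)]))
        assert angle_between_axes(ax1, ax2) == pytest.approx(57.0, abs=1.0)


class TestGateAndRg:
    def test_two_atom_distance(self, registry):
        s = Structure(
            id="gate",
            residues=[
                Residue("A", 75, "G", None, [Atom("C1'", "C", [0, 0, 0])]),
                Residue("A", 238, "U", None, [Atom("C1'", "C", [0, 0, 32.0])]),
            ],
        )
        assert gate_distance(s, registry) == pytest.approx(32.0)

    def test_gate_invariant_under_rigid_transform(self, d1_construct, registry):
        s, _ = d1_construct
        rot = Rotation.from_euler("xz", [1.0, -0.5]).as_matrix()
        moved = s.transformed(rot, np.array([10.0, 20.0, -5.0]))
        assert gate_distance(moved, registry) == pytest.approx(
            gate_distance(s, registry), abs=1e-9
        )

    def test_missing_gate_atom_names_residue(self, registry):
        s = Structure(
            id="gate",
            residues=[Residue("A", 75, "G", None, [Atom("C1'", "C", [0, 0, 0])]),
                      Residue("A", 239, "U", None, [Atom("C1'", "C", [0, 0, 1])])],
        )
        with pytest.raises(DescriptorError, match="238"):
            gate_distance(s, registry)

    def test_rg_two_atoms(self):
        s = cloud_structure(np.array([[0, 0, 0], [2.0, 0, 0]]))
        assert radius_of_gyration(s) == pytest.approx(1.0)

    def test_rg_ring_approaches_radius(self):
        r = 7.5
        for n, tol in [(12, 0.01), (400, 1e-5)]:
            ang = 2 * np.pi * np.arange(n) / n
            coords = np.column_stack([r * np.cos(ang), r * np.sin(ang), np.zeros(n)])
            assert radius_of_gyration(cloud_structure(coords)) == pytest.approx(r, abs=r * tol + 1e-9)

    def test_rg_matches_direct_formula(self, rng):
        coords = rng.normal(size=(80, 3)) * 4
        direct = np.sqrt(np.mean(np.sum((coords - coords.mean(0)) ** 2, axis=1)))
        assert radius_of_gyration(cloud_structure(coords)) == pytest.approx(direct, abs=1e-9)


class TestDescriptorSet:
    def test_construct_recovery_noiseless(self, d1_construct, registry):
        s, truth = d1_construct
        d = compute_descriptors(s, registry)
        for label in "ABCD":
            assert d.angle(label) == pytest.approx(truth.angle(label), abs=1.0)
        assert d.gate_distance == pytest.approx(32.0, abs=0.1)

    @pytest.mark.parametrize("angle_a", [30.0, 57.0, 62.9, 80.5, 90.0])
    def test_angle_recovery_under_noise(self, angle_a, registry):
        s, truth = make_d1_construct(angle_a=angle_a, noise_sigma=0.5, seed=7)
        d = compute_descriptors(s, registry)
        assert d.angle_A == pytest.approx(angle_a, abs=2.0)

    def test_descriptors_invariant_under_rigid_transform(self, d1_construct, registry):
        s, _ = d1_construct
        d0 = compute_descriptors(s, registry)
        rot = Rotation.from_euler("xyz", [2.0, 0.5, -1.5]).as_matrix()
        d1 = compute_descriptors(s.transformed(rot, np.array([7, -3, 2.0])), registry)
        for label in "ABCD":
            assert d1.angle(label) == pytest.approx(d0.angle(label), abs=1e-6)
        assert d1.gate_distance == pytest.approx(d0.gate_distance, abs=1e-6)
        assert d1.rg == pytest.approx(d0.rg, abs=1e-6)

    def test_descriptors_invariant_under_atom_permutation(self, d1_construct, registry):
        s, _ = d1_construct
        shuffled = s.copy()
        for r in shuffled.residues:
            r.atoms = list(reversed(r.atoms))
        d0 = compute_descriptors(s, registry)
        d1 = compute_descriptors(shuffled, registry)
        for label in "ABCD":
            assert d1.angle(label) == pytest.approx(d0.angle(label), abs=1e-9)

    def test_undirected_angles_coreported(self, d1_construct, registry):
        s, _ = d1_construct
        d = compute_descriptors(s, registry)
        assert set(d.undirected) == {"A", "B", "C", "D"}
        for label, v in d.undirected.items():
            assert 0.0 <= v <= 90.0
            assert v == pytest.approx(min(d.angle(label), 180 - d.angle(label)), abs=1e-9)
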