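"""Path-progress coordinates: milestone distances, spath/zpath, calibration."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ribogate.pathcv import (
    PathReference,
    build_path_from_ensemble,
    calibrate_lambda,
    milestone_distance,
    path_coordinates,
)
from ribogate.structures import Selection
from ribogate.superpose import PairingError, kabsch
from ribogate.synthetic import make_d1_construct, make_morph

P_SEL = Selection.from_ranges(
    "A", [(6, 23), (250, 267), (66, 75), (112, 121)], atoms={"P"}, name="path_atoms"
)


def frame_coords(frame, sel=P_SEL):
    from ribogate.structures import resolve_selection

    return resolve_selection(frame, sel).coords


@pytest.fixture(scope="module")
def morph100():
    a, _ = make_d1_construct(angle_a=62.9, gate_dist=32.0)
    b, _ = make_d1_construct(angle_a=80.5, gate_dist=37.8)
    return make_morph(a, b, 100)


@pytest.fixture(scope="module")
def path20(morph100):
    return build_path_from_ensemble(morph100.frames, P_SEL, n_milestones=20)


class TestMilestoneDistance:
    def test_zero_for_identical(self, rng):
        x = rng.normal(size=(30, 3))
        assert milestone_distance(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_zero_under_rigid_transform(self, rng):
        x = rng.normal(size=(30, 3))
        rot = Rotation.from_euler("xyz", [1.0, 2.0, 3.0]).as_matrix()
        assert milestone_distance(x @ rot.T + [5, 5, 5], x) == pytest.approx(0.0, abs=1e-9)

    def test_msd_equals_squared_kabsch_rmsd(self, rng):
        x = rng.normal(size=(40, 3)) * 3
        y = rng.normal(size=(40, 3)) * 3
        _, _, rmsd = kabsch(x, y)
        assert milestone_distance(x, y, "msd") == pytest.approx(rmsd**2, rel=1e-9)
        assert milestone_distance(x, y, "rmsd") == pytest.approx(rmsd, rel=1e-9)

    def test_atom_count_mismatch(self, rng):
        with pytest.raises(PairingError):
            milestone_distance(rng.normal(size=(10, 3)), rng.normal(size=(12, 3)))


class TestPathCoordinates:
    @pytest.fixture()
    def sharp_path(self, path20):
        # lambda * gap >> 1, the regime of the endpoint limit laws
        gaps = [
            milestone_distance(path20.milestones[i], path20.milestones[i + 1])
            for i in range(path20.n - 1)
        ]
        return PathReference(
            milestones=path20.milestones, lam=20.0 / float(np.mean(gaps))
        )

    def test_at_first_milestone(self, sharp_path):
        pc = path_coordinates(sharp_path.milestones[0], sharp_path)
        assert pc.spath == pytest.approx(1.0, abs=0.05)
        assert -np.log(sharp_path.n) / sharp_path.lam <= pc.zpath <= 1e-9

    def test_at_last_milestone(self, sharp_path):
        pc = path_coordinates(sharp_path.milestones[-1], sharp_path)
        assert pc.spath == pytest.approx(sharp_path.n, abs=0.05)

    def test_matches_naive_extended_precision(self, path20, morph100):
        for frame in morph100.frames[::17]:
            x = frame_coords(frame)
            fast = path_coordinates(x, path20)
            naive = path_coordinates(x, path20, naive=True)
            assert fast.spath == pytest.approx(naive.spath, abs=1e-9)
            assert fast.zpath == pytest.approx(naive.zpath, abs=1e-9)

    def test_equidistant_configuration_gives_midpoint(self, rng):
        # milestones perturbed from one base cloud along directions orthogonal
        # to rigid motions, all at equal amplitude -> all R equal -> (N+1)/2
        n_atoms, n_mil = 30, 5
        base = rng.normal(size=(n_atoms, 3))
        base -= base.mean(0)
        # rigid-motion generators: 3 translations + 3 infinitesimal rotations
        gens = []
        for k in range(3):
            g = np.zeros((n_atoms, 3))
            g[:, k] = 1.0
            gens.append(g.ravel())
        for k in range(3):
            e = np.zeros(3)
            e[k] = 1.0
            gens.append(np.cross(base, e).ravel())
        gbasis = np.linalg.qr(np.array(gens).T)[0]
        milestones = []
        for _ in range(n_mil):
            v = rng.normal(size=3 * n_atoms)
            v -= gbasis @ (gbasis.T @ v)
            v /= np.linalg.norm(v)
            milestones.append(base + 1e-3 * v.reshape(n_atoms, 3))
        ref = PathReference(milestones=milestones, lam=1.0)
        pc = path_coordinates(base, ref)
        assert pc.spath == pytest.approx((n_mil + 1) / 2, abs=1e-6)
        assert np.allclose(pc.per_milestone_R, pc.per_milestone_R[0], rtol=1e-3)

    def test_bounds_hold_for_arbitrary_inputs(self, path20, rng):
        for _ in range(20):
            x = path20.milestones[0] + rng.normal(size=path20.milestones[0].shape) * 2
            pc = path_coordinates(x, path20)
            assert 1.0 <= pc.spath <= path20.n
            assert pc.zpath >= -np.log(path20.n) / path20.lam - 1e-12

    def test_spath_invariant_under_rigid_transform_of_x(self, path20, morph100):
        x = frame_coords(morph100.frames[40])
        rot = Rotation.from_euler("zxz", [0.5, 1.0, -2.0]).as_matrix()
        pc0 = path_coordinates(x, path20)
        pc1 = path_coordinates(x @ rot.T + [10, -4, 3], path20)
        assert pc1.spath == pytest.approx(pc0.spath, abs=1e-6)
        assert pc1.zpath == pytest.approx(pc0.zpath, abs=1e-6)

    def test_monotone_along_clean_morph(self, path20, morph100):
        spaths = [path_coordinates(frame_coords(f), path20).spath for f in morph100.frames]
        assert np.all(np.diff(spaths) >= -1e-9)

    def test_bad_lambda_rejected(self, path20):
        with pytest.raises(ValueError):
            PathReference(milestones=path20.milestones, lam=0.0)


class TestCalibration:
    def test_constant_gap_formula(self, rng):
        base = rng.normal(size=(20, 3))
        # non-rigid stretch: scale one axis progressively for real MSD gaps
        milestones = [base + [0.0, 0.0, 0.1 * k] * np.ones((20, 1)) for k in range(4)]
        # translations are removed by alignment; instead perturb shape
        milestones = [base * (1 + 0.05 * k) for k in range(4)]
        gaps = [milestone_distance(milestones[i], milestones[i + 1]) for i in range(3)]
        lam = calibrate_lambda(milestones)
        assert lam == pytest.approx(2.3 / np.mean(gaps), rel=1e-9)

    def test_identical_milestones_rejected(self, rng):
        base = rng.normal(size=(10, 3))
        with pytest.raises(ValueError):
            calibrate_lambda([base, base.copy()])

    def test_two_milestones_use_single_gap(self, rng):
        a = rng.normal(size=(15, 3))
        b = a * 1.1
        lam = calibrate_lambda([a, b])
        assert lam == pytest.approx(2.3 / milestone_distance(a, b), rel=1e-9)

    def test_milestone_self_consistency(self, path20):
        # milestone k should evaluate close to spath = k
        for k, m in enumerate(path20.milestones, start=1):
            pc = path_coordinates(m, path20)
            assert pc.spath == pytest.approx(k, abs=0.25)


class TestBuildPath:
    def test_two_milestones_are_endpoints(self, morph100):
        ref = build_path_from_ensemble(morph100.frames, P_SEL, n_milestones=2)
        assert ref.provenance["chosen_frames"] == [0, 99]

    def test_all_frames_in_order(self, morph100):
        frames = morph100.frames[::10]
        ref = build_path_from_ensemble(frames, P_SEL, n_milestones=len(frames))
        assert ref.provenance["chosen_frames"] == list(range(len(frames)))

    def test_milestones_evenly_spaced_along_rmsd(self, morph100, path20):
        last = frame_coords(morph100.frames[-1])
        d = np.array([milestone_distance(m, last, "rmsd") for m in path20.milestones])
        steps = -np.diff(d)
        total = d[0] - d[-1]
        assert np.all(steps > 0)
        # deviation from perfectly even spacing, relative to the full range
        targets = np.linspace(d[0], d[-1], path20.n)
        assert np.max(np.abs(d - targets)) <= 0.05 * total

    def test_too_few_frames_rejected(self, morph100):
        with pytest.raises(ValueError):
            build_path_from_ensemble(morph100.frames[:5], P_SEL, n_milestones=10)
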