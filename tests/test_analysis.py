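"""Direction statistics: principal decompositions, angles, correlations, ROC."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from vesselfe.analysis import (
    beam_direction,
    build_records,
    correlation_suite,
    deviatoric_part,
    principal_decomposition,
    tension_compression_roc,
    vessel_angle,
)
from vesselfe.errors import ConfigError


class TestBeamDirection:
    def test_axis_aligned(self):
        assert beam_direction([0, 0, 0], [1, 0, 0]) == pytest.approx([1, 0, 0])

    def test_three_four_five(self):
        assert beam_direction([0, 0, 0], [3, 4, 0]) == pytest.approx(
            [0.6, 0.8, 0]
        )

    def test_equivariant_under_rotation(self, rng):
        a = rng.normal(size=3)
        b = rng.normal(size=3)
        d = beam_direction(a, b)
        for _ in range(5):
            R = Rotation.random(random_state=rng).as_matrix()
            assert beam_direction(R @ a, R @ b) == pytest.approx(R @ d)

    def test_coincident_nodes_rejected(self):
        with pytest.raises(ValueError):
            beam_direction([1, 2, 3], [1, 2, 3])


class TestPrincipalDecomposition:
    def test_diagonal_tensor(self):
        w, V = principal_decomposition(np.diag([5.0, 2.0, 1.0]))
        assert w == pytest.approx([5, 2, 1])
        assert np.abs(V[:, 0]) == pytest.approx([1, 0, 0])

    def test_hydrostatic_degenerate_contract(self):
        w, V = principal_decomposition(3.0 * np.eye(3))
        assert w == pytest.approx([3, 3, 3])
        assert V @ V.T == pytest.approx(np.eye(3))  # any orthonormal basis

    def test_spectral_reconstruction_on_random_tensors(self, rng):
        for _ in range(50):
            A = rng.normal(size=(3, 3))
            A = 0.5 * (A + A.T)
            w, V = principal_decomposition(A)
            assert np.all(np.diff(w) <= 1e-12)
            recon = (V * w) @ V.T
            assert np.abs(recon - A).max() < 1e-9

    def test_asymmetric_input_rejected(self):
        A = np.array([[1.0, 2.0, 0], [0, 1, 0], [0, 0, 1]])
        with pytest.raises(ValueError, match="symmetric"):
            principal_decomposition(A)


class TestDeviatoric:
    def test_hydrostatic_maps_to_zero(self):
        assert np.abs(deviatoric_part(7.0 * np.eye(3))).max() < 1e-15

    def test_traceless_input_unchanged(self):
        A = np.array([[1.0, 2, 0], [2, -3, 1], [0, 1, 2]])
        assert deviatoric_part(A) == pytest.approx(A)

    def test_additive_decomposition_reconstructs(self, rng):
        A = rng.normal(size=(10, 3, 3))
        A = 0.5 * (A + np.swapaxes(A, 1, 2))
        dev = deviatoric_part(A)
        vol = A - dev
        assert np.allclose(dev + vol, A)
        assert np.abs(np.trace(dev, axis1=1, axis2=2)).max() < 1e-12


class TestVesselAngle:
    def test_parallel_and_antiparallel_zero(self):
        assert vessel_angle([1, 0, 0], [1, 0, 0]) == pytest.approx(0.0)
        assert vessel_angle([1, 0, 0], [-1, 0, 0]) == pytest.approx(0.0)

    def test_orthogonal_ninety(self):
        assert vessel_angle([1, 0, 0], [0, 0, 1]) == pytest.approx(90.0)

    def test_forty_five_degrees(self):
        assert vessel_angle([1, 0, 0], np.array([1, 1, 0]) / np.sqrt(2)) == \
            pytest.approx(45.0)

    def test_non_unit_input_rejected(self):
        with pytest.raises(ValueError):
            vessel_angle([2, 0, 0], [1, 0, 0])


class TestBuildRecords:
    @staticmethod
    def _uniaxial_run(cube_mesh, tissue, vessel, dirs):
        from vesselfe.meshing import BeamMesh
        from vesselfe.solver import SolverControls, _run_explicit, PrescribedMotion

        n = len(dirs)
        c = np.full(3, 150.0)
        nodes = np.empty((2 * n, 3))
        nodes[0::2] = c - 35 * dirs
        nodes[1::2] = c + 35 * dirs
        beams = BeamMesh(nodes=nodes, radii=np.full(2 * n, 5.0),
                         elements=np.column_stack([np.arange(0, 2 * n, 2),
                                                   np.arange(1, 2 * n, 2)]))
        X = cube_mesh.nodes.copy()
        F = np.diag([1.1, 1 / np.sqrt(1.1), 1 / np.sqrt(1.1)])

        def motion(t):
            a = min(t / 0.2, 1.0)
            return X @ (np.eye(3) + a * (F - np.eye(3))).T

        ctl = SolverControls(
            prescribed=PrescribedMotion(np.arange(cube_mesh.n_nodes), motion),
            total_time=0.2, output_interval=0.05, fix_bottom=False)
        hist = _run_explicit(cube_mesh, beams, tissue, vessel, ctl, 0.2)
        return hist, beams

    def test_record_cardinality(self, cube_mesh, tissue, vessel, rng):
        dirs = rng.normal(size=(5, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        hist, beams = self._uniaxial_run(cube_mesh, tissue, vessel, dirs)
        rec = build_records(hist, cube_mesh, beams)
        assert len(rec) == hist.n_frames * beams.n_elements
        assert rec["time"].nunique() == hist.n_frames

    def test_angles_match_geometry_under_uniaxial_stress(
        self, cube_mesh, tissue, vessel, rng
    ):
        dirs = rng.normal(size=(8, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        hist, beams = self._uniaxial_run(cube_mesh, tissue, vessel, dirs)
        rec = build_records(hist, cube_mesh, beams)
        last = rec[rec["time"] == rec["time"].max()]
        # principal stress direction is the stretch axis (x); the beam angle
        # must match the geometric angle of the deformed beam to x
        F = np.diag([1.1, 1 / np.sqrt(1.1), 1 / np.sqrt(1.1)])
        d_def = dirs @ F.T
        d_def /= np.linalg.norm(d_def, axis=1, keepdims=True)
        geo = np.degrees(np.arccos(np.abs(d_def[:, 0])))
        assert np.abs(last["angle_stress"].to_numpy() - geo).max() < 0.1

    def test_axial_stress_decreases_with_angle_under_tension(
        self, cube_mesh, tissue, vessel
    ):
        angles = np.radians(np.linspace(5, 85, 9))
        dirs = np.column_stack([np.cos(angles), np.sin(angles),
                                np.zeros_like(angles)])
        hist, beams = self._uniaxial_run(cube_mesh, tissue, vessel, dirs)
        rec = build_records(hist, cube_mesh, beams)
        last = rec[rec["time"] == rec["time"].max()].sort_values("angle_stress")
        stresses = last["axial_stress"].to_numpy()
        assert np.all(np.diff(stresses) < 0)  # strictly decreasing in angle


def synthetic_records(rng, n=200):
    angle = rng.uniform(0, 90, size=n)
    strain = rng.uniform(0, 0.2, size=n)
    noise = rng.normal(0, 10, size=n)
    stress = 300 - 3.0 * angle + 800 * strain + noise
    return pd.DataFrame(
        {
            "angle_stress": angle,
            "angle_strain": angle + rng.normal(0, 2, size=n),
            "axial_stress": stress,
            "e1": strain,
            "s1": 5 * strain + rng.normal(0, 0.1, size=n),
        }
    )


class TestCorrelationSuite:
    def test_perfect_anticorrelation(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": -np.arange(10.0)})
        res = correlation_suite(df, "x", "y")
        assert res.r == pytest.approx(-1.0)
        assert res.slope == pytest.approx(-1.0)

    def test_partial_r_vanishes_by_construction(self, rng):
        n = 500
        z = rng.normal(size=n)
        x = rng.normal(size=n)
        x -= z * (x @ z) / (z @ z)  # x orthogonal to z
        df = pd.DataFrame({"x": x, "y": z.copy(), "z": z})
        res = correlation_suite(df, "x", "y", control="z")
        assert abs(res.partial_r) < 1e-10

    def test_matches_definitional_covariance_formulas(self, rng):
        df = synthetic_records(rng, n=20)
        res = correlation_suite(df, "angle_stress", "axial_stress",
                                control="s1")
        x = df["angle_stress"].to_numpy()
        y = df["axial_stress"].to_numpy()
        z = df["s1"].to_numpy()

        def r(a, b):
            a = a - a.mean()
            b = b - b.mean()
            return (a @ b) / np.sqrt((a @ a) * (b @ b))

        assert res.r == pytest.approx(r(x, y), abs=1e-12)
        expected_partial = (r(x, y) - r(x, z) * r(z, y)) / np.sqrt(
            (1 - r(x, z) ** 2) * (1 - r(z, y) ** 2)
        )
        assert res.partial_r == pytest.approx(expected_partial, abs=1e-12)

    def test_matches_pingouin_partial_correlation(self, rng):
        pingouin = pytest.importorskip("pingouin")
        df = synthetic_records(rng, n=100)
        res = correlation_suite(df, "angle_stress", "axial_stress",
                                control="e1")
        ref = pingouin.partial_corr(df, x="angle_stress", y="axial_stress",
                                    covar="e1")
        assert res.partial_r == pytest.approx(float(ref["r"].iloc[0]),
                                              abs=1e-9)

    def test_log_transform_drops_nonpositive_and_reports(self, rng):
        df = synthetic_records(rng)
        df.loc[:10, "axial_stress"] = -5.0
        res = correlation_suite(df, "angle_stress", "axial_stress",
                                transform="log10")
        assert res.n_dropped == 11
        assert res.n_used == len(df) - 11

    def test_all_dropped_fails(self):
        df = pd.DataFrame({"x": [1.0, 2, 3], "y": [-1.0, -2, -3]})
        with pytest.raises(ConfigError):
            correlation_suite(df, "x", "y", transform="log10")

    def test_zero_variance_fails(self):
        df = pd.DataFrame({"x": [1.0, 1, 1], "y": [1.0, 2, 3]})
        with pytest.raises(ConfigError):
            correlation_suite(df, "x", "y")


class TestRoc:
    @staticmethod
    def records_from(angles, stresses):
        return pd.DataFrame({"angle_stress": angles, "axial_stress": stresses})

    def test_perfect_separation_gives_auc_one(self):
        rec = self.records_from(
            np.r_[np.full(5, 10.0), np.full(5, 80.0)],
            np.r_[np.ones(5), -np.ones(5)],
        )
        res = tension_compression_roc(rec, n_bootstrap=50)
        assert res.auc == pytest.approx(1.0)

    def test_six_point_tie_matches_pair_counting(self):
        angles = np.array([10.0, 20, 30, 30, 50, 70])
        stress = np.array([1.0, 1, -1, 1, -1, -1])
        rec = self.records_from(angles, stress)
        res = tension_compression_roc(rec, n_bootstrap=10)
        # exhaustive pair count: score = -angle, tension should score higher
        pos = -angles[stress > 0]
        neg = -angles[stress < 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert res.auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_matches_sklearn_on_random_data(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        angles = rng.uniform(0, 90, 300)
        stress = rng.normal(size=300)
        stress[stress == 0] = 1.0
        rec = self.records_from(angles, stress)
        res = tension_compression_roc(rec, n_bootstrap=10)
        ref = sk.roc_auc_score((stress > 0).astype(int), -angles)
        assert res.auc == pytest.approx(ref, abs=1e-12)

    def test_independent_predictor_gives_half(self, rng):
        angles = rng.uniform(0, 90, 2000)
        stress = rng.choice([-1.0, 1.0], size=2000)
        res = tension_compression_roc(self.records_from(angles, stress),
                                      n_bootstrap=50)
        assert res.auc == pytest.approx(0.5, abs=0.03)

    def test_bootstrap_ci_brackets_auc_and_is_seeded(self, rng):
        angles = rng.uniform(0, 90, 300)
        df = self.records_from(angles, 100 - 2 * angles + rng.normal(0, 40, 300))
        a = tension_compression_roc(df, n_bootstrap=200, seed=5)
        b = tension_compression_roc(df, n_bootstrap=200, seed=5)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert a.ci_low <= a.auc <= a.ci_high

    def test_single_class_rejected(self):
        rec = self.records_from(np.arange(5.0), np.ones(5))
        with pytest.raises(ConfigError):
            tension_compression_roc(rec, n_bootstrap=10)
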