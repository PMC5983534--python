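import numpy as np
import pytest

from gazeclean import (
    FixationChunk,
    TransformMatrix,
    build_calibration_model,
    correct_path,
    correctness_measure,
    estimate_transform,
    gen_layout,
    inverse_weighted_correction,
    least_squares_transform,
    nearest_references,
)
from gazeclean.correction import CalibrationEntry, CalibrationModel
from gazeclean.errors import (
    DegenerateFitError,
    EmptyInputError,
    InvalidArgumentError,
    RecalibrationRequired,
)
from tests.conftest import static_chunk


def identity_model(positions):
    return CalibrationModel(
        [CalibrationEntry(np.asarray(p, float), TransformMatrix(np.eye(2))) for p in positions]
    )


class TestEstimateTransform:
    def test_exact_chunk_yields_identity(self):
        target = np.array([300.0, 200.0])
        chunk = FixationChunk(np.tile(target, (20, 1)), 0, 19)
        T = estimate_transform(chunk, target)
        assert np.allclose(target @ T.matrix, target, atol=1e-3)
        assert T.M == pytest.approx(1.0, abs=0.01)

    def test_recovers_inverse_of_known_distortion(self):
        # per-sample correspondences fully determine T = D^-1
        rng = np.random.default_rng(0)
        D = np.array([[1.1, 0.0], [0.0, 0.9]])
        clean = rng.uniform(100, 1200, (40, 2))
        observed = clean @ D
        T = estimate_transform(FixationChunk(observed, 0, 39), clean)
        assert np.allclose(T.matrix, np.linalg.inv(D), atol=0.02)

    @pytest.mark.parametrize("seed", range(20))
    def test_simplex_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        D = np.eye(2) + rng.uniform(-0.1, 0.1, (2, 2))
        clean = rng.uniform(50, 1300, (30, 2))
        observed = clean @ D + rng.normal(0, 2, clean.shape)
        T_nm = estimate_transform(observed, clean).matrix
        # independent closed form: normal equations solved directly
        T_ls = np.linalg.solve(observed.T @ observed, observed.T @ clean)
        assert np.abs(T_nm - T_ls).max() < 1e-4

    def test_single_target_maps_centroid_onto_it(self):
        rng = np.random.default_rng(2)
        target = np.array([500.0, 400.0])
        chunk = FixationChunk(target + np.array([25.0, -10.0]) + rng.normal(0, 3, (30, 2)), 0, 29)
        T = estimate_transform(chunk, target)
        assert np.allclose(chunk.centroid @ T.matrix, target, atol=1e-3)
        assert 0.8 < T.M < 1.2  # near-volume-preserving for a small drift

    def test_degenerate_chunk_raises(self):
        with pytest.raises(DegenerateFitError):
            estimate_transform(FixationChunk(np.zeros((5, 2)), 0, 4), [100.0, 100.0])
        with pytest.raises(InvalidArgumentError):
            estimate_transform(static_chunk([1, 1], 1, 5, 0), [np.nan, 0.0])


def test_correctness_measure_examples():
    assert correctness_measure(TransformMatrix(np.eye(2))) == pytest.approx(1.0)
    assert correctness_measure(np.array([[2.0, 0], [0, 0.5]])) == pytest.approx(1.0)
    assert correctness_measure(np.array([[0.5, 0], [0, 0.5]])) == pytest.approx(0.25)


def test_least_squares_requires_full_rank():
    pts = np.tile([5.0, 5.0], (10, 1))
    with pytest.raises(DegenerateFitError):
        least_squares_transform(pts, pts)


class TestCalibrationModel:
    def make_chunks(self, positions, corrupt=()):
        chunks = []
        for i, p in enumerate(positions):
            if i in corrupt:
                # corrupted dwell: gaze parked at the far corner, so the fitted
                # map shrinks heavily and fails the determinant check
                chunks.append(static_chunk([1257, 707], sigma=5, n=40, seed=100 + i))
            else:
                chunks.append(static_chunk(p, sigma=2, n=40, seed=i))
        return chunks

    def test_all_valid_no_replacements(self, calibration_layout):
        pos = calibration_layout.positions
        model = build_calibration_model(self.make_chunks(pos), pos)
        assert all(e.provenance == "fitted" for e in model.entries)
        assert all(e.transform.M >= 0.8 for e in model.entries)

    def test_one_corrupted_dwell_replaced_by_neighbour_mean(self, calibration_layout):
        pos = calibration_layout.positions
        model = build_calibration_model(self.make_chunks(pos, corrupt=(0,)), pos)
        assert model.entries[0].provenance == "replaced"
        # replacement is the elementwise mean of the 2 nearest valid transforms
        d = np.linalg.norm(pos[1:] - pos[0], axis=1)
        nbrs = 1 + np.argsort(d, kind="stable")[:2]
        expected = (model.entries[nbrs[0]].transform.matrix + model.entries[nbrs[1]].transform.matrix) / 2
        assert np.allclose(model.entries[0].transform.matrix, expected)

    def test_four_corrupted_dwells_require_recalibration(self, calibration_layout):
        pos = calibration_layout.positions
        with pytest.raises(RecalibrationRequired):
            build_calibration_model(self.make_chunks(pos, corrupt=(0, 1, 3, 4)), pos)

    def test_json_round_trip(self, calibration_layout, tmp_path):
        pos = calibration_layout.positions
        model = build_calibration_model(self.make_chunks(pos), pos)
        path = tmp_path / "cal.json"
        model.to_json(path)
        back = CalibrationModel.from_json(path)
        for a, b in zip(model.entries, back.entries):
            assert np.allclose(a.transform.matrix, b.transform.matrix)
            assert a.provenance == b.provenance


class TestNearestReferences:
    def test_coincident_reference_first(self):
        refs = np.array([[0, 0], [10, 0], [20, 0]], float)
        idx, d = nearest_references([10, 0], refs, 2)
        assert idx[0] == 1 and d[0] == 0.0

    def test_midway_query_returns_flanking_digits(self, ng50):
        refs = ng50.positions
        mid = (refs[3] + refs[4]) / 2
        idx, d = nearest_references(mid, refs, 2)
        assert set(idx) == {3, 4}

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(9)
        refs = rng.uniform(0, 1000, (9, 2))
        for _ in range(200):
            q = rng.uniform(0, 1000, 2)
            idx, d = nearest_references(q, refs, 4)
            full = sorted(range(9), key=lambda i: (np.linalg.norm(refs[i] - q), i))
            assert list(idx) == full[:4]
            assert np.all(np.diff(d) >= 0)

    def test_errors(self):
        with pytest.raises(EmptyInputError):
            nearest_references([0, 0], np.empty((0, 2)), 1)
        with pytest.raises(InvalidArgumentError):
            nearest_references([0, 0], np.eye(2), 3)


class TestInverseWeightedCorrection:
    def test_single_neighbour_applies_its_transform(self):
        chunk = static_chunk([100, 100], 2, 10, 0)
        T = TransformMatrix(np.array([[1.2, 0], [0, 0.8]]))
        out = inverse_weighted_correction(chunk, [T], [55.0])
        assert np.allclose(out.xy, chunk.xy @ T.matrix)

    def test_zero_distance_short_circuits(self):
        chunk = static_chunk([100, 100], 2, 10, 1)
        Ts = [TransformMatrix(np.eye(2) * s) for s in (1.0, 2.0, 3.0, 4.0)]
        out = inverse_weighted_correction(chunk, Ts, [5.0, 0.0, 3.0, 9.0])
        assert np.allclose(out.xy, chunk.xy @ Ts[1].matrix)

    def test_equal_distances_average_linear_maps(self):
        chunk = static_chunk([50, 80], 3, 12, 2)
        Ts = [TransformMatrix(np.eye(2)), TransformMatrix(2 * np.eye(2))]
        out = inverse_weighted_correction(chunk, Ts, [7.0, 7.0])
        assert np.allclose(out.xy, chunk.xy @ (1.5 * np.eye(2)))

    def test_weights_form_convex_combination(self):
        # output lies between the per-neighbour corrections componentwise
        chunk = static_chunk([200, 200], 2, 8, 3)
        Ts = [TransformMatrix(np.eye(2) * s) for s in (0.9, 1.0, 1.1)]
        out = inverse_weighted_correction(chunk, Ts, [3.0, 5.0, 11.0])
        lo = np.minimum.reduce([chunk.xy @ T.matrix for T in Ts])
        hi = np.maximum.reduce([chunk.xy @ T.matrix for T in Ts])
        assert np.all(out.xy >= lo - 1e-12) and np.all(out.xy <= hi + 1e-12)


class TestCorrectPath:
    def test_path_a_on_calibration_point_uses_its_transform(self, calibration_layout):
        pos = calibration_layout.positions
        model = identity_model(pos)
        scale = np.array([[1.3, 0], [0, 1.3]])
        model.entries[4].transform = TransformMatrix(scale)
        chunk = static_chunk(pos[4], 1, 20, 0)
        out = correct_path(chunk, "A", calibration=model)
        assert np.allclose(out.xy, chunk.xy @ scale)

    def test_identity_model_is_noop_for_supervised_paths(self, calibration_layout):
        model = identity_model(calibration_layout.positions)
        chunk = static_chunk([400, 300], 5, 30, 1)
        for path in ("A", "B"):
            out = correct_path(chunk, path, calibration=model)
            assert np.allclose(out.xy, chunk.xy, atol=1e-12)

    def test_paths_preserve_sample_count(self, calibration_layout, ng50):
        model = identity_model(calibration_layout.positions)
        chunk = static_chunk([300, 150], 4, 25, 5)
        for path, kwargs in [
            ("A", dict(calibration=model)),
            ("B", dict(calibration=model)),
            ("C", dict(stimulus_positions=ng50.positions)),
            ("D", dict(stimulus_positions=ng50.positions)),
        ]:
            assert len(correct_path(chunk, path, **kwargs)) == 25

    def test_prose_label_convention_swaps_a_and_b(self, calibration_layout):
        pos = calibration_layout.positions
        model = identity_model(pos)
        model.entries[0].transform = TransformMatrix(1.5 * np.eye(2))
        chunk = static_chunk(pos[0], 1, 15, 2)
        # algorithm labels: A = 1 nearest; prose labels: B = 1 nearest
        out_alg = correct_path(chunk, "A", calibration=model)
        out_prose = correct_path(chunk, "B", calibration=model, label_convention="prose")
        assert np.allclose(out_alg.xy, out_prose.xy)

    def test_unsupervised_path_d_recovers_distorted_session(self, ng50):
        # end-to-end nearest-stimulus recovery under a known linear distortion
        D = np.array([[1.05, 0.02], [0.0, 0.97]])
        rng = np.random.default_rng(7)
        raw_hits = corrected_hits = total = 0
        for trial in range(20):
            for k, ent in enumerate(ng50.entities):
                clean = ent.position + rng.normal(0, 2.0, (30, 2))
                chunk = FixationChunk(clean @ D, 0, 29, target_id=ent.id)
                out = correct_path(chunk, "D", stimulus_positions=ng50.positions)
                aoi = ng50.aoi(ent.id, "rectangle")
                from gazeclean import aoi_contains

                raw_hits += aoi_contains(aoi, chunk.centroid)
                corrected_hits += aoi_contains(aoi, out.centroid)
                total += 1
        assert corrected_hits / total > raw_hits / total

    def test_missing_model_errors(self, ng50):
        chunk = static_chunk([100, 100], 2, 10, 0)
        with pytest.raises(InvalidArgumentError):
            correct_path(chunk, "A")
        with pytest.raises(InvalidArgumentError):
            correct_path(chunk, "C")
        with pytest.raises(InvalidArgumentError):
            correct_path(chunk, "E", stimulus_positions=ng50.positions)


def test_distortion_recovery_frobenius_bound():
    # fully determined fits recover near-identity distortions to < 0.05
    rng = np.random.default_rng(12)
    for _ in range(20):
        D = np.eye(2) + rng.uniform(-0.1, 0.1, (2, 2))
        clean = rng.uniform(100, 1200, (50, 2))
        observed = clean @ D + rng.normal(0, 1.0, clean.shape)
        T = estimate_transform(observed, clean)
        assert np.linalg.norm(T.matrix @ D - np.eye(2)) < 0.05
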