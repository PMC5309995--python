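import numpy as np
import pytest

from nucleotool import aggregate as agg
from nucleotool import occupancy as occ
from nucleotool.aggregate import Feature, FeatureSet, ProfileMatrix


def _track(values, chrom="chr1", window=100):
    starts = np.arange(len(values)) * window
    return occ.OccupancyTrack(chrom, window, starts, np.asarray(values, float))


@pytest.fixture
def track():
    return _track(np.arange(10, dtype=float))  # windows 0..900, value = index


class TestFeatureSet:
    def test_anchor_is_centre(self):
        assert Feature("chr1", 100, 301, "f").anchor == 200

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            FeatureSet([Feature("chr1", 0, 10, "a"), Feature("chr1", 20, 30, "a")])

    def test_bed_roundtrip(self, tmp_path):
        feats = [
            Feature("chr1", 100, 300, "a", "+", 7.5),
            Feature("chr2", 50, 250, "b", "-", 1.0),
        ]
        path = tmp_path / "f.bed"
        agg.write_features(feats, path)
        back = agg.read_features(path)
        assert list(back) == feats
        assert back.scores() == {"a": 7.5, "b": 1.0}


class TestBuildProfileMatrix:
    def test_row_equals_extraction(self, track):
        feats = FeatureSet([Feature("chr1", 400, 500, "f")])  # anchor 450 -> window 400
        matrix, dropped = agg.build_profile_matrix({"chr1": track}, feats, 200)
        assert dropped == 0
        assert np.array_equal(matrix.positions, [-200, -100, 0, 100, 200])
        assert np.array_equal(matrix.values[0], [2, 3, 4, 5, 6])

    def test_minus_strand_reversed(self, track):
        plus = FeatureSet([Feature("chr1", 400, 500, "p", "+")])
        minus = FeatureSet([Feature("chr1", 400, 500, "m", "-")])
        mp, _ = agg.build_profile_matrix({"chr1": track}, plus, 200)
        mm, _ = agg.build_profile_matrix({"chr1": track}, minus, 200)
        assert np.array_equal(mm.values[0], mp.values[0][::-1])

    def test_boundary_gaps(self, track):
        feats = FeatureSet([Feature("chr1", 0, 100, "f")])  # anchor 50 -> window 0
        matrix, _ = agg.build_profile_matrix({"chr1": track}, feats, 200)
        assert np.isnan(matrix.values[0][:2]).all()  # positions -200, -100
        assert np.array_equal(matrix.values[0][2:], [0, 1, 2])

    def test_missing_chromosome_dropped(self, track):
        feats = FeatureSet([Feature("chr1", 400, 500, "a"), Feature("chrX", 400, 500, "b")])
        matrix, dropped = agg.build_profile_matrix({"chr1": track}, feats, 100)
        assert dropped == 1
        assert matrix.row_ids == ("a",)

    def test_flank_must_align(self, track):
        feats = FeatureSet([Feature("chr1", 400, 500, "f")])
        with pytest.raises(ValueError):
            agg.build_profile_matrix({"chr1": track}, feats, 150)

    def test_double_strand_flip_identity(self, track):
        feats = FeatureSet([Feature("chr1", 400, 500, "m", "-")])
        matrix, _ = agg.build_profile_matrix({"chr1": track}, feats, 200)
        assert np.array_equal(matrix.values[0][::-1][::-1], matrix.values[0])


class TestFilterArtifacts:
    def _matrix(self, rows):
        rows = np.asarray(rows, float)
        return ProfileMatrix(
            tuple(f"r{i}" for i in range(len(rows))),
            np.arange(rows.shape[1]),
            rows,
        )

    def test_spike_removed(self, rng):
        rows = np.ones((100, 20)) + rng.normal(0, 0.01, (100, 20))
        rows = np.abs(rows)
        rows[7, 3] = 1000.0
        matrix = self._matrix(rows)
        filtered, removed = agg.filter_artifacts(matrix, max_fold=10)
        assert removed == ["r7"]
        assert filtered.n_rows == 99

    def test_homogeneous_untouched(self):
        matrix = self._matrix(np.ones((5, 4)))
        filtered, removed = agg.filter_artifacts(matrix, max_fold=10)
        assert removed == [] and filtered.n_rows == 5

    def test_unreachable_threshold(self, rng):
        matrix = self._matrix(np.abs(rng.random((10, 5))) + 0.1)
        filtered, removed = agg.filter_artifacts(matrix, max_fold=1e12)
        assert removed == []

    def test_all_removed_errors(self):
        matrix = self._matrix([[0.0001, 0.0001, 100.0], [0.0001, 0.0001, 200.0]])
        with pytest.raises(ValueError):
            agg.filter_artifacts(matrix, max_fold=2)

    def test_max_fold_validation(self):
        with pytest.raises(ValueError):
            agg.filter_artifacts(self._matrix(np.ones((2, 2))), max_fold=1.0)


class TestAggregateProfile:
    def test_identical_rows(self):
        row = np.array([1.0, 2.0, 3.0])
        matrix = ProfileMatrix(("a", "b"), np.array([-1, 0, 1]), np.vstack([row, row]))
        _, mean, n = agg.aggregate_profile(matrix)
        assert np.array_equal(mean, row)
        assert np.array_equal(n, [2, 2, 2])

    def test_linearity(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([3.0, 2.0, 1.0])
        matrix = ProfileMatrix(("a", "b"), np.array([-1, 0, 1]), np.vstack([a, b]))
        _, mean, _ = agg.aggregate_profile(matrix)
        assert np.array_equal(mean, (a + b) / 2)

    def test_gap_aware_mean(self):
        values = np.array([[1.0, np.nan], [3.0, 4.0]])
        matrix = ProfileMatrix(("a", "b"), np.array([0, 1]), values)
        _, mean, n = agg.aggregate_profile(matrix)
        assert mean[0] == 2.0 and mean[1] == 4.0
        assert list(n) == [2, 1]

    def test_partition_recombination(self, rng):
        # aggregate of the whole = gap-weighted combination of the parts
        values = rng.random((10, 6))
        values[rng.random((10, 6)) < 0.2] = np.nan
        matrix = ProfileMatrix(tuple(f"r{i}" for i in range(10)), np.arange(6), values)
        _, mean_all, n_all = agg.aggregate_profile(matrix)
        top = ProfileMatrix(matrix.row_ids[:4], matrix.positions, values[:4])
        bottom = ProfileMatrix(matrix.row_ids[4:], matrix.positions, values[4:])
        _, m1, n1 = agg.aggregate_profile(top)
        _, m2, n2 = agg.aggregate_profile(bottom)
        combined = (np.nan_to_num(m1) * n1 + np.nan_to_num(m2) * n2) / (n1 + n2)
        assert np.allclose(mean_all[n_all > 0], combined[n_all > 0])


class TestSmoothProfile:
    def test_constant_unchanged(self):
        profile = np.full(100, 3.5)
        assert np.allclose(agg.smooth_profile(profile, 51, 3), profile)

    def test_linear_ramp_unchanged(self):
        ramp = np.linspace(0, 10, 200)
        assert np.allclose(agg.smooth_profile(ramp, 51, 3), ramp)

    def test_noise_reduction(self, rng):
        x = np.arange(500)
        clean = np.sin(2 * np.pi * x / 190)
        noisy = clean + rng.normal(0, 0.3, x.size)
        smoothed = agg.smooth_profile(noisy, 51, 3)
        rmse_before = np.sqrt(np.mean((noisy - clean) ** 2))
        rmse_after = np.sqrt(np.mean((smoothed - clean) ** 2))
        assert rmse_after < rmse_before

    @pytest.mark.parametrize("window,polyorder", [(50, 3), (3, 3), (201, 3)])
    def test_invalid_parameters(self, window, polyorder):
        with pytest.raises(ValueError):
            agg.smooth_profile(np.ones(100), window, polyorder)


class TestDerivativeProfile:
    def test_constant_zero(self):
        assert np.allclose(agg.derivative_profile(np.full(50, 2.0)), 0.0)

    def test_ramp_constant_slope(self):
        ramp = 3.0 * np.arange(50, dtype=float)
        assert np.allclose(agg.derivative_profile(ramp), 3.0)

    def test_ramp_with_step(self):
        ramp = 3.0 * np.arange(50, dtype=float)
        assert np.allclose(agg.derivative_profile(ramp, step=100.0), 0.03)

    def test_sine_derivative(self):
        x = np.arange(0, 1900, dtype=float)
        period = 190.0
        y = np.sin(2 * np.pi * x / period)
        deriv = agg.derivative_profile(y)
        expected = (2 * np.pi / period) * np.cos(2 * np.pi * x / period)
        assert np.allclose(deriv[1:-1], expected[1:-1], atol=1e-3)

    def test_too_short(self):
        with pytest.raises(ValueError):
            agg.derivative_profile([1.0])


class TestSymmetry:
    def test_strand_balanced_aggregate_symmetric(self):
        # asymmetric signal + balanced strands -> symmetric aggregate
        values = np.arange(21, dtype=float)
        track = _track(values)
        feats = FeatureSet(
            [Feature("chr1", 1000, 1100, "p", "+"), Feature("chr1", 1000, 1100, "m", "-")]
        )
        matrix, _ = agg.build_profile_matrix({"chr1": track}, feats, 500)
        _, mean, _ = agg.aggregate_profile(matrix)
        assert np.allclose(mean, mean[::-1])


class TestMatrixIO:
    def test_roundtrip(self, tmp_path, rng):
        values = rng.random((4, 5))
        values[0, 0] = np.nan
        matrix = ProfileMatrix(("a", "b", "c", "d"), np.array([-200, -100, 0, 100, 200]), values)
        path = tmp_path / "m.tsv.gz"
        agg.write_matrix(matrix, path)
        back = agg.read_matrix(path)
        assert back.row_ids == matrix.row_ids
        assert np.array_equal(back.positions, matrix.positions)
        assert np.allclose(back.values, matrix.values, equal_nan=True, atol=1e-6)

    def test_aggregate_export(self, tmp_path):
        agg.write_aggregate(np.array([-100, 0]), np.array([1.0, np.nan]), np.array([2, 0]), tmp_path / "a.tsv")
        lines = (tmp_path / "a.tsv").read_text().splitlines()
        assert lines[0] == "position\tmean\tn"
        assert lines[2].split("\t") == ["0", "nan", "0"]
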