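import numpy as np
import pytest

import hfnca as h
from hfnca.features import (
    ANGLE_SUM_LABEL,
    add_angle_sum,
    dihedral_to_trig,
    make_feature_table,
    read_feature_table,
    standardize,
    subsample_snapshots,
    write_feature_table,
)
from hfnca.internal_coords import InternalCoordinateSeries
from hfnca.io import Frame, Trajectory


def _series(values, labels, kinds):
    values = np.asarray(values, float)
    return InternalCoordinateSeries(
        values=values, labels=labels, kinds=kinds,
        frame_indices=np.arange(values.shape[0]),
    )


@pytest.mark.parametrize("theta,expected", [(0.0, (1.0, 0.0)), (90.0, (0.0, 1.0))])
def test_trig_expansion_reference_angles(theta, expected):
    s = _series([[theta], [theta]], ["X"], ["D"])
    m, labels, kinds = dihedral_to_trig(s)
    assert labels == ["X:cos", "X:sin"]
    assert kinds == ["Dcos", "Dsin"]
    np.testing.assert_allclose(m[0], expected, atol=1e-12)


def test_trig_identity_rowwise(rng):
    vals = rng.uniform(-180, 180, (50, 3))
    s = _series(vals, ["a", "b", "c"], ["D", "D", "D"])
    m, _, kinds = dihedral_to_trig(s)
    cos = m[:, [k == "Dcos" for k in kinds]]
    sin = m[:, [k == "Dsin" for k in kinds]]
    np.testing.assert_allclose(cos**2 + sin**2, 1.0, atol=1e-12)


def test_feature_count_identity():
    """columns = |bonds| + |angles| + 2|dihedrals| (+1 with angle sum)."""
    top = h.build_topology(h.make_idealized_geometry("semiquinone"))
    truth = h.default_ground_truth("semiquinone", seed=5)
    traj = h.simulate_trajectory(
        h.make_idealized_geometry("semiquinone"), truth, 12, seed=5
    )
    series = h.evaluate_series(traj, top)
    ft = h.make_feature_table(series)
    assert ft.n_features == 13 + 19 + 2 * 7 == 46
    ft2 = h.make_feature_table(series, angle_sum=True)
    assert ft2.n_features == 47
    assert ft2.feature_labels[-1] == ANGLE_SUM_LABEL


def test_angle_sum_is_360_for_planar_methyl(methyl_frame, methyl_topology):
    series = h.evaluate_series(Trajectory([methyl_frame]), methyl_topology)
    assert add_angle_sum(series)[0] == pytest.approx(360.0, abs=1e-9)


def test_angle_sum_decreases_under_pyramidal_distortion(methyl_topology):
    """Lifting the carbon out of the H3 plane strictly reduces the angle sum."""
    f = h.make_idealized_geometry("methyl")
    coords = f.coords.copy()
    coords[0, 2] += 0.3  # pyramidalize
    bent = Frame(f.elements, coords)
    series = h.evaluate_series(Trajectory([bent]), methyl_topology)
    assert add_angle_sum(series)[0] < 360.0 - 1e-6


def test_angle_sum_requires_angles():
    s = _series([[1.0], [1.1]], ["H1C1"], ["B"])
    with pytest.raises(ValueError, match="angle"):
        add_angle_sum(s)


def test_standardize_zscore_and_minmax(rng):
    X = rng.uniform(0, 10, (40, 3))
    Z, labels, std, keep = standardize(X, ["a", "b", "c"], "zscore")
    np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-9)
    np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-9)
    M, _, _, _ = standardize(np.array([[2.0], [4.0], [6.0]]), ["x"], "minmax")
    np.testing.assert_allclose(M[:, 0], [0.0, 0.5, 1.0], atol=1e-15)


def test_standardize_inverse_round_trip(rng, methyl_trajectory, methyl_topology):
    series = h.evaluate_series(methyl_trajectory, methyl_topology)
    for mode in ("zscore", "minmax"):
        ft = make_feature_table(series, mode=mode)
        np.testing.assert_allclose(ft.inverse(), series.values, atol=1e-12)


def test_constant_column_dropped_with_warning():
    X = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
    with pytest.warns(UserWarning, match="constant"):
        Z, labels, _, keep = standardize(X, ["var", "const"], "zscore")
    assert labels == ["var"]
    assert Z.shape == (5, 1)
    assert list(keep) == [True, False]


def test_subsample_unit_interval_gives_every_frame():
    np.testing.assert_array_equal(
        subsample_snapshots(7, (1, 1), seed=0), np.arange(7)
    )


def test_subsample_gaps_within_range_and_increasing():
    ids = subsample_snapshots(5000, (1, 80), seed=42)
    gaps = np.diff(ids)
    assert ids[0] == 0
    assert gaps.min() >= 1 and gaps.max() <= 80
    assert (gaps > 0).all()
    assert ids[-1] < 5000


def test_subsample_seed_reproducibility():
    a = subsample_snapshots(2000, (1, 80), seed=9)
    b = subsample_snapshots(2000, (1, 80), seed=9)
    c = subsample_snapshots(2000, (1, 80), seed=10)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, c)


def test_subsample_rejects_interval_beyond_trajectory():
    with pytest.raises(ValueError):
        subsample_snapshots(50, (1, 80), seed=0)


def test_subsample_expected_count_matches_uniform_gap_mean():
    """20 000 frames at gaps U{1..80} give about 20 000/40.5 ~ 494 snapshots."""
    counts = [
        subsample_snapshots(20_000, (1, 80), seed=s).size for s in range(200)
    ]
    mean_gap = 40.5
    expect = 20_000 / mean_gap
    gap_var = (80**2 - 1) / 12
    sd_single = np.sqrt(expect * gap_var) / mean_gap
    sd_mean = sd_single / np.sqrt(len(counts))
    assert abs(np.mean(counts) - expect) < 3 * sd_mean


def test_feature_table_tsv_round_trip(tmp_path, methyl_features):
    write_feature_table(
        methyl_features, tmp_path / "f.tsv", tmp_path / "f_meta.yaml"
    )
    back = read_feature_table(tmp_path / "f.tsv", tmp_path / "f_meta.yaml")
    np.testing.assert_array_equal(back.matrix, methyl_features.matrix)
    assert back.feature_labels == methyl_features.feature_labels
    assert back.kinds == methyl_features.kinds
    np.testing.assert_array_equal(back.snapshot_ids, methyl_features.snapshot_ids)


def test_make_feature_table_subsamples_rows(methyl_trajectory, methyl_topology):
    series = h.evaluate_series(methyl_trajectory, methyl_topology)
    ids = subsample_snapshots(len(methyl_trajectory), (1, 5), seed=2)
    ft = make_feature_table(series, snapshot_ids=ids)
    assert ft.matrix.shape[0] == ids.size
    np.testing.assert_array_equal(ft.snapshot_ids, ids)
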