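import numpy as np
import pytest

import hfnca as h
from hfnca.features import FeatureTable
from hfnca.synthetic import (
    GroundTruth,
    OscillationSpec,
    default_ground_truth,
    make_idealized_geometry,
    simulate_responses,
    simulate_trajectory,
)

EXPECTED_ATOMS = {"methyl": 4, "ethyl": 7, "methyl_peroxy": 6, "semiquinone": 13}
EXPECTED_BONDS = {"methyl": 3, "ethyl": 6, "methyl_peroxy": 5, "semiquinone": 13}


@pytest.mark.parametrize("name", sorted(EXPECTED_ATOMS))
def test_idealized_geometries_have_expected_topology(name):
    frame = make_idealized_geometry(name)
    assert frame.n_atoms == EXPECTED_ATOMS[name]
    bonds = h.detect_bonds(frame, 1.5)
    assert len(bonds) == EXPECTED_BONDS[name]


def test_unknown_radical_rejected():
    with pytest.raises(ValueError, match="unknown radical"):
        make_idealized_geometry("nitroxide")


def test_methyl_is_planar_with_carbon_at_centroid():
    f = make_idealized_geometry("methyl")
    assert np.allclose(f.coords[:, 2], 0.0)
    np.testing.assert_allclose(f.coords[1:].mean(axis=0), f.coords[0], atol=1e-12)


def _still_truth():
    osc = {
        "bond": OscillationSpec(amplitude=0.0),
        "angle": OscillationSpec(amplitude=0.0),
        "torsion": OscillationSpec(amplitude=0.0),
    }
    return GroundTruth(dependencies={}, noise_sd=0.0, oscillations=osc)


@pytest.mark.parametrize("name", ["methyl", "ethyl", "semiquinone"])
def test_zero_amplitude_trajectory_is_static(name):
    frame0 = make_idealized_geometry(name)
    traj = simulate_trajectory(frame0, _still_truth(), 5, seed=0)
    assert len(traj) == 5
    for f in traj.frames:
        np.testing.assert_allclose(f.coords, frame0.coords, atol=1e-9)


def test_trajectory_seed_reproducibility():
    frame0 = make_idealized_geometry("ethyl")
    truth = default_ground_truth("ethyl", seed=0)
    t1 = simulate_trajectory(frame0, truth, 30, seed=4)
    t2 = simulate_trajectory(frame0, truth, 30, seed=4)
    t3 = simulate_trajectory(frame0, truth, 30, seed=5)
    np.testing.assert_array_equal(t1.coords_array(), t2.coords_array())
    assert not np.array_equal(t1.coords_array(), t3.coords_array())


def test_trajectory_preserves_frame0_topology():
    frame0 = make_idealized_geometry("semiquinone")
    truth = default_ground_truth("semiquinone", seed=6)
    traj = simulate_trajectory(frame0, truth, 20, seed=6)
    ref = h.build_topology(frame0)
    got = h.build_topology(traj[0])
    assert got.bonds == ref.bonds
    assert got.angles == ref.angles
    assert got.dihedrals == ref.dihedrals


def test_excessive_amplitude_raises_with_advice():
    frame0 = make_idealized_geometry("methyl")
    osc = {
        "bond": OscillationSpec(amplitude=1.2, frequencies=(0.03,), phases=(1.5,)),
        "angle": OscillationSpec(amplitude=0.0),
        "torsion": OscillationSpec(amplitude=0.0),
    }
    truth = GroundTruth(dependencies={}, oscillations=osc)
    with pytest.raises(ValueError, match="amplitudes"):
        simulate_trajectory(frame0, truth, 60, seed=0)


def test_programmed_bond_sinusoid_recovered_within_2_percent():
    """A single-mode bond oscillation survives the Cartesian round trip."""
    amp, freq, phase = 0.06, 0.037, 0.8
    osc = {
        "bond": OscillationSpec(
            amplitude=amp, frequencies=(freq,), phases=(phase,), jitter_sd=0.0
        ),
        "angle": OscillationSpec(amplitude=0.0),
        "torsion": OscillationSpec(amplitude=0.0),
    }
    truth = GroundTruth(dependencies={}, oscillations=osc)
    frame0 = make_idealized_geometry("methyl")
    traj = simulate_trajectory(frame0, truth, 400, seed=1)
    top = h.build_topology(frame0)
    series = h.evaluate_series(traj, top)
    t = np.arange(1, 400)  # frame 0 is the unperturbed reference
    col = series.values[1:, 0] - 1.08  # H1C1 bond
    design = np.column_stack(
        [np.sin(2 * np.pi * freq * t), np.cos(2 * np.pi * freq * t)]
    )
    coef, *_ = np.linalg.lstsq(design, col, rcond=None)
    recovered = float(np.hypot(*coef))
    assert recovered == pytest.approx(amp, rel=0.02)


def _random_feature_table(rng, n=200, p=4):
    return FeatureTable(
        matrix=rng.standard_normal((n, p)),
        feature_labels=[f"f{i}" for i in range(p)],
        kinds=["B"] * p,
        standardization={"mode": "zscore", "params": {f"f{i}": (0.0, 1.0) for i in range(p)}},
        snapshot_ids=np.arange(n),
    )


def test_zero_noise_unit_coefficient_copies_feature(rng):
    ft = _random_feature_table(rng)
    truth = GroundTruth(
        dependencies={"H1:A_x": [("f2", 1.0)]}, noise_sd=0.0,
    )
    resp = simulate_responses(ft, truth, seed=0)
    np.testing.assert_array_equal(
        resp.component_vector("H1", "A_x").to_numpy(), ft.column("f2")
    )
    # components without planted signal are exactly zero at zero noise
    assert np.all(resp.component_vector("H1", "A_z").to_numpy() == 0.0)


def test_response_variance_follows_variance_algebra(rng):
    """sd(y) ~ sqrt(sum c^2 var + noise^2) for independent features."""
    ft = _random_feature_table(rng, n=2000)
    truth = GroundTruth(
        dependencies={"H1:A_x": [("f0", 0.8), ("f1", -0.5)]}, noise_sd=0.3,
    )
    resp = simulate_responses(ft, truth, seed=3)
    y = resp.component_vector("H1", "A_x").to_numpy()
    v0 = np.var(ft.column("f0"))
    v1 = np.var(ft.column("f1"))
    expect = np.sqrt(0.8**2 * v0 + 0.5**2 * v1 + 0.3**2)
    assert np.std(y) == pytest.approx(expect, rel=0.05)


def test_response_seed_reproducibility(rng):
    ft = _random_feature_table(rng)
    truth = GroundTruth(dependencies={"H1:A_x": [("f0", 1.0)]}, noise_sd=0.2)
    r1 = simulate_responses(ft, truth, seed=9)
    r2 = simulate_responses(ft, truth, seed=9)
    assert r1.table.equals(r2.table)


def test_dangling_feature_label_rejected(rng):
    ft = _random_feature_table(rng)
    truth = GroundTruth(dependencies={"H1:A_x": [("nope", 1.0)]})
    with pytest.raises(ValueError, match="unknown feature"):
        simulate_responses(ft, truth, seed=0)


def test_aiso_dependency_propagates_to_all_components(rng):
    ft = _random_feature_table(rng)
    truth = GroundTruth(dependencies={"H1:A_iso": [("f1", 1.0)]}, noise_sd=0.0)
    resp = simulate_responses(ft, truth, seed=0)
    for comp in ("A_x", "A_y", "A_z", "A_iso"):
        np.testing.assert_allclose(
            resp.component_vector("H1", comp).to_numpy(), ft.column("f1"), atol=1e-12
        )


def test_ground_truth_dict_round_trip():
    truth = default_ground_truth("methyl", seed=3)
    back = GroundTruth.from_dict(truth.to_dict())
    assert back.dependencies == truth.dependencies
    assert back.noise_sd == truth.noise_sd
    assert back.seed == truth.seed
    assert set(back.oscillations) == set(truth.oscillations)
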