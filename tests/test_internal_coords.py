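from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hfnca as h
from hfnca.internal_coords import (
    DegenerateGeometryError,
    bond_angle,
    detect_bonds,
    dihedral_angle,
    enumerate_angles,
    select_dihedrals,
)
from hfnca.io import Frame, Trajectory

TABLE_COUNTS = {
    "methyl": (3, 3, 0),
    "ethyl": (6, 9, 1),
    "methyl_peroxy": (5, 7, 1),
    "semiquinone": (13, 19, 7),
}


@pytest.mark.parametrize("name,expected", TABLE_COUNTS.items())
def test_topology_counts_for_idealized_radicals(name, expected):
    """Bond/angle/dihedral counts of the four reference radicals."""
    top = h.build_topology(h.make_idealized_geometry(name))
    assert (len(top.bonds), len(top.angles), len(top.dihedrals)) == expected


def test_two_distant_atoms_have_no_bond():
    f = Frame(["H", "H"], [[0, 0, 0], [2.0, 0, 0]])
    with pytest.warns(UserWarning, match="isolated"):
        assert detect_bonds(f, 1.5) == []


def test_single_diatomic_bond_yields_no_angles():
    assert enumerate_angles([(0, 1)]) == []


def test_methyl_has_no_dihedral():
    top = h.build_topology(h.make_idealized_geometry("methyl"))
    assert top.dihedrals == []


def test_ethyl_dihedral_central_bond_is_cc():
    top = h.build_topology(h.make_idealized_geometry("ethyl"))
    (a, b, c, d) = top.dihedrals[0]
    assert {b, c} == {0, 1}  # C1-C2


@pytest.mark.parametrize(
    "pts,expected",
    [
        (([0, 0, 0], [1, 0, 0], [2, 0, 0]), 180.0),
        (([1, 0, 0], [0, 0, 0], [0, 1, 0]), 90.0),
    ],
)
def test_bond_angle_reference_values(pts, expected):
    assert bond_angle(*pts) == pytest.approx(expected, abs=1e-12)


def test_bond_angle_agrees_with_atan2_formulation(rng):
    """Dual-formula oracle: arccos vs atan2(|u×v|, u·v)."""
    for _ in range(1000):
        p = rng.uniform(-2, 2, (3, 3))
        u, v = p[0] - p[1], p[2] - p[1]
        if min(np.linalg.norm(u), np.linalg.norm(v)) < 1e-3:
            continue
        ref = np.degrees(np.arctan2(np.linalg.norm(np.cross(u, v)), np.dot(u, v)))
        assert bond_angle(*p) == pytest.approx(ref, abs=1e-9)


def test_bond_angle_zero_arm_raises():
    with pytest.raises(DegenerateGeometryError):
        bond_angle([0, 0, 0], [0, 0, 0], [1, 0, 0])


@pytest.mark.parametrize(
    "d,expected",
    [
        ([1, 0, 1.0], 0.0),     # eclipsed
        ([-1, 0, 1.0], 180.0),  # anti
    ],
)
def test_dihedral_planar_reference_values(d, expected):
    a, b, c = [1, 0, 0], [0, 0, 0], [0, 0, 1.0]
    assert abs(dihedral_angle(a, b, c, d)) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("theta", [30.0, -30.0, 120.0, -120.0])
def test_dihedral_recovers_rotation_angle(theta):
    """Rotating the far atom about the central axis by theta (axis c -> b,
    matching the sign convention) returns theta."""
    a, b, c = np.array([1.0, 0, 0]), np.zeros(3), np.array([0, 0, 1.0])
    t = np.radians(-theta)  # rotation about b->c axis by -theta
    rot = np.array(
        [[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1]]
    )
    d = rot @ np.array([1.0, 0, 0]) + c
    assert dihedral_angle(a, b, c, d) == pytest.approx(theta, abs=1e-9)


def test_dihedral_collinear_backbone_raises():
    with pytest.raises(DegenerateGeometryError):
        dihedral_angle([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])


def _brute_force_counts(bonds, n_atoms):
    bond_set = {tuple(sorted(b)) for b in bonds}
    degree = np.zeros(n_atoms, int)
    for i, j in bond_set:
        degree[i] += 1
        degree[j] += 1
    angles = sum(
        1
        for i, j, k in (
            (i, j, k)
            for j in range(n_atoms)
            for i, k in combinations(range(n_atoms), 2)
            if i != j and k != j
        )
        if tuple(sorted((i, j))) in bond_set and tuple(sorted((j, k))) in bond_set
    )
    # bonds with a valid chain a-b-c-d, a != d, on either side
    dihedral_bonds = 0
    adj = {i: set() for i in range(n_atoms)}
    for i, j in bond_set:
        adj[i].add(j)
        adj[j].add(i)
    for b, c in sorted(bond_set):
        nb_b, nb_c = adj[b] - {c}, adj[c] - {b}
        if not nb_b or not nb_c:
            continue
        a = min(nb_b)  # the deterministic terminal choice
        if any(d != a for d in nb_c):
            dihedral_bonds += 1
    return angles, dihedral_bonds


def test_angle_and_dihedral_counts_match_brute_force(rng):
    """Count oracle on random small molecules: sum-of-C(d,2) for angles and
    one dihedral per eligible central bond."""
    for _ in range(30):
        n = int(rng.integers(4, 12))
        coords = rng.uniform(0, 2.5, (n, 3))
        frame = Frame(["C"] * n, coords)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bonds = detect_bonds(frame, cutoff=1.2)
        degree = np.zeros(n, int)
        for i, j in bonds:
            degree[i] += 1
            degree[j] += 1
        angles = enumerate_angles(bonds)
        assert len(angles) == sum(comb(int(d), 2) for d in degree)
        brute_angles, brute_dihedral_bonds = _brute_force_counts(bonds, n)
        assert len(angles) == brute_angles
        dihedrals = select_dihedrals(bonds)
        assert len(dihedrals) == brute_dihedral_bonds
        # one per central pair, valid chains
        centrals = {tuple(sorted((b, c))) for _, b, c, _ in dihedrals}
        assert len(centrals) == len(dihedrals)
        bond_set = {tuple(sorted(b)) for b in bonds}
        for a, b, c, d in dihedrals:
            assert a != d
            assert tuple(sorted((a, b))) in bond_set
            assert tuple(sorted((b, c))) in bond_set
            assert tuple(sorted((c, d))) in bond_set


def test_series_reproduces_construction_values(methyl_frame, methyl_topology):
    traj = Trajectory([methyl_frame])
    series = h.evaluate_series(traj, methyl_topology)
    np.testing.assert_allclose(series.values[0, :3], 1.08, atol=1e-9)
    np.testing.assert_allclose(series.values[0, 3:], 120.0, atol=1e-9)
    assert series.labels == ["H1C1", "H2C1", "H3C1", "H1C1H2", "H1C1H3", "H2C1H3"]


def test_semiquinone_has_39_structure_parameters():
    top = h.build_topology(h.make_idealized_geometry("semiquinone"))
    assert top.n_parameters == 39


def test_series_invariant_under_rigid_motion(rng):
    """Internal coordinates are unchanged by global rotation + translation."""
    truth = h.default_ground_truth("ethyl", seed=3)
    traj = h.simulate_trajectory(h.make_idealized_geometry("ethyl"), truth, 20, seed=3)
    top = h.build_topology(traj[0])
    ref = h.evaluate_series(traj, top)

    # random proper rotation via QR
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    shift = rng.uniform(-5, 5, 3)
    moved = Trajectory(
        [
            Frame(f.elements, f.coords @ q.T + shift, index=f.index)
            for f in traj.frames
        ]
    )
    got = h.evaluate_series(moved, top)
    np.testing.assert_allclose(got.values, ref.values, atol=1e-9)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.integers(0, 2**32 - 1))
def test_angle_and_dihedral_ranges(seed):
    """Angles lie in [0, 180]; dihedrals in (-180, 180]."""
    r = np.random.default_rng(seed)
    p = r.uniform(-1, 1, (4, 3))
    u, v = p[0] - p[1], p[2] - p[1]
    if min(np.linalg.norm(u), np.linalg.norm(v)) > 1e-3:
        ang = bond_angle(p[0], p[1], p[2])
        assert 0.0 <= ang <= 180.0
    try:
        tor = dihedral_angle(*p)
    except DegenerateGeometryError:
        return
    assert -180.0 < tor <= 180.0
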