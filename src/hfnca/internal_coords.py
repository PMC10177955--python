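"""Internal-coordinate (structure parameter) extraction from trajectories.

Molecular topology — bonds, bond angles, dihedral angles — is determined once
from the first frame (the geometry-optimized reference structure) using a
plain distance cutoff, and then evaluated on every frame of the trajectory.
Freezing the topology on frame 0 avoids spurious bonds from close non-bonded
contacts sampled later in the dynamics.

Conventions
-----------
* Bonds are unordered atom-index pairs stored as (i, j) with i < j; a bond is
  any pair with Euclidean distance strictly below the cutoff (default 1.5 Å,
  which covers the C–H, C–C, C–O, O–O and O–H bonds of small organic
  radicals).
* One bond angle (i, j, k), i < k, per unordered neighbor pair at every
  vertex j of degree ≥ 2; values in degrees, range [0, 180].
* Exactly one dihedral per central bond (b, c) where both endpoints have an
  additional neighbor: the terminal atoms are the lowest-index neighbors of
  b and c respectively (deterministic and order-stable); signed torsion in
  degrees, range (−180, 180].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import Frame, Trajectory, atom_labels

__all__ = [
    "InternalCoordinateSet",
    "InternalCoordinateSeries",
    "DegenerateGeometryError",
    "detect_bonds",
    "enumerate_angles",
    "select_dihedrals",
    "build_topology",
    "bond_angle",
    "dihedral_angle",
    "evaluate_series",
]

DEFAULT_CUTOFF = 1.5  # Å; distance threshold separating chemical bonds

_EPS = 1e-10


class DegenerateGeometryError(ValueError):
    """Zero-length bond vector or collinear dihedral backbone."""


def detect_bonds(frame0: Frame, cutoff: float = DEFAULT_CUTOFF) -> list[tuple[int, int]]:
    """All unordered atom pairs of ``frame0`` closer than ``cutoff`` Å.

    Atoms of degree zero trigger a warning (an isolated atom carries no
    structure parameters) but are not an error.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = frame0.coords
    n = frame0.n_atoms
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    bonds = [(i, j) for i in range(n) for j in range(i + 1, n) if dist[i, j] < cutoff]
    degree = np.zeros(n, dtype=int)
    for i, j in bonds:
        degree[i] += 1
        degree[j] += 1
    isolated = np.flatnonzero(degree == 0)
    if isolated.size:
        labels = atom_labels(frame0.elements)
        warnings.warn(
            f"isolated atoms (no neighbor within {cutoff} Å): "
            f"{[labels[i] for i in isolated]}",
            stacklevel=2,
        )
    return bonds


def _adjacency(bonds: Sequence[tuple[int, int]]) -> dict[int, list[int]]:
    adj: dict[int, list[int]] = {}
    for i, j in bonds:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    return {k: sorted(v) for k, v in adj.items()}


def enumerate_angles(bonds: Sequence[tuple[int, int]]) -> list[tuple[int, int, int]]:
    """One angle (i, j, k), i < k, per neighbor pair at each vertex j of degree ≥ 2."""
    adj = _adjacency(bonds)
    angles = []
    for j in sorted(adj):
        nb = adj[j]
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                angles.append((nb[a], j, nb[b]))
    return angles


def select_dihedrals(
    bonds: Sequence[tuple[int, int]],
) -> list[tuple[int, int, int, int]]:
    """Exactly one dihedral (a, b, c, d) per central bond with both endpoints of degree ≥ 2.

    Terminal atoms are chosen deterministically: ``a`` is the lowest-index
    neighbor of ``b`` other than ``c``, and ``d`` the lowest-index neighbor of
    ``c`` other than ``b``.  If that yields a == d (three-membered ring), ``d``
    advances to the next-lowest index; if no valid choice remains the bond is
    skipped.
    """
    adj = _adjacency(bonds)
    dihedrals = []
    for b, c in sorted(bonds):
        nb_b = [x for x in adj.get(b, []) if x != c]
        nb_c = [x for x in adj.get(c, []) if x != b]
        if not nb_b or not nb_c:
            continue
        a = nb_b[0]
        d = next((x for x in nb_c if x != a), None)
        if d is None:
            continue
        dihedrals.append((a, b, c, d))
    return dihedrals


@dataclass
class InternalCoordinateSet:
    """Frozen molecular topology: indexed bonds, angles, dihedrals plus the cutoff used."""

    bonds: list[tuple[int, int]]
    angles: list[tuple[int, int, int]]
    dihedrals: list[tuple[int, int, int, int]]
    cutoff: float = DEFAULT_CUTOFF
    atom_labels: list[str] = field(default_factory=list)

    @property
    def n_parameters(self) -> int:
        """Structure-parameter count: |bonds| + |angles| + |dihedrals|."""
        return len(self.bonds) + len(self.angles) + len(self.dihedrals)

    def labels(self) -> tuple[list[str], list[str]]:
        """Column labels and kind tags ('B', 'A', 'D') in evaluation order."""
        lab = self.atom_labels
        if not lab:
            raise ValueError("atom labels not set on this topology")
        names, kinds = [], []
        for i, j in self.bonds:
            names.append(f"{lab[j]}{lab[i]}")  # higher index first: H1C1
            kinds.append("B")
        for i, j, k in self.angles:
            names.append(f"{lab[i]}{lab[j]}{lab[k]}")
            kinds.append("A")
        for a, b, c, d in self.dihedrals:
            names.append(f"{lab[a]}{lab[b]}{lab[c]}{lab[d]}")
            kinds.append("D")
        return names, kinds

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "atom_labels": list(self.atom_labels),
            "bonds": [list(b) for b in self.bonds],
            "angles": [list(a) for a in self.angles],
            "dihedrals": [list(d) for d in self.dihedrals],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InternalCoordinateSet":
        return cls(
            bonds=[tuple(b) for b in d["bonds"]],
            angles=[tuple(a) for a in d["angles"]],
            dihedrals=[tuple(x) for x in d["dihedrals"]],
            cutoff=float(d["cutoff"]),
            atom_labels=list(d["atom_labels"]),
        )

    def report(self) -> str:
        """Human-readable topology summary."""
        names, kinds = self.labels()
        lines = [
            f"topology (cutoff {self.cutoff} Å): "
            f"{len(self.bonds)} bonds, {len(self.angles)} angles, "
            f"{len(self.dihedrals)} dihedrals",
        ]
        for name, kind in zip(names, kinds):
            lines.append(f"  {kind}  {name}")
        return "\n".join(lines)


def build_topology(frame0: Frame, cutoff: float = DEFAULT_CUTOFF) -> InternalCoordinateSet:
    """Detect bonds on the reference frame and enumerate angles and dihedrals."""
    bonds = detect_bonds(frame0, cutoff)
    return InternalCoordinateSet(
        bonds=bonds,
        angles=enumerate_angles(bonds),
        dihedrals=select_dihedrals(bonds),
        cutoff=cutoff,
        atom_labels=atom_labels(frame0.elements),
    )


def bond_angle(p_i, p_j, p_k) -> float:
    """Angle in degrees at vertex ``p_j``, clamped arccos of the normalized dot product."""
    u = np.asarray(p_i, float) - np.asarray(p_j, float)
    v = np.asarray(p_k, float) - np.asarray(p_j, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _EPS or nv < _EPS:
        raise DegenerateGeometryError("zero-length arm in bond angle")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral_angle(p_a, p_b, p_c, p_d) -> float:
    """Signed torsion in degrees, range (−180, 180], about the b–c axis.

    Positive when, looking down b→c, the far bond c–d is rotated clockwise
    from the near bond b–a (the standard atan2-of-cross-products convention).
    """
    p_a, p_b, p_c, p_d = (np.asarray(p, float) for p in (p_a, p_b, p_c, p_d))
    u1 = p_b - p_a
    u2 = p_c - p_b
    u3 = p_d - p_c
    n1 = np.cross(u1, u2)
    n2 = np.cross(u2, u3)
    nu2 = np.linalg.norm(u2)
    if nu2 < _EPS:
        raise DegenerateGeometryError("coincident central atoms in dihedral")
    if np.linalg.norm(n1) < _EPS or np.linalg.norm(n2) < _EPS:
        raise DegenerateGeometryError("collinear dihedral backbone")
    m1 = np.cross(n1, u2 / nu2)
    ang = float(np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2))))
    if ang <= -180.0:
        ang += 360.0
    return ang


@dataclass
class InternalCoordinateSeries:
    """Per-frame structure-parameter values: bonds (Å), angles and dihedrals (degrees)."""

    values: np.ndarray  # (n_frames, n_parameters)
    labels: list[str]
    kinds: list[str]  # 'B' | 'A' | 'D' per column
    frame_indices: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.frame_indices = np.asarray(self.frame_indices, int)
        if self.values.shape != (len(self.frame_indices), len(self.labels)):
            raise ValueError("values shape inconsistent with labels/frames")
        if len(self.kinds) != len(self.labels):
            raise ValueError("kinds and labels length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite internal coordinate values")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.labels)
        df.insert(0, "frame", self.frame_indices)
        return df


def _angles_vectorized(coords: np.ndarray, angles: Sequence[tuple[int, int, int]]) -> np.ndarray:
    idx = np.asarray(angles, int)
    u = coords[:, idx[:, 0]] - coords[:, idx[:, 1]]
    v = coords[:, idx[:, 2]] - coords[:, idx[:, 1]]
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    small = (nu < _EPS) | (nv < _EPS)
    if small.any():
        f = int(np.argwhere(small)[0][0])
        raise DegenerateGeometryError(f"zero-length angle arm at frame {f}")
    cosang = np.clip(np.einsum("fij,fij->fi", u, v) / (nu * nv), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def _dihedrals_vectorized(
    coords: np.ndarray, dihedrals: Sequence[tuple[int, int, int, int]]
) -> np.ndarray:
    idx = np.asarray(dihedrals, int)
    u1 = coords[:, idx[:, 1]] - coords[:, idx[:, 0]]
    u2 = coords[:, idx[:, 2]] - coords[:, idx[:, 1]]
    u3 = coords[:, idx[:, 3]] - coords[:, idx[:, 2]]
    n1 = np.cross(u1, u2)
    n2 = np.cross(u2, u3)
    nu2 = np.linalg.norm(u2, axis=-1)
    bad = (
        (nu2 < _EPS)
        | (np.linalg.norm(n1, axis=-1) < _EPS)
        | (np.linalg.norm(n2, axis=-1) < _EPS)
    )
    if bad.any():
        f = int(np.argwhere(bad)[0][0])
        raise DegenerateGeometryError(f"degenerate dihedral backbone at frame {f}")
    m1 = np.cross(n1, u2 / nu2[..., None])
    ang = np.degrees(
        np.arctan2(np.einsum("fij,fij->fi", m1, n2), np.einsum("fij,fij->fi", n1, n2))
    )
    ang[ang <= -180.0] += 360.0
    return ang


def evaluate_series(
    traj: Trajectory, ics: InternalCoordinateSet
) -> InternalCoordinateSeries:
    """Evaluate every bond, angle and dihedral of ``ics`` on every frame.

    Column order is bonds, then angles, then dihedrals, each in topology
    order; labels use element + ordinal atom names.  Degenerate geometry in
    any frame raises :class:`DegenerateGeometryError` naming the frame.
    """
    coords = traj.coords_array()  # (F, N, 3)
    cols = []
    if ics.bonds:
        idx = np.asarray(ics.bonds, int)
        cols.append(np.linalg.norm(coords[:, idx[:, 1]] - coords[:, idx[:, 0]], axis=-1))
    if ics.angles:
        cols.append(_angles_vectorized(coords, ics.angles))
    if ics.dihedrals:
        cols.append(_dihedrals_vectorized(coords, ics.dihedrals))
    values = np.hstack(cols) if cols else np.empty((len(traj), 0))
    names, kinds = ics.labels()
    return InternalCoordinateSeries(
        values=values,
        labels=names,
        kinds=kinds,
        frame_indices=np.array([f.index for f in traj.frames]),
    )
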