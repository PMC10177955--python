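"""Synthetic data generation: idealized radicals, oscillating trajectories, planted responses.

This module replaces the quantum-chemistry stage of the workflow (geometry
optimization, ab initio MD, hyperfine DFT) with controllable stand-ins:

* idealized geometries of four small organic radicals (methyl, ethyl, methyl
  peroxy, p-benzosemiquinone) with textbook bond lengths and angles;
* trajectories whose internal coordinates oscillate as superpositions of
  sine waves plus Gaussian jitter — the dominant character of real MD
  structure-parameter time series — rebuilt into Cartesian frames by
  sequential Z-matrix-style placement;
* hyperfine responses that are known linear functions of chosen feature
  columns plus Gaussian noise, so recovery of the planted dependencies can
  be verified exactly.

Default oscillation amplitudes (bonds ±0.1 Å, angles ±8°, torsions ±15°)
mimic the structure-parameter spreads of MD at several hundred kelvin while
keeping the frame-0 topology intact.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .features import FeatureTable
from .internal_coords import (
    DEFAULT_CUTOFF,
    bond_angle,
    build_topology,
    dihedral_angle,
)
from .io import Frame, HyperfineResponseSet, Trajectory, atom_labels

__all__ = [
    "OscillationSpec",
    "GroundTruth",
    "RADICALS",
    "make_idealized_geometry",
    "simulate_trajectory",
    "simulate_responses",
    "default_ground_truth",
]

RADICALS = ("methyl", "ethyl", "methyl_peroxy", "semiquinone")

_DEG = np.pi / 180.0


# ---------------------------------------------------------------------------
# idealized geometries
# ---------------------------------------------------------------------------

def _methyl() -> Frame:
    # planar CH3: C at the centroid, three H at 1.08 Å, 120° apart
    r = 1.08
    coords = [[0.0, 0.0, 0.0]]
    for k in range(3):
        phi = 90.0 * _DEG + k * 120.0 * _DEG
        coords.append([r * np.cos(phi), r * np.sin(phi), 0.0])
    return Frame(["C", "H", "H", "H"], np.array(coords), comment="idealized methyl radical")


def _tetra_dirs(axis: np.ndarray, phis: Sequence[float]) -> list[np.ndarray]:
    """Unit vectors at the tetrahedral angle (109.47°) from ``axis``."""
    axis = axis / np.linalg.norm(axis)
    # orthonormal complement
    helper = np.array([0.0, 1.0, 0.0])
    if abs(np.dot(helper, axis)) > 0.9:
        helper = np.array([0.0, 0.0, 1.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    ca, sa = -1.0 / 3.0, np.sqrt(8.0) / 3.0
    return [
        ca * axis + sa * (np.cos(p * _DEG) * e1 + np.sin(p * _DEG) * e2) for p in phis
    ]


def _ethyl() -> Frame:
    # CH2• radical center C1, methyl carbon C2; H1, H2 on C1; H3-H5 on C2
    cc, ch_a, ch_b = 1.49, 1.08, 1.09
    c1 = np.zeros(3)
    c2 = np.array([cc, 0.0, 0.0])
    h1 = ch_a * np.array([np.cos(120 * _DEG), np.sin(120 * _DEG), 0.0])
    h2 = ch_a * np.array([np.cos(-120 * _DEG), np.sin(-120 * _DEG), 0.0])
    hs = [c2 + ch_b * d for d in _tetra_dirs(c1 - c2, (90.0, 210.0, 330.0))]
    return Frame(
        ["C", "C", "H", "H", "H", "H", "H"],
        np.array([c1, c2, h1, h2, *hs]),
        comment="idealized ethyl radical",
    )


def _methyl_peroxy() -> Frame:
    # CH3-O1-O2•: C-O 1.44 Å, O-O 1.31 Å, C-O-O 111°
    co, oo, ch = 1.44, 1.31, 1.09
    c1 = np.zeros(3)
    o1 = np.array([co, 0.0, 0.0])
    o2 = o1 + oo * np.array([np.cos(111 * _DEG), np.sin(111 * _DEG), 0.0])
    hs = [c1 + ch * d for d in _tetra_dirs(o1 - c1, (90.0, 210.0, 330.0))]
    return Frame(
        ["C", "O", "O", "H", "H", "H"],
        np.array([c1, o1, o2, *hs]),
        comment="idealized methyl peroxy radical",
    )


def _semiquinone() -> Frame:
    # planar p-benzosemiquinone: ring C1-C2-C4-C6-C5-C3, carbonyl O1 on C1,
    # hydroxyl O2-H5 on C6, ring hydrogens H1-H4 on C2, C3, C4, C5
    ring_bond = 1.40
    ring_angles = {  # atom index -> position angle on the hexagon
        0: 90.0,   # C1 (top, carbonyl)
        1: 150.0,  # C2
        2: 30.0,   # C3
        3: 210.0,  # C4
        4: 330.0,  # C5
        5: 270.0,  # C6 (bottom, hydroxyl)
    }
    pos = {i: ring_bond * np.array([np.cos(a * _DEG), np.sin(a * _DEG), 0.0])
           for i, a in ring_angles.items()}
    out = {i: pos[i] / np.linalg.norm(pos[i]) for i in pos}  # outward unit vectors
    o1 = pos[0] + 1.25 * out[0]
    o2 = pos[5] + 1.36 * out[5]
    ring_h = {1: 1.08, 2: 1.08, 3: 1.08, 4: 1.08}
    h_ring = [pos[i] + ring_h[i] * out[i] for i in (1, 2, 3, 4)]
    # hydroxyl H: C6-O2-H5 angle ~109°, in plane
    to_c6 = (pos[5] - o2) / np.linalg.norm(pos[5] - o2)
    perp = np.array([1.0, 0.0, 0.0])
    h5 = o2 + 0.97 * (np.cos(109 * _DEG) * to_c6 + np.sin(109 * _DEG) * perp)
    coords = [pos[0], pos[1], pos[2], pos[3], pos[4], pos[5], o1, o2, *h_ring, h5]
    elements = ["C"] * 6 + ["O"] * 2 + ["H"] * 5
    return Frame(elements, np.array(coords), comment="idealized p-benzosemiquinone radical")


_BUILDERS = {
    "methyl": _methyl,
    "ethyl": _ethyl,
    "methyl_peroxy": _methyl_peroxy,
    "semiquinone": _semiquinone,
}


def make_idealized_geometry(name: str) -> Frame:
    """Idealized reference structure of one of the supported radicals."""
    try:
        return _BUILDERS[name]()
    except KeyError:
        raise ValueError(f"unknown radical {name!r}; choose from {RADICALS}") from None


# ---------------------------------------------------------------------------
# ground truth specification
# ---------------------------------------------------------------------------

@dataclass
class OscillationSpec:
    """Sinusoidal oscillation of one kind of internal coordinate.

    amplitude
        Total peak amplitude (Å for bonds, degrees for angles/torsions)
        split over ``n_modes`` superposed sine waves.
    frequencies / phases
        Explicit mode frequencies (cycles per frame) and phases (radians);
        if omitted they are drawn per coordinate from ``freq_range`` and
        [0, 2π) with the trajectory seed.
    jitter_sd
        Standard deviation of the per-frame Gaussian jitter.
    """

    amplitude: float
    n_modes: int = 3
    freq_range: tuple[float, float] = (0.01, 0.2)
    frequencies: tuple[float, ...] | None = None
    phases: tuple[float, ...] | None = None
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.jitter_sd < 0:
            raise ValueError("amplitude and jitter_sd must be nonnegative")


def _default_oscillations() -> dict:
    return {
        "bond": OscillationSpec(amplitude=0.10, jitter_sd=0.01),
        "angle": OscillationSpec(amplitude=8.0, jitter_sd=1.0),
        "torsion": OscillationSpec(amplitude=15.0, jitter_sd=2.0),
    }


@dataclass
class GroundTruth:
    """Planted structure–response dependencies and oscillation parameters.

    dependencies
        Response label (``"H1:A_iso"`` or ``"H1:A_x"`` etc.) mapped to a list
        of ``(feature_label, coefficient)`` terms; a dependency declared on
        ``A_iso`` is applied to each principal component so the isotropic
        mean inherits it.
    noise_sd
        Gaussian noise standard deviation per response label, or one scalar
        for all responses.
    oscillations
        Per internal-coordinate kind (``bond``, ``angle``, ``torsion``).
    """

    dependencies: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    noise_sd: float | dict[str, float] = 0.1
    oscillations: dict[str, OscillationSpec] = field(default_factory=_default_oscillations)
    seed: int = 0

    def noise_for(self, response_label: str) -> float:
        if isinstance(self.noise_sd, dict):
            nucleus = response_label.split(":")[0]
            return float(
                self.noise_sd.get(response_label, self.noise_sd.get(nucleus, 0.0))
            )
        return float(self.noise_sd)

    def to_dict(self) -> dict:
        return {
            "dependencies": {
                k: [[feat, float(c)] for feat, c in v]
                for k, v in self.dependencies.items()
            },
            "noise_sd": self.noise_sd,
            "oscillations": {
                kind: {
                    "amplitude": s.amplitude,
                    "n_modes": s.n_modes,
                    "freq_range": list(s.freq_range),
                    "frequencies": list(s.frequencies) if s.frequencies else None,
                    "phases": list(s.phases) if s.phases else None,
                    "jitter_sd": s.jitter_sd,
                }
                for kind, s in self.oscillations.items()
            },
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        osc = {
            kind: OscillationSpec(
                amplitude=float(s["amplitude"]),
                n_modes=int(s.get("n_modes", 3)),
                freq_range=tuple(s.get("freq_range", (0.01, 0.2))),
                frequencies=tuple(s["frequencies"]) if s.get("frequencies") else None,
                phases=tuple(s["phases"]) if s.get("phases") else None,
                jitter_sd=float(s.get("jitter_sd", 0.0)),
            )
            for kind, s in d.get("oscillations", {}).items()
        }
        return cls(
            dependencies={
                k: [(feat, float(c)) for feat, c in v]
                for k, v in d.get("dependencies", {}).items()
            },
            noise_sd=d.get("noise_sd", 0.1),
            oscillations=osc or _default_oscillations(),
            seed=int(d.get("seed", 0)),
        )


# ---------------------------------------------------------------------------
# internal-to-Cartesian rebuild (Z-matrix style)
# ---------------------------------------------------------------------------

def _construction_plan(frame0: Frame, bonds: list[tuple[int, int]]):
    """Breadth-first construction tree rooted at the highest-degree atom.

    Returns the placement order and, per atom, the reference triple
    (parent, angle reference, torsion reference or None).
    """
    n = frame0.n_atoms
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    adj = {k: sorted(v) for k, v in adj.items()}
    degree = {i: len(adj[i]) for i in range(n)}
    root = max(range(n), key=lambda i: (degree[i], -i))

    order = [root]
    parent: dict[int, int | None] = {root: None}
    seen = {root}
    dq = deque([root])
    while dq:
        u = dq.popleft()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                parent[v] = u
                order.append(v)
                dq.append(v)
    if len(order) < n:  # disconnected atoms: append, anchored to nothing
        raise ValueError("disconnected molecule; cannot build construction tree")

    coords0 = frame0.coords
    placed: list[int] = []
    refs: dict[int, tuple[int | None, int | None, int | None]] = {}
    for atom in order:
        p = parent[atom]
        if p is None:
            refs[atom] = (None, None, None)
        elif len(placed) == 1:
            refs[atom] = (p, None, None)
        else:
            # angle reference: parent of p if placed, else lowest placed neighbor of p
            q = parent.get(p)
            if q is None or q not in placed:
                q = next(x for x in adj[p] if x in placed and x != atom)
            # torsion reference: a placed atom bonded to q (proper torsion when
            # possible), else any placed atom, skipping collinear choices
            candidates = [x for x in adj[q] if x in placed and x not in (p, atom)]
            candidates += [x for x in placed if x not in (p, q) and x not in candidates]
            r = None
            for cand in candidates:
                n1 = np.cross(coords0[q] - coords0[cand], coords0[p] - coords0[q])
                if np.linalg.norm(n1) > 1e-8:
                    r = cand
                    break
            refs[atom] = (p, q, r)
        placed.append(atom)
    return order, refs


def _nerf(p, q, r, dist, angle_deg, torsion_deg):
    """Place an atom at given distance from p, angle at p toward q, torsion about p-q."""
    bc = p - q
    bc_u = bc / np.linalg.norm(bc)
    n = np.cross(q - r, bc)
    n_u = n / np.linalg.norm(n)
    m = np.cross(n_u, bc_u)
    theta = angle_deg * _DEG
    phi = torsion_deg * _DEG
    d2 = dist * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(phi), -np.sin(theta) * np.sin(phi)]
    )
    return p + d2[0] * bc_u + d2[1] * m + d2[2] * n_u


class _Rebuilder:
    """Rebuild Cartesian frames from per-frame internal coordinate values."""

    def __init__(self, frame0: Frame, order, refs):
        self.frame0 = frame0
        self.order = order
        self.refs = refs
        c0 = frame0.coords
        self.base: dict[int, tuple[float, float, float]] = {}
        self.plane_e2: dict[int, np.ndarray] = {}
        for atom in order:
            p, q, r = refs[atom]
            if p is None:
                continue
            d0 = float(np.linalg.norm(c0[atom] - c0[p]))
            if q is None:
                self.base[atom] = (d0, np.nan, np.nan)
                continue
            a0 = bond_angle(c0[atom], c0[p], c0[q])
            if r is None:
                # in-plane placement: remember the frame-0 in-plane direction
                e1 = c0[q] - c0[p]
                e1 /= np.linalg.norm(e1)
                v = c0[atom] - c0[p]
                perp = v - np.dot(v, e1) * e1
                self.plane_e2[atom] = perp / np.linalg.norm(perp)
                self.base[atom] = (d0, a0, np.nan)
            else:
                t0 = dihedral_angle(c0[r], c0[q], c0[p], c0[atom])
                self.base[atom] = (d0, a0, t0)

    def coordinate_keys(self) -> list[tuple[int, str]]:
        """(atom, kind) keys of all free internal coordinates, in placement order."""
        keys = []
        for atom in self.order:
            p, q, r = self.refs[atom]
            if p is None:
                continue
            keys.append((atom, "bond"))
            if q is not None:
                keys.append((atom, "angle"))
            if r is not None:
                keys.append((atom, "torsion"))
        return keys

    def rebuild(self, values: dict[tuple[int, str], float]) -> np.ndarray:
        """Cartesian coordinates for one frame from internal values.

        ``values`` may omit entries; omitted coordinates keep their frame-0
        value.  The first placed atoms are anchored to their frame-0
        positions/directions, so unperturbed internals reproduce frame 0
        exactly.
        """
        c0 = self.frame0.coords
        pos = np.empty_like(c0)
        for atom in self.order:
            p, q, r = self.refs[atom]
            if p is None:
                pos[atom] = c0[atom]
                continue
            d0, a0, t0 = self.base[atom]
            d = values.get((atom, "bond"), d0)
            if q is None:
                direction = c0[atom] - c0[p]
                direction /= np.linalg.norm(direction)
                pos[atom] = pos[p] + d * direction
                continue
            a = values.get((atom, "angle"), a0)
            if r is None:
                e1 = pos[q] - pos[p]
                e1 /= np.linalg.norm(e1)
                e2 = self.plane_e2[atom]
                e2 = e2 - np.dot(e2, e1) * e1
                e2 /= np.linalg.norm(e2)
                pos[atom] = pos[p] + d * (
                    np.cos(a * _DEG) * e1 + np.sin(a * _DEG) * e2
                )
            else:
                t = values.get((atom, "torsion"), t0)
                pos[atom] = _nerf(pos[p], pos[q], pos[r], d, a, t)
        return pos


# ---------------------------------------------------------------------------
# trajectory simulation
# ---------------------------------------------------------------------------

def _make_oscillator(spec: OscillationSpec, n_frames: int, rng: np.random.Generator):
    """Per-frame offsets: superposed sine waves plus Gaussian jitter."""
    t = np.arange(n_frames)
    if spec.frequencies is not None:
        freqs = np.asarray(spec.frequencies, float)
        phases = (
            np.asarray(spec.phases, float)
            if spec.phases is not None
            else rng.uniform(0.0, 2 * np.pi, freqs.size)
        )
        amps = np.full(freqs.size, spec.amplitude / max(freqs.size, 1))
    else:
        k = spec.n_modes
        freqs = rng.uniform(*spec.freq_range, k)
        phases = rng.uniform(0.0, 2 * np.pi, k)
        shares = rng.dirichlet(np.ones(k))
        amps = spec.amplitude * shares
    wave = np.zeros(n_frames)
    for A, f, ph in zip(amps, freqs, phases):
        wave += A * np.sin(2 * np.pi * f * t + ph)
    if spec.jitter_sd > 0:
        wave += rng.normal(0.0, spec.jitter_sd, n_frames)
    return wave


#: how far beyond the bond cutoff a programmed bond may stretch transiently
#: along the trajectory (bonds brushing past the cutoff in single snapshots
#: is normal MD behavior; topology is frozen from frame 0 anyway)
BOND_STRETCH_SLACK = 0.25  # Å


def _validate_topology(
    coords: np.ndarray, bonds: set[tuple[int, int]], cutoff: float, frame_idx: int
) -> None:
    """Guard against bond breaking/forming: bonds must stay below
    ``cutoff + BOND_STRETCH_SLACK`` and non-bonded pairs above ``cutoff``."""
    n = coords.shape[0]
    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    bond_mask = np.zeros((n, n), dtype=bool)
    for i, j in bonds:
        bond_mask[i, j] = bond_mask[j, i] = True
    np.fill_diagonal(dist, np.inf)
    stretched = bond_mask & (dist >= cutoff + BOND_STRETCH_SLACK)
    formed = ~bond_mask & (dist < cutoff)
    np.fill_diagonal(formed, False)
    if stretched.any():
        i, j = map(int, np.argwhere(stretched)[0])
        raise ValueError(
            f"frame {frame_idx}: bond ({i},{j}) stretched to {dist[i, j]:.3f} Å; "
            f"reduce oscillation amplitudes"
        )
    if formed.any():
        i, j = map(int, np.argwhere(formed)[0])
        raise ValueError(
            f"frame {frame_idx}: non-bonded pair ({i},{j}) at {dist[i, j]:.3f} Å "
            f"< cutoff; reduce oscillation amplitudes"
        )


def simulate_trajectory(
    frame0: Frame,
    truth: GroundTruth,
    n_frames: int,
    seed: int | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> Trajectory:
    """Generate a trajectory whose internal coordinates oscillate sinusoidally.

    A breadth-first construction tree rooted at the highest-degree atom
    defines an independent internal-coordinate set (distance to parent,
    angle, torsion); each coordinate receives its kind's oscillation plus
    jitter and the Cartesian frames are rebuilt by sequential placement.
    Ring-closing bonds, which are not part of the tree, receive their own
    oscillating target lengths, enforced by least-squares refinement of the
    ring angles and torsions whenever the rebuilt closure deviates.  Frame 0
    of the returned trajectory is the unperturbed reference structure (as in
    real MD output, whose first frame is the geometry-optimized structure);
    every frame is checked for bond breaking or forming, which raises with
    advice to reduce amplitudes.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    top = build_topology(frame0, cutoff)
    order, refs = _construction_plan(frame0, top.bonds)
    rb = _Rebuilder(frame0, order, refs)

    tree_edges = {
        tuple(sorted((atom, refs[atom][0])))
        for atom in order
        if refs[atom][0] is not None
    }
    closure_bonds = [b for b in top.bonds if tuple(sorted(b)) not in tree_edges]

    keys = rb.coordinate_keys()
    waves: dict[tuple[int, str], np.ndarray] = {}
    for key in keys:
        spec = truth.oscillations.get(key[1])
        if spec is None or spec.amplitude == 0 and spec.jitter_sd == 0:
            waves[key] = np.zeros(n_frames)
        else:
            waves[key] = _make_oscillator(spec, n_frames, rng)
    closure_targets: dict[tuple[int, int], np.ndarray] = {}
    bond_spec = truth.oscillations.get("bond")
    for b in closure_bonds:
        d0 = float(np.linalg.norm(frame0.coords[b[0]] - frame0.coords[b[1]]))
        wave = (
            _make_oscillator(bond_spec, n_frames, rng)
            if bond_spec is not None
            else np.zeros(n_frames)
        )
        closure_targets[b] = d0 + wave

    # closure refinement adjusts only the angle/torsion internals of atoms on
    # the tree path between the closure endpoints (the ring atoms); leaves
    # hanging off the ring cannot move the closure distance
    parent_of = {atom: refs[atom][0] for atom in order}

    def _path_to_root(a: int) -> list[int]:
        path = [a]
        while parent_of[path[-1]] is not None:
            path.append(parent_of[path[-1]])
        return path

    ring_atoms: set[int] = set()
    for i, j in closure_bonds:
        pi, pj = _path_to_root(i), _path_to_root(j)
        common = set(pi) & set(pj)
        lca = next(a for a in pi if a in common)
        ring_atoms |= set(pi[: pi.index(lca) + 1]) | set(pj[: pj.index(lca) + 1])
    refine_keys = [
        k for k in keys if k[0] in ring_atoms and k[1] in ("angle", "torsion")
    ]
    prior_scale = {"angle": 2.0, "torsion": 4.0}

    bonds_set = {tuple(sorted(b)) for b in top.bonds}
    closure_tol = 0.05  # Å
    base_idx = {"bond": 0, "angle": 1, "torsion": 2}

    # frame 0 is the unperturbed reference structure, as in real MD output
    # where the first frame is the geometry-optimized structure
    frames = [
        Frame(
            frame0.elements,
            frame0.coords.copy(),
            index=0,
            comment=frame0.comment or "reference structure",
        )
    ]
    for f in range(1, n_frames):
        vals = {
            key: rb.base[key[0]][base_idx[key[1]]] + waves[key][f] for key in keys
        }
        coords = rb.rebuild(vals)
        if closure_bonds:
            dev = max(
                abs(np.linalg.norm(coords[i] - coords[j]) - closure_targets[(i, j)][f])
                for i, j in closure_bonds
            )
            if dev > closure_tol:
                coords, vals = _refine_closures(
                    rb, vals, refine_keys, closure_bonds,
                    {b: closure_targets[b][f] for b in closure_bonds},
                    prior_scale,
                )
        _validate_topology(coords, bonds_set, cutoff, f)
        frames.append(
            Frame(frame0.elements, coords, index=f, comment=f"synthetic frame {f}")
        )
    return Trajectory(frames)


def _refine_closures(rb, vals, refine_keys, closure_bonds, targets, prior_scale):
    """Least-squares adjustment of ring angles/torsions to restore closures."""
    x0 = np.array([vals[k] for k in refine_keys])

    def residual(x):
        v = dict(vals)
        for k, xv in zip(refine_keys, x):
            v[k] = xv
        coords = rb.rebuild(v)
        res = [
            (np.linalg.norm(coords[i] - coords[j]) - targets[(i, j)]) / 0.005
            for i, j in closure_bonds
        ]
        res += [
            (xv - vals[k]) / prior_scale[k[1]] for k, xv in zip(refine_keys, x)
        ]
        return np.asarray(res)

    sol = least_squares(residual, x0, method="lm", xtol=1e-10, max_nfev=400)
    out = dict(vals)
    for k, xv in zip(refine_keys, sol.x):
        out[k] = xv
    return rb.rebuild(out), out


# ---------------------------------------------------------------------------
# response simulation
# ---------------------------------------------------------------------------

_PRINCIPAL = ("A_x", "A_y", "A_z")


def simulate_responses(
    features: FeatureTable,
    truth: GroundTruth,
    seed: int | None = None,
    nuclei: Sequence[str] | None = None,
) -> HyperfineResponseSet:
    """Responses as planted linear functions of feature columns plus noise.

    Every nucleus named in the dependency map (or in ``nuclei``) receives all
    three principal components; components without a planted dependency are
    pure noise.  Dependencies on ``A_iso`` are applied to each principal
    component, so the isotropic mean inherits them.
    """
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    dep_nuclei = list(dict.fromkeys(lab.split(":")[0] for lab in truth.dependencies))
    nuclei = list(nuclei) if nuclei is not None else dep_nuclei
    if not nuclei:
        raise ValueError("no nuclei to simulate (empty dependency map)")
    for lab, terms in truth.dependencies.items():
        for feat, _ in terms:
            if feat not in features.feature_labels:
                raise ValueError(
                    f"dependency {lab!r} references unknown feature {feat!r}"
                )

    n = features.matrix.shape[0]
    rows = []
    for nucleus in nuclei:
        comps = {}
        for comp in _PRINCIPAL:
            y = np.zeros(n)
            for key in (f"{nucleus}:{comp}", f"{nucleus}:A_iso"):
                for feat, coeff in truth.dependencies.get(key, []):
                    y = y + coeff * features.column(feat)
            sd = truth.noise_for(f"{nucleus}:{comp}")
            if sd > 0:
                y = y + rng.normal(0.0, sd, n)
            comps[comp] = y
        for r in range(n):
            rows.append(
                (
                    int(features.snapshot_ids[r]),
                    nucleus,
                    comps["A_x"][r],
                    comps["A_y"][r],
                    comps["A_z"][r],
                )
            )
    table = pd.DataFrame(rows, columns=["snapshot", "nucleus", "A_x", "A_y", "A_z"])
    return HyperfineResponseSet(table)


# ---------------------------------------------------------------------------
# ready-made ground truths
# ---------------------------------------------------------------------------

def default_ground_truth(name: str, seed: int = 0) -> GroundTruth:
    """A sensible planted truth for each radical.

    The methyl truth is exactly symmetric under relabeling of H1, H2, H3:
    each hydrogen's isotropic coupling depends (negatively) on its own C–H
    bond and (positively) on the opposite angle, and the carbon's on all
    three bonds equally — mirroring the qualitative structure–hyperfine
    pattern of a planar CH3 radical.
    """
    if name == "methyl":
        deps = {
            "H1:A_iso": [("H1C1", -1.0), ("H2C1H3", 0.7)],
            "H2:A_iso": [("H2C1", -1.0), ("H1C1H3", 0.7)],
            "H3:A_iso": [("H3C1", -1.0), ("H1C1H2", 0.7)],
            "C1:A_iso": [("H1C1", 0.6), ("H2C1", 0.6), ("H3C1", 0.6)],
        }
        return GroundTruth(dependencies=deps, noise_sd=0.3, seed=seed)
    if name == "ethyl":
        deps = {
            "H1:A_iso": [("H1C1", -1.0)],
            "H2:A_iso": [("H2C1", -1.0)],
            "H3:A_iso": [("H3C2C1H1:cos", 1.0)],
            "H4:A_iso": [("H3C2C1H1:cos", 1.0)],
            "H5:A_iso": [("H3C2C1H1:cos", 1.0)],
            "C1:A_iso": [("C2C1", 0.8)],
            "C2:A_iso": [("C2C1", 0.8)],
        }
        return GroundTruth(dependencies=deps, noise_sd=0.3, seed=seed)
    if name == "methyl_peroxy":
        deps = {
            "H1:A_iso": [("H1C1O1O2:cos", 1.0)],
            "H2:A_iso": [("H1C1O1O2:cos", 1.0)],
            "H3:A_iso": [("H1C1O1O2:cos", 1.0)],
            "C1:A_iso": [("O2O1", -1.0)],
            "O1:A_iso": [("O1C1", 0.8)],
            "O2:A_iso": [("C1O1O2", 0.8)],
        }
        return GroundTruth(dependencies=deps, noise_sd=0.3, seed=seed)
    if name == "semiquinone":
        frame = make_idealized_geometry(name)
        labels = atom_labels(frame.elements)
        # oxygen couplings follow the carbonyl bond, carbons their ring bonds,
        # hydrogens their own C-H bond; remaining components are noise
        deps = {f"{lab}:A_iso": [("O1C1", 0.8)] for lab in labels}
        return GroundTruth(dependencies=deps, noise_sd=0.3, seed=seed)
    raise ValueError(f"unknown radical {name!r}; choose from {RADICALS}")
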