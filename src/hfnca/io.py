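"""Reading and writing of multi-frame XYZ trajectories and hyperfine response tables.

The trajectory format is plain XYZ as emitted by quantum-chemistry MD codes:
each frame is an atom-count line, a free-form comment line, and one
``element x y z`` line per atom (coordinates in Å).  Extended-XYZ metadata in
the comment line is carried through opaquely and never parsed.

Hyperfine responses are tab- or comma-delimited tables with header columns
``snapshot, nucleus, A_x, A_y, A_z`` holding the principal values of the
hyperfine coupling tensor in MHz for each (MD snapshot, magnetic nucleus)
pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Frame",
    "Trajectory",
    "HyperfineResponseSet",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "read_response_table",
    "write_response_table",
    "atom_labels",
]

# Element symbols of the periodic table (1-118); used to validate XYZ input.
_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni "
    "Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I "
    "Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt "
    "Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No Lr "
    "Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og".split()
)

_RESPONSE_COLUMNS = ("snapshot", "nucleus", "A_x", "A_y", "A_z")


class XYZParseError(ValueError):
    """Malformed XYZ input (bad count line, truncated frame, bad atom line)."""


class FrameConsistencyError(ValueError):
    """Frames of one trajectory do not share the same atom ordering."""


class ResponseTableError(ValueError):
    """Malformed or inconsistent hyperfine response table."""


@dataclass
class Frame:
    """One trajectory frame: element symbols plus Cartesian coordinates in Å."""

    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3), Å
    index: int = 0
    comment: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n_atoms, 3) array")
        if len(self.elements) != self.coords.shape[0]:
            raise ValueError(
                f"frame {self.index}: {len(self.elements)} elements but "
                f"{self.coords.shape[0]} coordinate rows"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"frame {self.index}: non-finite coordinates")
        bad = [e for e in self.elements if e not in _ELEMENTS]
        if bad:
            raise ValueError(f"frame {self.index}: unknown element symbols {bad}")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclass
class Trajectory:
    """Ordered frames sharing one atom ordering; frame 0 is the reference geometry."""

    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        ref = self.frames[0].elements
        for f in self.frames:
            if f.elements != ref:
                raise FrameConsistencyError(
                    f"frame {f.index} element sequence differs from frame 0"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def elements(self) -> list[str]:
        return self.frames[0].elements

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    def coords_array(self) -> np.ndarray:
        """Stack all frame coordinates into an (n_frames, n_atoms, 3) array."""
        return np.stack([f.coords for f in self.frames])

    def atom_labels(self) -> list[str]:
        return atom_labels(self.elements)


def atom_labels(elements: Sequence[str]) -> list[str]:
    """Element + 1-based per-element ordinal labels in file order (H1, H2, C1, ...)."""
    counts: dict[str, int] = {}
    labels = []
    for el in elements:
        counts[el] = counts.get(el, 0) + 1
        labels.append(f"{el}{counts[el]}")
    return labels


def read_xyz_trajectory(path: str | Path) -> Trajectory:
    """Read a (possibly multi-frame) plain XYZ file.

    Raises
    ------
    XYZParseError
        If a count line is malformed or a frame is truncated; the message
        names the offending frame number.
    FrameConsistencyError
        If a later frame's element sequence differs from frame 0.
    """
    lines = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    pos = 0
    frame_no = 0
    while pos < len(lines):
        if not lines[pos].strip():  # tolerate trailing blank lines
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError:
            raise XYZParseError(
                f"frame {frame_no}: expected atom count, got {lines[pos]!r}"
            ) from None
        if n <= 0:
            raise XYZParseError(f"frame {frame_no}: non-positive atom count {n}")
        if pos + 2 + n > len(lines):
            raise XYZParseError(
                f"frame {frame_no}: declares {n} atoms but file is truncated"
            )
        comment = lines[pos + 1]
        elements: list[str] = []
        coords = np.empty((n, 3))
        for a in range(n):
            raw = lines[pos + 2 + a]
            parts = raw.split()
            if len(parts) < 4:
                raise XYZParseError(
                    f"frame {frame_no}: malformed atom line {raw!r}"
                )
            elements.append(parts[0])
            try:
                coords[a] = [float(v) for v in parts[1:4]]
            except ValueError:
                raise XYZParseError(
                    f"frame {frame_no}: non-numeric coordinate in {raw!r}"
                ) from None
        frames.append(Frame(elements, coords, index=frame_no, comment=comment))
        pos += 2 + n
        frame_no += 1
    if not frames:
        raise XYZParseError("file contains no frames")
    return Trajectory(frames)


def write_xyz_trajectory(traj: Trajectory, path: str | Path, decimals: int = 6) -> None:
    """Write a trajectory as plain multi-frame XYZ with fixed decimal precision."""
    out = []
    for f in traj.frames:
        out.append(str(f.n_atoms))
        out.append(f.comment)
        for el, (x, y, z) in zip(f.elements, f.coords):
            out.append(f"{el} {x:.{decimals}f} {y:.{decimals}f} {z:.{decimals}f}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


@dataclass
class HyperfineResponseSet:
    """Per-(snapshot, nucleus) hyperfine principal values A_x, A_y, A_z in MHz."""

    table: pd.DataFrame  # columns: snapshot, nucleus, A_x, A_y, A_z

    def __post_init__(self) -> None:
        missing = [c for c in _RESPONSE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ResponseTableError(f"missing columns: {missing}")
        dup = self.table.duplicated(subset=["snapshot", "nucleus"])
        if dup.any():
            rows = self.table.loc[dup, ["snapshot", "nucleus"]].values.tolist()
            raise ResponseTableError(f"duplicate (snapshot, nucleus) records: {rows}")
        for c in ("A_x", "A_y", "A_z"):
            if not np.all(np.isfinite(self.table[c].to_numpy(dtype=float))):
                raise ResponseTableError(f"non-finite values in column {c}")
        self.table = self.table.reset_index(drop=True)

    @property
    def snapshot_ids(self) -> np.ndarray:
        """Sorted unique snapshot indices present in the set."""
        return np.sort(self.table["snapshot"].unique())

    @property
    def nucleus_labels(self) -> list[str]:
        """Nucleus labels in first-appearance order."""
        return list(dict.fromkeys(self.table["nucleus"]))

    def with_aiso(self) -> pd.DataFrame:
        """Return the table with an ``A_iso`` column (mean of principal values)."""
        t = self.table.copy()
        t["A_iso"] = t[["A_x", "A_y", "A_z"]].mean(axis=1)
        return t

    def component_vector(self, nucleus: str, component: str) -> pd.Series:
        """One response column for one nucleus, indexed by snapshot id.

        ``component`` is one of ``A_x``, ``A_y``, ``A_z``, ``A_iso``.
        """
        t = self.with_aiso()
        sub = t[t["nucleus"] == nucleus]
        if sub.empty:
            raise KeyError(f"nucleus {nucleus!r} not in response set")
        if component not in ("A_x", "A_y", "A_z", "A_iso"):
            raise KeyError(f"unknown component {component!r}")
        return sub.set_index("snapshot")[component].sort_index()


def read_response_table(path: str | Path) -> HyperfineResponseSet:
    """Read a tab- or comma-delimited hyperfine response table (auto-detected)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ResponseTableError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in _RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise ResponseTableError(f"{path}: missing columns {missing}")
    for c in ("A_x", "A_y", "A_z"):
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = vals.isna() & df[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +header +1-based
            raise ResponseTableError(
                f"{path}: non-numeric value {df[c][bad].iloc[0]!r} in column {c}, line {row}"
            )
        df[c] = vals
    df["snapshot"] = df["snapshot"].astype(int)
    return HyperfineResponseSet(df[list(_RESPONSE_COLUMNS)])


def write_response_table(
    responses: HyperfineResponseSet, path: str | Path, sep: str = "\t"
) -> None:
    """Write the response table as delimited UTF-8 text (full float precision)."""
    responses.table.to_csv(path, sep=sep, index=False, float_format="%.17g")
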