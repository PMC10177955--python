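"""Feature engineering: from internal-coordinate series to the standardized design matrix.

Dihedral angles are circular variables with a discontinuity at ±180°, so each
dihedral column is expanded into its cosine and sine before modelling.  Bond
angles live on [0°, 180°] and are kept as-is; bonds are kept in Å.  An
optional extra feature sums all bond angles of the molecule, a proxy for
pyramidal distortion at trigonal centers (360° when planar).  Every feature
column is standardized individually so a single regularization strength is
comparable across features of different units and spread.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .internal_coords import InternalCoordinateSeries

__all__ = [
    "FeatureTable",
    "dihedral_to_trig",
    "add_angle_sum",
    "standardize",
    "subsample_snapshots",
    "make_feature_table",
    "write_feature_table",
    "read_feature_table",
]

ANGLE_SUM_LABEL = "sum_angles"

_CONST_TOL = 1e-12


@dataclass
class FeatureTable:
    """Snapshots × standardized features, with labels and standardization metadata.

    ``kinds`` tags each column: ``B`` bond, ``A`` angle, ``Dcos``/``Dsin``
    dihedral trig pair, ``S`` angle sum.  ``standardization`` records the mode
    and per-feature parameters needed for the inverse transform.
    """

    matrix: np.ndarray  # (n_snapshots, n_features), unitless
    feature_labels: list[str]
    kinds: list[str]
    standardization: dict
    snapshot_ids: np.ndarray = field(default_factory=lambda: np.array([], int))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        self.snapshot_ids = np.asarray(self.snapshot_ids, int)
        if self.matrix.shape[1] != len(self.feature_labels):
            raise ValueError("matrix width inconsistent with labels")
        if len(self.kinds) != len(self.feature_labels):
            raise ValueError("kinds and labels length mismatch")
        if self.snapshot_ids.size == 0:
            self.snapshot_ids = np.arange(self.matrix.shape[0])
        if self.snapshot_ids.size != self.matrix.shape[0]:
            raise ValueError("snapshot_ids length inconsistent with matrix")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def column(self, label: str) -> np.ndarray:
        try:
            return self.matrix[:, self.feature_labels.index(label)]
        except ValueError:
            raise KeyError(f"no feature column {label!r}") from None

    def inverse(self) -> np.ndarray:
        """Undo the standardization, recovering the raw feature values."""
        mode = self.standardization["mode"]
        p = self.standardization["params"]
        out = self.matrix.copy()
        for c, lab in enumerate(self.feature_labels):
            a, b = p[lab]
            if mode == "zscore":
                out[:, c] = out[:, c] * b + a  # (mean, sd)
            else:
                out[:, c] = out[:, c] * (b - a) + a  # (min, max)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.feature_labels)
        df.insert(0, "snapshot", self.snapshot_ids)
        return df


def write_feature_table(ft: FeatureTable, path, meta_path) -> None:
    """Export the feature matrix as TSV plus a YAML sidecar with labels,
    kinds and standardization parameters."""
    import yaml

    ft.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.17g")
    meta = {
        "feature_labels": list(ft.feature_labels),
        "kinds": list(ft.kinds),
        "standardization": {
            "mode": ft.standardization["mode"],
            "params": {
                k: [float(a), float(b)]
                for k, (a, b) in ft.standardization["params"].items()
            },
        },
    }
    from pathlib import Path

    Path(meta_path).write_text(yaml.safe_dump(meta, sort_keys=False), encoding="utf-8")


def read_feature_table(path, meta_path) -> FeatureTable:
    """Read back a feature table written by :func:`write_feature_table`."""
    import yaml
    from pathlib import Path

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    meta = yaml.safe_load(Path(meta_path).read_text())
    labels = list(meta["feature_labels"])
    std = {
        "mode": meta["standardization"]["mode"],
        "params": {
            k: (float(v[0]), float(v[1]))
            for k, v in meta["standardization"]["params"].items()
        },
    }
    return FeatureTable(
        matrix=df[labels].to_numpy(float),
        feature_labels=labels,
        kinds=list(meta["kinds"]),
        standardization=std,
        snapshot_ids=df["snapshot"].to_numpy(int),
    )


def dihedral_to_trig(
    series: InternalCoordinateSeries,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Expand each dihedral column (degrees) into a (cos, sin) pair.

    Bond and angle columns pass through untouched; column order is preserved
    with the trig pair replacing its dihedral in place.  Returns
    ``(matrix, labels, kinds)`` with kinds ``B``/``A``/``Dcos``/``Dsin``.
    """
    cols, labels, kinds = [], [], []
    for c, (lab, kind) in enumerate(zip(series.labels, series.kinds)):
        v = series.values[:, c]
        if kind == "D":
            rad = np.radians(v)
            cols.append(np.cos(rad))
            labels.append(f"{lab}:cos")
            kinds.append("Dcos")
            cols.append(np.sin(rad))
            labels.append(f"{lab}:sin")
            kinds.append("Dsin")
        else:
            cols.append(v)
            labels.append(lab)
            kinds.append(kind)
    matrix = np.column_stack(cols) if cols else np.empty((series.values.shape[0], 0))
    return matrix, labels, kinds


def add_angle_sum(series: InternalCoordinateSeries) -> np.ndarray:
    """Per-frame sum of all bond-angle values in degrees (pyramidality gauge)."""
    mask = [k == "A" for k in series.kinds]
    if not any(mask):
        raise ValueError("no angle columns; cannot form angle-sum feature")
    return series.values[:, mask].sum(axis=1)


def standardize(
    matrix: np.ndarray, labels: list[str], mode: str = "zscore"
) -> tuple[np.ndarray, list[str], dict, np.ndarray]:
    """Standardize each column individually; drop constant columns with a warning.

    ``zscore`` maps to zero mean / unit standard deviation; ``minmax`` to
    [0, 1].  Returns ``(Z, kept_labels, standardization, kept_mask)`` where
    ``standardization`` holds the mode and per-label parameters for the
    inverse transform.
    """
    matrix = np.asarray(matrix, float)
    if matrix.shape[0] < 2:
        raise ValueError("standardization needs at least 2 rows")
    if mode not in ("zscore", "minmax"):
        raise ValueError(f"unknown standardization mode {mode!r}")
    params: dict[str, tuple[float, float]] = {}
    keep = np.ones(matrix.shape[1], dtype=bool)
    cols = []
    kept_labels = []
    for c, lab in enumerate(labels):
        x = matrix[:, c]
        if mode == "zscore":
            a, b = float(np.mean(x)), float(np.std(x))
            spread = b
        else:
            a, b = float(np.min(x)), float(np.max(x))
            spread = b - a
        if spread < _CONST_TOL:
            warnings.warn(f"dropping constant feature column {lab!r}", stacklevel=2)
            keep[c] = False
            continue
        cols.append((x - a) / (b if mode == "zscore" else (b - a)))
        kept_labels.append(lab)
        params[lab] = (a, b)
    Z = np.column_stack(cols) if cols else np.empty((matrix.shape[0], 0))
    return Z, kept_labels, {"mode": mode, "params": params}, keep


def subsample_snapshots(
    n_frames: int, interval_range: tuple[int, int] = (1, 80), seed: int = 0
) -> np.ndarray:
    """Snapshot indices starting at 0 with i.i.d. uniform-integer gaps.

    Randomized (rather than regular) spacing avoids aliasing with the
    near-periodic oscillation of structure parameters along a trajectory.
    """
    lo, hi = int(interval_range[0]), int(interval_range[1])
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid interval range [{lo}, {hi}]")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if hi > n_frames:
        raise ValueError(
            f"interval upper bound {hi} exceeds trajectory length {n_frames}"
        )
    rng = np.random.default_rng(seed)
    ids = [0]
    while True:
        nxt = ids[-1] + int(rng.integers(lo, hi + 1))
        if nxt >= n_frames:
            break
        ids.append(nxt)
    return np.asarray(ids, int)


def make_feature_table(
    series: InternalCoordinateSeries,
    mode: str = "zscore",
    angle_sum: bool = False,
    snapshot_ids: np.ndarray | None = None,
) -> FeatureTable:
    """Full feature pipeline: optional row subsetting, trig expansion, optional
    angle-sum column, then per-column standardization.

    ``snapshot_ids`` selects rows by frame index (e.g. the output of
    :func:`subsample_snapshots`); standardization statistics are computed on
    the selected rows only.
    """
    if snapshot_ids is not None:
        snapshot_ids = np.asarray(snapshot_ids, int)
        index = {f: r for r, f in enumerate(series.frame_indices)}
        missing = [int(s) for s in snapshot_ids if s not in index]
        if missing:
            raise ValueError(f"snapshot ids not in series: {missing}")
        rows = np.array([index[s] for s in snapshot_ids])
        series = InternalCoordinateSeries(
            values=series.values[rows],
            labels=series.labels,
            kinds=series.kinds,
            frame_indices=snapshot_ids,
        )
    matrix, labels, kinds = dihedral_to_trig(series)
    if angle_sum:
        matrix = np.column_stack([matrix, add_angle_sum(series)])
        labels = labels + [ANGLE_SUM_LABEL]
        kinds = kinds + ["S"]
    Z, kept_labels, std, keep = standardize(matrix, labels, mode)
    kept_kinds = [k for k, m in zip(kinds, keep) if m]
    return FeatureTable(
        matrix=Z,
        feature_labels=kept_labels,
        kinds=kept_kinds,
        standardization=std,
        snapshot_ids=series.frame_indices,
    )
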