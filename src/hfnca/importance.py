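"""Assembly of per-molecule importance matrices.

For every magnetic nucleus and every hyperfine component (the principal
values A_x, A_y, A_z and the isotropic part A_iso, the mean of the three),
an independent NCA fit maps the standardized structure-parameter features to
that response.  The resulting nonnegative importances stack into a 3-D array
indexed (feature, component, nucleus) — the molecule's importance matrix.
A single shared regularization strength keeps importances comparable across
nuclei and components.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureTable
from .io import HyperfineResponseSet
from .nca import DEFAULT_LAMBDA, NCAConfig, NCAModel, fit_nca

__all__ = ["ImportanceMatrix", "COMPONENTS", "compute_aiso", "build_importance_matrix"]

logger = logging.getLogger(__name__)

COMPONENTS = ("A_x", "A_y", "A_z", "A_iso")


class AlignmentError(ValueError):
    """Feature snapshots and response snapshots do not match."""


def compute_aiso(A_x, A_y, A_z):
    """Isotropic hyperfine coupling: the mean of the three principal values (MHz).

    (The rotation-invariant part of the tensor; one third of its trace.)
    """
    return (np.asarray(A_x, float) + np.asarray(A_y, float) + np.asarray(A_z, float)) / 3.0


@dataclass
class ImportanceMatrix:
    """Nonnegative NCA importances indexed (feature, component, nucleus)."""

    values: np.ndarray  # (n_features, n_components, n_nuclei)
    feature_labels: list[str]
    component_labels: tuple[str, ...]
    nucleus_labels: list[str]
    lam: float
    models: dict = field(default_factory=dict, repr=False)  # (component, nucleus) -> NCAModel

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        expected = (
            len(self.feature_labels),
            len(self.component_labels),
            len(self.nucleus_labels),
        )
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != labels {expected}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite importance values")
        if np.any(self.values < 0):
            raise ValueError("importances must be nonnegative")

    def slice(self, component: str) -> pd.DataFrame:
        """Feature × nucleus importance table for one hyperfine component."""
        c = self.component_labels.index(component)
        return pd.DataFrame(
            self.values[:, c, :], index=self.feature_labels, columns=self.nucleus_labels
        )

    def get(self, feature: str, component: str, nucleus: str) -> float:
        return float(
            self.values[
                self.feature_labels.index(feature),
                self.component_labels.index(component),
                self.nucleus_labels.index(nucleus),
            ]
        )

    def to_long_dataframe(self) -> pd.DataFrame:
        """Long-format table: feature, component, nucleus, importance."""
        rows = []
        for f, flab in enumerate(self.feature_labels):
            for c, clab in enumerate(self.component_labels):
                for n, nlab in enumerate(self.nucleus_labels):
                    rows.append((flab, clab, nlab, self.values[f, c, n]))
        return pd.DataFrame(rows, columns=["feature", "component", "nucleus", "importance"])

    @classmethod
    def from_long_dataframe(cls, df: pd.DataFrame, lam: float = float("nan")) -> "ImportanceMatrix":
        features = list(dict.fromkeys(df["feature"]))
        components = tuple(dict.fromkeys(df["component"]))
        nuclei = list(dict.fromkeys(df["nucleus"]))
        values = np.zeros((len(features), len(components), len(nuclei)))
        fi = {f: i for i, f in enumerate(features)}
        ci = {c: i for i, c in enumerate(components)}
        ni = {n: i for i, n in enumerate(nuclei)}
        for _, row in df.iterrows():
            values[fi[row["feature"]], ci[row["component"]], ni[row["nucleus"]]] = row[
                "importance"
            ]
        return cls(values, features, components, nuclei, lam)


def _fit_seed(base_seed: int | None, nucleus: str, component: str) -> int | None:
    """Stable per-fit seed derived from the base seed and the fit's labels."""
    if base_seed is None:
        return None
    tag = zlib.crc32(f"{nucleus}:{component}".encode())
    return int((int(base_seed) + tag) % (2**31))


def build_importance_matrix(
    features: FeatureTable,
    responses: HyperfineResponseSet,
    lam: float = DEFAULT_LAMBDA,
    config: NCAConfig | None = None,
    seed: int | None = 0,
) -> ImportanceMatrix:
    """One independent NCA fit per (component, nucleus); stack importances.

    The feature snapshots and the response snapshots must describe the same
    set of MD frames; a mismatch raises :class:`AlignmentError` listing the
    offending ids.  Each fit uses the shared ``lam`` and a per-fit seed
    derived from ``seed`` and the (nucleus, component) labels, so results are
    reproducible and independent of fit order.
    """
    config = config or NCAConfig()
    nuclei = responses.nucleus_labels
    if not nuclei:
        raise ValueError("empty response set")

    feat_ids = np.asarray(features.snapshot_ids, int)
    resp_ids = set(int(s) for s in responses.snapshot_ids)
    missing = sorted(set(int(s) for s in feat_ids) - resp_ids)
    extra = sorted(resp_ids - set(int(s) for s in feat_ids))
    if missing or extra:
        raise AlignmentError(
            f"snapshot mismatch between features and responses; "
            f"missing from responses: {missing[:10]}, "
            f"not in features: {extra[:10]}"
        )

    n_feat = features.n_features
    values = np.zeros((n_feat, len(COMPONENTS), len(nuclei)))
    models: dict[tuple[str, str], NCAModel] = {}
    for ni, nucleus in enumerate(nuclei):
        for ci, component in enumerate(COMPONENTS):
            y_series = responses.component_vector(nucleus, component)
            try:
                y = y_series.loc[feat_ids].to_numpy(float)
            except KeyError:
                have = set(y_series.index)
                gap = sorted(set(int(s) for s in feat_ids) - have)
                raise AlignmentError(
                    f"nucleus {nucleus} missing snapshots {gap[:10]}"
                ) from None
            model = fit_nca(
                features.matrix, y, lam, config, seed=_fit_seed(seed, nucleus, component)
            )
            logger.info(
                "NCA fit %s %s: objective=%.5g converged=%s iters=%d",
                nucleus,
                component,
                model.objective_value,
                model.converged,
                model.iterations,
            )
            values[:, ci, ni] = model.importances
            models[(component, nucleus)] = model

    return ImportanceMatrix(
        values=values,
        feature_labels=list(features.feature_labels),
        component_labels=COMPONENTS,
        nucleus_labels=list(nuclei),
        lam=float(lam),
        models=models,
    )
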