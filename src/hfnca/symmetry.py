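"""Symmetry-based quality descriptors for importance matrices.

Magnetically equivalent nuclei (e.g. the three methyl hydrogens) must show
identical importance patterns once their feature columns are permuted into a
common canonical ordering — for a methyl hydrogen HX: first its own C–H
bond, then the remaining bonds, then the angle opposite HX (not involving
it), then the remaining angles.  Deviations from this ideal quantify the
statistical quality of a dataset without knowing the true importances:

* group MSE descriptor — cumulative mean-squared difference between the
  permutation-aligned importance columns of every pair of equivalent nuclei,
  summed over the chosen tensor components (by default the anisotropic
  principal values A_x, A_y, A_z);
* block standard-deviation descriptor — for a single nucleus whose features
  come in equivalent blocks (e.g. the three C–H bond entries for the central
  carbon), the mean over blocks and components of the within-block standard
  deviation of importances.

Both are zero exactly when the symmetry holds and grow with statistical
noise, so they decrease as the number of analyzed snapshots grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .importance import ImportanceMatrix

__all__ = [
    "EquivalenceSpec",
    "group_mse_descriptor",
    "block_std_descriptor",
    "methyl_equivalence_spec",
]

ANISOTROPIC_COMPONENTS = ("A_x", "A_y", "A_z")


@dataclass
class EquivalenceSpec:
    """User-declared magnetic-equivalence structure of a molecule.

    nucleus_groups
        Sets of nucleus labels expected equivalent, e.g. ``[["H1","H2","H3"]]``.
    permutation_maps
        Per nucleus, a feature-index permutation ``perm`` such that
        ``column[perm]`` is that nucleus's importance column in canonical
        ordering.
    feature_blocks
        Per nucleus, disjoint index blocks of features expected mutually
        equivalent (for the standard-deviation descriptor).
    """

    nucleus_groups: list[list[str]] = field(default_factory=list)
    permutation_maps: dict[str, list[int]] = field(default_factory=dict)
    feature_blocks: dict[str, list[list[int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for nuc, perm in self.permutation_maps.items():
            if sorted(perm) != list(range(len(perm))):
                raise ValueError(f"permutation for {nuc} is not a bijection: {perm}")
        for nuc, blocks in self.feature_blocks.items():
            flat = [i for b in blocks for i in b]
            if len(flat) != len(set(flat)):
                raise ValueError(f"feature blocks for {nuc} overlap")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "nucleus_groups": self.nucleus_groups,
                    "permutation_maps": self.permutation_maps,
                    "feature_blocks": self.feature_blocks,
                },
                sort_keys=False,
            ),
            encoding="utf-8",
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EquivalenceSpec":
        d = yaml.safe_load(Path(path).read_text())
        return cls(
            nucleus_groups=[list(g) for g in d.get("nucleus_groups", [])],
            permutation_maps={k: list(v) for k, v in d.get("permutation_maps", {}).items()},
            feature_blocks={
                k: [list(b) for b in v] for k, v in d.get("feature_blocks", {}).items()
            },
        )


def _aligned_column(
    matrix: ImportanceMatrix, spec: EquivalenceSpec, nucleus: str, component: str
) -> np.ndarray:
    if nucleus not in matrix.nucleus_labels:
        raise KeyError(f"nucleus {nucleus!r} not in importance matrix")
    col = matrix.values[
        :, matrix.component_labels.index(component), matrix.nucleus_labels.index(nucleus)
    ]
    perm = spec.permutation_maps.get(nucleus)
    if perm is None:
        raise KeyError(f"no permutation map for nucleus {nucleus!r}")
    if len(perm) != col.shape[0]:
        raise ValueError(
            f"permutation for {nucleus} covers {len(perm)} features, matrix has {col.shape[0]}"
        )
    return col[np.asarray(perm, int)]


def group_mse_descriptor(
    matrix: ImportanceMatrix,
    spec: EquivalenceSpec,
    components: Sequence[str] = ANISOTROPIC_COMPONENTS,
) -> float:
    """Cumulative permutation-aligned MSE over all pairs of equivalent nuclei.

    For every declared group, every unordered pair of members and every
    selected component, the mean squared difference of the aligned columns is
    computed; the descriptor is the sum of all contributions (zero iff the
    aligned columns agree exactly).
    """
    total = 0.0
    if not spec.nucleus_groups:
        raise ValueError("equivalence spec declares no nucleus groups")
    for group in spec.nucleus_groups:
        for n1, n2 in combinations(sorted(group), 2):
            for comp in components:
                c1 = _aligned_column(matrix, spec, n1, comp)
                c2 = _aligned_column(matrix, spec, n2, comp)
                total += float(np.mean((c1 - c2) ** 2))
    return total


def block_std_descriptor(
    matrix: ImportanceMatrix,
    nucleus: str,
    blocks: Sequence[Sequence[int]] | None = None,
    components: Sequence[str] = ANISOTROPIC_COMPONENTS,
    spec: EquivalenceSpec | None = None,
) -> float:
    """Mean within-block standard deviation of importances for one nucleus.

    ``blocks`` (or ``spec.feature_blocks[nucleus]``) lists index sets of
    features that symmetry renders equivalent for this nucleus; the sample
    (n−1) standard deviation is computed per block and component and
    averaged.  Scales linearly with the matrix (homogeneous of degree 1).
    """
    if blocks is None:
        if spec is None or nucleus not in spec.feature_blocks:
            raise ValueError(f"no feature blocks given for nucleus {nucleus!r}")
        blocks = spec.feature_blocks[nucleus]
    if nucleus not in matrix.nucleus_labels:
        raise KeyError(f"nucleus {nucleus!r} not in importance matrix")
    ni = matrix.nucleus_labels.index(nucleus)
    sds = []
    for comp in components:
        ci = matrix.component_labels.index(comp)
        col = matrix.values[:, ci, ni]
        for block in blocks:
            idx = np.asarray(block, int)
            if idx.size < 2:
                raise ValueError(f"feature block {list(block)} has fewer than 2 entries")
            sds.append(float(np.std(col[idx], ddof=1)))
    return float(np.mean(sds))


def methyl_equivalence_spec(
    feature_labels: Sequence[str],
    hydrogens: Sequence[str] = ("H1", "H2", "H3"),
    center: str = "C1",
) -> EquivalenceSpec:
    """Build the equivalence spec of a methyl-type CH3 center automatically.

    Expects the feature labels to contain the three bonds ``HXC1`` and three
    angles ``HiC1Hj``; any further features (e.g. the angle-sum column) are
    appended to the canonical ordering unchanged, since they are invariant
    under hydrogen relabeling.  Feature blocks for the central atom are the
    three bond entries and the three angle entries.
    """
    labels = list(feature_labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    bonds = {h: f"{h}{center}" for h in hydrogens}
    for h, b in bonds.items():
        if b not in idx:
            raise ValueError(f"expected bond feature {b!r} not found")
    angle_of_pair = {}
    for h1, h2 in combinations(hydrogens, 2):
        for cand in (f"{h1}{center}{h2}", f"{h2}{center}{h1}"):
            if cand in idx:
                angle_of_pair[frozenset((h1, h2))] = cand
                break
        else:
            raise ValueError(f"expected angle feature for pair {h1},{h2} not found")

    core = set(bonds.values()) | set(angle_of_pair.values())
    rest = [lab for lab in labels if lab not in core]

    perms: dict[str, list[int]] = {}
    for h in hydrogens:
        others = sorted(x for x in hydrogens if x != h)
        order = [bonds[h]]
        order += [bonds[o] for o in others]
        order.append(angle_of_pair[frozenset(others)])  # opposite angle
        own_angles = sorted(
            angle_of_pair[frozenset((h, o))] for o in others
        )
        order += own_angles
        order += rest
        perms[h] = [idx[lab] for lab in order]

    blocks = {
        center: [
            sorted(idx[b] for b in bonds.values()),
            sorted(idx[a] for a in angle_of_pair.values()),
        ]
    }
    return EquivalenceSpec(
        nucleus_groups=[list(hydrogens)],
        permutation_maps=perms,
        feature_blocks=blocks,
    )
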