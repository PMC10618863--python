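"""Species relatedness matrices from class-specific phylogenies.

Under Brownian trait evolution the expected covariance between two
species is the branch length shared on their root-to-tip paths, i.e. the
depth of their most recent common ancestor; the variance of a species is
its root-to-tip distance.  Birds and mammals enter the analysis on
separate trees, and their cross-class covariance is set to zero by
block-diagonal assembly.  Blocks are optionally rescaled to correlation
form (unit diagonal) first, so that class-specific tree heights cannot
leak into the variance partitioning of the meta-regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from stresstherm.io_schema import ValidationFailure, normalize_species_name

__all__ = ["PhyloCov", "vcov_from_tree", "block_combine"]

_PSD_TOL = 1e-10


@dataclass
class PhyloCov:
    """Species-labelled relatedness (variance-covariance) matrix."""

    species: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.species), len(self.species)):
            raise ValidationFailure("matrix shape does not match species list")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValidationFailure("relatedness matrix must be symmetric")
        self.matrix = m
        tr = float(np.trace(m))
        min_eig = float(np.linalg.eigvalsh(m)[0]) if len(self.species) else 0.0
        if tr > 0 and min_eig < -_PSD_TOL * tr:
            raise ValidationFailure(
                f"relatedness matrix not positive semi-definite "
                f"(min eigenvalue {min_eig:.3g})"
            )

    def normalized(self) -> "PhyloCov":
        """Correlation form: unit diagonal, entries scaled by sqrt(v_i v_j)."""
        d = np.sqrt(np.diag(self.matrix))
        if np.any(d <= 0):
            raise ValidationFailure("zero diagonal entry; cannot normalize")
        return PhyloCov(list(self.species), self.matrix / np.outer(d, d))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.species, columns=self.species)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


def vcov_from_tree(tree: dendropy.Tree, species: Sequence[str]) -> PhyloCov:
    """Shared-path relatedness matrix for the requested species, in order.

    Entry (i, j) is the distance from the root to the most recent common
    ancestor of tips i and j; the diagonal holds root-to-tip distances.
    Requested species must match tips after name normalization.
    """
    tree = tree.clone(depth=1)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    tip_by_name: dict[str, dendropy.Node] = {}
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None and leaf.taxon.label:
            tip_by_name[normalize_species_name(leaf.taxon.label)] = leaf
    wanted = [normalize_species_name(s) for s in species]
    missing = [s for s, w in zip(species, wanted) if w not in tip_by_name]
    if missing:
        raise ValidationFailure(f"species missing from tree: {missing}")
    nodes = [tip_by_name[w] for w in wanted]

    # root-to-tip path node sets, for MRCA depth lookups
    paths: list[list[dendropy.Node]] = []
    for node in nodes:
        path = []
        cur = node
        while cur is not None:
            path.append(cur)
            cur = cur.parent_node
        paths.append(path)
    n = len(nodes)
    m = np.zeros((n, n))
    for i in range(n):
        m[i, i] = nodes[i].root_distance
        ancestors_i = {id(a): a for a in paths[i]}
        for j in range(i + 1, n):
            mrca = next(a for a in paths[j] if id(a) in ancestors_i)
            m[i, j] = m[j, i] = mrca.root_distance
    return PhyloCov(list(species), m)


def block_combine(
    bird_cov: PhyloCov, mammal_cov: PhyloCov, *, normalize: bool = True
) -> PhyloCov:
    """Block-diagonal bird/mammal relatedness with zero cross-class entries.

    With ``normalize`` (default) each block is scaled to unit diagonal
    before assembly, so the two classes contribute on a common scale.
    """
    overlap = set(map(normalize_species_name, bird_cov.species)) & set(
        map(normalize_species_name, mammal_cov.species)
    )
    if overlap:
        raise ValidationFailure(f"species in both classes: {sorted(overlap)}")
    a = bird_cov.normalized() if normalize else bird_cov
    b = mammal_cov.normalized() if normalize else mammal_cov
    na, nb = len(a.species), len(b.species)
    m = np.zeros((na + nb, na + nb))
    m[:na, :na] = a.matrix
    m[na:, na:] = b.matrix
    return PhyloCov(list(a.species) + list(b.species), m)
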