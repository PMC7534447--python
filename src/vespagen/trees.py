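"""Ultrametricity checking, tree age scaling and clade-age reporting.

On an ultrametric tree, branch lengths are proportional to time, so
rescaling every branch by a single factor calibrates the tree to an
absolute root age (e.g., a published divergence estimate in millions of
years); the age of any most-recent-common-ancestor node then reads off
directly as root_age minus its depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np

__all__ = [
    "AgeReport",
    "check_ultrametric",
    "scale_to_root_age",
    "mrca_age",
]


@dataclass
class AgeReport:
    """Ages implied by a calibrated ultrametric tree (same units as root_age)."""

    root_age: float
    clade_ages: dict[str, float]
    scale_factor: float


def _leaf_depths(tree: dendropy.Tree) -> np.ndarray:
    tree.calc_node_root_distances(
        return_leaf_distances_only=False
    )
    return np.array(
        [leaf.root_distance for leaf in tree.leaf_node_iter()], dtype=float
    )


def check_ultrametric(
    tree: dendropy.Tree, rel_tol: float = 1e-6
) -> tuple[bool, float]:
    """Compare all root-to-tip path lengths.

    Returns (is_ultrametric, max_relative_deviation) where the deviation
    is measured from the mean depth, relative to the mean.  The tolerance
    is relative because published "ultrametric" trees carry rounding noise
    proportional to their depth.
    """
    depths = _leaf_depths(tree)
    mean = depths.mean()
    if mean == 0:
        raise ValueError("zero mean root-to-tip distance")
    max_rel_dev = float(np.abs(depths - mean).max() / mean)
    return max_rel_dev <= rel_tol, max_rel_dev


def _root_height(tree: dendropy.Tree) -> float:
    return float(_leaf_depths(tree).mean())


def mrca_age(tree: dendropy.Tree, tips: Sequence[str]) -> float:
    """Age (root height minus node depth) of the MRCA of a tip set on an
    ultrametric tree.  Invariant under permutation of the query tips."""
    labels = list(tips)
    if len(set(labels)) < 2:
        raise ValueError("need at least two distinct tips")
    known = {t.label for t in tree.taxon_namespace}
    unknown = set(labels) - known
    if unknown:
        raise KeyError(f"unknown tips: {sorted(unknown)}")
    mrca = tree.mrca(taxon_labels=labels)
    depth = 0.0
    node = mrca
    while node.parent_node is not None:
        depth += node.edge.length or 0.0
        node = node.parent_node
    return _root_height(tree) - depth


def scale_to_root_age(
    tree: dendropy.Tree,
    root_age: float,
    clades: Optional[dict[str, Sequence[str]]] = None,
    rel_tol: float = 1e-6,
) -> tuple[dendropy.Tree, AgeReport]:
    """Rescale every branch so the root-to-tip distance equals `root_age`.

    The input tree must be ultrametric within `rel_tol` (see
    check_ultrametric) and is not modified; a scaled clone is returned
    together with an AgeReport carrying the scale factor and the MRCA ages
    of any named clades (label -> tip list).
    """
    if root_age <= 0:
        raise ValueError("root_age must be > 0")
    ok, dev = check_ultrametric(tree, rel_tol=rel_tol)
    if not ok:
        raise ValueError(
            f"tree is not ultrametric (max relative deviation {dev:.3g}); "
            "run check_ultrametric and fix branch lengths first"
        )
    factor = root_age / _root_height(tree)
    scaled = tree.clone(depth=1)
    for edge in scaled.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * factor
    clade_ages = {
        label: mrca_age(scaled, tips) for label, tips in (clades or {}).items()
    }
    report = AgeReport(
        root_age=float(root_age), clade_ages=clade_ages, scale_factor=float(factor)
    )
    return scaled, report
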