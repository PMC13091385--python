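"""Lightweight distance-based phylogenetics.

Poisson-corrected amino-acid distances, neighbor joining, a column-resampling
bootstrap, and the basal-placement frequency statistic used to ask whether
protistan sequences consistently fall outside (below) the land-plant clade.
Full maximum-likelihood inference is out of scope: externally produced
Newick trees can be fed straight into :func:`basal_placement_frequency`.
"""

from __future__ import annotations

import io as _io
import math
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .io import GAP, AlignedBlock, log

#: cap applied when the observed mismatch fraction saturates (p >= 1), where
#: the Poisson correction -ln(1-p) diverges.
DEFAULT_SATURATION_CAP = 5.0


def poisson_distance(a: str, b: str, saturation_cap: float = DEFAULT_SATURATION_CAP) -> float:
    """Poisson-corrected distance between two aligned sequences.

    p is the mismatch fraction over columns where both sequences are
    non-gap; d = -ln(1 - p).  Saturated pairs (p >= 1 after correction
    domain) are capped at ``saturation_cap`` and flagged in the log.
    """
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    same = 0
    comparable = 0
    for x, y in zip(a, b):
        if x == GAP or y == GAP:
            continue
        comparable += 1
        if x == y:
            same += 1
    if comparable == 0:
        raise ValueError("no co-non-gap columns between sequences")
    p = 1.0 - same / comparable
    if p >= 1.0 or -math.log(1.0 - p) > saturation_cap:
        log.debug("poisson_distance saturated (p=%.3f), capped at %s", p, saturation_cap)
        return saturation_cap
    return -math.log(1.0 - p)


def distance_matrix(block: AlignedBlock, saturation_cap: float = DEFAULT_SATURATION_CAP) -> DistanceMatrix:
    labels = [r.id for r in block.records]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = poisson_distance(
                block.records[i].seq, block.records[j].seq, saturation_cap
            )
    return DistanceMatrix(d, labels)


def neighbor_joining(dm: DistanceMatrix | np.ndarray, labels: Sequence[str] | None = None) -> TreeNode:
    """Neighbor joining on a symmetric distance matrix.

    Negative branch-length estimates (a known NJ artifact on noisy data)
    are clamped to zero and flagged.  Exact on additive matrices.
    """
    if not isinstance(dm, DistanceMatrix):
        arr = np.asarray(dm, dtype=float)
        if not np.allclose(arr, arr.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        dm = DistanceMatrix(arr, list(labels) if labels else None)
    if dm.shape[0] < 4:
        raise ValueError("need >= 4 taxa for neighbor joining")
    tree = _skbio_nj(dm)
    n_clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            n_clamped += 1
    if n_clamped:
        log.debug("neighbor_joining: clamped %d negative branch lengths", n_clamped)
    return tree


def bootstrap_trees(
    block: AlignedBlock,
    reps: int = 100,
    rng: np.random.Generator | None = None,
    saturation_cap: float = DEFAULT_SATURATION_CAP,
) -> list[TreeNode]:
    """Column-resampling bootstrap: resample alignment columns with
    replacement, rebuild the NJ tree per replicate."""
    if block.width < 2:
        raise ValueError("alignment width must be >= 2")
    if rng is None:
        rng = np.random.default_rng(0)
    rows = [r.seq for r in block.records]
    labels = [r.id for r in block.records]
    trees = []
    for _ in range(reps):
        cols = rng.integers(0, block.width, size=block.width)
        resampled = ["".join(row[c] for c in cols) for row in rows]
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = poisson_distance(resampled[i], resampled[j], saturation_cap)
        trees.append(neighbor_joining(DistanceMatrix(d, labels)))
    return trees


def _bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    all_tips = frozenset(t.name for t in tree.tips())
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_tips) - 1:
            parts.add(min(side, all_tips - side, key=sorted))
    return parts


def bootstrap_support(reference: TreeNode, trees: Sequence[TreeNode]) -> dict[frozenset[str], float]:
    """Support for each internal bipartition of the reference tree: the
    fraction of bootstrap trees containing that bipartition."""
    ref_parts = _bipartitions(reference)
    counts = {part: 0 for part in ref_parts}
    for t in trees:
        parts = _bipartitions(t)
        for part in ref_parts:
            if part in parts:
                counts[part] += 1
    return {part: c / len(trees) for part, c in counts.items()}


def annotate_support(reference: TreeNode, trees: Sequence[TreeNode]) -> TreeNode:
    """Write bootstrap supports onto the reference tree's internal nodes."""
    support = bootstrap_support(reference, trees)
    all_tips = frozenset(t.name for t in reference.tips())
    for node in reference.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        key = min(side, all_tips - side, key=sorted)
        if key in support:
            node.name = f"{support[key]:.2f}"
    return reference


def _plants_basal_event(
    tree: TreeNode, l_labels: set[str], p_labels: set[str], outgroup: str | None
) -> bool:
    tips = {t.name for t in tree.tips()}
    missing = (l_labels | p_labels) - tips
    if missing:
        raise ValueError(f"labels missing from tree: {sorted(missing)}")
    if outgroup is not None:
        rooted = tree.root_at(tree.find(outgroup))
    else:
        rooted = tree.root_at_midpoint()
    lca = rooted.lca([rooted.find(lbl) for lbl in l_labels])
    clade = {t.name for t in lca.tips()}
    return l_labels <= clade and not (clade & p_labels)


def basal_placement_frequency(
    trees: Sequence[TreeNode],
    l_labels: Sequence[str],
    p_labels: Sequence[str],
    outgroup: str | None = None,
) -> float:
    """Fraction of trees in which the land-plant leaves form a clade with
    every protist leaf outside it, on the rooted tree (user-designated
    outgroup preferred, midpoint rooting otherwise)."""
    l_set = set(l_labels)
    p_set = set(p_labels)
    if not l_set or not p_set:
        raise ValueError("both label sets must be non-empty")
    events = sum(
        1 for t in trees if _plants_basal_event(t, l_set, p_set, outgroup)
    )
    return events / len(trees)


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def newick_to_string(tree: TreeNode) -> str:
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
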