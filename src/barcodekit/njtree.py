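"""Neighbor-Joining gene trees with nonparametric bootstrap support.

Tree construction follows the Saitou–Nei agglomeration (via scikit-bio);
negative branch-length estimates are clamped to zero.  Bootstrap support for
an internal edge is the percentage of column-resampled replicates whose NJ
tree contains the same bipartition of the tip set; resampling is per
alignment column, agnostic to codon position.  Data sets with inestimable
(saturated) pairs must be pre-filtered — trees cannot be built over missing
distances.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import skbio
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import TreeNode, nj as _skbio_nj

from .distances import DistanceMatrix, distance_matrix_from_codes, encode_sequences
from .seqio import BarcodeDataset

__all__ = ["nj_build", "bootstrap_support", "tree_bipartitions"]


def nj_build(dm: DistanceMatrix) -> TreeNode:
    """Unrooted NJ tree from a complete distance matrix."""
    if len(dm.ids) < 3:
        raise ValueError("need at least 3 sequences for a tree")
    if np.isnan(dm.condensed()).any():
        raise ValueError(
            "distance matrix has missing pairs; exclude or impute the affected "
            "sequences before building a tree"
        )
    return _skbio_nj(SkbioDM(dm.d, ids=dm.ids), neg_as_zero=True)


def tree_bipartitions(tree: TreeNode, reference_tip: str) -> set[frozenset[str]]:
    """Canonical internal bipartitions of an unrooted tree.

    Each internal edge splits the tips in two; the side *not* containing
    ``reference_tip`` is the canonical representative, making bipartitions
    comparable across trees regardless of rooting.  Trivial (single-tip or
    full-set) sides are dropped.
    """
    tips = frozenset(t.name for t in tree.tips())
    out: set[frozenset[str]] = set()
    for side in tree.subsets():
        side = frozenset(side)
        if reference_tip in side:
            side = tips - side
        if 1 < len(side) < len(tips) - 1:
            out.add(side)
    return out


def bootstrap_support(
    ds: BarcodeDataset,
    model: str = "K2P",
    n_reps: int = 1000,
    seed: int = 0,
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """NJ tree with bootstrap bipartition supports.

    Returns the tree built on the full alignment, with each internal node's
    ``support`` attribute (and name) set to the percentage of replicates
    containing its bipartition, plus the support table itself.  A fixed seed
    makes supports bit-identical across runs.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    codes = encode_sequences(ds.sequences())
    full = distance_matrix_from_codes(codes, ds.ids, model=model)
    tree = nj_build(full)
    ref = ds.ids[0]
    observed = tree_bipartitions(tree, ref)

    rng = np.random.default_rng(seed)
    L = codes.shape[1]
    hits = {bp: 0 for bp in observed}
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep_dm = distance_matrix_from_codes(codes[:, cols], ds.ids, model=model)
        if np.isnan(rep_dm.condensed()).any():
            # replicate with inestimable pairs cannot vote
            continue
        rep_tree = nj_build(rep_dm)
        rep_bps = tree_bipartitions(rep_tree, ref)
        for bp in observed:
            if bp in rep_bps:
                hits[bp] += 1
    support = {bp: 100.0 * k / n_reps for bp, k in hits.items()}

    tips = frozenset(ds.ids)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = tips - side
        if side in support:
            node.support = support[side]
            node.name = f"{support[side]:.0f}"
    return tree, support
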