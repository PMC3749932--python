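"""Distance-based genealogies with bootstrap support.

Neighbor-joining trees on p- or Jukes-Cantor distances stand in for
likelihood genealogies here; for these data the branching orders agree,
and all outputs are labelled distance-based. Bootstrap support is the
percentage of column-resampled replicate trees containing each
bipartition (seeded, deterministic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .diversity import jukes_cantor_distance
from .segments import GAP, N_CODE, encode_alignment

logger = logging.getLogger(__name__)


def distance_matrix(
    names: list[str], seqs: list[str], model: str = "JC"
) -> tuple[np.ndarray, list[str]]:
    """Pairwise distance matrix under p-distance or Jukes-Cantor.

    Columns with a gap or N in either member of a pair are skipped
    pairwise. Raises for a pair whose p-distance puts the JC correction
    out of domain, naming the pair.
    """
    if model not in {"p", "JC"}:
        raise ValueError(f"unknown model {model!r}")
    m = encode_alignment(seqs)
    n = m.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (m[i] != GAP) & (m[j] != GAP) & (m[i] != N_CODE) & (m[j] != N_CODE)
            p = float(np.mean(m[i][ok] != m[j][ok])) if ok.any() else 0.0
            if model == "JC":
                try:
                    d = jukes_cantor_distance(p)
                except ValueError as err:
                    raise ValueError(
                        f"JC distance undefined for pair ({names[i]}, {names[j]}): {err}"
                    ) from err
            else:
                d = p
            out[i, j] = out[j, i] = d
    return out, list(names)


def nj_tree(matrix: np.ndarray, names: list[str]) -> TreeNode:
    """Neighbor-joining tree; negative branch lengths clamped to zero."""
    if len(names) < 3:
        raise ValueError("need at least three taxa for a tree")
    if not np.allclose(matrix, matrix.T):
        raise ValueError("distance matrix must be symmetric")
    tree = nj(DistanceMatrix(matrix, ids=names))
    n_clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            n_clamped += 1
    if n_clamped:
        logger.info("clamped %d negative NJ branch lengths to 0", n_clamped)
    return tree


def _bipartitions(tree: TreeNode, taxa: frozenset) -> set[frozenset]:
    """Non-trivial splits of the (unrooted) tree, canonicalized as the
    smaller side (ties by sorted tuple)."""
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = taxa - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        splits.add(canon)
    return splits


def bootstrap_support(
    names: list[str],
    seqs: list[str],
    reps: int = 1000,
    seed: int = 0,
    model: str = "JC",
) -> tuple[TreeNode, dict[frozenset, float]]:
    """NJ tree plus bootstrap support (%) per non-trivial bipartition.

    Columns are resampled with replacement ``reps`` times; support for a
    split of the full-data tree is the percentage of replicate trees
    containing it. Internal nodes of the returned tree carry their
    support in ``name`` (rounded %).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    m = encode_alignment(seqs)
    taxa = frozenset(names)
    dm, _ = distance_matrix(names, seqs, model=model)
    main = nj_tree(dm, names)
    main_splits = _bipartitions(main, taxa)
    counts = {s: 0 for s in main_splits}
    rng = np.random.default_rng(seed)
    chars = np.array([list(x) for x in seqs])
    for _ in range(reps):
        cols = rng.integers(0, m.shape[1], size=m.shape[1])
        rseqs = ["".join(s) for s in chars[:, cols]]
        try:
            rdm, _ = distance_matrix(names, rseqs, model=model)
        except ValueError:
            continue  # JC out of domain in a resample: replicate dropped
        rsplits = _bipartitions(nj_tree(rdm, names), taxa)
        for s in main_splits & rsplits:
            counts[s] += 1
    support = {s: 100.0 * c / reps for s, c in counts.items()}
    for node in main.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        canon = min(side, taxa - side, key=lambda s: (len(s), tuple(sorted(s))))
        if canon in support:
            node.name = f"{support[canon]:.0f}"
    return main, support


def root_with_outgroup(tree: TreeNode, outgroup: str) -> TreeNode:
    """Root on the branch leading to the outgroup tip."""
    tip = tree.find(outgroup)
    rooted = tree.root_at(tip.parent)
    return rooted


def mean_internal_branch_length(tree: TreeNode) -> float:
    """Mean internal branch length — short internal branches are the
    tree-shape signature of a recent sweep (star-like genealogy)."""
    lens = [
        node.length
        for node in tree.non_tips(include_self=False)
        if node.length is not None
    ]
    return float(np.mean(lens)) if lens else 0.0


def tree_depth_stats(tree: TreeNode) -> dict:
    tips = list(tree.tips())
    depths = [t.accumulate_to_ancestor(tree.root()) for t in tips]
    return dict(mean_tip_depth=float(np.mean(depths)), n_tips=len(tips))
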