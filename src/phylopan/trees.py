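"""Distance-based tree inference and tree comparison.

Builds the three trees the incongruence analysis compares — a slow marker
gene tree, a core-genome tree, and a gene-composition (Jaccard) dendrogram —
and quantifies their topological discordance with the Robinson–Foulds
distance.  Trees are neighbor-joining (on Jukes–Cantor distances) or UPGMA;
branch supports come from column bootstrap of the underlying alignment or
presence/absence matrix.
"""
from __future__ import annotations

import io
import logging
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

#: Jukes–Cantor distance assigned when the mismatch fraction reaches the
#: saturation point p >= 3/4 where the formula diverges.
JC_SATURATION_CAP = 5.0

_VALID = frozenset(b"ACGT")


def _seq_array(msa: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    names = list(msa)
    lengths = {len(s) for s in msa.values()}
    if len(lengths) != 1:
        raise ValueError("alignment sequences must have equal length")
    arr = np.frombuffer("".join(msa[n].upper() for n in names).encode(), dtype=np.uint8)
    return names, arr.reshape(len(names), -1)


def jc_distance_matrix(msa: Mapping[str, str], cap: float = JC_SATURATION_CAP) -> pd.DataFrame:
    """Pairwise Jukes–Cantor distances from a (possibly gapped) alignment.

    For each pair, only columns where both sequences carry an unambiguous
    nucleotide (A/C/G/T) are compared; d = -(3/4) ln(1 - (4/3) p) with p the
    mismatch fraction over those columns.  p >= 3/4 saturates at ``cap``.
    """
    names, arr = _seq_array(msa)
    if len(names) < 2:
        raise ValueError("need at least two sequences")
    valid = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = both.sum()
            if m == 0:
                raise ValueError(
                    f"no mutually comparable columns between {names[i]} and {names[j]}"
                )
            p = np.count_nonzero(arr[i, both] != arr[j, both]) / m
            if p >= 0.75:
                warnings.warn(
                    f"JC distance saturated (p={p:.3f}) for pair "
                    f"({names[i]}, {names[j]}); capping at {cap}"
                )
                dist = cap
            else:
                dist = -0.75 * np.log1p(-4.0 * p / 3.0)
            d[i, j] = d[j, i] = dist
    return pd.DataFrame(d, index=names, columns=names)


def jaccard_distance_matrix(pa: pd.DataFrame) -> pd.DataFrame:
    """Jaccard distance (1 - |A∩B|/|A∪B|) between strain gene-content rows.

    A pair of strains with no gene families at all is assigned distance 0 by
    convention (logged); this cannot occur for matrices produced by the
    simulator, which guarantees a non-empty core.
    """
    x = pa.to_numpy(dtype=bool).astype(np.int64)
    inter = x @ x.T
    sizes = x.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - inter / union
    empty = union == 0
    if empty.any():
        logger.info("empty/empty strain pairs assigned Jaccard distance 0")
        d[empty] = 0.0
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=pa.index, columns=pa.index)


def _check_square_symmetric(d: pd.DataFrame) -> np.ndarray:
    m = d.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1] or list(d.index) != list(d.columns):
        raise ValueError("distance matrix must be square with matching labels")
    if not np.allclose(m, m.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    return m


def nj_tree(d: pd.DataFrame) -> TreeNode:
    """Saitou–Nei neighbor joining.

    Negative estimated branch lengths are clamped to 0 with the deficit
    moved to the sister edge so the pair's summed length is preserved.  Ties
    in the Q criterion resolve to the lowest-index pair, making the result
    deterministic.  The returned tree is unrooted (trifurcating root).
    """
    m = _check_square_symmetric(d)
    labels = list(d.index)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [TreeNode(name=str(lab)) for lab in labels]
    dist = m.copy()
    while len(nodes) > 3:
        n = len(nodes)
        r = dist.sum(axis=1)
        q = (n - 2) * dist - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)  # first minimum: lowest index pair
        if i > j:
            i, j = j, i
        li = 0.5 * dist[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = dist[i, j] - li
        if li < 0:
            lj, li = lj + li, 0.0
        if lj < 0:
            li, lj = li + lj, 0.0
        nodes[i].length = float(max(li, 0.0))
        nodes[j].length = float(max(lj, 0.0))
        parent = TreeNode(children=[nodes[i], nodes[j]])
        newd = 0.5 * (dist[i, :] + dist[j, :] - dist[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        dist = np.vstack([np.hstack([[0.0], newd[keep]]),
                          np.hstack([newd[keep][:, None], dist[np.ix_(keep, keep)]])])
        nodes = [parent] + [nodes[k] for k in keep]
    # resolve the final three nodes with the three-point formulas
    (a, b, c) = nodes
    dab, dac, dbc = dist[0, 1], dist[0, 2], dist[1, 2]
    a.length = float(max(0.5 * (dab + dac - dbc), 0.0))
    b.length = float(max(0.5 * (dab + dbc - dac), 0.0))
    c.length = float(max(0.5 * (dac + dbc - dab), 0.0))
    return TreeNode(children=[a, b, c])


def upgma_tree(d: pd.DataFrame) -> TreeNode:
    """UPGMA agglomeration: ultrametric tree, node height = half the mean
    inter-cluster distance, ties broken toward the lowest-index pair."""
    m = _check_square_symmetric(d)
    labels = list(d.index)
    if len(labels) < 3:
        raise ValueError("UPGMA needs at least 3 taxa")
    nodes = [TreeNode(name=str(lab)) for lab in labels]
    heights = [0.0] * len(nodes)
    sizes = [1] * len(nodes)
    dist = m.astype(float).copy()
    while len(nodes) > 1:
        n = len(nodes)
        work = dist.copy()
        np.fill_diagonal(work, np.inf)
        i, j = np.unravel_index(np.argmin(work), work.shape)
        if i > j:
            i, j = j, i
        h = dist[i, j] / 2.0
        nodes[i].length = float(h - heights[i])
        nodes[j].length = float(h - heights[j])
        parent = TreeNode(children=[nodes[i], nodes[j]])
        merged = (sizes[i] * dist[i, :] + sizes[j] * dist[j, :]) / (sizes[i] + sizes[j])
        keep = [k for k in range(n) if k not in (i, j)]
        dist = np.vstack([np.hstack([[0.0], merged[keep]]),
                          np.hstack([merged[keep][:, None], dist[np.ix_(keep, keep)]])])
        nodes = [parent] + [nodes[k] for k in keep]
        heights = [h] + [heights[k] for k in keep]
        sizes = [sizes[i] + sizes[j]] + [sizes[k] for k in keep]
    root = nodes[0]
    root.length = None
    return root


def patristic_matrix(tree: TreeNode) -> pd.DataFrame:
    """Tip-to-tip path-length (patristic) distance matrix."""
    dm = tree.tip_tip_distances()
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


def scaled_patristic(tree: TreeNode) -> pd.DataFrame:
    """Patristic distances scaled so the largest pairwise divergence is 1.

    This is the 'core genome divergence' axis: 0 = no distance, 1 = the
    longest distance on the tree.  An all-zero tree yields an all-zero
    matrix with a warning.
    """
    d = patristic_matrix(tree)
    mx = float(d.to_numpy().max())
    if mx == 0:
        warnings.warn("tree has no nonzero patristic distance; returning zeros")
        return d
    return d / mx


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial unrooted bipartitions of the tip set.

    Each bipartition is canonicalised as a frozenset of its two sides, so
    rooted and unrooted representations of the same topology agree.
    """
    all_tips = frozenset(t.name for t in tree.tips())
    out: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_tips - side
        if len(side) >= 2 and len(other) >= 2:
            out.add(frozenset((side, other)))
    return out


def rf_distance(t1: TreeNode, t2: TreeNode) -> int:
    """Unweighted Robinson–Foulds distance: bipartitions in exactly one tree."""
    tips1 = {t.name for t in t1.tips()}
    tips2 = {t.name for t in t2.tips()}
    if tips1 != tips2:
        raise ValueError(
            f"tip sets differ: only-in-first={sorted(tips1 - tips2)}, "
            f"only-in-second={sorted(tips2 - tips1)}"
        )
    return len(bipartitions(t1) ^ bipartitions(t2))


def bootstrap_support(
    data,
    method: str = "nj",
    n_reps: int = 100,
    seed: int = 0,
    distance: str | None = None,
) -> TreeNode:
    """Point-estimate tree with bootstrap supports on internal edges.

    ``data`` is either an aligned MSA mapping (columns = sites, distance
    defaults to Jukes–Cantor) or a boolean presence/absence DataFrame
    (columns = gene families, distance defaults to Jaccard).  Columns are
    resampled with replacement ``n_reps`` times; the support of an internal
    edge is the percentage of replicate trees containing its bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if isinstance(data, pd.DataFrame):
        distance = distance or "jaccard"
        ncol = data.shape[1]

        def subset(cols):
            return data.iloc[:, cols]
    else:
        distance = distance or "jc"
        names, arr = _seq_array(data)
        ncol = arr.shape[1]

        def subset(cols):
            sub = arr[:, cols]
            return {n: sub[i].tobytes().decode() for i, n in enumerate(names)}

    def dist_of(d):
        if distance == "jaccard":
            return jaccard_distance_matrix(d)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return jc_distance_matrix(d)

    builder = {"nj": nj_tree, "upgma": upgma_tree}[method]
    point = builder(dist_of(subset(np.arange(ncol))))
    point_bips = {}
    all_tips = frozenset(t.name for t in point.tips())
    for node in point.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) >= 2 and len(all_tips - side) >= 2:
            point_bips[node] = frozenset((side, all_tips - side))
    counts = {bip: 0 for bip in point_bips.values()}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep = builder(dist_of(subset(cols)))
        rep_bips = bipartitions(rep)
        for bip in counts:
            if bip in rep_bips:
                counts[bip] += 1
    for node, bip in point_bips.items():
        support = 100.0 * counts[bip] / n_reps
        node.support = support
        node.name = f"{support:g}"
    return point


def collapse_low_support(tree: TreeNode, threshold: float = 50.0) -> TreeNode:
    """Collapse internal edges whose bootstrap support is below ``threshold``
    into polytomies (off by default in the pipeline)."""
    tree = tree.copy()
    for node in list(tree.non_tips(include_self=False)):
        if getattr(node, "support", None) is not None and node.support < threshold:
            parent = node.parent
            for child in list(node.children):
                node.remove(child)
                if child.length is not None and node.length is not None:
                    child.length += node.length
                parent.append(child)
            parent.remove(node)
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path_or_str) -> TreeNode:
    if isinstance(path_or_str, str) and path_or_str.lstrip().startswith("("):
        return TreeNode.read(io.StringIO(path_or_str), format="newick")
    return TreeNode.read(str(path_or_str), format="newick")
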