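import numpy as np
import pandas as pd
import pytest

from phylopan import simulate, trees


@pytest.fixture(scope="session")
def yule8():
    return simulate.simulate_species_tree(8, seed=11)


@pytest.fixture(scope="session")
def yule16():
    return simulate.simulate_species_tree(16, seed=7)


@pytest.fixture(scope="session")
def five_tip_tree():
    """Fixed non-ultrametric 5-tip tree used for frozen-value checks."""
    return trees.read_newick("((A:0.3,B:0.3):0.7,((C:0.4,D:0.4):0.2,E:0.6):0.4);")


@pytest.fixture(scope="session")
def star6():
    return trees.read_newick("(" + ",".join(f"T{i}:1.0" for i in range(6)) + ");")


@pytest.fixture(scope="session")
def small_pangenome():
    """Small but complete synthetic study shared across tests."""
    return simulate.simulate_pangenome(
        n_taxa=10, seed=42, core_length=2000, core_size=60, accessory_pool=40,
        gain_rate=800.0, loss_rate=5.0,
    )


def brute_force_upgma_heights(d: np.ndarray):
    """Independent UPGMA oracle: returns the sorted list of merge heights and
    the final cluster merge sequence as frozensets, by direct agglomeration
    over all original-pair averages."""
    n = d.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    heights = []
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                pairs = [(a, b) for a in clusters[i] for b in clusters[j]]
                avg = sum(d[a, b] for a, b in pairs) / len(pairs)
                if best is None or avg < best[0]:
                    best = (avg, i, j)
        avg, i, j = best
        merged = clusters[i] | clusters[j]
        merges.append(merged)
        heights.append(avg / 2.0)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return heights, merges


def tree_clusters(tree):
    """All tip-sets under internal nodes (including root) as frozensets of
    tip indices parsed from names like 'T3'."""
    out = []
    for node in tree.non_tips(include_self=True):
        out.append(frozenset(int(t.name[1:]) for t in node.tips()))
    return out


def random_additive_matrix(n, seed):
    """Distance matrix that is exactly additive on a random Yule tree."""
    t = simulate.simulate_species_tree(n, seed=seed, depth=1.0)
    # perturb branch lengths so the tree is not ultrametric
    rng = np.random.default_rng(seed + 1)
    for node in t.traverse(include_self=False):
        node.length = node.length * rng.uniform(0.5, 2.0) + 0.01
    d = trees.patristic_matrix(t)
    return t, d
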