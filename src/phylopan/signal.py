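"""Blomberg's K phylogenetic signal with a tip-shuffling permutation test.

K compares how a trait's variance partitions on a tree with the Brownian
motion (BM) expectation: K ≈ 1 for traits that diffused along the tree,
K ≈ 0 for traits independent of it.  Screening each metabolite against the
marker, core-genome, and gene-composition trees — and asking whether
significance on one topology fails to transfer to the others — is the
metabolite-side readout of taxonomic/metabolic incongruence.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "phylo_covariance",
    "blomberg_k",
    "blomberg_k_many",
    "k_permutation_test",
    "signal_screen",
    "incongruent_metabolites",
    "KResult",
]

# Absolute slack when comparing permuted K values with the observed K, so
# exact algebraic ties (e.g. K ≡ 1 on a star tree) count as >= despite
# floating-point jitter.
_TIE_EPS = 1e-9


def phylo_covariance(tree: TreeNode) -> pd.DataFrame:
    """Tip × tip phylogenetic covariance V: shared root-to-MRCA branch length.

    V[i, j] = depth of the most recent common ancestor of tips i and j;
    the diagonal holds root-to-tip depths.  Computed from root-to-tip depths
    and patristic distances via V = (depth_i + depth_j - d_ij) / 2.
    """
    tips = list(tree.tips())
    names = [t.name for t in tips]
    depth = {}
    for node in tree.preorder(include_self=True):
        d = 0.0 if node.parent is None else depth[id(node.parent)] + (node.length or 0.0)
        depth[id(node)] = d
    depths = np.array([depth[id(t)] for t in tips])
    dm = tree.tip_tip_distances()
    order = [list(dm.ids).index(n) for n in names]
    d = dm.data[np.ix_(order, order)]
    v = 0.5 * (depths[:, None] + depths[None, :] - d)
    v = 0.5 * (v + v.T)
    return pd.DataFrame(v, index=names, columns=names)


@dataclass
class _KEngine:
    """Precomputed pieces of the K statistic for one covariance matrix."""

    v_inv: np.ndarray
    ones_v_ones: float
    expected_ratio: float  # (tr V - n / 1'V⁻¹1) / (n-1), the BM expectation

    @classmethod
    def from_covariance(cls, v: np.ndarray) -> "_KEngine":
        n = v.shape[0]
        try:
            v_inv = np.linalg.inv(v)
        except np.linalg.LinAlgError:
            warnings.warn("singular phylogenetic covariance; using pseudo-inverse")
            v_inv = np.linalg.pinv(v)
        one = np.ones(n)
        ovo = float(one @ v_inv @ one)
        expected = (np.trace(v) - n / ovo) / (n - 1)
        return cls(v_inv=v_inv, ones_v_ones=ovo, expected_ratio=expected)

    def k_many(self, x: np.ndarray) -> np.ndarray:
        """K for each column of an (n_tips, n_traits) matrix."""
        n = x.shape[0]
        a_hat = (self.v_inv.sum(axis=0) @ x) / self.ones_v_ones
        r = x - a_hat
        mse0 = (r * r).sum(axis=0) / (n - 1)
        mse = (r * (self.v_inv @ r)).sum(axis=0) / (n - 1)
        return (mse0 / mse) / self.expected_ratio


def _as_matrix(v) -> np.ndarray:
    return v.to_numpy(dtype=float) if isinstance(v, pd.DataFrame) else np.asarray(v, float)


def blomberg_k(trait: Sequence[float], v) -> float:
    """Blomberg's K of one trait given the tree covariance ``v``.

    Uses the phylogenetically-correct mean â = (1'V⁻¹x)/(1'V⁻¹1), the ratio
    MSE0/MSE of ordinary to GLS mean squared error, and the BM expectation
    of that ratio, (tr V − n/(1'V⁻¹1))/(n−1).  Requires >= 4 tips and a
    non-constant trait.
    """
    x = np.asarray(trait, dtype=float)
    vm = _as_matrix(v)
    if x.ndim != 1 or x.shape[0] != vm.shape[0]:
        raise ValueError("trait length must equal the covariance dimension")
    if x.shape[0] < 4:
        raise ValueError("K needs at least 4 tips")
    if np.ptp(x) == 0:
        raise ValueError("K is undefined for a constant trait")
    return float(_KEngine.from_covariance(vm).k_many(x[:, None])[0])


def blomberg_k_many(traits, v) -> np.ndarray:
    """Vectorised K for many traits sharing one tree.

    ``traits`` is an (n_tips, n_traits) array or DataFrame (tips as rows,
    ordered like ``v``); returns one K per column.
    """
    x = traits.to_numpy(dtype=float) if isinstance(traits, pd.DataFrame) else np.asarray(
        traits, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    vm = _as_matrix(v)
    if x.shape[0] != vm.shape[0]:
        raise ValueError("trait rows must match the covariance dimension")
    return _KEngine.from_covariance(vm).k_many(x)


@dataclass
class KResult:
    metabolite: str
    tree: str
    k: float
    p: float
    n_randomizations: int

    @property
    def significant(self) -> bool:
        return self.p < 0.01


def k_permutation_test(
    trait: Sequence[float],
    v,
    n_randomizations: int = 1000,
    seed: int = 0,
    metabolite: str = "trait",
    tree: str = "tree",
) -> KResult:
    """Randomization test for K: trait values shuffled across tips.

    p = (1 + #{K_perm >= K_obs}) / (n + 1); the add-one correction keeps p
    in (0, 1] and valid at finite n.
    """
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    x = np.asarray(trait, dtype=float)
    vm = _as_matrix(v)
    engine = _KEngine.from_covariance(vm)
    if x.shape[0] < 4:
        raise ValueError("K needs at least 4 tips")
    if np.ptp(x) == 0:
        raise ValueError("K is undefined for a constant trait")
    k_obs = float(engine.k_many(x[:, None])[0])
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(x[:, None], (1, n_randomizations)), axis=0)
    k_perm = engine.k_many(perms)
    n_ge = int(np.count_nonzero(k_perm >= k_obs - _TIE_EPS))
    p = (1 + n_ge) / (n_randomizations + 1)
    return KResult(metabolite=metabolite, tree=tree, k=k_obs, p=p,
                   n_randomizations=n_randomizations)


def signal_screen(
    traits: pd.DataFrame,
    trees: Mapping[str, TreeNode],
    n_randomizations: int = 1000,
    seed: int = 0,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """K and permutation p for every metabolite × tree combination.

    ``traits`` is strains × metabolites; every tree must cover exactly the
    trait matrix's strain set.  Per-metabolite RNG streams are derived from
    (seed, tree index, metabolite index) so results do not depend on
    iteration order.  Returns a tidy frame with a significance flag at
    ``alpha`` (default 0.01).
    """
    strains = list(traits.index)
    rows = []
    for t_idx, (tag, tree) in enumerate(trees.items()):
        tip_names = {t.name for t in tree.tips()}
        missing = sorted(set(strains) ^ tip_names)
        if missing:
            raise ValueError(f"tree '{tag}' strain mismatch: {missing}")
        v = phylo_covariance(tree).loc[strains, strains]
        engine = _KEngine.from_covariance(v.to_numpy())
        for m_idx, met in enumerate(traits.columns):
            x = traits[met].to_numpy(dtype=float)
            if np.ptp(x) == 0:
                warnings.warn(f"metabolite {met} constant; skipped")
                continue
            res = k_permutation_test(
                x, v, n_randomizations=n_randomizations,
                seed=np.random.SeedSequence([seed, t_idx, m_idx]).generate_state(1)[0],
                metabolite=str(met), tree=tag,
            )
            rows.append((res.metabolite, res.tree, res.k, res.p,
                         res.n_randomizations, res.p < alpha))
    return pd.DataFrame(
        rows, columns=["metabolite", "tree", "K", "p", "n", f"significant_at_{alpha:g}"]
    )


def incongruent_metabolites(screen: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Metabolites significant on at least one tree but not on all trees.

    These are the paper-style discordance calls: phylogenetic signal that
    depends on which measure of relatedness built the tree.
    """
    sig = screen.assign(sig=screen["p"] < alpha)
    per = sig.groupby("metabolite")["sig"].agg(["sum", "count"])
    mask = (per["sum"] >= 1) & (per["sum"] < per["count"])
    return per[mask].rename(columns={"sum": "n_significant_trees", "count": "n_trees"})
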