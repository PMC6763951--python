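"""Synthetic pangenomes, marker alignments, features, and metabolite traits.

Every downstream stage of the incongruence analysis is exercised on data
from this module.  The generator emulates the statistical structure the
analysis assumes:

- a pure-birth (Yule) species tree scaled to a chosen root-to-tip depth in
  expected substitutions/site;
- a slowly evolving single-copy (optionally multi-copy) marker gene and a
  much faster concatenated core alignment, both site-independent
  Jukes–Cantor, so marker identity stays high while genomes diverge;
- accessory gene families under gain/loss along branches, so strains that
  are identical at the marker still differ in gene content;
- categorical feature families (resistance / GCF / CAZy / hallmark) tied to
  accessory families or drawn independently;
- metabolite traits evolved as Brownian motion on the tree (phylogenetic
  signal present) or as white noise (signal absent), expanded into a
  replicated two-ion-mode LC-MS-style long table with media controls and
  missing-at-random dropout.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .features import FeatureAnnotation, FEATURE_CATEGORIES, CATEGORY_FLAGS
from .signal import phylo_covariance

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# species tree


def simulate_species_tree(
    n_taxa: int, birth_rate: float = 1.0, seed: int = 0, depth: float = 0.1
) -> TreeNode:
    """Pure-birth (Yule) ultrametric tree with ``n_taxa`` tips.

    Branch lengths are rescaled so every root-to-tip path equals ``depth``
    (expected substitutions/site at rate multiplier 1).  Deterministic for
    a fixed seed; tips are labelled S01, S02, ... in birth order.
    """
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    if birth_rate <= 0 or depth <= 0:
        raise ValueError("birth_rate and depth must be positive")
    rng = _rng(seed)
    root = TreeNode()
    first, second = TreeNode(), TreeNode()
    root.extend([first, second])
    active: list[tuple[TreeNode, float]] = [(first, 0.0), (second, 0.0)]
    t = 0.0
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        idx = int(rng.integers(k))
        node, born = active.pop(idx)
        node.length = t - born
        left, right = TreeNode(), TreeNode()
        node.extend([left, right])
        active.append((left, t))
        active.append((right, t))
    t_end = t + rng.exponential(1.0 / (birth_rate * n_taxa))
    for i, (node, born) in enumerate(active):
        node.length = t_end - born
    for i, tip in enumerate(root.tips()):
        tip.name = f"S{i + 1:02d}"
    scale = depth / t_end
    for node in root.traverse(include_self=False):
        node.length = (node.length or 0.0) * scale
    return root


# ---------------------------------------------------------------------------
# sequence evolution


def _evolve_along(tree: TreeNode, root_states: np.ndarray, rate_multiplier: float,
                  rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Evolve integer-coded sites down the tree under Jukes–Cantor."""
    length = root_states.shape[0]
    states = {id(tree): root_states}
    tips: dict[str, np.ndarray] = {}
    for node in tree.preorder(include_self=False):
        d = (node.length or 0.0) * rate_multiplier
        p_change = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
        parent = states[id(node.parent)]
        child = parent.copy()
        if p_change > 0:
            mask = rng.random(length) < p_change
            n_mut = int(mask.sum())
            if n_mut:
                child[mask] = (child[mask] + rng.integers(1, 4, size=n_mut)) % 4
        if node.is_tip():
            tips[node.name] = child
        else:
            states[id(node)] = child
    return tips


def _decode(states: np.ndarray) -> str:
    return BASES[states].tobytes().decode()


def evolve_alignment(
    tree: TreeNode, length: int, rate_multiplier: float = 1.0, seed: int = 0
) -> dict[str, str]:
    """Gapless MSA: one sequence per tip, Jukes–Cantor along branch length ×
    ``rate_multiplier``, sites independent, uniform root composition."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if rate_multiplier < 0:
        raise ValueError("rate_multiplier must be >= 0")
    rng = _rng(seed)
    root = rng.integers(0, 4, size=length, dtype=np.int64)
    tips = _evolve_along(tree, root, rate_multiplier, rng)
    return {name: _decode(s) for name, s in tips.items()}


def duplicate_marker(
    msa: dict[str, str], n_copies: int = 2, divergence: float = 0.005, seed: int = 0
) -> dict[str, dict[str, str]]:
    """Optionally expand a single-copy marker alignment into ``n_copies``
    slightly diverged within-genome copies (exercises the best-copy rule)."""
    rng = _rng(seed)
    out: dict[str, dict[str, str]] = {}
    for genome, seq in msa.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        states = np.searchsorted(BASES, arr)
        copies = {"rrn1": seq}
        for c in range(2, n_copies + 1):
            p = 0.75 * (1.0 - np.exp(-4.0 * divergence / 3.0))
            mask = rng.random(states.shape[0]) < p
            mutated = states.copy()
            n_mut = int(mask.sum())
            if n_mut:
                mutated[mask] = (mutated[mask] + rng.integers(1, 4, size=n_mut)) % 4
            copies[f"rrn{c}"] = _decode(mutated)
        out[genome] = copies
    return out


# ---------------------------------------------------------------------------
# gene content


def evolve_gene_content(
    tree: TreeNode,
    core_size: int = 200,
    accessory_pool: int = 100,
    gain_rate: float = 1500.0,
    loss_rate: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Presence/absence matrix under branch-wise gene gain and loss.

    Core families (``core_size``) are present in every strain and immune to
    loss.  The root additionally carries ``accessory_pool`` accessory
    families.  Along each branch of length L, Poisson(gain_rate·L) new
    families arise (an infinitely-many-families model: every gain founds a
    new family that propagates to descendants) and each accessory family
    present survives with probability exp(−loss_rate·L).
    """
    if gain_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = _rng(seed)
    core = [f"core{i:05d}" for i in range(core_size)]
    counter = accessory_pool
    root_acc = frozenset(f"acc{i:05d}" for i in range(accessory_pool))
    content = {id(tree): root_acc}
    tip_content: dict[str, frozenset] = {}
    for node in tree.preorder(include_self=False):
        d = node.length or 0.0
        parent_acc = sorted(content[id(node.parent)])
        keep = rng.random(len(parent_acc)) < np.exp(-loss_rate * d)
        survivors = {f for f, k in zip(parent_acc, keep) if k}
        n_gain = int(rng.poisson(gain_rate * d))
        for _ in range(n_gain):
            survivors.add(f"acc{counter:05d}")
            counter += 1
        acc = frozenset(survivors)
        if node.is_tip():
            tip_content[node.name] = acc
        else:
            content[id(node)] = acc
    strains = [t.name for t in tree.tips()]
    families = core + sorted(set().union(*tip_content.values())) if tip_content else core
    pa = pd.DataFrame(False, index=strains, columns=families)
    pa.loc[:, core] = True
    for strain, acc in tip_content.items():
        if acc:
            pa.loc[strain, sorted(acc)] = True
    return pa


@dataclass
class SimulatedPangenome:
    """Bundle of the simulated genome-scale objects for one parameter set."""

    tree: TreeNode
    marker_msa: dict[str, str]
    marker_copies: dict[str, dict[str, str]]
    core_msa: dict[str, str]
    pa: pd.DataFrame
    family_sequences: dict[str, dict[str, str]]
    family_length: dict[str, int]
    genome_length: pd.Series


def attach_family_sequences(
    tree: TreeNode,
    pa: pd.DataFrame,
    rate_multiplier: float = 1.0,
    length_range: tuple[int, int] = (300, 1500),
    seed: int = 0,
) -> tuple[dict[str, dict[str, str]], dict[str, int]]:
    """Per-strain representative sequences for every family.

    Each family gets a root sequence of length uniform in ``length_range``
    evolved down the whole tree at the core rate; a strain's representative
    is its tip sequence, read only where the family is present.  All
    families are evolved as one concatenated alignment and sliced.
    """
    rng = _rng(seed)
    families = list(pa.columns)
    lengths = rng.integers(length_range[0], length_range[1] + 1, size=len(families))
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    total = int(offsets[-1])
    root = rng.integers(0, 4, size=total, dtype=np.int64)
    tips = _evolve_along(tree, root, rate_multiplier, rng)
    fam_len = {f: int(l) for f, l in zip(families, lengths)}
    seqs: dict[str, dict[str, str]] = {}
    pa_bool = pa.astype(bool)
    for strain, states in tips.items():
        decoded = _decode(states)
        present = pa_bool.loc[strain]
        seqs[strain] = {
            fam: decoded[offsets[k]:offsets[k + 1]]
            for k, fam in enumerate(families)
            if present[fam]
        }
    genome_length = pd.Series(
        {s: sum(len(x) for x in d.values()) for s, d in seqs.items()}, name="genome_length"
    )
    return seqs, genome_length


def simulate_pangenome(
    n_taxa: int = 16,
    seed: int = 0,
    depth: float = 0.1,
    birth_rate: float = 1.0,
    marker_length: int = 1500,
    marker_rate: float = 0.05,
    marker_copies: int = 1,
    core_length: int = 10000,
    core_rate: float = 1.0,
    core_size: int = 200,
    accessory_pool: int = 100,
    gain_rate: float = 1500.0,
    loss_rate: float = 5.0,
    family_rate: float = 1.0,
) -> SimulatedPangenome:
    """One coherent synthetic study: tree, marker, core, content, sequences.

    Defaults encode the regime the analysis is about: the marker evolves
    ~20× slower than the core (so many strain pairs exceed 99% marker
    identity while core genomes diverge measurably) and accessory turnover
    is fast (so content differs even between marker-identical strains).
    Sub-seeds for each component are derived from ``seed``.
    """
    ss = np.random.SeedSequence(seed).spawn(6)
    tree = simulate_species_tree(n_taxa, birth_rate=birth_rate, seed=ss[0], depth=depth)
    marker = evolve_alignment(tree, marker_length, marker_rate, seed=ss[1])
    core = evolve_alignment(tree, core_length, core_rate, seed=ss[2])
    pa = evolve_gene_content(tree, core_size, accessory_pool, gain_rate, loss_rate, seed=ss[3])
    seqs, glen = attach_family_sequences(tree, pa, family_rate, seed=ss[4])
    copies = (
        duplicate_marker(marker, marker_copies, seed=ss[5])
        if marker_copies > 1
        else {g: {"rrn1": s} for g, s in marker.items()}
    )
    return SimulatedPangenome(
        tree=tree, marker_msa=marker, marker_copies=copies, core_msa=core, pa=pa,
        family_sequences=seqs, family_length={f: len(next(iter(seqs.values())).get(f, ""))
                                             for f in pa.columns},
        genome_length=glen,
    )


# ---------------------------------------------------------------------------
# features


def assign_feature_families(
    pa: pd.DataFrame,
    category: str,
    n_families: int = 30,
    prevalence_distribution="tied",
    seed: int = 0,
) -> FeatureAnnotation:
    """Synthetic feature calls (resistance / gcf / cazy / hallmark).

    ``prevalence_distribution``:

    - ``"tied"`` (default): each feature inherits the presence pattern of a
      randomly chosen accessory family, so feature overlap tracks gene
      content;
    - a float p or array of per-feature floats: independent Bernoulli(p)
      presence per strain.

    Categories with a flag vocabulary (resistance: strict/loose, gcf:
    full/fragment) get a flag drawn uniformly per feature.
    """
    if category not in FEATURE_CATEGORIES:
        raise ValueError(f"unknown feature category: {category!r}")
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = _rng(seed)
    strains = list(pa.index)
    fids = [f"{category}{i:04d}" for i in range(n_families)]
    presence = pd.DataFrame(False, index=strains, columns=fids)
    if isinstance(prevalence_distribution, str) and prevalence_distribution == "tied":
        acc = [c for c in pa.columns if not c.startswith("core")]
        if not acc:
            raise ValueError("no accessory families to tie features to")
        chosen = rng.choice(len(acc), size=n_families, replace=True)
        for fid, k in zip(fids, chosen):
            presence[fid] = pa[acc[k]].astype(bool).to_numpy()
        tied_to = {fid: acc[k] for fid, k in zip(fids, chosen)}
    else:
        p = np.broadcast_to(np.asarray(prevalence_distribution, dtype=float), (n_families,))
        for fid, pi in zip(fids, p):
            presence[fid] = rng.random(len(strains)) < pi
        tied_to = {}
    flags = None
    vocab = CATEGORY_FLAGS.get(category)
    if vocab:
        flags = {fid: vocab[int(rng.integers(len(vocab)))] for fid in fids}
    sets = {s: set(presence.columns[presence.loc[s]]) for s in strains}
    return FeatureAnnotation(category=category, sets=sets, flags=flags, tied_to=tied_to)


# ---------------------------------------------------------------------------
# traits and LC-MS


@dataclass
class SimulatedTraits:
    """Metabolite trait matrix with per-trait generator provenance."""

    values: pd.DataFrame  # strains × metabolites
    generator: dict[str, str]  # metabolite -> 'bm' | 'white_noise'
    sigma2: float
    tree: TreeNode = field(repr=False, default=None)


def simulate_traits(
    tree: TreeNode, n_bm: int = 20, n_noise: int = 20, sigma2: float = 1.0, seed: int = 0
) -> SimulatedTraits:
    """Brownian-motion traits (covariance σ²·V(tree)) plus white-noise traits.

    Noise traits are iid normal with variance matched to the mean BM tip
    variance (σ²·mean diag V) so both kinds live on a comparable scale.
    """
    if n_bm + n_noise < 1:
        raise ValueError("need at least one trait")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    rng = _rng(seed)
    v = phylo_covariance(tree)
    strains = list(v.index)
    n = len(strains)
    cols = {}
    generator = {}
    if n_bm:
        vm = v.to_numpy() + 1e-12 * np.eye(n)
        chol = np.linalg.cholesky(vm)
        z = rng.standard_normal((n, n_bm))
        bm = np.sqrt(sigma2) * (chol @ z)
        for k in range(n_bm):
            name = f"bm{k + 1:03d}"
            cols[name] = bm[:, k]
            generator[name] = "bm"
    scale = np.sqrt(sigma2 * float(np.mean(np.diag(v.to_numpy()))))
    for k in range(n_noise):
        name = f"wn{k + 1:03d}"
        cols[name] = scale * rng.standard_normal(n)
        generator[name] = "white_noise"
    values = pd.DataFrame(cols, index=strains)
    return SimulatedTraits(values=values, generator=generator, sigma2=sigma2, tree=tree)


CONTROL_STRAIN = "media_control"


def simulate_lcms(
    traits: SimulatedTraits,
    n_replicates: int = 5,
    missing_rate: float = 0.1,
    control_level: float = 100.0,
    seed: int = 0,
    signal_fold: float = 10.0,
    noise_sd: float = 0.1,
) -> pd.DataFrame:
    """Long LC-MS-style table with replicates, two ion modes, and controls.

    Sample abundance = control_level · signal_fold · e_mode · exp(trait) ·
    exp(N(0, noise_sd)); each metabolite gets a fixed per-ion-mode
    efficiency e ~ U(0.3, 1).  Media-control rows sit at control_level with
    the same multiplicative noise.  Missingness is completely at random:
    each non-control row is dropped with probability ``missing_rate``
    (missing values are absent rows).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = _rng(seed)
    strains = list(traits.values.index)
    mets = list(traits.values.columns)
    modes = ["pos", "neg"]
    eff = {(m, mode): rng.uniform(0.3, 1.0) for m in mets for mode in modes}
    rows = []
    for met in mets:
        for mode in modes:
            e = eff[(met, mode)]
            for strain in strains:
                mu = control_level * signal_fold * e * np.exp(traits.values.loc[strain, met])
                for rep in range(1, n_replicates + 1):
                    ab = mu * np.exp(rng.normal(0.0, noise_sd))
                    rows.append((strain, rep, mode, met, ab, False))
            for rep in range(1, n_replicates + 1):
                ab = control_level * e * np.exp(rng.normal(0.0, noise_sd))
                rows.append((CONTROL_STRAIN, rep, mode, met, ab, True))
    df = pd.DataFrame(
        rows, columns=["strain", "replicate", "ion_mode", "metabolite", "abundance",
                       "is_control"],
    )
    if missing_rate > 0:
        drop = (~df["is_control"]) & (rng.random(len(df)) < missing_rate)
        df = df[~drop].reset_index(drop=True)
    return df
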