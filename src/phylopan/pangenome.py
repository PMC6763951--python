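"""Gene-family clustering, content overlap, and aligned-region ANI.

Genomes are summarised as presence/absence over gene families (orthologs).
Families come either from simulation or from single-linkage clustering of
gene sequences at identity/coverage cutoffs (>75%/>75% by default).
Average nucleotide identity is computed over the shared-family alignments,
with explicit aligned/unaligned length accounting, so the familiar
ANI-vs-marker-identity comparison can be made on any pangenome.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import align as _al


@dataclass
class AniResult:
    """ANI over shared gene families plus length accounting for one pair."""

    ani: float
    aligned_length: int  # summed residues of both genomes inside shared-family alignments
    unaligned_length: int  # genome length not covered by shared families
    n_shared_families: int


@dataclass
class Pangenome:
    """Presence/absence matrix with optional per-strain family sequences.

    ``pa``: strains × families boolean DataFrame.
    ``sequences``: strain -> {family -> representative nucleotide sequence}.
    ``genome_length``: total bp per strain; defaults to the summed length of
    that strain's gene sequences when sequences are attached.
    """

    pa: pd.DataFrame
    sequences: dict[str, dict[str, str]] = field(default_factory=dict)
    genome_length: pd.Series | None = None

    def __post_init__(self):
        if self.genome_length is None and self.sequences:
            self.genome_length = pd.Series(
                {s: sum(len(x) for x in fams.values()) for s, fams in self.sequences.items()}
            )

    @property
    def strains(self) -> list[str]:
        return list(self.pa.index)

    def content(self, strain: str) -> set[str]:
        row = self.pa.loc[strain]
        return set(row.index[row.astype(bool)])


def _pair_stats(a: str, b: str) -> tuple[float, float, float, int]:
    """identity, coverage_a, coverage_b, n non-gap-both columns of the best
    global alignment of two genes."""
    ga, gb = _al.global_align(a, b)
    arr_a = np.frombuffer(ga.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(gb.encode(), dtype=np.uint8)
    gap = ord("-")
    both = (arr_a != gap) & (arr_b != gap)
    n_both = int(both.sum())
    if n_both == 0:
        return 0.0, 0.0, 0.0, 0
    matches = int(np.count_nonzero(arr_a[both] == arr_b[both]))
    return matches / n_both, n_both / len(a), n_both / len(b), n_both


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def cluster_gene_families(
    genes: Mapping[str, Mapping[str, str]],
    identity_cutoff: float = 0.75,
    coverage_cutoff: float = 0.75,
) -> Pangenome:
    """Single-linkage gene-family clustering at identity/coverage cutoffs.

    An edge joins two genes when alignment coverage exceeds
    ``coverage_cutoff`` on *both* genes and identity exceeds
    ``identity_cutoff`` (strict inequalities).  Connected components are
    families; the family id is the lexicographically smallest member gene
    id, prefixed 'fam:'.
    """
    for cut in (identity_cutoff, coverage_cutoff):
        if not 0 < cut <= 1:
            raise ValueError("cutoffs must be in (0, 1]")
    records = [(strain, gid, seq) for strain, d in genes.items() for gid, seq in d.items()]
    if not records:
        return Pangenome(pa=pd.DataFrame(dtype=bool))
    keys = [f"{s}:{g}" for s, g, _ in records]
    uf = _UnionFind(keys)
    for (i, (_, _, sa)), (j, (_, _, sb)) in itertools.combinations(enumerate(records), 2):
        ident, cov_a, cov_b, _ = _pair_stats(sa, sb)
        if ident > identity_cutoff and cov_a > coverage_cutoff and cov_b > coverage_cutoff:
            uf.union(keys[i], keys[j])
    fam_of = {k: f"fam:{uf.find(k)}" for k in keys}
    strains = list(genes)
    families = sorted(set(fam_of.values()))
    pa = pd.DataFrame(False, index=strains, columns=families)
    seqs: dict[str, dict[str, str]] = {s: {} for s in strains}
    for (strain, gid, seq), key in zip(records, keys):
        fam = fam_of[key]
        pa.loc[strain, fam] = True
        seqs[strain].setdefault(fam, seq)  # first gene per strain is the representative
    return Pangenome(pa=pa, sequences=seqs)


def shared_unshared(pa: pd.DataFrame, strain_i: str, strain_j: str) -> tuple[int, int]:
    """(#families in both, #families in exactly one) for a strain pair."""
    a = pa.loc[strain_i].to_numpy(dtype=bool)
    b = pa.loc[strain_j].to_numpy(dtype=bool)
    shared = int(np.count_nonzero(a & b))
    unshared = int(np.count_nonzero(a ^ b))
    return shared, unshared


def family_frequency_spectrum(
    pa: pd.DataFrame, core_fraction: float = 0.9, rare_fraction: float = 0.1
) -> tuple[pd.Series, int, int]:
    """Histogram of per-family prevalence (number of carrier strains), plus
    the count of core families (prevalence >= core_fraction of strains) and
    rare families (prevalence < rare_fraction)."""
    for f in (core_fraction, rare_fraction):
        if not 0 < f < 1:
            raise ValueError("fractions must be in (0, 1)")
    n_strains = pa.shape[0]
    carriers = pa.astype(bool).sum(axis=0)
    spectrum = carriers.value_counts().sort_index()
    spectrum.index.name = "n_strains_carrying"
    prevalence = carriers / n_strains
    n_core = int((prevalence >= core_fraction).sum())
    n_rare = int((prevalence < rare_fraction).sum())
    return spectrum, n_core, n_rare


def compute_ani(genome_a: str, genome_b: str, pg: Pangenome) -> AniResult:
    """Ortholog-based ANI: length-weighted mean identity over shared families.

    Each shared family's two representatives are globally aligned (equal
    lengths compare directly); identity is read at columns where both are
    non-gapped and weighted by the count of such columns.  Aligned length
    per genome is its residues inside those alignments; unaligned length is
    the remainder of both genome lengths.  Zero shared families is an error
    (ANI undefined), distinct from ANI = 0.
    """
    for g in (genome_a, genome_b):
        if g not in pg.sequences or g not in pg.pa.index:
            raise KeyError(f"genome {g} not present with sequences")
    seqs_a, seqs_b = pg.sequences[genome_a], pg.sequences[genome_b]
    shared = sorted(set(seqs_a) & set(seqs_b) & set(pg.content(genome_a) & pg.content(genome_b)))
    if not shared:
        raise ValueError(f"ANI undefined: no shared families between {genome_a} and {genome_b}")
    w_sum = 0.0
    ident_sum = 0.0
    aligned_a = aligned_b = 0
    for fam in shared:
        sa, sb = seqs_a[fam], seqs_b[fam]
        if len(sa) == len(sb):
            xa = np.frombuffer(sa.encode(), dtype=np.uint8)
            xb = np.frombuffer(sb.encode(), dtype=np.uint8)
            n_both = len(sa)
            ident = np.count_nonzero(xa == xb) / n_both
            res_a = res_b = n_both
        else:
            ident, cov_a, cov_b, n_both = _pair_stats(sa, sb)
            res_a = int(round(cov_a * len(sa)))
            res_b = int(round(cov_b * len(sb)))
        ident_sum += ident * n_both
        w_sum += n_both
        aligned_a += res_a
        aligned_b += res_b
    ani = 100.0 * ident_sum / w_sum
    lengths = pg.genome_length
    la = int(lengths[genome_a]) if lengths is not None else aligned_a
    lb = int(lengths[genome_b]) if lengths is not None else aligned_b
    unaligned = max(la - aligned_a, 0) + max(lb - aligned_b, 0)
    return AniResult(ani=float(ani), aligned_length=aligned_a + aligned_b,
                     unaligned_length=unaligned, n_shared_families=len(shared))


def ani_table(pg: Pangenome) -> pd.DataFrame:
    """All-pairs ANI with shared/unshared counts, one row per unordered pair."""
    rows = []
    for a, b in itertools.combinations(pg.strains, 2):
        res = compute_ani(a, b, pg)
        shared, unshared = shared_unshared(pg.pa, a, b)
        rows.append((a, b, res.ani, res.aligned_length, res.unaligned_length,
                     shared, unshared))
    return pd.DataFrame(
        rows,
        columns=["strain_a", "strain_b", "ani", "aligned_bp", "unaligned_bp",
                 "shared", "unshared"],
    )


def read_presence_absence(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(bool)


def write_presence_absence(pa: pd.DataFrame, path) -> None:
    pa.astype(int).to_csv(path, sep="\t", index_label="strain")
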