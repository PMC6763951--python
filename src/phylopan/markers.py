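"""Pairwise marker-gene (rRNA-like) percent identity between genomes.

Implements the marker workflow used to place strains on the familiar
16S-style identity axis: keep predicted marker copies whose length falls
within a tolerance of a reference (e.g. 1,738 bp for a 16S-like gene,
±20%), align the retained copies, read percent identity at columns where
both sequences are non-gapped, and — for multi-copy genomes — report the
best copy-vs-copy match per genome pair.
"""
from __future__ import annotations

import itertools
import logging
from typing import Mapping

import numpy as np
import pandas as pd

from . import align as _al

logger = logging.getLogger(__name__)

# MarkerGeneSet: genome id -> {gene id -> sequence}
MarkerGeneSet = Mapping[str, Mapping[str, str]]

GAP_CHARS = frozenset("-.")


def filter_by_reference_length(
    genes: MarkerGeneSet, reference_length: int, tolerance: float = 0.2
) -> dict[str, dict[str, str]]:
    """Keep marker copies with length in the closed interval
    [ref·(1−tol), ref·(1+tol)].

    Genomes that lose every copy are excluded (with a logged warning); they
    cannot appear in the pairwise identity matrix.
    """
    if reference_length <= 0:
        raise ValueError("reference_length must be positive")
    if not 0 < tolerance < 1:
        raise ValueError("tolerance must be in (0, 1)")
    lo = reference_length * (1 - tolerance)
    hi = reference_length * (1 + tolerance)
    out: dict[str, dict[str, str]] = {}
    for genome, copies in genes.items():
        kept = {g: s for g, s in copies.items() if lo <= len(s) <= hi}
        if kept:
            out[genome] = kept
        else:
            logger.warning(
                "genome %s: all %d marker copies outside [%.1f, %.1f] bp; excluded",
                genome, len(copies), lo, hi,
            )
    return out


def percent_identity_nongapped(aligned_a: str, aligned_b: str) -> float:
    """Percent identity over columns where both sequences are non-gapped.

    Columns containing an N in either sequence count as non-gap but
    non-matching.  Raises if no mutually non-gapped column exists.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    a = aligned_a.upper()
    b = aligned_b.upper()
    compared = matches = 0
    for ca, cb in zip(a, b):
        if ca in GAP_CHARS or cb in GAP_CHARS:
            continue
        compared += 1
        if ca == cb and ca != "N":
            matches += 1
    if compared == 0:
        raise ValueError("identity undefined: no mutually non-gapped column")
    return 100.0 * matches / compared


def _flatten(genes: MarkerGeneSet) -> dict[str, str]:
    """Record ids 'genome:gene' for a joint alignment of all copies."""
    flat = {}
    for genome, copies in genes.items():
        for gene, seq in copies.items():
            flat[f"{genome}:{gene}"] = seq
    return flat


def pairwise_marker_identity(genes: MarkerGeneSet, aligner: str = "auto") -> pd.DataFrame:
    """Symmetric percent-identity matrix between genomes.

    For each genome pair the entry is the maximum identity over all
    copy-vs-copy comparisons (the best-copy rule).  Backends:

    - ``"prealigned"``: sequences are already one joint alignment
      (equal lengths, gaps allowed).
    - ``"mafft"``: one joint multiple alignment of every retained copy,
      then column identity — mirrors aligning all genes together.
    - ``"pairwise"``: independent global alignment per copy pair
      (match 1 / mismatch −1 / gap open −2 / extend −0.5).
    - ``"auto"`` (default): prealigned if all lengths agree, else mafft if
      on PATH, else pairwise.
    """
    if len(genes) < 2:
        raise ValueError("need at least two genomes with retained marker copies")
    flat = _flatten(genes)
    if aligner == "auto":
        if len({len(s) for s in flat.values()}) == 1:
            aligner = "prealigned"
        elif _al.mafft_available():
            aligner = "mafft"
        else:
            aligner = "pairwise"
    if aligner == "mafft":
        flat = _al.mafft_align(flat)
        aligner = "prealigned"
    elif aligner == "prealigned":
        if len({len(s) for s in flat.values()}) != 1:
            raise ValueError("prealigned backend requires equal-length sequences")
    elif aligner != "pairwise":
        raise ValueError(f"unknown aligner backend: {aligner}")

    genomes = list(genes)
    mat = pd.DataFrame(100.0, index=genomes, columns=genomes, dtype=float)
    for ga, gb in itertools.combinations(genomes, 2):
        best = -np.inf
        for ca in genes[ga]:
            for cb in genes[gb]:
                ka, kb = f"{ga}:{ca}", f"{gb}:{cb}"
                if aligner == "pairwise":
                    sa, sb = _al.global_align(genes[ga][ca], genes[gb][cb])
                else:
                    sa, sb = flat[ka], flat[kb]
                best = max(best, percent_identity_nongapped(sa, sb))
        mat.loc[ga, gb] = mat.loc[gb, ga] = best
    return mat


def identity_matrix_from_alignment(msa: Mapping[str, str]) -> pd.DataFrame:
    """Fast single-copy path: percent identity straight from a joint MSA."""
    return pairwise_marker_identity({g: {"m": s} for g, s in msa.items()},
                                    aligner="prealigned")


def write_identity_matrix(mat: pd.DataFrame, path) -> None:
    mat.round(2).to_csv(path, sep="\t", index_label="strain")


def read_marker_fasta(path) -> dict[str, dict[str, str]]:
    """Multi-FASTA with record ids 'genome:gene' -> MarkerGeneSet."""
    out: dict[str, dict[str, str]] = {}
    for rec_id, seq in _al.read_fasta(path).items():
        genome, _, gene = rec_id.partition(":")
        out.setdefault(genome, {})[gene or "gene1"] = seq
    return out
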