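"""Thin alignment backends shared by the marker-identity and pangenome code.

Global pairwise alignment uses Bio.Align.PairwiseAligner (match 1,
mismatch -1, gap open -2, gap extend -0.5).  A joint multiple alignment of
many sequences is delegated to mafft when sequences are unaligned; inputs
that are already of equal length are treated as aligned.
"""
from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path
from typing import Mapping

from Bio import Align, SeqIO


def make_aligner(mode: str = "global") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


def global_align(a: str, b: str) -> tuple[str, str]:
    """Best global alignment of two sequences as gapped strings."""
    aln = make_aligner("global").align(a.upper(), b.upper())[0]
    return str(aln[0]), str(aln[1])


def mafft_available() -> bool:
    return shutil.which("mafft") is not None


def mafft_align(seqs: Mapping[str, str]) -> dict[str, str]:
    """Joint multiple alignment via the mafft command-line tool."""
    if not mafft_available():
        raise RuntimeError("mafft not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "in.fasta"
        with open(fasta, "w") as fh:
            for name, seq in seqs.items():
                fh.write(f">{name}\n{seq}\n")
        out = subprocess.run(
            ["mafft", "--auto", "--quiet", str(fasta)],
            capture_output=True, text=True, check=True,
        ).stdout
    from io import StringIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(StringIO(out), "fasta")}


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")
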