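"""Genome sequence access and sequence-derived features (GC content).

Sequences are held in memory (the genomes used here are small synthetic ones
or subsets); :func:`load_fasta` reads standard FASTA via Biopython.
"""

from __future__ import annotations

import math

from Bio import SeqIO

from .events import ValidationError

_VALID = set("ACGTNacgtn")


class InMemoryGenome:
    """Chromosome name -> sequence string, with BED-style ``fetch``."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences = dict(sequences)

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.sequences:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        seq = self.sequences[chrom]
        if start < 0 or end > len(seq) or start >= end:
            raise ValidationError(
                f"fetch {chrom}:{start}-{end} outside chromosome of length {len(seq)}"
            )
        return seq[start:end]


def load_fasta(path) -> InMemoryGenome:
    return InMemoryGenome({rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")})


def write_fasta(genome: InMemoryGenome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def gc_content(sequence: str) -> float:
    """Fraction (G+C)/(A+C+G+T), case-insensitive; N bases are excluded.

    Returns NaN for an all-N (or empty) sequence. Any other character is an
    error.
    """
    if not set(sequence) <= _VALID:
        bad = sorted(set(sequence) - _VALID)
        raise ValidationError(f"illegal characters in sequence: {bad}")
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        return math.nan
    return gc / (gc + at)
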