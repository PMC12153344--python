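"""Minimal genome sequence container and FASTA round-trip helpers."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

VALID_BASES = frozenset("ACGT")


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A named DNA sequence over the {A,C,G,T} alphabet (forward strand)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(f"genome contains non-ACGT characters: {sorted(bad)!r}")

    def __len__(self) -> int:
        return len(self.seq)

    def base(self, pos: int) -> str:
        """Base at 1-based position ``pos`` on the forward strand."""
        if not 1 <= pos <= len(self.seq):
            raise IndexError(f"position {pos} outside 1..{len(self.seq)}")
        return self.seq[pos - 1]


def as_sequence(genome: "GenomeSequence | str") -> str:
    return genome.seq if isinstance(genome, GenomeSequence) else genome


def read_fasta(path: str | Path) -> GenomeSequence:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if len(records) > 1:
        raise ValueError(f"expected a single-sequence FASTA, got {len(records)} records")
    rec = records[0]
    return GenomeSequence(id=rec.id, seq=str(rec.seq).upper())


def write_fasta(genome: GenomeSequence, path: str | Path) -> None:
    rec = SeqRecord(Seq(genome.seq), id=genome.id, description="")
    SeqIO.write([rec], str(path), "fasta")
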