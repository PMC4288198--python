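"""RNA sequence container and FASTA I/O.

All sequences are normalized to RNA semantics on input: upper-case, T mapped
to U, any other character rejected with its position. Coordinates throughout
the package are 0-based half-open; presentation layers (BED, report TSVs)
convert at the edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")
_COMPLEMENT = str.maketrans("ACGU", "UGCA")


class SequenceAlphabetError(ValueError):
    """Raised when a residue outside {A,C,G,U,T} (case-insensitive) is seen."""

    def __init__(self, seq_id: str, position: int, char: str):
        self.seq_id = seq_id
        self.position = position
        self.char = char
        super().__init__(
            f"sequence {seq_id!r}: invalid residue {char!r} at position {position} "
            "(0-based); expected A/C/G/U (T accepted and mapped to U)"
        )


def normalize_residues(raw: str, seq_id: str = "<anon>") -> str:
    """Upper-case, map T->U and validate against the RNA alphabet."""
    residues = raw.upper().replace("T", "U")
    for i, ch in enumerate(residues):
        if ch not in RNA_ALPHABET:
            raise SequenceAlphabetError(seq_id, i, raw[i])
    return residues


def complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)


def reverse_complement(residues: str) -> str:
    """Reverse complement of an RNA string (5'->3' in, 5'->3' out)."""
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NucleotideSequence:
    """An identified RNA sequence over {A,C,G,U}.

    Construct through :meth:`from_raw` when the input may contain DNA
    characters or lower case.
    """

    id: str
    residues: str

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r}: empty sequences are not allowed")
        for i, ch in enumerate(self.residues):
            if ch not in RNA_ALPHABET:
                raise SequenceAlphabetError(self.id, i, ch)

    @classmethod
    def from_raw(cls, seq_id: str, raw: str) -> "NucleotideSequence":
        return cls(seq_id, normalize_residues(raw, seq_id))

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, key) -> str:
        return self.residues[key]

    def segment(self, start: int, end: int) -> str:
        """Residues of the half-open interval [start, end)."""
        if not (0 <= start <= end <= len(self.residues)):
            raise IndexError(
                f"span [{start}, {end}) outside sequence {self.id!r} of length {len(self)}"
            )
        return self.residues[start:end]

    def reverse_complement(self) -> "NucleotideSequence":
        return NucleotideSequence(f"{self.id}|rc", reverse_complement(self.residues))


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a (multi-)FASTA file, accepting DNA and mapping to RNA."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(NucleotideSequence.from_raw(rec.id, str(rec.seq)))
    return records


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | Path) -> None:
    """Write sequences as 60-column wrapped FASTA, emitting U for RNA."""
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)
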