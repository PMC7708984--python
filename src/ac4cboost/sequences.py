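"""Reading, validation and normalization of candidate mRNA windows.

Benchmark windows for ac4C site prediction are 415-nt sequences whose
center carries five consecutive CXX motifs (C followed by any two
nucleotides), the middle C being the candidate acetylated cytidine.
Sequences are handled on the DNA alphabet {A, C, G, T}; RNA input (U)
is accepted and mapped to T.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGT")

_VALID_INPUT = frozenset("ACGTUacgtu")


class SequenceValidationError(ValueError):
    """Raised when an input sequence violates the alphabet or structure rules."""


@dataclass(frozen=True)
class RnaSequence:
    """A validated, normalized candidate window.

    Attributes
    ----------
    id : str
        Record identifier (FASTA header token).
    residues : str
        Normalized residues over {A, C, G, T}.
    """

    id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.residues)


def normalize_sequence(raw: str, id: str) -> RnaSequence:
    """Uppercase, map U->T and validate the alphabet.

    Ambiguity codes (N, R, Y, ...) are rejected: the downstream encoders
    have no defined value for them.  Error messages report 1-based
    positions.
    """
    if not raw:
        raise SequenceValidationError(f"sequence '{id}': empty sequence")
    for pos, ch in enumerate(raw, start=1):
        if ch not in _VALID_INPUT:
            raise SequenceValidationError(
                f"sequence '{id}': invalid character {ch!r} at position {pos} "
                f"(allowed: A, C, G, T, U, case-insensitive)"
            )
    residues = raw.upper().replace("U", "T")
    return RnaSequence(id=id, residues=residues)


def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read a FASTA file into a list of normalized sequences.

    Multi-line records are concatenated; every record passes through
    :func:`normalize_sequence`, so ambiguity codes raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    out: list[RnaSequence] = []
    with path.open() as handle:
        first = handle.read(1)
        if first and first not in (">", ";"):
            raise ValueError(f"{path}: sequence data before first FASTA header")
        handle.seek(0)
        for record in SeqIO.parse(handle, "fasta"):
            out.append(normalize_sequence(str(record.seq), record.id))
    return out


def write_fasta(seqs: Iterable[RnaSequence], path: str | Path) -> Path:
    """Write normalized sequences as FASTA with 60-column line wrapping."""
    path = Path(path)
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    with path.open("w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(records)
    return path


def central_c_positions(length: int) -> list[int]:
    """1-based positions required to be C by the central five-CXX block.

    For odd length L the central position is c = (L+1)/2; the five CXX
    motifs span c-6 .. c+8 with required Cs at {c-6, c-3, c, c+3, c+6},
    placing a C (the candidate acetylated cytidine) at the exact center.
    """
    if length < 15:
        raise SequenceValidationError(
            f"sequence length {length} < 15: central CXX block does not fit"
        )
    c = (length + 1) // 2
    return [c - 6, c - 3, c, c + 3, c + 6]


def has_central_cxx_block(seq: RnaSequence) -> bool:
    """True iff the five consecutive central CXX motifs are present.

    Checks that positions c-6, c-3, c, c+3, c+6 (1-based, c = (L+1)/2;
    208 for the benchmark length 415) all hold C.
    """
    positions = central_c_positions(seq.length)
    return all(seq.residues[p - 1] == "C" for p in positions)


def check_motifs(
    seqs: Iterable[RnaSequence], strict: bool = False
) -> list[RnaSequence]:
    """Warn (or raise, if strict) about sequences lacking the central motif.

    The motif constraint describes how the benchmark was constructed; at
    prediction time it is advisory by default.
    """
    bad = [s.id for s in seqs if not has_central_cxx_block(s)]
    if bad:
        msg = (
            f"{len(bad)} sequence(s) lack the central five-CXX block "
            f"(first: {bad[0]})"
        )
        if strict:
            raise SequenceValidationError(msg)
        warnings.warn(msg, stacklevel=2)
    return list(seqs)
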