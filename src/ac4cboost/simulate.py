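"""Seeded synthetic benchmark generator.

Emulates the structure of the ac4C benchmark so every pipeline stage is
testable without external downloads: 415-nt windows carrying five
consecutive central CXX motifs, a 1:9 positive:negative imbalance, and
positives enriched in the GC-rich trinucleotides GGG, CGG, GGC and CCC.

Enrichment is implemented as a position-independent composition tilt:
G and C are drawn with probability q = w^(1/3)/4 each in positives
(w = ``enrichment_weight``), so under independent sampling each of the
four target trinucleotides is elevated by a factor of exactly w relative
to the uniform negatives, and the signal is distributed across the whole
window rather than pasted in as motifs — matching how a global
composition feature (PseEIIP) separates the real classes.  With w = 1
positives and negatives are drawn from the same distribution (the null
control).  No claim of distributional fidelity to the real benchmark's
negative-sampling procedure is made.

All randomness flows through numpy's seeded PCG64 generator, so output
is byte-identical across runs and platforms for a given spec.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .sequences import RnaSequence, central_c_positions, write_fasta

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic benchmark draw.

    Defaults are the standard small benchmark used throughout the test
    suite: 120 positives, 1080 negatives (the 1:9 imbalance), 415-nt
    windows, 4-fold trinucleotide enrichment, seed 42.
    """

    n_pos: int = 120
    n_neg: int = 1080
    length: int = 415
    enrichment_weight: float = 4.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.length % 2 == 0 or self.length < 15:
            raise ValueError(
                f"length must be odd and >= 15 to fit the central CXX block; "
                f"got {self.length}"
            )
        if self.enrichment_weight < 1:
            raise ValueError("enrichment_weight must be >= 1")
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("sample counts must be non-negative")


def _base_probabilities(enrichment_weight: float) -> np.ndarray:
    """Per-nucleotide probabilities (A, C, G, T) of the positive class."""
    q = min(enrichment_weight ** (1 / 3) / 4.0, 0.45)
    p_at = (1.0 - 2.0 * q) / 2.0
    return np.array([p_at, q, q, p_at])


def _draw(
    rng: np.random.Generator,
    n: int,
    length: int,
    probs: np.ndarray,
    prefix: str,
) -> list[RnaSequence]:
    forced = np.array(central_c_positions(length)) - 1
    chars = _BASES[rng.choice(4, size=(n, length), p=probs)]
    chars[:, forced] = "C"
    return [
        RnaSequence(id=f"{prefix}{i + 1}", residues="".join(row))
        for i, row in enumerate(chars)
    ]


def generate_dataset(
    spec: SyntheticSpec | None = None,
) -> tuple[list[RnaSequence], np.ndarray]:
    """Draw a labeled synthetic benchmark; positives first, then negatives.

    Every sequence carries the central five-CXX block by construction.
    Deterministic for a given spec (single seeded generator).
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    uniform = np.full(4, 0.25)
    positives = _draw(
        rng, spec.n_pos, spec.length, _base_probabilities(spec.enrichment_weight),
        "pos_",
    )
    negatives = _draw(rng, spec.n_neg, spec.length, uniform, "neg_")
    labels = np.concatenate(
        [np.ones(spec.n_pos, dtype=int), np.zeros(spec.n_neg, dtype=int)]
    )
    return positives + negatives, labels


def write_fixture(
    seqs: Sequence[RnaSequence],
    labels: Sequence[int],
    directory: str | Path,
) -> dict[str, Path]:
    """Write pos.fa / neg.fa / labels.tsv consumable by the CLI verbatim."""
    labels = np.asarray(labels)
    if len(seqs) != labels.shape[0]:
        raise ValueError(f"{len(seqs)} sequences vs {labels.shape[0]} labels")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pos = [s for s, y in zip(seqs, labels) if y == 1]
    neg = [s for s, y in zip(seqs, labels) if y == 0]
    paths = {
        "pos": write_fasta(pos, directory / "pos.fa"),
        "neg": write_fasta(neg, directory / "neg.fa"),
        "labels": directory / "labels.tsv",
    }
    with paths["labels"].open("w") as handle:
        handle.write("id\tlabel\n")
        for s, y in zip(seqs, labels):
            handle.write(f"{s.id}\t{int(y)}\n")
    return paths
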