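"""Sequence feature encodings for ac4C site classification.

Five representations and their concatenations:

* one-hot: per position, A=(1,0,0,0), T=(0,1,0,0), G=(0,0,1,0),
  C=(0,0,0,1) (channel order A, T, G, C);
* NCP (nucleotide chemical property): per position a 3-bit triple
  (ring structure, amino/keto group, hydrogen-bond strength) —
  x=1 iff A/C (single amino group side), y=1 iff A/G (purine),
  z=1 iff A/T (weak pairing): A=(1,1,1), C=(1,0,0), G=(0,1,0),
  T=(0,0,1);
* ND (nucleotide density): d_i = (occurrences of nucleotide n_i within
  positions 1..i) / i — a cumulative prefix frequency carrying both
  composition and positional information;
* k-mer composition for k = 1, 2, 3: normalized overlapping-window
  frequencies, 4 + 16 + 64 = 84 features;
* EIIP: per-position electron-ion interaction pseudopotential
  (A 0.1260, C 0.1340, G 0.0806, T 0.1335);
* PseEIIP: per trinucleotide xyz, (EIIP_x + EIIP_y + EIIP_z) * f_xyz
  with f the normalized trinucleotide frequency — 64 features.

For the 415-nt benchmark windows the dimensions are one-hot 1660,
NCP 1245, NCP+ND 1660, k-mer 84, EIIP+PseEIIP 415 + 64 = 479.
"""

from __future__ import annotations

from enum import Enum
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .sequences import RnaSequence

#: electron-ion interaction pseudopotential of each nucleotide
EIIP = {"A": 0.1260, "C": 0.1340, "G": 0.0806, "T": 0.1335}

#: channel order of the one-hot encoding
ONEHOT_ORDER = "ATGC"

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


class EncodingScheme(str, Enum):
    """Feature representation schemes and their closed-form dimensions."""

    ONEHOT = "onehot"
    NCP = "ncp"
    ND = "nd"
    NCP_ND = "ncp_nd"
    KMER = "kmer"
    EIIP = "eiip"
    PSEEIIP = "pseeiip"
    EIIP_PSEEIIP = "eiip_pseeiip"

    @property
    def length_free(self) -> bool:
        """Whether the dimension is independent of sequence length."""
        return self in (EncodingScheme.KMER, EncodingScheme.PSEEIIP)

    def dimension(self, L: int) -> int:
        """Feature-vector length for a sequence of length ``L``."""
        return {
            EncodingScheme.ONEHOT: 4 * L,
            EncodingScheme.NCP: 3 * L,
            EncodingScheme.ND: L,
            EncodingScheme.NCP_ND: 4 * L,
            EncodingScheme.KMER: 84,
            EncodingScheme.EIIP: L,
            EncodingScheme.PSEEIIP: 64,
            EncodingScheme.EIIP_PSEEIIP: L + 64,
        }[self]


def _codes(seq: RnaSequence) -> np.ndarray:
    return np.frombuffer(seq.residues.encode(), dtype=np.uint8)


def encode_onehot(seq: RnaSequence) -> np.ndarray:
    """One-hot encode, channel order (A, T, G, C), 4L values."""
    order = np.frombuffer(ONEHOT_ORDER.encode(), dtype=np.uint8)
    return (_codes(seq)[:, None] == order[None, :]).astype(float).ravel()


def encode_ncp(seq: RnaSequence) -> np.ndarray:
    """Nucleotide chemical property triples (x, y, z), 3L values."""
    codes = _codes(seq)
    x = np.isin(codes, np.frombuffer(b"AC", dtype=np.uint8))
    y = np.isin(codes, np.frombuffer(b"AG", dtype=np.uint8))
    z = np.isin(codes, np.frombuffer(b"AT", dtype=np.uint8))
    return np.stack([x, y, z], axis=1).astype(float).ravel()


def encode_nd(seq: RnaSequence) -> np.ndarray:
    """Nucleotide density: prefix frequency of the resident nucleotide."""
    codes = _codes(seq)
    L = len(codes)
    out = np.empty(L)
    counts = {b: 0 for b in _BASES}
    for i, ch in enumerate(seq.residues):
        counts[ch] += 1
        out[i] = counts[ch] / (i + 1)
    return out


def encode_ncp_nd(seq: RnaSequence) -> np.ndarray:
    """NCP followed by ND, 3L + L = 4L values."""
    return np.concatenate([encode_ncp(seq), encode_nd(seq)])


def _kmer_frequencies(seq: RnaSequence, k: int) -> np.ndarray:
    """Normalized frequencies of the 4**k k-mers over overlapping windows."""
    if seq.length < k:
        raise ValueError(f"sequence length {seq.length} < k = {k}")
    idx = np.array([_BASE_INDEX[b] for b in seq.residues])
    n_windows = seq.length - k + 1
    # base-4 positional code of each window
    window_codes = np.zeros(n_windows, dtype=np.int64)
    for j in range(k):
        window_codes = window_codes * 4 + idx[j : j + n_windows]
    counts = np.bincount(window_codes, minlength=4**k)
    return counts / n_windows


def encode_kmer(seq: RnaSequence) -> np.ndarray:
    """k-mer composition for k = 1, 2, 3; 84 values, lexicographic per block."""
    if seq.length < 3:
        raise ValueError("k-mer encoding requires length >= 3")
    return np.concatenate([_kmer_frequencies(seq, k) for k in (1, 2, 3)])


def encode_eiip(seq: RnaSequence) -> np.ndarray:
    """Per-position EIIP values, L values."""
    table = np.zeros(256)
    for base, value in EIIP.items():
        table[ord(base)] = value
    return table[_codes(seq)]


def encode_pseeiip(seq: RnaSequence) -> np.ndarray:
    """Trinucleotide pseudo-EIIP: (EIIP_x+EIIP_y+EIIP_z) * f_xyz, 64 values."""
    if seq.length < 3:
        raise ValueError("PseEIIP encoding requires length >= 3")
    freqs = _kmer_frequencies(seq, 3)
    weights = np.array(
        [EIIP[x] + EIIP[y] + EIIP[z] for x, y, z in product(_BASES, repeat=3)]
    )
    return weights * freqs


def encode_eiip_pseeiip(seq: RnaSequence) -> np.ndarray:
    """EIIP followed by PseEIIP, L + 64 values."""
    return np.concatenate([encode_eiip(seq), encode_pseeiip(seq)])


_ENCODERS: dict[EncodingScheme, Callable[[RnaSequence], np.ndarray]] = {
    EncodingScheme.ONEHOT: encode_onehot,
    EncodingScheme.NCP: encode_ncp,
    EncodingScheme.ND: encode_nd,
    EncodingScheme.NCP_ND: encode_ncp_nd,
    EncodingScheme.KMER: encode_kmer,
    EncodingScheme.EIIP: encode_eiip,
    EncodingScheme.PSEEIIP: encode_pseeiip,
    EncodingScheme.EIIP_PSEEIIP: encode_eiip_pseeiip,
}


def encode_sequence(seq: RnaSequence, scheme: EncodingScheme) -> np.ndarray:
    """Encode one sequence under the named scheme."""
    return _ENCODERS[EncodingScheme(scheme)](seq)


def feature_names(scheme: EncodingScheme, L: int) -> list[str]:
    """Deterministic human-readable feature names for a scheme.

    Position features are named ``N{i}`` (1-based) with a channel suffix
    where a position yields several values (``N12_A`` for one-hot,
    ``N12_x`` for NCP, ``N12_d`` for ND); k-mer features carry their
    k-mer string; PseEIIP features are ``EIIP_AAA`` .. ``EIIP_TTT``.
    """
    scheme = EncodingScheme(scheme)
    positions = range(1, L + 1)
    if scheme is EncodingScheme.ONEHOT:
        return [f"N{i}_{c}" for i in positions for c in ONEHOT_ORDER]
    if scheme is EncodingScheme.NCP:
        return [f"N{i}_{c}" for i in positions for c in "xyz"]
    if scheme is EncodingScheme.ND:
        return [f"N{i}_d" for i in positions]
    if scheme is EncodingScheme.NCP_ND:
        return feature_names(EncodingScheme.NCP, L) + feature_names(
            EncodingScheme.ND, L
        )
    if scheme is EncodingScheme.KMER:
        return [
            "".join(kmer)
            for k in (1, 2, 3)
            for kmer in product(_BASES, repeat=k)
        ]
    if scheme is EncodingScheme.EIIP:
        return [f"N{i}" for i in positions]
    if scheme is EncodingScheme.PSEEIIP:
        return ["EIIP_" + "".join(t) for t in product(_BASES, repeat=3)]
    if scheme is EncodingScheme.EIIP_PSEEIIP:
        return feature_names(EncodingScheme.EIIP, L) + feature_names(
            EncodingScheme.PSEEIIP, L
        )
    raise ValueError(f"unknown scheme {scheme!r}")  # pragma: no cover


@dataclass
class FeatureMatrix:
    """Named feature columns for a sequence set under one encoding scheme."""

    scheme: EncodingScheme
    feature_names: list[str]
    values: np.ndarray
    sequence_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError(
                f"{self.values.shape[1]} columns vs "
                f"{len(self.feature_names)} feature names"
            )
        if self.sequence_ids and len(self.sequence_ids) != self.values.shape[0]:
            raise ValueError("sequence_ids length must match row count")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_sequences(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        index = self.sequence_ids or None
        return pd.DataFrame(self.values, columns=self.feature_names, index=index)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        frame = self.to_frame()
        frame.index.name = "id"
        frame.to_csv(path)
        return path

    @classmethod
    def from_csv(cls, path: str | Path, scheme: EncodingScheme) -> "FeatureMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(
            scheme=EncodingScheme(scheme),
            feature_names=list(frame.columns),
            values=frame.to_numpy(dtype=float),
            sequence_ids=[str(i) for i in frame.index],
        )


def encode_dataset(
    seqs: Sequence[RnaSequence] | Iterable[RnaSequence],
    scheme: EncodingScheme,
    length: int | None = None,
) -> FeatureMatrix:
    """Encode a sequence set into one feature matrix, preserving order.

    Position-wise schemes require all sequences to share one length;
    KMER and PSEEIIP are length-free.  ``length`` fixes the column count
    when ``seqs`` is empty (default: the 415-nt benchmark window).
    """
    scheme = EncodingScheme(scheme)
    seqs = list(seqs)
    if seqs:
        lengths = {s.length for s in seqs}
        if not scheme.length_free and len(lengths) > 1:
            raise ValueError(
                f"scheme {scheme.value} requires equal-length sequences; "
                f"got lengths {sorted(lengths)}"
            )
        L = seqs[0].length
        values = np.stack([encode_sequence(s, scheme) for s in seqs])
    else:
        L = length if length is not None else 415
        values = np.empty((0, scheme.dimension(L)))
    return FeatureMatrix(
        scheme=scheme,
        feature_names=feature_names(scheme, L),
        values=values,
        sequence_ids=[s.id for s in seqs],
    )
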