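"""Encoder correctness: printed single-base codes, closed-form dimensions,
and agreement with independent brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ac4cboost import (
    EIIP,
    EncodingScheme,
    FeatureMatrix,
    RnaSequence,
    encode_dataset,
    encode_sequence,
    feature_names,
)
from ac4cboost.encoders import (
    encode_eiip,
    encode_eiip_pseeiip,
    encode_kmer,
    encode_ncp,
    encode_ncp_nd,
    encode_nd,
    encode_onehot,
    encode_pseeiip,
)

BASES = "ACGT"


def seq(residues: str) -> RnaSequence:
    return RnaSequence("s", residues)


# ---------------------------------------------------------------- oracles


def oracle_onehot(residues):
    table = {"A": (1, 0, 0, 0), "T": (0, 1, 0, 0), "G": (0, 0, 1, 0),
             "C": (0, 0, 0, 1)}
    return [v for ch in residues for v in table[ch]]


def oracle_ncp(residues):
    out = []
    for ch in residues:
        out += [int(ch in "AC"), int(ch in "AG"), int(ch in "AT")]
    return out


def oracle_nd(residues):
    return [
        residues[: i + 1].count(ch) / (i + 1)
        for i, ch in enumerate(residues)
    ]


def oracle_kmer(residues):
    out = []
    for k in (1, 2, 3):
        windows = [residues[i : i + k] for i in range(len(residues) - k + 1)]
        for kmer in ("".join(t) for t in itertools.product(BASES, repeat=k)):
            out.append(windows.count(kmer) / len(windows))
    return out


def oracle_eiip(residues):
    return [EIIP[ch] for ch in residues]


def oracle_pseeiip(residues):
    windows = [residues[i : i + 3] for i in range(len(residues) - 2)]
    out = []
    for t in itertools.product(BASES, repeat=3):
        tri = "".join(t)
        f = windows.count(tri) / len(windows)
        out.append((EIIP[t[0]] + EIIP[t[1]] + EIIP[t[2]]) * f)
    return out


ORACLES = {
    EncodingScheme.ONEHOT: oracle_onehot,
    EncodingScheme.NCP: oracle_ncp,
    EncodingScheme.ND: oracle_nd,
    EncodingScheme.NCP_ND: lambda r: oracle_ncp(r) + oracle_nd(r),
    EncodingScheme.KMER: oracle_kmer,
    EncodingScheme.EIIP: oracle_eiip,
    EncodingScheme.PSEEIIP: oracle_pseeiip,
    EncodingScheme.EIIP_PSEEIIP: lambda r: oracle_eiip(r) + oracle_pseeiip(r),
}


# ---------------------------------------------------------- printed codes


class TestSingleBaseCodes:
    @pytest.mark.parametrize(
        "base, code",
        [("A", (1, 0, 0, 0)), ("T", (0, 1, 0, 0)), ("G", (0, 0, 1, 0)),
         ("C", (0, 0, 0, 1))],
    )
    def test_onehot_channel_order(self, base, code):
        assert tuple(encode_onehot(seq(base))) == code

    @pytest.mark.parametrize(
        "base, triple",
        [("A", (1, 1, 1)), ("C", (1, 0, 0)), ("G", (0, 1, 0)),
         ("T", (0, 0, 1))],
    )
    def test_ncp_triples(self, base, triple):
        assert tuple(encode_ncp(seq(base))) == triple

    def test_ncp_injective_per_position(self):
        triples = {tuple(encode_ncp(seq(b))) for b in BASES}
        assert len(triples) == 4

    def test_eiip_constants(self):
        assert EIIP == {"A": 0.1260, "C": 0.1340, "G": 0.0806, "T": 0.1335}
        np.testing.assert_array_equal(
            encode_eiip(seq("ACGT")), [0.1260, 0.1340, 0.0806, 0.1335]
        )

    def test_eiip_homopolymer(self):
        np.testing.assert_array_equal(encode_eiip(seq("GGG")), [0.0806] * 3)


class TestWorkedExamples:
    def test_nd_prefix_densities(self):
        np.testing.assert_allclose(
            encode_nd(seq("ACGTA")), [1.0, 0.5, 1 / 3, 0.25, 0.4]
        )
        np.testing.assert_array_equal(encode_nd(seq("AAAA")), [1.0] * 4)

    def test_ncp_nd_single_base(self):
        np.testing.assert_array_equal(encode_ncp_nd(seq("A")), [1, 1, 1, 1.0])

    def test_kmer_acgt(self):
        vec = encode_kmer(seq("ACGT"))
        names = feature_names(EncodingScheme.KMER, 4)
        got = dict(zip(names, vec))
        assert got["A"] == got["C"] == got["G"] == got["T"] == 0.25
        assert got["AC"] == got["CG"] == got["GT"] == pytest.approx(1 / 3)
        assert got["AA"] == 0
        assert got["ACG"] == got["CGT"] == 0.5
        assert sum(v for k, v in got.items() if len(k) == 3) == pytest.approx(1)

    def test_kmer_homopolymer(self):
        vec = dict(zip(feature_names(EncodingScheme.KMER, 8),
                       encode_kmer(seq("A" * 8))))
        assert vec["A"] == vec["AA"] == vec["AAA"] == 1.0
        assert sum(vec.values()) == 3.0

    def test_pseeiip_poly_a(self):
        vec = encode_pseeiip(seq("A" * 10))
        assert vec[0] == pytest.approx(0.3780)
        assert np.count_nonzero(vec) == 1

    def test_pseeiip_acg(self):
        names = feature_names(EncodingScheme.PSEEIIP, 3)
        got = dict(zip(names, encode_pseeiip(seq("ACG"))))
        assert got["EIIP_ACG"] == pytest.approx(0.1260 + 0.1340 + 0.0806)
        assert sum(v != 0 for v in got.values()) == 1

    def test_eiip_pseeiip_poly_a_415(self):
        vec = encode_eiip_pseeiip(seq("A" * 415))
        assert vec.shape == (479,)
        np.testing.assert_array_equal(vec[:415], [0.1260] * 415)
        assert vec[415] == pytest.approx(0.3780)
        assert np.count_nonzero(vec[416:]) == 0


# ------------------------------------------------------- dimension laws


EXPECTED_DIM = {
    EncodingScheme.ONEHOT: lambda L: 4 * L,
    EncodingScheme.NCP: lambda L: 3 * L,
    EncodingScheme.ND: lambda L: L,
    EncodingScheme.NCP_ND: lambda L: 4 * L,
    EncodingScheme.KMER: lambda L: 84,
    EncodingScheme.EIIP: lambda L: L,
    EncodingScheme.PSEEIIP: lambda L: 64,
    EncodingScheme.EIIP_PSEEIIP: lambda L: L + 64,
}


@pytest.mark.parametrize("scheme", list(EncodingScheme))
@given(L=st.integers(min_value=3, max_value=500), data=st.data())
@settings(max_examples=25, deadline=None)
def test_dimension_law(scheme, L, data):
    residues = data.draw(st.text(alphabet=BASES, min_size=L, max_size=L))
    vec = encode_sequence(seq(residues), scheme)
    assert vec.shape == (EXPECTED_DIM[scheme](L),)
    assert vec.shape == (scheme.dimension(L),)
    assert len(feature_names(scheme, L)) == vec.shape[0]


@pytest.mark.parametrize("scheme", list(EncodingScheme))
def test_benchmark_window_dimensions(scheme):
    vec = encode_sequence(seq("ACGT" * 103 + "ACG"), scheme)  # 415 nt
    assert vec.shape == (scheme.dimension(415),)


# ------------------------------------------------------ oracle agreement


@pytest.mark.parametrize("scheme", list(EncodingScheme))
def test_agrees_with_brute_force_oracle(scheme):
    """200 random sequences of length 3-60 vs the naive implementation."""
    rng = np.random.default_rng(2024)
    for _ in range(200):
        L = int(rng.integers(3, 61))
        residues = "".join(rng.choice(list(BASES), size=L))
        np.testing.assert_allclose(
            encode_sequence(seq(residues), scheme),
            ORACLES[scheme](residues),
            atol=1e-12,
        )


# ----------------------------------------------------------- invariants


@given(st.text(alphabet=BASES, min_size=3, max_size=80))
@settings(max_examples=60, deadline=None)
def test_kmer_blocks_sum_to_one(residues):
    vec = encode_kmer(seq(residues))
    for block in (vec[:4], vec[4:20], vec[20:]):
        assert abs(block.sum() - 1.0) < 1e-12


@given(st.text(alphabet=BASES, min_size=3, max_size=80))
@settings(max_examples=60, deadline=None)
def test_pseeiip_nonneg_support_and_bound(residues):
    vec = encode_pseeiip(seq(residues))
    windows = {residues[i : i + 3] for i in range(len(residues) - 2)}
    names = feature_names(EncodingScheme.PSEEIIP, len(residues))
    assert np.all(vec >= 0)
    for name, value in zip(names, vec):
        assert (value > 0) == (name.removeprefix("EIIP_") in windows)
    assert vec.sum() <= 3 * max(EIIP.values()) + 1e-12  # weighted-mean bound


@given(st.text(alphabet=BASES, min_size=1, max_size=80))
@settings(max_examples=60, deadline=None)
def test_nd_times_position_is_integer_count(residues):
    vec = encode_nd(seq(residues))
    counts = vec * np.arange(1, len(residues) + 1)
    np.testing.assert_allclose(counts, np.round(counts), atol=1e-9)


@pytest.mark.parametrize("scheme", list(EncodingScheme))
def test_encoders_are_pure(scheme):
    s = seq("ACGTGGCCAGT")
    np.testing.assert_array_equal(
        encode_sequence(s, scheme), encode_sequence(s, scheme)
    )


# ----------------------------------------------------- dataset encoding


class TestEncodeDataset:
    def test_shape_and_order(self):
        seqs = [RnaSequence(f"s{i}", "ACGT" * 103 + "ACG") for i in range(10)]
        X = encode_dataset(seqs, EncodingScheme.EIIP_PSEEIIP)
        assert X.values.shape == (10, 479)
        assert X.sequence_ids == [f"s{i}" for i in range(10)]

    def test_empty_list_keeps_column_count(self):
        X = encode_dataset([], EncodingScheme.EIIP_PSEEIIP)
        assert X.values.shape == (0, 479)
        assert len(X.feature_names) == 479

    def test_mixed_lengths_positionwise_raises(self):
        seqs = [seq("ACGTACG"), RnaSequence("t", "ACGTA")]
        with pytest.raises(ValueError, match="equal-length"):
            encode_dataset(seqs, EncodingScheme.EIIP)

    def test_mixed_lengths_ok_for_length_free(self):
        seqs = [seq("ACGTACG"), RnaSequence("t", "ACGTA")]
        X = encode_dataset(seqs, EncodingScheme.KMER)
        assert X.values.shape == (2, 84)

    def test_csv_round_trip(self, tmp_path):
        seqs = [RnaSequence(f"s{i}", "ACGTGGC") for i in range(3)]
        X = encode_dataset(seqs, EncodingScheme.KMER)
        path = X.to_csv(tmp_path / "m.csv")
        back = FeatureMatrix.from_csv(path, EncodingScheme.KMER)
        np.testing.assert_allclose(back.values, X.values)
        assert back.feature_names == X.feature_names
        assert back.sequence_ids == X.sequence_ids

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            FeatureMatrix(EncodingScheme.EIIP, ["N1"], np.array([[np.inf]]))


class TestFeatureNames:
    def test_eiip_positions(self):
        names = feature_names(EncodingScheme.EIIP, 415)
        assert names[0] == "N1" and names[-1] == "N415"
        assert "N198" in names and "N216" in names

    def test_pseeiip_lexicographic(self):
        names = feature_names(EncodingScheme.PSEEIIP, 10)
        assert names[0] == "EIIP_AAA" and names[-1] == "EIIP_TTT"
        assert len(names) == 64 == len(set(names))

    def test_kmer_block_sizes(self):
        names = feature_names(EncodingScheme.KMER, 10)
        assert len(names) == 84
        assert [len(n) for n in names] == [1] * 4 + [2] * 16 + [3] * 64

    def test_onehot_and_ncp_channel_suffixes(self):
        assert feature_names(EncodingScheme.ONEHOT, 2)[:4] == [
            "N1_A", "N1_T", "N1_G", "N1_C"
        ]
        assert feature_names(EncodingScheme.NCP, 1) == ["N1_x", "N1_y", "N1_z"]
        nd_names = feature_names(EncodingScheme.NCP_ND, 2)
        assert nd_names[-1] == "N2_d" and len(nd_names) == 8
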