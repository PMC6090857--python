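from collections import Counter
from itertools import product

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from m6apred import FeatureLayout, SnpTable, assemble, feature_matrix
from m6apred.features import (
    density,
    encode_binary,
    encode_cpd,
    entropy_features,
    kmer_frequencies,
    location_features,
    snp_state_vector,
)
from m6apred.io import RunConfig, SampleTable

windows = st.text(alphabet="ACGU", min_size=1, max_size=60)


def make_window(rng, flank=25):
    w = "".join(rng.choice(list("ACGU"), size=2 * flank + 1))
    return w[:flank] + "A" + w[flank + 1:]


class TestBinaryAndCpd:
    @pytest.mark.parametrize("ch,code", [
        ("A", (1, 0, 0, 0)), ("C", (0, 1, 0, 0)),
        ("G", (0, 0, 1, 0)), ("U", (0, 0, 0, 1)), ("N", (0, 0, 0, 0))])
    def test_binary_codes(self, ch, code):
        assert tuple(encode_binary(ch)) == code

    @pytest.mark.parametrize("ch,code", [
        ("A", (1, 1, 1)), ("C", (0, 0, 1)),
        ("G", (1, 0, 0)), ("U", (0, 1, 0)), ("N", (0, 0, 0))])
    def test_cpd_codes(self, ch, code):
        assert tuple(encode_cpd(ch)) == code

    def test_block_lengths_on_51nt_window(self, rng):
        w = make_window(rng)
        assert encode_binary(w).shape == (204,)
        assert encode_cpd(w).shape == (153,)

    def test_all_padding_encodes_to_zero(self):
        assert not encode_binary("NNN").any()
        assert not encode_cpd("NNN").any()

    def test_illegal_character_named(self):
        with pytest.raises(ValueError, match="position 2"):
            encode_binary("ACXA")


class TestDensity:
    def test_hand_evaluated_example(self):
        assert np.allclose(density("AACG"), [1, 1, 1 / 3, 1 / 4])

    def test_homopolymer(self):
        assert np.allclose(density("AAAA"), [1, 1, 1, 1])

    def test_padding_gets_zero_and_does_not_count(self):
        # N at position 1: A at position 2 has count 1 over index 2
        assert np.allclose(density("NA"), [0, 0.5])

    @given(windows)
    def test_matches_prefix_count_oracle(self, w):
        got = density(w)
        for i, ch in enumerate(w, start=1):
            expected = w[:i].count(ch) / i
            assert got[i - 1] == pytest.approx(expected)

    @given(windows)
    def test_bounded_by_unit_interval(self, w):
        d = density(w)
        assert (d >= 0).all() and (d <= 1).all()


class TestKmer:
    def test_homopolymer_concentrates_on_one_kmer(self):
        freqs = kmer_frequencies("AAAA", 2)
        assert freqs[0] == 1.0 and freqs.sum() == 1.0

    def test_default_sizes_give_80_dimensions(self, rng):
        w = make_window(rng)
        assert len(kmer_frequencies(w, 2)) + len(kmer_frequencies(w, 3)) == 80

    def test_k_larger_than_window_rejected(self):
        with pytest.raises(ValueError):
            kmer_frequencies("ACG", 4)

    def test_n_windows_excluded_from_both_sides(self):
        # ACN GU: valid 2-windows are AC and GU only
        freqs = kmer_frequencies("ACNGU", 2)
        idx = {"".join(km): i for i, km in enumerate(product("ACGU", repeat=2))}
        assert freqs[idx["AC"]] == 0.5 and freqs[idx["GU"]] == 0.5
        assert freqs.sum() == pytest.approx(1.0)

    @given(windows, st.integers(min_value=1, max_value=3))
    def test_matches_dictionary_count_oracle(self, w, k):
        if k > len(w):
            return
        counts = Counter(w[i:i + k] for i in range(len(w) - k + 1))
        total = sum(counts.values())
        got = kmer_frequencies(w, k)
        for i, km in enumerate(product("ACGU", repeat=k)):
            assert got[i] == pytest.approx(counts["".join(km)] / total)


class TestEntropy:
    def test_uniform_window(self):
        f = entropy_features("ACGU" * 5)
        p_a, p_g, p_u, p_c, en, ren, igs = f
        assert (p_a, p_g, p_u, p_c) == (0.25, 0.25, 0.25, 0.25)
        assert en == pytest.approx(2.0)
        assert ren == pytest.approx(0.0)
        assert igs == pytest.approx(2.0)

    def test_homopolymer_window(self):
        f = entropy_features("A" * 51)
        assert f[4] == pytest.approx(0.0)       # En
        assert f[5] == pytest.approx(-2.0)      # REn
        assert f[6] == pytest.approx(2.0)       # IGS

    def test_all_padding_rejected(self):
        with pytest.raises(ValueError):
            entropy_features("NNN")

    def test_frequencies_ignore_padding(self):
        f = entropy_features("NNAA")
        assert f[0] == 1.0  # p_A over non-N characters


class TestLocation:
    def test_worked_values(self):
        assert tuple(location_features(101, 1000)) == (100, 0.1)
        assert tuple(location_features(1, 777)) == (0, 0.0)

    def test_relative_strictly_increases_with_position(self):
        rel = [location_features(p, 500)[1] for p in range(1, 501, 7)]
        assert all(b > a for a, b in zip(rel, rel[1:]))

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            location_features(0, 100)
        with pytest.raises(ValueError):
            location_features(101, 100)


class TestSnpStates:
    def test_empty_table_gives_zeros(self):
        v = snp_state_vector("tx", 100, 400, SnpTable(), 25)
        assert v.shape == (51,) and not v.any()

    def test_snp_at_site_sets_center_bit(self):
        table = SnpTable.from_pairs([("tx", 100)])
        v = snp_state_vector("tx", 100, 400, table, 25)
        assert v[25] == 1 and v.sum() == 1

    def test_matches_coordinate_arithmetic_oracle(self, rng):
        pairs = [("tx", int(p)) for p in rng.integers(1, 400, size=60)]
        table = SnpTable.from_pairs(pairs)
        for pos in (1, 26, 200, 390, 400):
            v = snp_state_vector("tx", pos, 400, table, 25)
            for j, off in enumerate(range(-25, 26)):
                coord = pos + off
                expected = 1.0 if (1 <= coord <= 400 and ("tx", coord) in table) else 0.0
                assert v[j] == expected

    def test_padded_offsets_are_zero(self):
        table = SnpTable.from_pairs([("tx", p) for p in range(1, 400)])
        v = snp_state_vector("tx", 5, 390, table, 25)
        assert not v[:21].any() and v[21:].all()


class TestAssembly:
    def test_default_dimension_is_509(self, rng):
        cfg = RunConfig()
        vec = assemble("tx", 100, 400, make_window(rng), SnpTable(),
                       tuple(range(-6, 6)), cfg)
        assert vec.shape == (509,)

    def test_disabling_snp_block_gives_497(self, rng):
        vec = assemble("tx", 100, 400, make_window(rng), None, None, RunConfig())
        assert vec.shape == (497,)

    def test_layout_offsets_against_sentinel_probe(self):
        """Each block of the assembled vector equals its encoder's output."""
        cfg = RunConfig()
        w = ("ACGU" * 13)[:51]
        w = w[:25] + "A" + w[26:]
        table = SnpTable.from_pairs([("tx", 98)])  # offset -2
        sel = (-2, -1, 2)
        vec = assemble("tx", 100, 400, w, table, sel, cfg)
        layout = FeatureLayout(snp_offsets=sel)
        off = layout.block_offsets()
        assert np.array_equal(vec[off["binary"]:off["binary"] + 204], encode_binary(w))
        assert np.array_equal(vec[off["cpd"]:off["cpd"] + 153], encode_cpd(w))
        assert np.array_equal(vec[off["density"]:off["density"] + 51], density(w))
        kmers = np.concatenate([kmer_frequencies(w, 2), kmer_frequencies(w, 3)])
        assert np.array_equal(vec[off["kmer"]:off["kmer"] + 80], kmers)
        assert np.array_equal(vec[off["entropy"]:off["entropy"] + 7],
                              entropy_features(w))
        assert np.array_equal(vec[off["location"]:off["location"] + 2],
                              location_features(100, 400))
        assert tuple(vec[off["snp"]:]) == (1.0, 0.0, 0.0)

    def test_feature_names_align_with_layout(self):
        layout = FeatureLayout(snp_offsets=(-2, -1, 2))
        names = layout.feature_names()
        assert len(names) == layout.n_features
        for block, start in layout.block_offsets().items():
            assert names[start].startswith(block + ".")

    def test_motif_constant_columns(self, tiny_corpus):
        """Binary/CPD bits at offsets 0 and +1 are constant on DRACH samples.

        The motif forces A at the site and C immediately downstream, so the
        corresponding one-hot and chemical-property columns never vary —
        the same columns that earn zero importance in a trained model.
        """
        X, names = feature_matrix(tiny_corpus.samples, tiny_corpus.snp_table,
                                  None, RunConfig())
        for name in ("binary.pos+0.A", "binary.pos+1.C", "cpd.pos+0.ring",
                     "cpd.pos+1.func"):
            col = X[:, names.index(name)]
            assert col.min() == col.max() == 1.0

    def test_identical_windows_give_identical_blocks(self, rng):
        w = make_window(rng)
        cfg = RunConfig()
        a = assemble("tx", 100, 400, w, SnpTable(), None, cfg)
        b = assemble("other", 100, 400, w, SnpTable(), None, cfg)
        assert np.array_equal(a, b)

    def test_wrong_window_length_rejected(self):
        with pytest.raises(ValueError, match="window length"):
            assemble("tx", 10, 100, "GGACU", SnpTable(), None, RunConfig())
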