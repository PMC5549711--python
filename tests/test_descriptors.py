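import numpy as np
import pytest
from hypothesis import given, strategies as st

from ppiboost.descriptors import (
    DescriptorError,
    auto_covariance,
    composition,
    distribution,
    feature_names,
    frequency_descriptor,
    pair_features,
    protein_features,
    transition,
)
from ppiboost.encoding import (
    builtin_property_tables,
    encode_qualitative,
    encode_quantitative,
)
from ppiboost.sequence_io import ALPHABET, ProteinSequence

from _oracles import (
    auto_covariance_oracle,
    composition_oracle,
    distribution_oracle,
    frequency_oracle,
    transition_oracle,
)

TABLES = builtin_property_tables()

group_seqs = st.lists(st.integers(min_value=1, max_value=3), min_size=2, max_size=80)
protein_strs = st.text(alphabet=ALPHABET, min_size=1, max_size=120)


class TestFrequency:
    def test_homopolymer(self):
        f = frequency_descriptor("AAAA")
        assert f[0] == 1.0 and f[1:].sum() == 0.0

    def test_two_residues(self):
        f = frequency_descriptor("ACAC")
        assert f[ALPHABET.index("A")] == 0.5
        assert f[ALPHABET.index("C")] == 0.5
        assert f.sum() == pytest.approx(1.0)

    @given(protein_strs)
    def test_sums_to_one_and_matches_oracle(self, s):
        f = frequency_descriptor(s)
        assert f.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(f, frequency_oracle(s, ALPHABET), atol=1e-12)


class TestComposition:
    @pytest.mark.parametrize(
        "groups, expected",
        [
            ([1, 1, 1], (1.0, 0.0, 0.0)),
            ([1, 2, 3, 1], (0.5, 0.25, 0.25)),
        ],
    )
    def test_examples(self, groups, expected):
        np.testing.assert_allclose(composition(np.array(groups)), expected)

    @given(group_seqs)
    def test_sums_to_one(self, groups):
        assert composition(np.array(groups)).sum() == pytest.approx(1.0, abs=1e-9)


class TestTransition:
    @pytest.mark.parametrize(
        "groups, expected",
        [
            ([2, 2, 2, 2], (0.0, 0.0, 0.0)),
            ([1, 2, 1, 2], (100.0, 0.0, 0.0)),
            ([1, 3, 2], (0.0, 50.0, 50.0)),
        ],
    )
    def test_examples(self, groups, expected):
        np.testing.assert_allclose(transition(np.array(groups)), expected)

    def test_too_short(self):
        with pytest.raises(DescriptorError, match="length >= 2"):
            transition(np.array([1]))


class TestDistribution:
    def test_all_one_group(self):
        d = distribution(np.array([1, 1, 1, 1]))
        np.testing.assert_allclose(d[:5], [25, 25, 50, 75, 100])
        assert d[5:].sum() == 0.0

    def test_absent_group_is_zeros(self):
        d = distribution(np.array([1, 2, 1, 2]))
        np.testing.assert_allclose(d[10:], np.zeros(5))

    @given(group_seqs)
    def test_bounded_and_nondecreasing_within_group(self, groups):
        d = distribution(np.array(groups))
        assert ((d >= 0) & (d <= 100)).all()
        for k in range(3):
            block = d[5 * k : 5 * k + 5]
            if block.any():
                assert (np.diff(block) >= 0).all()


class TestAutoCovariance:
    def test_constant_sequence_is_zero(self):
        np.testing.assert_allclose(auto_covariance(np.ones(40), 30), np.zeros(30))

    def test_alternating_example_matches_loop_oracle(self):
        v = [1.0, -1.0, 1.0, -1.0, 1.0]
        np.testing.assert_allclose(
            auto_covariance(np.array(v), 4), auto_covariance_oracle(v, 4),
            atol=1e-12,
        )

    @given(
        st.lists(st.floats(-5, 5), min_size=8, max_size=60),
        st.integers(min_value=1, max_value=5),
    )
    def test_shift_invariance(self, vals, lag_max):
        v = np.array(vals)
        np.testing.assert_allclose(
            auto_covariance(v, lag_max),
            auto_covariance(v + 17.5, lag_max),
            atol=1e-8,
        )

    def test_too_short_names_minimum_length(self):
        with pytest.raises(DescriptorError, match="minimum length 31"):
            auto_covariance(np.ones(30), 30)


class TestProteinVector:
    def test_length_and_block_structure(self, random_sequences):
        seq = random_sequences[0]
        f = protein_features(seq)
        assert f.shape == (347,)
        names = feature_names()
        assert len(names) == 347
        assert sum(n.startswith("f.") for n in names) == 20
        ctd = [n for n in names if n.split(".")[0] in ("c", "t", "d")]
        assert len(ctd) == 147
        ac = [n for n in names if n.startswith("ac.")]
        assert len(ac) == 180
        for prop in TABLES.quantitative:
            assert sum(n.startswith(f"ac.{prop.name}.") for n in names) == 30

    def test_block_invariants(self, random_sequences):
        names = feature_names()
        for seq in random_sequences[:10]:
            f = protein_features(seq)
            assert np.isfinite(f).all()
            assert f[:20].sum() == pytest.approx(1.0, abs=1e-9)
            for prop in TABLES.qualitative:
                idx = [i for i, n in enumerate(names)
                       if n.startswith(f"c.{prop.name}.")]
                assert f[idx].sum() == pytest.approx(1.0, abs=1e-9)
                didx = [i for i, n in enumerate(names)
                        if n.startswith(f"d.{prop.name}.")]
                assert ((f[didx] >= 0) & (f[didx] <= 100)).all()

    def test_too_short_sequence_rejected(self):
        seq = ProteinSequence(id="short", residues="ACDEFGHIKLMNPQRSTVWY")
        with pytest.raises(DescriptorError, match="too short"):
            protein_features(seq)

    def test_frequency_and_composition_are_permutation_invariant(self):
        rng = np.random.default_rng(7)
        residues = "".join(rng.choice(list(ALPHABET), 80))
        shuffled = "".join(rng.permutation(list(residues)))
        assert residues != shuffled
        np.testing.assert_allclose(
            frequency_descriptor(residues), frequency_descriptor(shuffled)
        )
        prop = TABLES.qualitative[0]
        np.testing.assert_allclose(
            composition(encode_qualitative(residues, prop)),
            composition(encode_qualitative(shuffled, prop)),
        )

    def test_positional_descriptors_are_not_permutation_invariant(self):
        # concrete witness: a block sequence vs its interleaving
        blocked = "A" * 20 + "L" * 20
        interleaved = "AL" * 20
        prop = {p.name: p for p in TABLES.qualitative}["hydrophobicity"]
        gb = encode_qualitative(blocked, prop)
        gi = encode_qualitative(interleaved, prop)
        assert not np.allclose(transition(gb), transition(gi))
        assert not np.allclose(distribution(gb), distribution(gi))
        quant = TABLES.quantitative[0]
        vb = encode_quantitative(blocked, quant)
        vi = encode_quantitative(interleaved, quant)
        assert not np.allclose(auto_covariance(vb, 10), auto_covariance(vi, 10))


class TestOracleEquivalence:
    """Optimized descriptors vs literal loop transcriptions, 200 random proteins."""

    def test_ctd_and_ac_match_loop_oracles(self, random_sequences):
        for seq in random_sequences:
            for prop in TABLES.qualitative:
                g = encode_qualitative(seq, prop)
                glist = g.tolist()
                np.testing.assert_allclose(
                    composition(g), composition_oracle(glist), atol=1e-10)
                np.testing.assert_allclose(
                    transition(g), transition_oracle(glist), atol=1e-10)
                np.testing.assert_allclose(
                    distribution(g), distribution_oracle(glist), atol=1e-10)
            for prop in TABLES.quantitative:
                v = encode_quantitative(seq, prop)
                np.testing.assert_allclose(
                    auto_covariance(v, 30),
                    auto_covariance_oracle(v.tolist(), 30),
                    atol=1e-10,
                )


class TestPairVector:
    def test_concatenation(self, random_sequences):
        fa = protein_features(random_sequences[0])
        fb = protein_features(random_sequences[1])
        pv = pair_features(fa, fb)
        assert pv.shape == (694,)
        np.testing.assert_array_equal(pv[:347], fa)
        np.testing.assert_array_equal(pv[347:], fb)

    def test_self_pair_halves_identical(self, random_sequences):
        f = protein_features(random_sequences[2])
        pv = pair_features(f, f)
        np.testing.assert_array_equal(pv[:347], pv[347:])

    def test_swapped_order_is_a_permutation(self, random_sequences):
        fa = protein_features(random_sequences[0])
        fb = protein_features(random_sequences[1])
        ab, ba = pair_features(fa, fb), pair_features(fb, fa)
        np.testing.assert_array_equal(np.sort(ab), np.sort(ba))
        assert not np.array_equal(ab, ba)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DescriptorError):
            pair_features(np.zeros(347), np.zeros(346))
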