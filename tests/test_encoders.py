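import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppiboost.encoders import (
    EncoderConfig,
    encode_ad,
    encode_pair,
    encode_protein,
    encode_pseaac,
    encode_psepssm,
    encode_rsiv,
    pseudo_pssm,
)
from ppiboost.properties import physicochemical_properties, pseaac_properties
from ppiboost.seqio import AMINO_ACIDS, PSSMatrix, ProteinRecord
from conftest import random_protein
import _oracles

sequences = st.text(alphabet=AMINO_ACIDS, min_size=15, max_size=60)


class TestDimensionalContracts:
    def test_default_dimensions(self, protein60, rng):
        pssm = pseudo_pssm(protein60)
        assert len(encode_pseaac(protein60)) == 31
        assert len(encode_psepssm(protein60, pssm)) == 200
        assert len(encode_rsiv(protein60)) == 197
        assert len(encode_ad(protein60)) == 231
        fused = encode_protein(protein60, pssm)
        assert len(fused) == 659
        assert len(encode_pair(fused, fused)) == 1318

    def test_dimensions_are_additive_in_config(self, protein60):
        config = EncoderConfig(lam=0, xi=0, lag=1)
        fused = encode_protein(protein60, pseudo_pssm(protein60), config)
        assert len(fused) == 20 + 20 + 197 + 21 == 258
        assert config.n_features == 258

    def test_names_unique_and_prefixed(self, protein60):
        fused = encode_protein(protein60, pseudo_pssm(protein60))
        assert len(set(fused.names)) == 659
        prefixes = {n.split("_")[0] for n in fused.names}
        assert prefixes == {"pseaac", "psepssm", "rsiv", "ad"}


class TestPseAAC:
    def test_homopolymer_collapses_to_composition(self):
        prot = ProteinRecord("poly", "AAAAAAAAAA")
        vec = encode_pseaac(prot, EncoderConfig(lam=1))
        expected = np.zeros(21)
        expected[AMINO_ACIDS.index("A")] = 1.0
        np.testing.assert_allclose(vec.values, expected, atol=1e-12)

    def test_bruteforce_small_sequence(self):
        prot = ProteinRecord("t", "ACDCACDC")
        vec = encode_pseaac(prot, EncoderConfig(lam=2, w=0.05))
        oracle = _oracles.pseaac_bruteforce("ACDCACDC", lam=2, w=0.05)
        np.testing.assert_allclose(vec.values, oracle, atol=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(seq=sequences)
    def test_components_nonnegative_sum_one(self, seq):
        vec = encode_pseaac(ProteinRecord("h", seq))
        assert np.all(vec.values >= 0)
        assert abs(vec.values.sum() - 1.0) < 1e-9

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="too short"):
            encode_pseaac(ProteinRecord("s", "ACDE"), EncoderConfig(lam=11))

    def test_composition_block_permutation_invariant(self, rng):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=40))
        shuffled = "".join(rng.permutation(list(seq)))
        v1 = encode_pseaac(ProteinRecord("a", seq))
        v2 = encode_pseaac(ProteinRecord("b", shuffled))
        # composition ratios are permutation invariant; normalizer is not
        c1 = v1.values[:20] / v1.values[:20].sum()
        c2 = v2.values[:20] / v2.values[:20].sum()
        np.testing.assert_allclose(c1, c2, atol=1e-12)


class TestPsePSSM:
    def test_constant_pssm_gives_all_zero(self):
        prot = ProteinRecord("c", "ACDEFGHIKLMN")
        pssm = PSSMatrix("c", np.full((12, 20), 3.0))
        vec = encode_psepssm(prot, pssm)
        np.testing.assert_array_equal(vec.values, np.zeros(200))

    def test_bruteforce_random_matrix(self, rng):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=12))
        scores = rng.integers(-8, 9, size=(12, 20)).astype(float)
        vec = encode_psepssm(ProteinRecord("r", seq), PSSMatrix("r", scores),
                             EncoderConfig(xi=3))
        oracle = _oracles.psepssm_bruteforce(scores.tolist(), xi=3)
        np.testing.assert_allclose(vec.values, oracle, atol=1e-10)

    def test_row_count_mismatch_errors(self, rng):
        prot = ProteinRecord("m", "ACDEFGHIKL")
        pssm = PSSMatrix("m", rng.integers(-5, 6, size=(9, 20)).astype(float))
        with pytest.raises(ValueError, match="rows"):
            encode_psepssm(prot, pssm)


class TestRSIV:
    def test_homopolymer_single_class(self):
        vec = encode_rsiv(ProteinRecord("g", "GGGG"))
        values, names = vec.values, vec.names
        class_block = values[120:127]
        assert np.count_nonzero(class_block) == 1 and class_block[0] == 1.0  # {A,G,V}
        dipep = values[127:176].reshape(7, 7)
        assert dipep[0, 0] == 1.0 and np.count_nonzero(dipep) == 1
        trans = values[176:]
        np.testing.assert_array_equal(trans, np.zeros(21))

    def test_hand_enumerated_counts(self):
        # ARNDCQ: classes 0,4,3,5,6,3; adjacent pairs (0,4),(4,3),(3,5),(5,6),(6,3)
        vec = encode_rsiv(ProteinRecord("h", "ARNDCQ"))
        oracle = _oracles.rsiv_bruteforce("ARNDCQ")
        np.testing.assert_allclose(vec.values, oracle, atol=1e-12)
        dipep = vec.values[127:176].reshape(7, 7)
        assert dipep[0, 4] == dipep[4, 3] == dipep[3, 5] == dipep[5, 6] == dipep[6, 3] == 0.2

    def test_composition_block_permutation_invariant(self, rng):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=40))
        shuffled = "".join(rng.permutation(list(seq)))
        v1 = encode_rsiv(ProteinRecord("a", seq)).values
        v2 = encode_rsiv(ProteinRecord("b", shuffled)).values
        np.testing.assert_allclose(v1[:127], v2[:127], atol=1e-12)

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="too short"):
            encode_rsiv(ProteinRecord("s", "A"))


class TestAD:
    def test_homopolymer_conventions(self):
        prot = ProteinRecord("p", "WWWWWWWWWWWW")
        vec = encode_ad(prot, EncoderConfig(lag=3))
        values = vec.values.reshape(3, 7, 3)
        tables = physicochemical_properties()
        for pi, table in enumerate(tables):
            np.testing.assert_allclose(values[0, pi], table.normalized["W"] ** 2, atol=1e-12)
        np.testing.assert_array_equal(values[1], np.zeros((7, 3)))  # Moran
        np.testing.assert_array_equal(values[2], np.zeros((7, 3)))  # Geary

    def test_bruteforce_random_sequence(self, rng):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=15))
        vec = encode_ad(ProteinRecord("r", seq), EncoderConfig(lag=4))
        oracle = _oracles.ad_bruteforce(seq, lag=4)
        assert len(vec) == 84
        np.testing.assert_allclose(vec.values, oracle, atol=1e-10)

    @settings(max_examples=40, deadline=None)
    @given(seq=sequences)
    def test_moran_geary_ranges(self, seq):
        vec = encode_ad(ProteinRecord("h", seq), EncoderConfig(lag=5))
        values = vec.values.reshape(3, 7, 5)
        assert np.all(values[2] >= 0)  # Geary
        assert np.all(values[1] >= -1 - 1e-9) and np.all(values[1] <= 1.05)  # Moran


class TestFusionAndPairs:
    def test_line_wrapping_invariance(self, tmp_path, protein60):
        from ppiboost.seqio import read_fasta, write_fasta

        p1 = tmp_path / "w10.fasta"
        p2 = tmp_path / "w200.fasta"
        write_fasta([protein60], p1, width=10)
        write_fasta([protein60], p2, width=200)
        r1, r2 = read_fasta(p1)[0], read_fasta(p2)[0]
        v1 = encode_protein(r1, pseudo_pssm(r1))
        v2 = encode_protein(r2, pseudo_pssm(r2))
        np.testing.assert_array_equal(v1.values, v2.values)

    def test_self_pair_duplicates_halves(self, protein60):
        vec = encode_protein(protein60, pseudo_pssm(protein60))
        pair = encode_pair(vec, vec)
        np.testing.assert_array_equal(pair.values[:659], pair.values[659:])

    def test_pair_symmetry_swaps_halves(self, rng):
        a = random_protein(rng, 55, "pa")
        b = random_protein(rng, 65, "pb")
        va = encode_protein(a, pseudo_pssm(a))
        vb = encode_protein(b, pseudo_pssm(b))
        ab = encode_pair(va, vb).values
        ba = encode_pair(vb, va).values
        np.testing.assert_array_equal(ab[:659], ba[659:])
        np.testing.assert_array_equal(ab[659:], ba[:659])

    def test_mismatched_lengths_error(self, protein60):
        v1 = encode_protein(protein60, pseudo_pssm(protein60))
        v2 = encode_protein(protein60, pseudo_pssm(protein60), EncoderConfig(lam=5))
        with pytest.raises(ValueError, match="layout"):
            encode_pair(v1, v2)


class TestPropertyTables:
    def test_normalization_invariants(self):
        for table in pseaac_properties() + physicochemical_properties():
            vals = np.array([table.normalized[a] for a in AMINO_ACIDS])
            assert abs(vals.mean()) < 1e-10
            assert abs(vals.std() - 1) < 1e-10
            assert len(table.raw) == 20

    def test_wildcard_contributes_mean(self):
        table = pseaac_properties()[0]
        assert table.value("X") == 0.0
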