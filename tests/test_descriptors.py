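import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from plantloc.descriptors import (
    BLOCKS,
    DEFAULT_PARAMS,
    FEATURE_SCHEMA,
    DescriptorError,
    aac,
    ctd,
    extract_features,
    extract_table,
    geary,
    physchem_indices,
    pseaac,
    qso_socn,
    read_feature_table,
    scale_projection,
    write_feature_table,
)
from plantloc.external_scores import ExternalScores, MockScoreProvider
from plantloc.scales import CTD_GROUPS, MULTI_SCALES, TRANSFER_GUY
from plantloc.seqio import AA_ALPHABET, Dataset, ProteinRecord
from tests_util_sequences import random_protein

UNIFORM20 = "ACDEFGHIKLMNPQRSTVWY"


class TestAAC:
    def test_homopolymer(self):
        v = aac("AAAA")
        assert v[0] == 1.0 and v[1:].sum() == 0.0

    def test_uniform(self):
        assert np.allclose(aac(UNIFORM20), 0.05)

    def test_direct_count(self):
        v = aac("AAC")
        assert v[AA_ALPHABET.index("A")] == pytest.approx(2 / 3)
        assert v[AA_ALPHABET.index("C")] == pytest.approx(1 / 3)

    def test_empty_errors(self):
        with pytest.raises(DescriptorError):
            aac("")


class TestPseAAC:
    def test_homopolymer_reduces_to_padded_aac(self):
        v = pseaac("AAAAA", "parallel", lam=2, weight=0.05)
        expected = np.zeros(22)
        expected[0] = 1.0
        assert np.allclose(v, expected)

    @pytest.mark.parametrize(
        "mode,dim", [("parallel", 22), ("serial", 26), ("paac", 30), ("apaac", 30)]
    )
    def test_block_dimensions(self, mode, dim):
        seq = random_protein(60, seed=3)
        assert pseaac(seq, mode).shape == (dim,)

    def test_weight_to_zero_converges_to_aac(self):
        seq = random_protein(80, seed=5)
        for mode in ("parallel", "serial", "paac", "apaac"):
            v = pseaac(seq, mode, weight=1e-9)
            assert np.allclose(v[:20], aac(seq), atol=1e-7)

    def test_too_short_names_mode(self):
        with pytest.raises(DescriptorError, match="paac"):
            pseaac("ACDEF", "paac")

    @pytest.mark.parametrize("seed", range(5))
    def test_parallel_matches_bruteforce(self, seed):
        seq = random_protein(40, seed=seed) if seed else "ACDKWH"
        got = pseaac(seq, "parallel", lam=2, weight=0.05)
        assert np.allclose(got, oracles.pseaac_type1_oracle(seq, 2, 0.05), rtol=1e-10)

    def test_serial_and_apaac_match_bruteforce(self):
        seq = random_protein(55, seed=9)
        assert np.allclose(
            pseaac(seq, "serial", lam=2, weight=0.05),
            oracles.pseaac_type2_oracle(seq, 2, 0.05),
            rtol=1e-10,
        )
        assert np.allclose(
            pseaac(seq, "apaac", lam=5, weight=0.1),
            oracles.apaac_oracle(seq, 5, 0.1),
            rtol=1e-10,
        )


class TestCTD:
    def test_homopolymer_distribution(self):
        C, T, D = ctd("A" * 10)
        for p, prop in enumerate(CTD_GROUPS):
            g = next(i for i, members in enumerate(CTD_GROUPS[prop]) if "A" in members)
            c_block = C[3 * p : 3 * p + 3]
            assert c_block[g] == 1.0 and c_block.sum() == 1.0
            assert np.all(T[3 * p : 3 * p + 3] == 0.0)
            d_block = D[15 * p + 5 * g : 15 * p + 5 * g + 5]
            assert np.allclose(d_block, [10, 30, 50, 80, 100])

    def test_composition_sums_to_one_per_property(self):
        C, _, _ = ctd(random_protein(90, seed=2))
        for p in range(7):
            assert C[3 * p : 3 * p + 3].sum() == pytest.approx(1.0, abs=1e-9)

    def test_transitions_sum_to_one_when_any_exist(self):
        _, T, _ = ctd(random_protein(90, seed=4))
        for p in range(7):
            block = T[3 * p : 3 * p + 3]
            assert block.sum() == pytest.approx(1.0, abs=1e-9) or block.sum() == 0.0

    def test_alternating_cross_groups(self):
        # hydrophobicity groups place A (neutral) and C (hydrophobic) apart
        _, T, _ = ctd("ACACAC")
        p = list(CTD_GROUPS).index("hydrophobicity")
        assert T[3 * p : 3 * p + 3].max() == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce(self, seed):
        seq = random_protein(35 + 40 * seed, seed=seed)
        C, T, D = ctd(seq)
        oC, oT, oD = oracles.ctd_oracle(seq)
        assert np.allclose(C, oC) and np.allclose(T, oT) and np.allclose(D, oD)


class TestGeary:
    def test_homopolymer_is_one(self):
        assert np.all(geary("A" * 20) == 1.0)

    def test_dimension(self):
        assert geary(random_protein(50, seed=1)).shape == (40,)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce(self, seed):
        seq = random_protein(50, seed=seed)
        assert np.allclose(geary(seq), oracles.geary_oracle(seq), rtol=1e-10)


class TestQSO:
    def test_dimensions(self):
        qso, socn = qso_socn(random_protein(30, seed=1))
        assert qso.shape == (60,) and socn.shape == (20,)

    def test_homopolymer_zero_coupling(self):
        qso, socn = qso_socn("W" * 15)
        assert np.all(socn == 0.0)
        # composition part reduces to normalized AAC
        assert qso[AA_ALPHABET.index("W")] == pytest.approx(1.0)
        assert np.all(qso[20:30] == 0.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce(self, seed):
        seq = random_protein(30, seed=seed)
        qso, socn = qso_socn(seq)
        oq, os_ = oracles.qso_socn_oracle(seq)
        assert np.allclose(qso, oq, rtol=1e-10) and np.allclose(socn, os_, rtol=1e-10)


class TestScaleProjection:
    def test_single_residue_identity(self):
        z = MULTI_SCALES["zscales"]
        assert np.allclose(scale_projection("W", z), z.table["W"])

    def test_two_residue_midpoint(self):
        z = MULTI_SCALES["zscales"]
        mid = (np.atleast_1d(z.table["A"]) + np.atleast_1d(z.table["W"])) / 2
        assert np.allclose(scale_projection("AW", z), mid)

    def test_zscale_dimension(self):
        assert MULTI_SCALES["zscales"].d == 5


class TestPhyschem:
    def test_aliphatic_homopolymer(self):
        assert physchem_indices("AAAA")["aIndex"] == pytest.approx(100.0)

    def test_boman_single_residue(self):
        assert physchem_indices("WW")["Boman"] == pytest.approx(TRANSFER_GUY["W"])

    def test_instability_matches_dipeptide_sum(self):
        seq = "APAPAPAPAP"
        got = physchem_indices(seq)["Instaindex"]
        assert got == pytest.approx(oracles.instability_oracle(seq), rel=1e-9)

    def test_pi_agrees_with_gridscan(self):
        for seq in ("K", "DDE", "KRKRH", random_protein(40, seed=6)):
            got = physchem_indices(seq + seq)["pI"] if len(seq) < 2 else physchem_indices(seq)["pI"]
            assert got == pytest.approx(oracles.pi_gridscan_oracle(seq * 2 if len(seq) < 2 else seq), abs=0.01)

    def test_charge_signs(self):
        assert physchem_indices("KKKKKKKKKK")["Charge"] > 0
        assert physchem_indices("DDDDDDDDDD")["Charge"] < 0


class TestExtraction:
    def test_schema_is_479_unique_names(self):
        assert len(FEATURE_SCHEMA) == 479
        assert len(set(FEATURE_SCHEMA)) == 479

    def test_block_sizes_match_schema(self):
        sizes = {name: len(feats) for name, feats in BLOCKS.items()}
        assert sizes == {
            "AAC": 20, "APAAC": 30, "Blosum": 8, "CTDC": 21, "CTDD": 105,
            "CTDT": 21, "Geary": 40, "PAAC": 30, "PsePC": 22, "PseSC": 26,
            "Scalar": 57, "QSO": 60, "SOCN": 20, "External": 18, "Homology": 1,
        }

    def test_deterministic(self):
        rec = ProteinRecord("r", random_protein(50, seed=8))
        ext = ExternalScores()
        assert np.array_equal(extract_features(rec, ext), extract_features(rec, ext))

    def test_short_sequence_rejected(self):
        rec = ProteinRecord("r", "ACDEFGHIKL")  # 10 < 11
        with pytest.raises(DescriptorError, match="r"):
            extract_features(rec, ExternalScores())

    def test_table_roundtrip_12_digits(self, tmp_path):
        ds = Dataset([ProteinRecord(f"r{i}", random_protein(40, seed=i)) for i in range(3)])
        df = extract_table(ds, MockScoreProvider(seed=1))
        assert df.shape == (3, 479)
        path = tmp_path / "feat.tsv"
        write_feature_table(df, path)
        back = read_feature_table(path)
        assert list(back.columns) == list(df.columns)
        assert np.allclose(back.to_numpy(), df.to_numpy(), rtol=1e-11)

    def test_empty_dataset_header_only(self):
        df = extract_table(Dataset([]), MockScoreProvider())
        assert df.shape == (0, 479)


@settings(max_examples=30, deadline=None)
@given(st.text(alphabet=AA_ALPHABET, min_size=12, max_size=120))
def test_composition_invariants(seq):
    """AAC and per-property CTDC always sum to 1; PseAAC heads track AAC."""
    assert aac(seq).sum() == pytest.approx(1.0, abs=1e-9)
    C, _, _ = ctd(seq)
    for p in range(7):
        assert C[3 * p : 3 * p + 3].sum() == pytest.approx(1.0, abs=1e-9)
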