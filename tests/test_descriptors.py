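import numpy as np
import pytest

import oracles
from bactipred import (
    DescriptorConfig,
    LabeledDataset,
    ProteinRecord,
    aac,
    apaac,
    build_feature_matrix,
    dipeptide_composition,
    feature_names,
    pseaac,
    ss_features,
)
from bactipred.descriptors import (
    CTD_PROPERTIES,
    ctd_composition,
    ctd_distribution,
    ctd_transition,
    descriptor_vector,
    predict_secondary_structure,
)


def rec(seq):
    return ProteinRecord("t", seq)


# ---------------------------------------------------------------------------
# simple compositions
# ---------------------------------------------------------------------------

def test_aac_homopolymer():
    v = aac(rec("GG"))
    assert v[oracles.AA.index("G")] == 1.0 and v.sum() == pytest.approx(1.0)


def test_aac_uniform():
    assert np.allclose(aac(rec("ACDEFGHIKLMNPQRSTVWY")), 0.05)


def test_aac_direct_count():
    v = aac(rec("KKC"))
    assert v[oracles.AA.index("K")] == pytest.approx(2 / 3)
    assert v[oracles.AA.index("C")] == pytest.approx(1 / 3)


def test_dpc_single_pair_type():
    v = dipeptide_composition(rec("AAA"))
    assert v[0] == 1.0 and v.sum() == pytest.approx(1.0)


def test_dpc_direct_count():
    v = dipeptide_composition(rec("ACAC"))
    ac = oracles.AA.index("A") * 20 + oracles.AA.index("C")
    ca = oracles.AA.index("C") * 20 + oracles.AA.index("A")
    assert v[ac] == pytest.approx(2 / 3) and v[ca] == pytest.approx(1 / 3)


def test_dpc_single_residue_errors():
    with pytest.raises(ValueError):
        dipeptide_composition(rec("A"))


# ---------------------------------------------------------------------------
# pseudo amino-acid composition
# ---------------------------------------------------------------------------

def test_pseaac_homopolymer_kills_correlation():
    v = pseaac(rec("A" * 12))
    assert v[oracles.AA.index("A")] == pytest.approx(1.0)
    assert np.allclose(np.delete(v, oracles.AA.index("A")), 0.0)


def test_pseaac_too_short_names_minimum():
    with pytest.raises(ValueError, match="11"):
        pseaac(rec("A" * 10))


def test_pseaac_weight_limit_recovers_plain_composition():
    seq = "MKCLRWYEDGHST"
    cfg = DescriptorConfig(pseaac_weight=1e-12)
    v = pseaac(rec(seq), cfg)
    assert np.allclose(v[:20], aac(rec(seq)), atol=1e-8)
    assert np.allclose(v[20:], 0.0, atol=1e-8)


def test_apaac_homopolymer_tail_constant():
    v = apaac(rec("G" * 12))
    # lag autocorrelations of a constant profile are identical across lags
    h_terms = v[20::2]
    assert np.allclose(h_terms, h_terms[0])


@pytest.mark.parametrize("fn,oracle,n", [
    (pseaac, oracles.naive_pseaac, 30),
    (apaac, oracles.naive_apaac, 40),
])
def test_pseudo_compositions_match_hand_transcription(fn, oracle, n):
    seq = "MKCLRWYEDGHST"
    got = fn(rec(seq))
    assert got.shape == (n,)
    assert np.allclose(got, oracle(seq), atol=1e-12)
    assert got.sum() == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# CTD
# ---------------------------------------------------------------------------

def test_ctd_composition_balanced_example():
    assert np.allclose(ctd_composition(rec("RRGGCC"), "hydrophobicity"), 1 / 3)


def test_ctd_composition_homopolymer_charge():
    v = ctd_composition(rec("KKKK"), "charge")
    assert v[0] == 1.0  # K/R is the positive-charge group


def test_ctd_transition_hand_enumeration():
    assert np.allclose(
        ctd_transition(rec("RRGGCC"), "hydrophobicity"), [0.2, 0.0, 0.2]
    )


def test_ctd_transition_homopolymer_zero():
    assert np.allclose(ctd_transition(rec("AAAA"), "hydrophobicity"), 0.0)


def test_ctd_transition_alternating_two_groups():
    assert ctd_transition(rec("RGRGRG"), "hydrophobicity")[0] == pytest.approx(1.0)


def test_ctd_distribution_hand_convention():
    v = ctd_distribution(rec("RRGGCC"), "hydrophobicity")
    assert np.allclose(v[:5], [100 / 6, 100 / 6, 100 / 6, 100 / 6, 200 / 6])


def test_ctd_distribution_absent_group_zeros():
    v = ctd_distribution(rec("KKKK"), "charge")
    assert np.allclose(v[5:], 0.0)  # groups 2 and 3 absent


def test_ctd_distribution_bounded():
    v = ctd_distribution(rec("MKCLRWYEDGHST"), "polarity")
    assert (v >= 0).all() and (v <= 100).all()


# ---------------------------------------------------------------------------
# secondary structure
# ---------------------------------------------------------------------------

def test_polyalanine_predicts_all_helix():
    assert predict_secondary_structure(rec("A" * 20)) == "H" * 20


def test_glycine_proline_rich_predicts_coil():
    states = predict_secondary_structure(rec("GPGGPGGPGGPG"))
    assert states.count("C") / len(states) > 0.9


def test_ss_prediction_contract():
    seq = "MKCLRWYEDGHSTAAAGPPI"
    states = predict_secondary_structure(rec(seq))
    assert len(states) == len(seq) and set(states) <= set("HEC")


def test_ss_features_single_run():
    v = ss_features("HHHH")
    assert np.allclose(v, [1.0, 1.0, 0, 0, 0, 0])


def test_ss_features_alternating():
    v = ss_features("HECHEC")
    assert np.allclose(v, [1 / 3, 1 / 6, 1 / 3, 1 / 6, 1 / 3, 1 / 6])


def test_ss_features_run_enumeration():
    v = ss_features("CCHHHCC")
    assert v[0] == pytest.approx(3 / 7) and v[1] == pytest.approx(3 / 7)
    assert v[4] == pytest.approx(4 / 7) and v[5] == pytest.approx(2 / 7)


# ---------------------------------------------------------------------------
# oracle equivalence and matrix assembly
# ---------------------------------------------------------------------------

def test_every_descriptor_matches_naive_oracle(random_sequences):
    """Vectorized descriptors equal the loop-based transcription of the
    formulas on 100 seeded random sequences."""
    for r in random_sequences:
        seq = r.sequence
        assert np.allclose(aac(r), oracles.naive_aac(seq), atol=1e-12)
        assert np.allclose(dipeptide_composition(r), oracles.naive_dpc(seq), atol=1e-12)
        assert np.allclose(pseaac(r), oracles.naive_pseaac(seq), atol=1e-10)
        assert np.allclose(apaac(r), oracles.naive_apaac(seq), atol=1e-10)
        for prop in CTD_PROPERTIES:
            assert np.allclose(ctd_composition(r, prop), oracles.naive_ctd_composition(seq, prop))
            assert np.allclose(ctd_transition(r, prop), oracles.naive_ctd_transition(seq, prop))
            assert np.allclose(ctd_distribution(r, prop), oracles.naive_ctd_distribution(seq, prop))
        states = predict_secondary_structure(r)
        assert states == oracles.naive_secondary_structure(seq)
        assert np.allclose(ss_features(states), oracles.naive_ss_features(states))


def test_normalization_identities(random_sequences):
    for r in random_sequences[:30]:
        assert aac(r).sum() == pytest.approx(1.0, abs=1e-9)
        assert dipeptide_composition(r).sum() == pytest.approx(1.0, abs=1e-9)
        assert pseaac(r).sum() == pytest.approx(1.0, abs=1e-9)
        assert apaac(r).sum() == pytest.approx(1.0, abs=1e-9)
        for prop in CTD_PROPERTIES:
            assert ctd_composition(r, prop).sum() == pytest.approx(1.0, abs=1e-9)
            assert ctd_transition(r, prop).sum() <= 1.0 + 1e-12


def test_feature_names_frozen_and_dimensioned():
    names = feature_names()
    assert len(names) == 643
    assert names == feature_names()  # stable across calls
    prefixes = {"AAC": 20, "DPC": 400, "PAAC": 30, "APAAC": 40, "CTD": 147, "SS": 6}
    for prefix, n in prefixes.items():
        assert sum(1 for c in names if c.split("_")[0] == prefix) == n


def test_matrix_shape_and_order(random_sequences):
    ds = LabeledDataset(random_sequences[:3])
    m = build_feature_matrix(ds)
    assert m.shape == (3, 643)
    assert list(m.columns) == feature_names()
    assert np.isfinite(m.to_numpy()).all()
    assert np.allclose(m.iloc[0].to_numpy(), descriptor_vector(random_sequences[0]))


def test_matrix_rejects_short_sequences():
    ds = LabeledDataset([ProteinRecord("ok", "M" * 15), ProteinRecord("bad", "MKC")])
    with pytest.raises(ValueError, match="bad"):
        build_feature_matrix(ds)
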