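"""Feature math: composition, PAAC against an independent naive oracle,
entropy, hydropathy, mass and charge."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acpfuse import features
from acpfuse.features import (
    ChargeParams,
    PAACParams,
    aa_frequencies,
    charge_at_ph,
    coupling,
    decode_indices,
    featurize_dataset,
    gravy,
    index_encode,
    manual_features,
    molecular_weight,
    paac,
    shannon_entropy,
    tier_correlation,
)
from acpfuse.io import LabeledDataset, Peptide
from acpfuse.tables import ALPHABET, HOPP_WOODS, KYTE_DOOLITTLE, SIDE_CHAIN_MASS

from conftest import make_random_peptides

# A published experimentally validated ACP (cecropin-like, cationic).
ACP_SEQ = "KLWKKIEKLIKKLLTSIR"


# ---------------------------------------------------------------------------
# independent naive oracle for PAAC, written with pure-python loops and its
# own standardization; shares no code path with acpfuse.features
def _naive_scales():
    out = []
    for table in (KYTE_DOOLITTLE, HOPP_WOODS, SIDE_CHAIN_MASS):
        vals = [table[aa] for aa in ALPHABET]
        mean = sum(vals) / 20.0
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / 20.0)
        out.append({aa: (table[aa] - mean) / sd for aa in ALPHABET})
    return out


def naive_paac(seq, lam=10, w=0.05):
    scales = _naive_scales()
    L = len(seq)
    f = {aa: seq.count(aa) / L for aa in ALPHABET}
    taus = []
    for k in range(1, lam + 1):
        total = 0.0
        for i in range(L - k):
            r1, r2 = seq[i], seq[i + k]
            total += sum((s[r2] - s[r1]) ** 2 for s in scales) / 3.0
        taus.append(total / (L - k))
    denom = sum(f.values()) + w * sum(taus)
    return [f[aa] / denom for aa in ALPHABET] + [w * t / denom for t in taus]


# ---------------------------------------------------------------------------
peptide_strategy = st.text(alphabet=ALPHABET, min_size=11, max_size=60)


@given(peptide_strategy)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_paac_simplex_property(seq):
    """For any valid peptide the 30 PAAC components form a probability
    simplex: non-negative, summing to one."""
    p = paac(seq)
    assert p.shape == (30,)
    assert (p >= 0).all()
    assert p.sum() == pytest.approx(1.0, abs=1e-12)


@given(peptide_strategy)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_encode_decode_round_trip_property(seq):
    assert decode_indices(index_encode(seq, 60)) == seq


class TestComposition:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ADGF", {"A": 0.25, "D": 0.25, "G": 0.25, "F": 0.25}),
            ("AAAA", {"A": 1.0}),
            (ALPHABET, {aa: 0.05 for aa in ALPHABET}),
        ],
    )
    def test_frequencies(self, seq, expected):
        freqs = aa_frequencies(seq)
        for i, aa in enumerate(ALPHABET):
            assert freqs[i] == pytest.approx(expected.get(aa, 0.0))
        assert freqs.sum() == pytest.approx(1.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            aa_frequencies("")


class TestCoupling:
    def test_identical_residues_give_zero(self):
        scales = PAACParams().scale_matrix()
        assert coupling("A", "A", scales) == 0.0

    def test_symmetric(self):
        scales = PAACParams().scale_matrix()
        for a, b in [("A", "K"), ("G", "W"), ("C", "Y")]:
            assert coupling(a, b, scales) == pytest.approx(coupling(b, a, scales))

    def test_matches_hand_computation(self):
        # oracle: pure-python evaluation on independently standardized tables
        s = _naive_scales()
        expected = sum((tab["W"] - tab["G"]) ** 2 for tab in s) / 3.0
        assert coupling("G", "W", PAACParams().scale_matrix()) == pytest.approx(
            expected, abs=1e-12
        )


class TestTierCorrelation:
    def test_homopolymer_zero(self):
        scales = PAACParams().scale_matrix()
        for k in (1, 2, 5):
            assert tier_correlation("AAAAAA", k, scales) == 0.0

    def test_alternating_tier2_zero(self):
        scales = PAACParams().scale_matrix()
        assert tier_correlation("ADAD", 2, scales) == 0.0

    def test_tier1_is_mean_of_adjacent_couplings(self):
        scales = PAACParams().scale_matrix()
        expected = np.mean(
            [coupling(a, b, scales) for a, b in [("A", "D"), ("D", "G"), ("G", "F")]]
        )
        assert tier_correlation("ADGF", 1, scales) == pytest.approx(expected)

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            tier_correlation("ADGF", 4, PAACParams().scale_matrix())

    def test_order_sensitivity_witness(self):
        # same composition, different order => different tier correlation
        scales = PAACParams().scale_matrix()
        assert tier_correlation("AKAKAKAKAKAK", 1, scales) != pytest.approx(
            tier_correlation("AAAAAAKKKKKK", 1, scales)
        )


class TestPAAC:
    def test_lambda_zero_equals_frequencies(self, random_peptides):
        for seq in random_peptides[:20]:
            np.testing.assert_allclose(
                paac(seq, PAACParams(lam=0)), aa_frequencies(seq), atol=1e-15
            )

    def test_components_sum_to_one(self, random_peptides):
        for seq in random_peptides:  # 100 peptides
            p = paac(seq)
            assert (p >= 0).all()
            assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_homopolymer_is_one_hot(self):
        p = paac("AAAAAAAAAAAA")
        assert p[0] == pytest.approx(1.0)
        assert np.all(p[1:] == 0.0)

    def test_agrees_with_naive_oracle(self):
        for seq in [ACP_SEQ] + make_random_peptides(seed=7, n=50):
            np.testing.assert_allclose(paac(seq), naive_paac(seq), atol=1e-10)

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="lambda"):
            paac("ADGFADGF")  # L=8 <= lambda=10

    def test_scale_normalization(self):
        scales = PAACParams().scale_matrix()
        np.testing.assert_allclose(scales.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(scales.std(axis=1), 1.0, atol=1e-12)


class TestScalarFeatures:
    @pytest.mark.parametrize(
        "seq,expected",
        [("AAAA", 0.0), ("ADGF", math.log(4)), (ALPHABET, math.log(20))],
    )
    def test_entropy_values(self, seq, expected):
        assert shannon_entropy(seq) == pytest.approx(expected)

    def test_entropy_bounds_and_homopolymer_iff_zero(self, random_peptides):
        for seq in random_peptides:
            h = shannon_entropy(seq)
            assert 0.0 <= h <= math.log(20) + 1e-12
            assert (h == 0.0) == (len(set(seq)) == 1)

    @pytest.mark.parametrize(
        "seq,expected", [("AA", 1.8), ("KK", -3.9), ("AILV", 3.575)]
    )
    def test_gravy(self, seq, expected):
        assert gravy(seq) == pytest.approx(expected)

    def test_gravy_matches_reference_scale(self):
        # cross-check our pinned Kyte-Doolittle table against Biopython's
        from Bio.SeqUtils.ProtParamData import kd

        assert kd == KYTE_DOOLITTLE
        from Bio.SeqUtils.ProtParamData import hw

        assert hw == HOPP_WOODS

    def test_molecular_weight(self):
        assert molecular_weight("G") == pytest.approx(75.07, abs=0.01)
        assert molecular_weight("GG") == pytest.approx(132.12, abs=0.01)

    def test_molecular_weight_peptide_bond_additivity(self):
        s1, s2 = "KLWK", "ADGFY"
        assert molecular_weight(s1 + s2) == pytest.approx(
            molecular_weight(s1) + molecular_weight(s2) - 18.02
        )

    def test_permutation_invariance(self):
        seq = ACP_SEQ
        perm = "".join(sorted(seq))
        assert gravy(seq) == pytest.approx(gravy(perm))
        assert molecular_weight(seq) == pytest.approx(molecular_weight(perm))
        assert charge_at_ph(seq) == pytest.approx(charge_at_ph(perm))


class TestCharge:
    def test_strictly_decreasing_in_ph(self, random_peptides):
        for seq in random_peptides[:20]:
            charges = [charge_at_ph(seq, ChargeParams(ph=ph)) for ph in
                       (1, 3, 5, 7, 9, 11, 13)]
            assert all(a > b for a, b in zip(charges, charges[1:]))

    def test_two_term_hand_evaluation(self):
        # GG has only termini ionizable; at pH = pKa(N-term) the basic term
        # is exactly +1/2 and the C-term is nearly fully deprotonated
        params = ChargeParams(ph=8.6)
        expected = 0.5 - 1.0 / (1.0 + 10.0 ** (3.6 - 8.6))
        assert charge_at_ph("GG", params) == pytest.approx(expected, abs=1e-12)

    def test_polylysine_limit_at_low_ph(self):
        # four K side chains + N-terminus essentially fully protonated
        assert charge_at_ph("KKKK", ChargeParams(ph=1.0)) == pytest.approx(5.0, abs=0.01)

    def test_cationic_acp_positive_at_neutral_ph(self):
        assert charge_at_ph(ACP_SEQ, ChargeParams(ph=7.0)) > 3.0


class TestManualFeatureVector:
    def test_dimension_is_35(self):
        vec = manual_features(ACP_SEQ).to_array()
        assert vec.shape == (35,)
        assert len(features.FEATURE_NAMES) == 35

    def test_homopolymer_composite(self):
        v = manual_features("AAAAAAAAAAAA")
        assert v.paac[0] == pytest.approx(1.0)
        assert v.shannon == 0.0
        assert v.gravy == pytest.approx(1.8)
        assert v.length == 12

    def test_composition_consistency(self):
        # the composite vector equals the concatenation of the parts
        v = manual_features(ACP_SEQ)
        arr = v.to_array()
        np.testing.assert_allclose(arr[:30], paac(ACP_SEQ))
        assert arr[30] == len(ACP_SEQ)
        assert arr[31] == pytest.approx(shannon_entropy(ACP_SEQ))
        assert arr[32] == pytest.approx(gravy(ACP_SEQ))
        assert arr[33] == pytest.approx(molecular_weight(ACP_SEQ))
        assert arr[34] == pytest.approx(charge_at_ph(ACP_SEQ))


class TestIndexEncoding:
    def test_mapping_and_padding(self):
        enc = index_encode("ADGF", 6)
        np.testing.assert_array_equal(enc.indices, [1, 3, 6, 5, 0, 0])
        assert enc.true_length == 4

    def test_single_residue(self):
        np.testing.assert_array_equal(index_encode("A", 1).indices, [1])

    def test_round_trip(self, random_peptides):
        for seq in random_peptides[:20]:
            assert decode_indices(index_encode(seq, 80)) == seq

    def test_truncation_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="acpfuse.features"):
            enc = index_encode("ADGFADGF", 4)
        assert enc.true_length == 4
        assert "truncated" in caplog.text


class TestFeaturizeDataset:
    def _dataset(self, seqs, label=1):
        return LabeledDataset(
            [Peptide(id=f"p{i}", seq=s, label=label) for i, s in enumerate(seqs)]
        )

    def test_shapes_and_determinism(self, random_peptides):
        ds = self._dataset(random_peptides[:20])
        m1, e1, y1 = featurize_dataset(ds, max_len=60)
        m2, e2, y2 = featurize_dataset(ds, max_len=60)
        assert m1.shape == (20, 35) and e1.shape == (20, 60) and y1.shape == (20,)
        np.testing.assert_array_equal(m1, m2)
        np.testing.assert_array_equal(e1, e2)

    def test_failing_sequence_reported_with_id(self):
        ds = self._dataset(["KLWKKIEKLIKKLLTSIR", "ADGFADGF"])  # second too short
        with pytest.raises(ValueError, match="p1"):
            featurize_dataset(ds)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            featurize_dataset(LabeledDataset([]))
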