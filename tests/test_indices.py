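import math

import numpy as np
import pytest
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from hypothesis import given, settings
from hypothesis import strategies as st

import codonforge as cf
from codonforge.exceptions import UndefinedStatisticError

from _oracles import wright_enc_oracle


def table(counts):
    return cf.CodonCountTable(counts)


class TestRSCU:
    def test_published_phe_counts(self, code):
        values = cf.rscu(table({"TTT": 6873, "TTC": 2665}), code)
        assert round(values["TTC"], 2) == 0.56
        assert round(values["TTT"], 2) == 1.44

    def test_published_sixfold_arg_counts(self, code):
        counts = {"CGT": 5325, "CGC": 1765, "CGA": 2696, "CGG": 892,
                  "AGA": 3524, "AGG": 1169}
        assert round(cf.rscu(table(counts), code)["CGT"], 2) == 2.08

    def test_uniform_family_is_one(self, code):
        values = cf.rscu(table({"GCT": 10, "GCC": 10, "GCA": 10, "GCG": 10}),
                         code)
        assert all(values[c] == pytest.approx(1.0)
                   for c in ("GCT", "GCC", "GCA", "GCG"))

    def test_absent_family_undefined_not_zero(self, code):
        values = cf.rscu(table({"GCT": 5}), code)
        assert math.isnan(values["TGT"])  # Cys family unobserved

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_family_sums_equal_degeneracy(self, seed):
        """Sum of RSCU over an observed family equals its codon count."""
        code = cf.default_code()
        rng = np.random.default_rng(seed)
        counts = {c: int(rng.integers(0, 40)) for c in code.sense_codons}
        if sum(counts.values()) == 0:
            counts["GCT"] = 1
        values = cf.rscu(table(counts), code)
        for aa, family in code.families.items():
            if sum(counts[c] for c in family) > 0:
                assert sum(values[c] for c in family) == \
                    pytest.approx(len(family))


class TestENC:
    def test_uniform_usage_is_61(self, code):
        t = table({c: 20 for c in code.sense_codons})
        assert cf.enc(t, code) == 61.0

    def test_single_codon_per_family_is_20(self, code):
        t = table({family[0]: 50 for family in code.families.values()})
        assert cf.enc(t, code) == pytest.approx(20.0)

    def test_clamp_at_61_and_raw_value(self, code):
        # small-sample evenness can push the raw estimate beyond 61
        t = table({c: 2 for c in code.sense_codons})
        assert cf.enc(t, code) == 61.0
        assert cf.enc(t, code, clamp=False) > 61.0

    def test_matches_brute_force_oracle_on_toy_gene(self, code):
        rng = np.random.default_rng(42)
        codons = list(code.sense_codons)
        draw = rng.choice(len(codons), size=200,
                          p=rng.dirichlet(np.ones(len(codons))))
        counts = {}
        for k in draw:
            counts[codons[k]] = counts.get(codons[k], 0) + 1
        expected = wright_enc_oracle(counts, dict(code.families))
        assert cf.enc(table(counts), code) == pytest.approx(expected)

    def test_undefined_when_no_family_estimable(self, code):
        with pytest.raises(UndefinedStatisticError):
            cf.enc(table({"ATG": 10, "TGG": 5, "GCT": 1}), code)


class TestCAI:
    def test_weights_hand_division(self, code):
        weights = cf.cai_weights([table({"GAA": 90, "GAG": 10})], code)
        assert weights.w["GAA"] == 1.0
        assert weights.w["GAG"] == pytest.approx(1 / 9)

    def test_equal_counts_both_weight_one(self, code):
        weights = cf.cai_weights([table({"TTT": 5, "TTC": 5})], code)
        assert weights.w["TTT"] == weights.w["TTC"] == 1.0

    def test_zero_count_codon_floored(self, code):
        weights = cf.cai_weights([table({"GAA": 90})], code)
        assert weights.w["GAG"] == 0.01

    def test_max_weight_gene_scores_one(self, code):
        weights = cf.cai_weights([table({"GAA": 90, "GAG": 10})], code)
        assert cf.cai(table({"GAA": 30}), weights) == pytest.approx(1.0)

    def test_geometric_mean_two_codons(self, code):
        weights = cf.cai_weights(
            [table({"GAA": 100, "GAG": 25, "TTT": 100, "TTC": 100})], code)
        gene = table({"GAA": 1, "GAG": 1})
        assert cf.cai(gene, weights) == pytest.approx(math.sqrt(0.25))

    def test_no_eligible_codons_undefined(self, code):
        weights = cf.cai_weights([table({"GAA": 90, "GAG": 10})], code)
        with pytest.raises(UndefinedStatisticError):
            cf.cai(table({"ATG": 5, "TGG": 2}), weights)

    def test_reference_scores_at_least_uniform_gene(self, code):
        """The reference's own pooled CAI is >= that of uniform usage."""
        ref = table({"GAA": 90, "GAG": 10, "TTT": 80, "TTC": 20})
        weights = cf.cai_weights([ref], code)
        uniform = table({"GAA": 1, "GAG": 1, "TTT": 1, "TTC": 1})
        assert cf.cai(ref, weights) >= cf.cai(uniform, weights)


class TestSCUO:
    def test_uniform_usage_is_zero(self, code):
        t = table({c: 10 for c in code.sense_codons})
        assert cf.scuo(t, code) == pytest.approx(0.0, abs=1e-12)

    def test_single_codon_per_family_is_one(self, code):
        t = table({family[0]: 50 for family in code.families.values()})
        assert cf.scuo(t, code) == pytest.approx(1.0)

    def test_hand_entropy_twofold_family(self, code):
        # one two-codon family at p = (0.75, 0.25)
        t = table({"TTT": 75, "TTC": 25})
        h = -(0.75 * math.log(0.75) + 0.25 * math.log(0.25))
        expected = (math.log(2) - h) / math.log(2)
        assert cf.scuo(t, code) == pytest.approx(expected)
        assert expected == pytest.approx(0.1887, abs=5e-4)

    def test_met_trp_only_undefined(self, code):
        with pytest.raises(UndefinedStatisticError):
            cf.scuo(table({"ATG": 5, "TGG": 5}), code)


def test_scuo_and_enc_move_oppositely_on_bias_sweep(code):
    """Sweeping a two-codon family from even to exclusive usage makes
    SCUO non-decreasing and ENC non-increasing."""
    background = {family[0]: 30 for family in code.families.values()
                  if family[0] not in ("TTT",)}
    scuos, encs = [], []
    for n_ttt in (50, 60, 75, 90, 100):
        counts = dict(background)
        counts["TTT"] = n_ttt
        counts["TTC"] = 100 - n_ttt
        t = table(counts)
        scuos.append(cf.scuo(t, code))
        encs.append(cf.enc(t, code))
    assert all(b >= a - 1e-12 for a, b in zip(scuos, scuos[1:]))
    assert all(b <= a + 1e-12 for a, b in zip(encs, encs[1:]))


class TestProteinIndices:
    def test_all_ile_gravy(self, code):
        assert cf.gravy(table({"ATT": 10}), code) == pytest.approx(4.5)

    def test_gravy_matches_biopython_on_translated_protein(self, code):
        seq = "ATGGCTTTCAAAGAACGTTGGTATCCG"  # MAFKERWYP
        t = cf.codon_counts(seq, code)
        expected = ProteinAnalysis("MAFKERWYP").gravy()
        assert cf.gravy(t, code) == pytest.approx(expected)

    def test_aromaticity_extremes(self, code):
        fyw = table({"TTT": 1, "TAT": 1, "TGG": 1})
        assert cf.aromaticity(fyw, code) == 1.0
        none = table({"GCT": 3, "AAA": 2})
        assert cf.aromaticity(none, code) == 0.0


class TestAggregateUsage:
    def test_pooled_counts_and_rscu(self, code):
        genes = [table({"TTT": 1}), table({"TTT": 2, "TTC": 1})]
        out = cf.aggregate_usage_table(genes, code).set_index("codon")
        assert out.loc["TTT", "n"] == 3 and out.loc["TTC", "n"] == 1
        assert out.loc["TTT", "rscu"] == pytest.approx(1.5)

    def test_single_gene_equals_own_rscu(self, code):
        counts = {"GCT": 4, "GCC": 2, "TTT": 3, "TTC": 1}
        out = cf.aggregate_usage_table([table(counts)], code)
        own = cf.rscu(table(counts), code)
        merged = out.set_index("codon")
        for codon in counts:
            assert merged.loc[codon, "rscu"] == pytest.approx(own[codon])

    def test_ter_rows_present_and_n_conserved(self, code):
        genes = [table({"GCT": 5, "TAA": 1}), table({"GCC": 2, "TGA": 1})]
        out = cf.aggregate_usage_table(genes, code)
        assert set(out.loc[out["amino_acid"] == "TER", "codon"]) == \
            {"TAA", "TAG", "TGA"}
        assert out["n"].sum() == 9
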