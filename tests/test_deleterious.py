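import itertools

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from stockload.deleterious import (
    AA_CATEGORY, AnnotatedLocus, ProteinHit, annotate_codon_change,
    class_frequency_table, classify_effect, filter_protein_hits, load_ratio,
    load_summary, translate_codon,
)
from stockload.genotype_io import MISSING
from stockload.popgen_stats import diversity_summary

from conftest import make_genotypes, two_pop_map


def hit(ref, alt, score=None, lid="L1"):
    return ProteinHit(lid, 26, 26, 1.0, ref, alt, score)


class TestFilterProteinHits:
    def test_thresholds(self):
        kept, counts = filter_protein_hits([
            ProteinHit("a", 26, 26, 1.0, "AAA", "AAG"),
            ProteinHit("b", 26, 20, 1.0, "AAA", "AAG"),
            ProteinHit("c", 26, 26, 0.90, "AAA", "AAG"),
        ])
        assert [h.locus_id for h in kept] == ["a"]
        assert counts == {"identities": 1, "percent_identity": 1}

    def test_boundary_25_of_26_retained(self):
        # 25/26 = 96.2% passes both >= thresholds
        kept, _ = filter_protein_hits([ProteinHit("a", 26, 25, 25 / 26, "AAA", "AAG")])
        assert len(kept) == 1
        assert 25 / 26 == pytest.approx(0.962, abs=5e-4)


class TestAnnotateCodonChange:
    @pytest.mark.parametrize("ref,alt,synonymy,directed", [
        ("GCT", "GCC", "synonymous", None),
        ("AAA", "GAA", "nonsynonymous", ("Pos", "Neg")),   # Lys -> Glu
        ("GAT", "GAA", "nonsynonymous", ("Neg", "Neg")),   # Asp -> Glu
    ])
    def test_known_changes(self, ref, alt, synonymy, directed):
        a = annotate_codon_change(hit(ref, alt))
        assert a.synonymy == synonymy
        assert a.directed_class == directed

    def test_stop_gain_flagged_nonsense(self):
        a = annotate_codon_change(hit("TAC", "TAA"))
        assert a.synonymy == "nonsense"
        assert a.directed_class is None

    def test_multiple_differences_rejected(self):
        with pytest.raises(ValueError, match="2 positions"):
            annotate_codon_change(hit("AAA", "GGA"))

    def test_synonymy_matches_exhaustive_neighbor_enumeration(self, rng):
        """Check all 9 single-nucleotide neighbors of 50 random codons
        against a biopython-translation oracle."""
        bases = "ACGT"
        codons = ["".join(rng.choice(list(bases), 3)) for _ in range(50)]
        for c in codons:
            if str(Seq(c).translate()) == "*":
                continue
            for pos, b in itertools.product(range(3), bases):
                if b == c[pos]:
                    continue
                c2 = c[:pos] + b + c[pos + 1:]
                a = annotate_codon_change(hit(c, c2))
                aa1, aa2 = str(Seq(c).translate()), str(Seq(c2).translate())
                if aa2 == "*":
                    assert a.synonymy == "nonsense"
                elif aa1 == aa2:
                    assert a.synonymy == "synonymous"
                else:
                    assert a.synonymy == "nonsynonymous"

    def test_undirected_collapse_conserves_counts(self, rng):
        """Folding directed classes onto unordered pairs is a surjection
        that preserves total counts."""
        cats = sorted(set(AA_CATEGORY.values()) - {"Sel"})
        directed = [(a, b) for a in cats for b in cats if a != b]
        counts = {d: int(rng.integers(1, 10)) for d in directed}
        undirected = {}
        for (a, b), k in counts.items():
            undirected[frozenset((a, b))] = undirected.get(frozenset((a, b)), 0) + k
        assert sum(undirected.values()) == sum(counts.values())
        assert all(len(u) == 2 for u in undirected)


class TestClassifyEffect:
    def test_boundaries(self):
        assert classify_effect(-3.1) == "deleterious"
        assert classify_effect(-2.5) == "unclassified"
        assert classify_effect(0.4) == "neutral"
        assert classify_effect(None) == "unclassified"

    def test_counts_match_brute_force(self, rng):
        scores = rng.normal(-2.5, 2.0, size=50)
        classes = [classify_effect(s) for s in scores]
        assert classes.count("deleterious") == int((scores < -2.5).sum())
        assert classes.count("neutral") == int((scores > -2.5).sum())


class TestLoadRatio:
    def test_printed_row_tu(self):
        assert load_ratio(0.69, 2549, 4982) == pytest.approx(1.35, abs=0.01)

    def test_printed_row_ca(self):
        assert load_ratio(0.57, 2454, 4982) == pytest.approx(1.16, abs=0.02)

    def test_identity_when_proportions_equal(self):
        assert load_ratio(2549 / 4982, 2549, 4982) == pytest.approx(1.0)

    def test_scale_free(self):
        assert load_ratio(0.5, 100, 400) == pytest.approx(load_ratio(0.5, 300, 1200))

    def test_zero_polymorphic_raises(self):
        with pytest.raises(ZeroDivisionError):
            load_ratio(0.5, 0, 100)


def annotated(lid, effect_class, score=-5.0):
    if effect_class == "deleterious":
        return AnnotatedLocus(lid, "nonsynonymous", "K", "E", "Pos", "Neg",
                              ("Pos", "Neg"), frozenset(("Pos", "Neg")), score,
                              "deleterious")
    if effect_class == "neutral":
        return AnnotatedLocus(lid, "nonsynonymous", "D", "E", "Neg", "Neg",
                              ("Neg", "Neg"), frozenset(("Neg",)), 0.5, "neutral")
    return AnnotatedLocus(lid, "synonymous", "A", "A", "Hyd", "Hyd",
                          None, None, None, "unclassified")


class TestLoadSummary:
    def build(self):
        # 2 pops x 6 SNPs; loci L0..L5; L0,L1,L2 deleterious, L3 neutral, L4,L5 syn
        # pop A (rows 0-3), pop B (rows 4-7)
        d = np.array([
            # L0: global minor = alt; A carries it, B does not
            [1, 2, 0, 0, 1, 0],
            [0, 2, 0, 0, 1, 0],
            [0, 2, 0, 1, 0, 0],
            [1, 2, 0, 1, 0, 0],
            # pop B
            [0, 2, 2, 0, 1, 1],
            [0, 2, 2, 0, 1, 0],
            [0, 2, 2, 1, 2, 0],
            [0, 2, 2, 0, 0, 1],
        ], dtype=np.int8)
        g = make_genotypes(d, locus_ids=[f"L{j}" for j in range(6)])
        pm = two_pop_map(g, 4)
        ann = [annotated("L0", "deleterious"), annotated("L1", "deleterious"),
               annotated("L2", "deleterious"), annotated("L3", "neutral"),
               annotated("L4", "syn"), annotated("L5", "syn")]
        return g, pm, ann

    def test_hand_planted_panel(self):
        g, pm, ann = self.build()
        div = diversity_summary(g, pm)
        ls = load_summary(g, pm, ann, div)
        # L1 is fixed alt everywhere -> global freq 1 -> minor allele is REF,
        # local minor freq 0 in both pops -> absent
        # L0: global alt freq 2/16 -> minor is alt; A freq 0.25, B freq 0
        # L2: global alt freq 8/16 = 0.5 -> not > 0.5, minor stays alt;
        #     A freq 0, B freq 1 (fixed deleterious in B)
        a, b = ls.loc["A"], ls.loc["B"]
        assert a["del_present"] == 1 and b["del_present"] == 1
        assert a["del_proportion"] == pytest.approx(1 / 3)
        assert b["n_fixed_del"] == 1 and a["n_fixed_del"] == 0
        assert a["mean_del_maf"] == pytest.approx(0.25)
        assert b["mean_del_maf"] == pytest.approx(1.0)
        # load ratio = del_proportion / prop_polymorphic
        assert a["load_ratio"] == pytest.approx(
            (1 / 3) / float(div.loc["A", "prop_polymorphic"]))

    def test_fixed_allele_counts_as_present_and_fixed(self):
        g, pm, ann = self.build()
        ls = load_summary(g, pm, ann, diversity_summary(g, pm))
        assert ls.loc["B", "del_present"] >= ls.loc["B", "n_fixed_del"] == 1

    def test_population_without_deleterious_alleles(self):
        d = np.array([[0, 0], [0, 0], [1, 1], [1, 1]], dtype=np.int8)
        g = make_genotypes(d, locus_ids=["L0", "L1"])
        pm = two_pop_map(g, 2)
        ann = [annotated("L0", "deleterious"), annotated("L1", "deleterious")]
        ls = load_summary(g, pm, ann, diversity_summary(g, pm))
        assert ls.loc["A", "del_present"] == 0
        assert ls.loc["A", "del_proportion"] == 0

    def test_no_deleterious_raises(self):
        g, pm, _ = self.build()
        with pytest.raises(ValueError):
            load_summary(g, pm, [annotated("L4", "syn")],
                         diversity_summary(g, pm))


class TestClassFrequencyTable:
    def test_classes_and_orientation(self):
        d = np.array([[2, 0], [2, 1], [2, 0], [2, 1]], dtype=np.int8)
        g = make_genotypes(d, locus_ids=["L0", "L1"])
        pm = pd.Series(["A"] * 4, index=g.individual_ids)
        ann = [annotated("L0", "deleterious"), annotated("L1", "syn")]
        tab = class_frequency_table(g, pm, ann)
        # L0 fixed alt: global freq 1 -> minor is ref -> local freq 0
        del_rows = tab[tab.snp_class == "deleterious"]
        assert del_rows["freq"].iloc[0] == 0.0
        syn_rows = tab[tab.snp_class == "synonymous"]
        assert syn_rows["freq"].iloc[0] == pytest.approx(0.25)
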