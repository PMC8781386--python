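import itertools

import numpy as np
import pytest

from tandemshm import tandems
from tandemshm.io_model import (
    ALL_DINUCLEOTIDES,
    DbsCatalog,
    DinucSubstitutionTable,
    NUCLEOTIDES,
    SubstitutionEvent,
    ValidationError,
    legal_outcomes,
    reverse_complement,
)

from conftest import make_allele


def tdns(ref, alt, start=0, allele="A*01"):
    return SubstitutionEvent(
        allele_name=allele, start=start, germline_bases=ref, observed_bases=alt
    )


class TestClassification:
    def test_inversion_example(self):
        assert tandems.classify_outcome("AG", "GA") == tandems.INVERSION

    def test_swap_example(self):
        # AG -> CA: the germline 5' base A reappears at the 3' slot
        assert tandems.classify_outcome("AG", "CA") == tandems.JUXTALOCATION_5P

    def test_other_example(self):
        assert tandems.classify_outcome("AC", "GT") == tandems.OTHER

    def test_3p_juxtalocation(self):
        # AG -> GC: the germline 3' base G reappears at the 5' slot
        assert tandems.classify_outcome("AG", "GC") == tandems.JUXTALOCATION_3P

    def test_homodimer_always_other(self):
        for ref in ("AA", "CC", "GG", "TT"):
            for alt in legal_outcomes(ref):
                assert tandems.classify_outcome(ref, alt) == tandems.OTHER

    def test_illegal_pair_rejected(self):
        with pytest.raises(ValidationError):
            tandems.classify_outcome("AG", "AG")

    def test_k_guard(self):
        with pytest.raises(ValidationError):
            tandems.classify_tdns(tdns("A", "G"))

    def test_event_wrapper(self):
        assert tandems.classify_tdns(tdns("AG", "GA")) == tandems.INVERSION

    def test_enumeration_oracle(self):
        """Brute-force enumeration over the 108 heterodimer pairs.

        The oracle classifies by first principles (positional equality of
        germline bases in the outcome) independently of the implementation.
        """
        oracle_counts = {"inversion": 0, "juxtalocation": 0, "other": 0}
        impl_counts = {"inversion": 0, "juxtalocation": 0, "other": 0}
        n_pairs = 0
        for x, y in itertools.product(NUCLEOTIDES, repeat=2):
            if x == y:
                continue
            for xp, yp in itertools.product(NUCLEOTIDES, repeat=2):
                if xp == x or yp == y:
                    continue
                n_pairs += 1
                if xp == y and yp == x:
                    oracle_counts["inversion"] += 1
                elif xp == y or yp == x:
                    oracle_counts["juxtalocation"] += 1
                else:
                    oracle_counts["other"] += 1
                cat = tandems.classify_outcome(x + y, xp + yp)
                if cat == tandems.INVERSION:
                    impl_counts["inversion"] += 1
                elif cat in (tandems.JUXTALOCATION_5P, tandems.JUXTALOCATION_3P):
                    impl_counts["juxtalocation"] += 1
                else:
                    impl_counts["other"] += 1
        assert n_pairs == 108
        assert oracle_counts == {"inversion": 12, "juxtalocation": 48, "other": 48}
        assert impl_counts == oracle_counts


class TestExpectedFractions:
    def test_values(self):
        expected = tandems.expected_category_fractions()
        assert expected["inversion"] == pytest.approx(1 / 9)
        assert expected["juxtalocation"] == pytest.approx(4 / 9)
        assert expected["other"] == pytest.approx(4 / 9)
        assert sum(expected.values()) == pytest.approx(1.0)


class TestFractionTest:
    def test_exact_match(self):
        z, p = tandems.compare_fraction_to_expected(100, 900, 1 / 9)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_extreme(self):
        _, p = tandems.compare_fraction_to_expected(900, 900, 1 / 9)
        assert p < 1e-6

    def test_guards(self):
        with pytest.raises(ValidationError):
            tandems.compare_fraction_to_expected(1, 0, 0.5)
        with pytest.raises(ValidationError):
            tandems.compare_fraction_to_expected(1, 10, 1.5)


class TestCodonSlot:
    @pytest.mark.parametrize("start,slot", [(0, 1), (1, 2), (2, 3), (3, 1), (5, 3)])
    def test_slots(self, start, slot):
        allele = make_allele("ACGTACGTA")
        event = tdns("XX", "YY", start=start)
        event.germline_bases = allele.ungapped[start : start + 2]
        event.observed_bases = "".join(
            "A" if b != "A" else "C" for b in event.germline_bases
        )
        assert tandems.assign_codon_slot(event, allele) == slot

    def test_frame_offset(self):
        allele = make_allele("GACGTACGTA", frame_offset=1)
        assert tandems.assign_codon_slot(tdns("AC", "CA", start=1), allele) == 1

    def test_upstream_of_frame(self):
        allele = make_allele("GACGTACGTA", frame_offset=1)
        with pytest.raises(ValidationError):
            tandems.assign_codon_slot(tdns("GA", "AG", start=0), allele)


class TestClassifyEffect:
    def test_sns_synonymous(self):
        allele = make_allele("CTGAAA")
        event = SubstitutionEvent(
            allele_name="A*01", start=2, germline_bases="G", observed_bases="A"
        )
        call = tandems.classify_effect(event, allele)
        assert call.effect == tandems.SYNONYMOUS  # CTG and CTA both encode Leu
        assert call.codon_slot == 3

    def test_slot2_nonsense(self):
        allele = make_allele("TGGAAA")
        call = tandems.classify_effect(tdns("GG", "AA", start=1), allele)
        assert call.codon_slot == 2
        assert call.effect == tandems.NONSENSE  # TGG -> TAA stop

    def test_slot3_mixed_is_nonsynonymous(self):
        # CTG|GGA -> CTA|AGA: Leu->Leu synonymous, Gly->Arg replacement
        allele = make_allele("CTGGGA")
        call = tandems.classify_effect(tdns("GG", "AA", start=2), allele)
        assert call.codon_slot == 3
        assert call.effect == tandems.NONSYNONYMOUS

    def test_slot3_double_synonymous(self):
        # CTG|CGA -> CTC|AGA: Leu->Leu and Arg->Arg
        allele = make_allele("CTGCGA")
        call = tandems.classify_effect(tdns("GC", "CA", start=2), allele)
        assert call.effect == tandems.DOUBLE_SYNONYMOUS

    def test_slot3_double_replacement(self):
        # AAA|CCC -> AAG? need both changed: AAA->AAT (Lys->Asn), CCC->GCC (Pro->Ala)
        allele = make_allele("AAACCC")
        call = tandems.classify_effect(tdns("AC", "TG", start=2), allele)
        assert call.effect == tandems.DOUBLE_REPLACEMENT

    def test_incomplete_trailing_codon_skipped(self):
        allele = make_allele("CTGA")  # second codon incomplete
        assert tandems.classify_effect(tdns("GA", "AG", start=2), allele) is None

    def test_oracle_all_single_substitutions(self, genetic_code):
        """classify_effect agrees with a hardcoded-code translator for all
        nine substitutions of every sense codon."""
        for codon, aa in genetic_code.items():
            if aa == "*":
                continue
            allele = make_allele(codon + "GGTGGT")
            for i in range(3):
                for b in NUCLEOTIDES:
                    if b == codon[i]:
                        continue
                    event = SubstitutionEvent(
                        allele_name="A*01", start=i,
                        germline_bases=codon[i], observed_bases=b,
                    )
                    call = tandems.classify_effect(event, allele)
                    mutated = codon[:i] + b + codon[i + 1 :]
                    expected_aa = genetic_code[mutated]
                    if expected_aa == "*":
                        assert call.effect == tandems.NONSENSE
                    elif expected_aa == aa:
                        assert call.effect == tandems.SYNONYMOUS
                    else:
                        assert call.effect == tandems.NONSYNONYMOUS
                    assert call.codon_slot == i + 1


class TestGermlineContext:
    def test_both(self):
        # germline T[CT]C: both the -1 window TC and the +1 window TC match
        allele = make_allele("TCTC")
        assert (
            tandems.germline_context_containment(tdns("CT", "TC", start=1), allele)
            == tandems.BOTH
        )

    def test_not_present(self):
        allele = make_allele("AAGT")
        assert (
            tandems.germline_context_containment(tdns("AG", "GA", start=1), allele)
            == tandems.NOT_PRESENT
        )

    def test_pos_minus1_only(self):
        # germline GA[AG]T: -1 window AA... pick GA TDNS with obs "AA"
        allele = make_allele("GAAGT")
        event = tdns("AG", "GA", start=2)
        # -1 window = germline[1:3] = "AA" != "GA"; +1 window = germline[3:5] = "GT"
        assert tandems.germline_context_containment(event, allele) == tandems.NOT_PRESENT
        event2 = tdns("AG", "GT", start=2)
        # +1 window "GT" matches
        assert tandems.germline_context_containment(event2, allele) == tandems.POS_T2

    def test_boundary_never_matches(self):
        allele = make_allele("CTAG")
        event = tdns("CT", "GA", start=0)
        assert tandems.germline_context_containment(event, allele) == tandems.NOT_PRESENT


class TestMotifs:
    def test_wrcy_forward_5p(self):
        # TACT is WRCY (W=T, R=A, C, Y=T) with the C at position 2
        allele = make_allele("TACTG")
        annotation = tandems.annotate_aid_motifs(tdns("CT", "TC", start=2), allele)
        assert annotation[("WRCY", "5p", "forward")]

    def test_wa_forward_sns(self):
        allele = make_allele("GTAAC")
        event = SubstitutionEvent(
            allele_name="A*01", start=2, germline_bases="A", observed_bases="G"
        )
        annotation = tandems.annotate_aid_motifs(event, allele)
        assert annotation[("WA", "5p", "forward")]
        # a k=1 event's 5'-most and 3'-most base coincide
        assert annotation[("WA", "3p", "forward")]

    def test_no_match(self):
        allele = make_allele("GGGGG")
        annotation = tandems.annotate_aid_motifs(tdns("GG", "AA", start=1), allele)
        assert not annotation.any()

    def test_reverse_complement_motif(self):
        # coding strand AGCTA contains RGYW at 0 (A=R,G,C=Y,T=W)? A is R, G,
        # C is Y, T is W -> hotspot G at position 1
        allele = make_allele("AGCTA")
        event = SubstitutionEvent(
            allele_name="A*01", start=1, germline_bases="G", observed_bases="C"
        )
        annotation = tandems.annotate_aid_motifs(event, allele)
        assert annotation[("WRCY", "5p", "reverse_complement")]

    def test_hotspot_anchoring_is_strict(self):
        # WRCY present but its C is not at an event end -> no flag
        allele = make_allele("TACTG")
        event = SubstitutionEvent(
            allele_name="A*01", start=4, germline_bases="G", observed_bases="A"
        )
        annotation = tandems.annotate_aid_motifs(event, allele)
        assert not annotation[("WRCY", "5p", "forward")]
        assert not annotation[("WRCY", "3p", "forward")]


class TestDinucTable:
    def test_single_event(self):
        table = tandems.build_dinuc_table([tdns("AG", "GA")])
        assert table[("AG", "GA")] == 1
        assert table.total == 1

    def test_double_count(self):
        table = tandems.build_dinuc_table([tdns("AG", "GA"), tdns("AG", "GA")])
        assert table[("AG", "GA")] == 2

    def test_empty(self):
        assert tandems.build_dinuc_table([]).total == 0

    def test_k1_rejected(self):
        with pytest.raises(ValidationError):
            tandems.build_dinuc_table([tdns("A", "G")])


class TestDbs78Collapse:
    def test_known_cells(self):
        table = DinucSubstitutionTable()
        table.increment("GA", "TT")
        catalog = tandems.to_dbs78(table)
        assert catalog["TC>AA"] == 1

        table2 = DinucSubstitutionTable()
        table2.increment("AC", "GT")
        assert tandems.to_dbs78(table2)["AC>GT"] == 1

    def test_mass_conservation(self, rng):
        table = DinucSubstitutionTable()
        for _ in range(50):
            ref = str(rng.choice(ALL_DINUCLEOTIDES))
            alt = str(rng.choice(legal_outcomes(ref)))
            table.increment(ref, alt, float(rng.integers(1, 5)))
        assert tandems.to_dbs78(table).total == pytest.approx(table.total)

    def test_reverse_complement_invariance(self, rng):
        table = DinucSubstitutionTable()
        for _ in range(50):
            ref = str(rng.choice(ALL_DINUCLEOTIDES))
            alt = str(rng.choice(legal_outcomes(ref)))
            table.increment(ref, alt)
        a = tandems.to_dbs78(table)
        b = tandems.to_dbs78(table.reverse_complemented())
        assert np.array_equal(a.values, b.values)


class TestCosine:
    def test_self_similarity(self, rng):
        v = rng.random(78)
        catalog = DbsCatalog(v)
        assert tandems.cosine_similarity(catalog, catalog) == pytest.approx(1.0)

    def test_disjoint(self):
        a = np.zeros(78)
        b = np.zeros(78)
        a[0] = 1
        b[1] = 1
        assert tandems.cosine_similarity(DbsCatalog(a), DbsCatalog(b)) == 0.0

    def test_closed_form(self):
        a = np.zeros(78)
        b = np.zeros(78)
        a[0] = a[1] = 1
        b[0] = 1
        assert tandems.cosine_similarity(DbsCatalog(a), DbsCatalog(b)) == pytest.approx(
            1 / np.sqrt(2)
        )

    def test_symmetry_and_scale_invariance(self, rng):
        a = DbsCatalog(rng.random(78))
        b = DbsCatalog(rng.random(78))
        assert tandems.cosine_similarity(a, b) == pytest.approx(
            tandems.cosine_similarity(b, a)
        )
        scaled = DbsCatalog(a.values * 7.5)
        assert tandems.cosine_similarity(scaled, b) == pytest.approx(
            tandems.cosine_similarity(a, b)
        )

    def test_zero_vector_rejected(self):
        with pytest.raises(ValidationError):
            tandems.cosine_similarity(DbsCatalog.zeros(), DbsCatalog(np.ones(78)))
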