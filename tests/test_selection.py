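"""ORF detection, NG86 site counting, SNV classification and dN/dS."""

import math

import pytest
from Bio.Seq import Seq
from hypothesis import given
from hypothesis import strategies as st

from castevar import (
    DegenerateInputError,
    ReferenceMismatchError,
    SNVRecord,
    SaturationError,
    dnds_from_counts,
    find_longest_orf,
    jc_distance,
    ng86_site_counts,
)
from castevar.selection import (
    CODON_TO_AA,
    NONCODING,
    NONSYNONYMOUS,
    STOP_CODONS,
    SYNONYMOUS,
    classify_snv,
    find_longest_orf as _flo,
)

BASES = "ACGT"


class TestFindLongestOrf:
    @pytest.mark.parametrize(
        "seq, start, end",
        [
            ("ATGAAATAA", 1, 9),
            # length 12 at start 12 beats length 9 at start 3
            ("CCATGGCCTAAATGAAAGGGTGA", 12, 23),
            ("atgaaataa", 1, 9),  # case-insensitive
            ("AUGAAAUAA", 1, 9),  # RNA input normalised
        ],
    )
    def test_examples(self, seq, start, end):
        orf = find_longest_orf(seq, "t")
        assert (orf.start, orf.end) == (start, end)
        assert orf.length % 3 == 0

    @pytest.mark.parametrize("seq", ["AAACCCGGG", "ATGAAAAAA", "TAAATG", ""])
    def test_no_bounded_orf(self, seq):
        # no ATG, or no in-frame stop after the ATG
        assert find_longest_orf(seq) is None

    def test_tie_broken_by_smallest_start(self):
        # two ORFs of 9 nt in different frames; the earlier start wins
        seq = "ATGAAATAAA" + "ATGCCCTAG"
        orf = find_longest_orf(seq)
        assert orf.start == 1

    def test_rejects_non_nucleotide(self):
        with pytest.raises(ValueError):
            find_longest_orf("ATGNNNTAA")

    def test_orf_invariants(self, small_study):
        reference, _, coding_table, _ = small_study
        for tid, coding in coding_table.items():
            orf = coding.orf
            seq = reference[tid]
            cds = seq[orf.start - 1 : orf.end]
            assert cds.startswith("ATG") and cds[-3:] in STOP_CODONS
            assert len(cds) % 3 == 0
            assert not any(
                cds[i : i + 3] in STOP_CODONS for i in range(0, len(cds) - 3, 3)
            )


def _oracle_codon_sites(codon):
    """Brute force: enumerate all 9 single-base changes, classify with the
    independent Biopython translator."""
    aa = str(Seq(codon).translate())
    syn = nonsyn = stop = 0
    for pos in range(3):
        for alt in BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            maa = str(Seq(mutant).translate())
            if maa == "*":
                stop += 1
            elif maa == aa:
                syn += 1
            else:
                nonsyn += 1
    return syn / 3, nonsyn / 3, stop / 3


class TestNg86SiteCounts:
    @pytest.mark.parametrize(
        "codon, syn, nonsyn",
        [("TTT", 1 / 3, 8 / 3), ("GGG", 1.0, 2.0), ("TGT", 1 / 3, 7 / 3)],
    )
    def test_single_codon_examples(self, codon, syn, nonsyn):
        sc = ng86_site_counts(codon)
        assert sc.syn_sites == pytest.approx(syn, abs=1e-12)
        assert sc.nonsyn_sites == pytest.approx(nonsyn, abs=1e-12)

    def test_matches_bruteforce_oracle_on_all_sense_codons(self):
        sense = [c for c in CODON_TO_AA if c not in STOP_CODONS]
        assert len(sense) == 61
        for codon in sense:
            syn, nonsyn, stop = _oracle_codon_sites(codon)
            sc = ng86_site_counts(codon)
            assert sc.syn_sites == syn, codon
            assert sc.nonsyn_sites == nonsyn, codon
            assert sc.stop_adjacent_sites == stop, codon

    def test_site_mass_conservation(self):
        seq = "ATGAAATGTGGGTTT"
        sc = ng86_site_counts(seq)
        assert sc.syn_sites + sc.nonsyn_sites + sc.stop_adjacent_sites == pytest.approx(
            3 * sc.n_codons
        )
        assert sc.n_codons == 5

    def test_terminal_stop_stripped_and_additive(self):
        with_stop = ng86_site_counts("ATGAAATAA")
        without = ng86_site_counts("ATG") + ng86_site_counts("AAA")
        assert with_stop.syn_sites == pytest.approx(without.syn_sites, abs=1e-12)
        assert with_stop.nonsyn_sites == pytest.approx(without.nonsyn_sites, abs=1e-12)

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            ng86_site_counts("ATGA")
        with pytest.raises(ValueError):
            ng86_site_counts("ATGTAAAAATAA")  # internal stop


class TestJcDistance:
    @pytest.mark.parametrize(
        "p, expected", [(0.0, 0.0), (0.1, 0.10733), (0.5, 0.82396)]
    )
    def test_closed_form(self, p, expected):
        assert jc_distance(p) == pytest.approx(expected, abs=1e-5)

    @pytest.mark.parametrize("p", [0.75, 0.9, 1.0])
    def test_saturation(self, p):
        with pytest.raises(SaturationError):
            jc_distance(p)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            jc_distance(-0.01)

    def test_small_p_limit(self):
        p = 1e-4
        assert abs(jc_distance(p) - p) / p < 1e-3

    @given(st.floats(min_value=0.0, max_value=0.74, allow_nan=False))
    def test_monotone_and_above_identity(self, p):
        d = jc_distance(p)
        assert d >= p * (1 - 1e-12)  # equality up to rounding as p -> 0
        assert jc_distance(min(p + 1e-6, 0.7400001)) >= d


class TestClassifySnv:
    REF = {"t1": "ATGAAATAA"}

    def _orf(self):
        return _flo(self.REF["t1"], "t1")

    @pytest.mark.parametrize(
        "pos, ref, alt, expected",
        [
            (6, "A", "G", SYNONYMOUS),     # AAA -> AAG, Lys -> Lys
            (4, "A", "C", NONSYNONYMOUS),  # AAA -> CAA, Lys -> Gln
            (5, "A", "T", NONSYNONYMOUS),  # AAA -> ATA, Lys -> Ile
            (8, "A", "G", NONCODING),      # inside terminal TAA
        ],
    )
    def test_examples(self, pos, ref, alt, expected):
        assert classify_snv(self._orf(), SNVRecord("t1", pos, ref, alt), self.REF) == expected

    def test_stopgain(self):
        # AAA codon, first base A>T gives TAA
        assert classify_snv(self._orf(), SNVRecord("t1", 4, "A", "T"), self.REF) == "stopgain"

    def test_reference_mismatch_raises(self):
        with pytest.raises(ReferenceMismatchError):
            classify_snv(self._orf(), SNVRecord("t1", 6, "C", "G"), self.REF)

    def test_no_orf_is_noncoding(self):
        ref = {"t2": "AAACCCGGG"}
        assert classify_snv(None, SNVRecord("t2", 2, "A", "G"), ref) == NONCODING


class TestDnDs:
    def test_hand_computed_example(self):
        est = dnds_from_counts(2, 4, 10, 40)
        assert est.p_s == pytest.approx(0.2)
        assert est.p_n == pytest.approx(0.1)
        assert est.d_s == pytest.approx(0.23262, abs=1e-4)
        assert est.d_n == pytest.approx(0.10733, abs=1e-4)
        assert est.ratio == pytest.approx(0.4614, abs=1e-4)

    def test_equal_proportions_give_unit_ratio(self):
        est = dnds_from_counts(3, 12, 30, 120)
        assert est.ratio == pytest.approx(1.0, abs=1e-12)

    def test_zero_syn_subs_gives_undefined_ratio(self):
        est = dnds_from_counts(0, 5, 10, 40)
        assert est.d_s == 0.0
        assert est.ratio is None

    def test_no_sites_raises(self):
        with pytest.raises(DegenerateInputError):
            dnds_from_counts(0, 0, 0.0, 0.0)

    def test_estimate_on_tiny_library(self):
        from castevar import LibraryVariants, estimate_dnds

        # ATG + 10x AAA + TAA: syn sites 10/3 (third positions of Lys only
        # partially; AAA -> AAG is the single synonymous change per codon)
        ref = {"t1": "ATG" + "AAA" * 10 + "TAA"}
        lib = LibraryVariants(
            "L",
            records=[
                SNVRecord("t1", 6, "A", "G", 50),   # synonymous (AAA->AAG)
                SNVRecord("t1", 7, "A", "C", 50),   # nonsynonymous (AAA->CAA)
                SNVRecord("t1", 35, "A", "G", 50),  # inside terminal TAA
            ],
        )
        est = estimate_dnds(lib, ref)
        assert est.n_syn == 1 and est.n_nonsyn == 1 and est.n_noncoding == 1
        from castevar.selection import ng86_site_counts as _sc

        sites = _sc("ATG" + "AAA" * 10)
        assert est.p_s == pytest.approx(1 / sites.syn_sites)
        assert est.p_n == pytest.approx(1 / sites.nonsyn_sites)
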