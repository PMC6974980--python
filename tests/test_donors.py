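"""Donor templates: arm arithmetic, PAM silencing, Coding-bar design, verification."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

import hdrquant as hq
from hdrquant.locus import ConfigurationError, Interval, Substitution, revcomp
from hdrquant.readproc import SubstitutionEvent


@pytest.fixture(scope="module")
def wide_locus_edit():
    """A 400 nt locus leaves room for 137 nt homology arms."""
    return hq.simulate_locus(1, amplicon_len=400)


@pytest.fixture(scope="module")
def core25(wide_locus_edit):
    """A 25 nt edited core containing the guide-covered window."""
    locus, edit = wide_locus_edit
    pats = hq.derive_patterns(locus, edit, hq.minimal_flank(locus, edit))
    return Interval(pats.pattern_interval.start - 1, pats.pattern_interval.end + 1)


class TestDonorAssembly:
    def test_lssdna_length_from_symmetric_arms(self, wide_locus_edit, core25):
        locus, edit = wide_locus_edit
        donor = hq.build_lssdna_donor(locus, edit, arm_len=137, core_interval=core25)
        assert len(donor.sequence) == 299  # 25 nt core + 2 * 137 nt arms
        assert donor.left_arm_len == donor.right_arm_len == 137
        assert hq.verify_donor(donor, locus, edit).passed

    def test_length_bookkeeping(self, wide_locus_edit, core25):
        locus, edit = wide_locus_edit
        donor = hq.build_lssdna_donor(locus, edit, arm_len=150, core_interval=core25)
        assert len(donor.sequence) == 300 + len(core25)

    def test_antisense_is_reverse_complement_of_sense(self, wide_locus_edit, core25):
        locus, edit = wide_locus_edit
        sense = hq.build_lssdna_donor(locus, edit, 60, "sense", core25)
        anti = hq.build_lssdna_donor(locus, edit, 60, "antisense", core25)
        assert anti.sequence == revcomp(sense.sequence)
        assert hq.verify_donor(anti, locus, edit).passed

    def test_arms_exceeding_context_report_shortfall(self, wide_locus_edit, core25):
        locus, edit = wide_locus_edit
        with pytest.raises(ConfigurationError, match="exceed"):
            hq.build_lssdna_donor(locus, edit, arm_len=400, core_interval=core25)

    def test_ssodn_symmetric_arm_split(self, wide_locus_edit, core25):
        locus, edit = wide_locus_edit
        donor = hq.build_ssodn(locus, edit, total_len=105, core_interval=core25)
        assert (donor.left_arm_len, donor.right_arm_len) == (40, 40)
        assert len(donor.sequence) == 105
        assert hq.verify_donor(donor, locus, edit).passed

    def test_ssodn_too_short_errors(self, wide_locus_edit, core25):
        locus, edit = wide_locus_edit
        with pytest.raises(ConfigurationError):
            hq.build_ssodn(locus, edit, total_len=26, core_interval=core25)

    def test_ssodn_asymmetric_split(self, wide_locus_edit, core25):
        locus, edit = wide_locus_edit
        donor = hq.build_ssodn(
            locus, edit, total_len=129, symmetry="asymmetric",
            asym_split=(36, 68), core_interval=core25,
        )
        assert donor.left_arm_len + donor.right_arm_len + len(core25) == 129
        with pytest.raises(ConfigurationError, match="asym_split"):
            hq.build_ssodn(locus, edit, total_len=129, symmetry="asymmetric",
                           core_interval=core25)

    def test_roundtrip_alignment_recovers_substitutions(self, wide_locus_edit, core25):
        """Aligning a donor back to the reference finds exactly the edit."""
        locus, edit = wide_locus_edit
        donor = hq.build_lssdna_donor(locus, edit, 137, core_interval=core25)
        res = hq.global_align(donor.sequence, locus.amplicon_seq)
        subs = {
            (d.position, d.alt)
            for d in res.diffs
            if isinstance(d, SubstitutionEvent)
        }
        assert subs == {(s.position, s.alt_base) for s in edit.substitutions}


class TestVerifyDonor:
    def test_intact_pam_fails_recut_check(self, wide_locus_edit, core25):
        locus, edit = wide_locus_edit
        # a donor built from an edit whose substitutions all sit outside the
        # guide window leaves the protospacer+PAM intact
        pats = hq.derive_patterns(locus, edit, hq.minimal_flank(locus, edit))
        pos = pats.pattern_interval.start - 20
        lone = hq.EditSpec(
            substitutions=(
                Substitution(pos, locus.amplicon_seq[pos],
                             "A" if locus.amplicon_seq[pos] != "A" else "C"),
            )
        )
        donor = hq.build_lssdna_donor(
            locus, lone, 60, core_interval=Interval(pos - 2, pats.pattern_interval.end)
        )
        report = hq.verify_donor(donor, locus, lone)
        failed = {c.name for c in report.failed_checks()}
        assert "recut_prevented" in failed

    def test_mutated_arm_reported_with_position(self, wide_locus_edit, core25):
        locus, edit = wide_locus_edit
        donor = hq.build_lssdna_donor(locus, edit, 137, core_interval=core25)
        seq = list(donor.sequence)
        seq[5] = "A" if seq[5] != "A" else "C"  # corrupt the left arm
        broken = hq.DonorTemplate(
            sequence="".join(seq),
            donor_kind=donor.donor_kind,
            left_arm_len=donor.left_arm_len,
            right_arm_len=donor.right_arm_len,
            strand=donor.strand,
            applied_substitutions=donor.applied_substitutions,
            core_interval=donor.core_interval,
        )
        report = hq.verify_donor(broken, locus, edit)
        (arm_check,) = [c for c in report.checks if c.name == "arm_identity"]
        assert not arm_check.passed
        amplicon_pos = donor.core_interval.start - donor.left_arm_len + 5
        assert str(amplicon_pos) in arm_check.detail


def _locus_for_pam(codons_11_to_26: str, cds: tuple[int, int], frame: int = 0):
    """Helper: protospacer [3,23), PAM [23,26), custom coding content."""
    amp = ("ATG" + codons_11_to_26)[:60].ljust(60, "A")
    return hq.ReferenceLocus(
        "t", amp, cds_interval=Interval(*cds), cds_frame=frame,
        protospacer_interval=Interval(3, 23), pam_interval=Interval(23, 26),
        guide_strand="+",
    )


class TestSilencePam:
    def test_wobble_pam_g_preferred(self):
        # CDS frame puts PAM base 24 at the wobble of a Pro codon CCG;
        # the deterministic choice is the smallest synonymous codon: CCA
        amp = "A" + "ATGGCTACTGACCATAAAGCTC" + "CG" + "GCA" + "A" * 22
        # positions: proto [3,23), pam [23,26)='CGG' (NGG), cds [1,28) frame 0
        locus = hq.ReferenceLocus(
            "t", amp, cds_interval=Interval(1, 28), cds_frame=0,
            protospacer_interval=Interval(3, 23), pam_interval=Interval(23, 26),
            guide_strand="+",
        )
        assert amp[22:25] == "CCG"  # Pro codon ending on the first PAM G
        (sub,) = hq.silence_pam(locus, hq.EditSpec(substitutions=()))
        assert (sub.position, sub.ref_base, sub.alt_base) == (24, "G", "A")
        assert "pam_silencing" in sub.roles

    def test_trp_pam_falls_back_to_seed(self):
        # PAM codon TGG (Trp) has no synonymous alternative -> seed fallback
        amp = "AA" + "ATGGCTACTGACCATAAAGCT" + "TGG" + "A" * 24
        locus = hq.ReferenceLocus(
            "t", amp, cds_interval=Interval(2, 26), cds_frame=0,
            protospacer_interval=Interval(3, 23), pam_interval=Interval(23, 26),
            guide_strand="+",
        )
        assert amp[23:26] == "TGG"
        (sub,) = hq.silence_pam(locus, hq.EditSpec(substitutions=()))
        seed = locus.seed_interval
        assert seed.contains(sub.position)
        assert not locus.pam_interval.contains(sub.position)
        # and the change is synonymous
        edited = amp[: sub.position] + sub.alt_base + amp[sub.position + 1 :]
        from hdrquant.locus import translate_cds

        assert translate_cds(locus, edited) == locus.wt_protein()

    def test_no_synonymous_option_raises(self):
        # seed region made of Trp/Met codons only: nothing synonymous exists
        amp = "AA" + "ATGGCTACT" + "TGGTGGATGTGG" + "TGG" + "A" * 24
        locus = hq.ReferenceLocus(
            "t", amp, cds_interval=Interval(2, 26), cds_frame=0,
            protospacer_interval=Interval(3, 23), pam_interval=Interval(23, 26),
            guide_strand="+",
        )
        with pytest.raises(ConfigurationError, match="no synonymous"):
            hq.silence_pam(locus, hq.EditSpec(substitutions=()))

    def test_noncoding_pam_mutates_first_g(self):
        rng = np.random.default_rng(3)
        amp = "".join(rng.choice(list("ACT"), size=30)) + "AGG" + "T" * 17
        locus = hq.ReferenceLocus(
            "t", amp, cds_interval=Interval(40, 49), cds_frame=0,
            protospacer_interval=Interval(10, 30), pam_interval=Interval(30, 33),
            guide_strand="+",
        )
        (sub,) = hq.silence_pam(locus, hq.EditSpec(substitutions=()))
        assert (sub.position, sub.ref_base, sub.alt_base) == (31, "G", "A")


def _synonymous_codons_independent():
    """Codon->synonyms table built directly from Bio.Seq translation."""
    table: dict[str, list[str]] = {}
    codons = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
    for c in codons:
        aa = str(Seq(c).translate())
        table.setdefault(aa, []).append(c)
    return {c: [x for x in table[str(Seq(c).translate())] if x != c] for c in codons}


def _iupac_hits(seq: str, recognition: str) -> set[int]:
    """Independent site scan: expand IUPAC to concrete words, scan both strands."""
    from Bio.Data.IUPACData import ambiguous_dna_values

    words = {
        "".join(w)
        for w in itertools.product(*(ambiguous_dna_values[c] for c in recognition))
    }
    words |= {revcomp(w) for w in words}
    k = len(recognition)
    return {i for i in range(len(seq) - k + 1) if seq[i : i + k] in words}


class TestDesignCodingBar:
    @pytest.fixture
    def nine_base_locus(self):
        amp = "T" * 10 + "CGCATTGAC" + "T" * 10
        return hq.ReferenceLocus(
            "t", amp, cds_interval=Interval(10, 19), cds_frame=0
        )

    def test_arg_ile_asp_window(self, nine_base_locus):
        """In CGC-ATT-GAC the only 2-change de-novo palindromic site is ClaI."""
        enzymes = [
            hq.RestrictionEnzyme("PvuI", "CGATCG", 4),
            hq.RestrictionEnzyme("ClaI", "ATCGAT", 2),
        ]
        cands = hq.design_coding_bar(
            nine_base_locus, hq.EditSpec(substitutions=()), enzymes,
            window=Interval(10, 19), max_changes=2,
        )
        assert all(c.enzyme.name != "PvuI" for c in cands)
        clai = [c for c in cands if c.enzyme.name == "ClaI"]
        assert clai
        best = clai[0]
        assert best.n_changes == 2
        assert {(s.position, s.ref_base, s.alt_base) for s in best.substitutions} == {
            (15, "T", "C"),  # ATT -> ATC (Ile)
            (18, "C", "T"),  # GAC -> GAT (Asp)
        }
        assert best.site_position == 13

    def test_existing_site_not_de_novo(self):
        amp = "T" * 6 + "ATCGAT" + "CGCATTGAC" + "T" * 6
        locus = hq.ReferenceLocus("t", amp, cds_interval=Interval(12, 21), cds_frame=0)
        cands = hq.design_coding_bar(
            locus, hq.EditSpec(substitutions=()),
            [hq.RestrictionEnzyme("ClaI", "ATCGAT", 2)],
            window=Interval(12, 21), max_changes=2,
        )
        assert all(c.site_position != 6 for c in cands)

    def test_max_changes_zero_only_edit_created_sites(self):
        # the non-synonymous edit itself completes a ClaI site
        amp = "T" * 10 + "ATCGAA" + "GGC" + "T" * 10
        locus = hq.ReferenceLocus("t", amp, cds_interval=Interval(10, 19), cds_frame=0)
        edit = hq.EditSpec(substitutions=(Substitution(15, "A", "T"),))
        cands = hq.design_coding_bar(
            locus, edit, [hq.RestrictionEnzyme("ClaI", "ATCGAT", 2)],
            window=Interval(10, 19), max_changes=0,
        )
        assert [c.site_position for c in cands] == [10]
        assert cands[0].substitutions == ()

    def test_empty_enzyme_list_errors(self, nine_base_locus):
        with pytest.raises(ConfigurationError):
            hq.design_coding_bar(
                nine_base_locus, hq.EditSpec(substitutions=()), [],
                window=Interval(10, 19),
            )

    def test_all_candidates_are_synonymous(self, sim_locus_edit):
        locus, edit = sim_locus_edit
        from hdrquant.locus import apply_substitutions, translate_cds

        window = Interval(
            locus.protospacer_interval.start, locus.protospacer_interval.start + 21
        )
        cands = hq.design_coding_bar(
            locus, hq.EditSpec(substitutions=()),
            list(hq.load_enzyme_table().values()), window, max_changes=2,
        )
        assert cands
        for c in cands:
            edited = apply_substitutions(locus.amplicon_seq, c.substitutions)
            assert translate_cds(locus, edited) == locus.wt_protein()

    def test_bruteforce_enumeration_equivalence(self):
        """Exhaustive <=2-codon enumeration agrees with the designer's output."""
        rng = np.random.default_rng(11)
        core = "".join(rng.choice(list("ACGT"), size=27))  # 9 codons
        amp = "T" * 12 + core + "T" * 12
        locus = hq.ReferenceLocus("t", amp, cds_interval=Interval(12, 39), cds_frame=0)
        window = Interval(12, 39)
        enzymes = list(hq.load_enzyme_table().values())
        got = {
            (
                tuple((s.position, s.ref_base, s.alt_base) for s in c.substitutions),
                c.enzyme.name,
                c.site_position,
            )
            for c in hq.design_coding_bar(
                locus, hq.EditSpec(substitutions=()), enzymes, window, max_changes=2
            )
        }
        # independent enumeration
        syn = _synonymous_codons_independent()
        max_site = max(len(e.recognition) for e in enzymes)
        scan_lo, scan_hi = window.start - (max_site - 1), window.end + (max_site - 1)
        wt_scan = amp[scan_lo:scan_hi]
        codon_starts = list(range(12, 39, 3))
        expected = set()
        for r in range(0, 3):
            for combo in itertools.combinations(range(9), r):
                choices = [syn[core[3 * k : 3 * k + 3]] for k in combo]
                for picked in itertools.product(*choices):
                    seq = list(core)
                    subs = []
                    for k, alt in zip(combo, picked):
                        for j in range(3):
                            if core[3 * k + j] != alt[j]:
                                subs.append(
                                    (codon_starts[k] + j, core[3 * k + j], alt[j])
                                )
                            seq[3 * k + j] = alt[j]
                    edited = amp[:12] + "".join(seq) + amp[39:]
                    ed_scan = edited[scan_lo:scan_hi]
                    for enz in enzymes:
                        wt_hits = _iupac_hits(wt_scan, enz.recognition)
                        for p in _iupac_hits(ed_scan, enz.recognition) - wt_hits:
                            expected.add((tuple(subs), enz.name, p + scan_lo))
        assert got == expected
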