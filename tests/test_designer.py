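"""LAHR template construction, ssODN and CAPR design, codon-aware
disruption and candidate scoring."""

import dataclasses

import pytest
from hypothesis import given
from hypothesis import strategies as st

from lahrkit import (
    AS_CAS12A,
    Candidate,
    DesignParams,
    Edit,
    Locus,
    LocusSpec,
    PlantedPam,
    apply_edits,
    build_lahr_template,
    design_capr,
    design_ssodn,
    enumerate_designs,
    find_sites,
    make_locus,
    score_candidate,
    silent_disruption_candidates,
    simulate_capr,
    simulate_perfect_lahr,
    staggered_cut,
    template_to_oligos,
)
from lahrkit.errors import (
    AnnotationError,
    DisruptionModeError,
    LigationIncompatibleError,
    NoSiteError,
    OverhangEditError,
    PlacementError,
)
from lahrkit.seqcore import CdsAnnotation, reverse_complement

from conftest import PROTOSPACER, correction_edit


class TestBuildLahrTemplate:
    def test_manual_six_bp_arm(self, single_site_locus, single_site):
        """Worked example: 6-bp arm against the 19th-base nick gives top
        'ACCTTG' and bottom 'ATTGCAAGGT' (5' ATTG = revcomp of genomic
        overhang CAAT)."""
        cut = staggered_cut(single_site, 19)
        t = build_lahr_template(single_site_locus, cut, None, arm_len=6)
        assert t.top_strand == "ACCTTG"
        assert t.bottom_strand == "ATTGCAAGGT"
        assert t.overhang_seq == "ATTG" == reverse_complement(cut.overhang_seq)

    def test_default_arm_lengths(self, design_locus, design_cut):
        t = build_lahr_template(design_locus, design_cut, None, DesignParams())
        assert len(t.top_strand) == 80
        assert len(t.bottom_strand) == 84
        assert t.bottom_strand.endswith(reverse_complement(t.top_strand))

    def test_blunt_end_type(self, design_locus, design_cut):
        t = build_lahr_template(
            design_locus, design_cut, None, DesignParams(end_type="blunt")
        )
        assert t.overhang_seq == ""
        assert len(t.bottom_strand) == len(t.top_strand)
        assert t.bottom_strand == reverse_complement(t.top_strand)

    @pytest.mark.parametrize("end_type,ov_len", [("5nt", 5), ("4nt", 4), ("3nt", 3)])
    def test_overhang_length_variants(self, design_locus, design_cut, end_type, ov_len):
        t = build_lahr_template(
            design_locus, design_cut, None, DesignParams(end_type=end_type)
        )
        assert len(t.overhang_seq) == ov_len
        assert len(t.bottom_strand) == len(t.top_strand) + ov_len

    def test_three_prime_variant_moves_overhang_to_top(self, design_locus, design_cut):
        t = build_lahr_template(
            design_locus, design_cut, None, DesignParams(end_type="3prime")
        )
        assert len(t.top_strand) == 80 + 4
        assert len(t.bottom_strand) == 80

    def test_edit_inside_overhang_rejected_by_default(self, design_locus, design_cut):
        edit = correction_edit(design_locus, design_cut.nick_top + 1)
        with pytest.raises(OverhangEditError):
            build_lahr_template(design_locus, design_cut, edit, DesignParams())
        params = DesignParams(allow_overhang_edit=True)
        build_lahr_template(design_locus, design_cut, edit, params)  # override works

    def test_edit_outside_arm_rejected(self, design_locus, design_cut):
        edit = correction_edit(design_locus, design_cut.nick_top - 30)
        with pytest.raises(PlacementError):
            build_lahr_template(design_locus, design_cut, edit, arm_len=20)


class TestSimulatePerfectLahr:
    def test_no_edit_is_identity(self, design_locus, design_cut):
        t = build_lahr_template(design_locus, design_cut, None, DesignParams())
        assert simulate_perfect_lahr(design_locus, design_cut, t) == design_locus.seq

    def test_round_trip_equals_apply_edits(self, design_locus, design_cut):
        edit = correction_edit(design_locus, design_cut.nick_top - 3)
        t = build_lahr_template(design_locus, design_cut, edit, DesignParams())
        got = simulate_perfect_lahr(design_locus, design_cut, t)
        assert got == apply_edits(design_locus, [edit])

    def test_mismatched_overhang_fails_strict_ligation(self, design_locus, design_cut):
        t = build_lahr_template(
            design_locus, design_cut, None, DesignParams(end_type="mismatched")
        )
        with pytest.raises(LigationIncompatibleError):
            simulate_perfect_lahr(design_locus, design_cut, t, strict=True)

    def test_minus_strand_round_trip(self, design_locus):
        mirrored = design_locus.mirrored()
        (site,) = find_sites(Locus(mirrored.name, mirrored.seq))
        assert site.strand == "-"
        cut = staggered_cut(site, 19)
        edit = correction_edit(mirrored, cut.nick_top + 3)
        t = build_lahr_template(mirrored, cut, edit, DesignParams())
        got = simulate_perfect_lahr(mirrored, cut, t)
        assert got == apply_edits(mirrored, [edit])


class TestEnumerateDesigns:
    def test_single_qualifying_site(self, design_locus, design_cut):
        edit = correction_edit(design_locus, design_cut.nick_top - 3)  # distance 2
        report = enumerate_designs(design_locus, edit, DesignParams())
        assert len(report) == 1
        assert report[0].distance == 2

    def test_distant_edit_filtered_then_recovered_by_wider_window(self, design_locus, design_cut):
        edit = correction_edit(design_locus, design_cut.nick_top - 26)  # distance 25
        narrow = enumerate_designs(design_locus, edit, DesignParams())
        assert len(narrow) == 0
        assert narrow.diagnostics  # rejection is explained
        wide = enumerate_designs(
            design_locus, edit, DesignParams(distance_window=(0, 30))
        )
        assert len(wide) >= 1

    def test_candidates_round_trip(self, design_locus, design_cut):
        edit = correction_edit(design_locus, design_cut.nick_top - 5)
        for params in (DesignParams(), DesignParams(disruption_mode="pam")):
            for cand in enumerate_designs(design_locus, edit, params):
                got = simulate_perfect_lahr(design_locus, cand.cut, cand.template)
                assert got == apply_edits(design_locus, list(cand.template.edits_carried))

    def test_strand_mirror_symmetry(self, design_locus, design_cut):
        """Designing against the reverse complement with the mirrored
        edit yields the identical template molecules."""
        edit = correction_edit(design_locus, design_cut.nick_top - 5)
        fwd = enumerate_designs(design_locus, edit, DesignParams())
        mirrored = design_locus.mirrored()
        rev = enumerate_designs(
            Locus(mirrored.name, mirrored.seq), edit.mirrored(len(design_locus.seq)), DesignParams()
        )
        fwd_molecules = {(c.template.top_strand, c.template.bottom_strand) for c in fwd}
        rev_molecules = {(c.template.top_strand, c.template.bottom_strand) for c in rev}
        assert fwd_molecules == rev_molecules


class TestSilentDisruption:
    def test_pam_third_t_at_codon_third_position(self):
        """PAM TTTG whose third T is the wobble base of a Phe codon:
        the T->C synonymous change breaks the PAM and is returned."""
        seq = "ATG" "TTT" "GGA" "CAC" "CTG" "GAT" "GAA" "CTG" "CAC" "GGA" "TAA"
        locus = Locus("cds", seq, CdsAnnotation(0, 33, "+", 0))
        site = next(s for s in find_sites(locus) if s.pam_interval == (3, 7))
        cands = silent_disruption_candidates(locus, site, DesignParams(disruption_mode="pam"))
        assert cands == [Edit(5, "T", "C")]

    def test_seed_without_synonymous_codons_is_empty(self):
        """Seed spanned by ATG/TGG codons (Met/Trp admit no synonymous
        single change) yields no candidates."""
        seq = "GC" + "TTTC" + "ATGTGG" + "CACGATGAACTGCACGA"
        locus = Locus("cds", seq, CdsAnnotation(0, 27, "+", 0))
        site = next(s for s in find_sites(locus) if s.pam_interval == (2, 6))
        cands = silent_disruption_candidates(locus, site, DesignParams(disruption_mode="seed"))
        assert cands == []

    def test_both_modes_unrepresentable(self):
        with pytest.raises(DisruptionModeError):
            DesignParams(disruption_mode="pam+seed")

    def test_missing_cds_requires_override(self):
        locus = Locus("bare", "GCAG" + "TTTC" + PROTOSPACER + "GCAG")
        (site,) = find_sites(locus)
        with pytest.raises(AnnotationError):
            silent_disruption_candidates(locus, site, DesignParams(disruption_mode="pam"))
        cands = silent_disruption_candidates(
            locus, site, DesignParams(disruption_mode="pam", allow_noncoding_disruption=True)
        )
        assert cands  # without codon constraints the PAM is always breakable

    def test_plus_strand_cds_always_offers_pam_break(self, design_locus):
        """One of the three PAM Ts always falls on a codon wobble
        position, where T->C is universally synonymous — so a fully
        covered plus-strand CDS always admits a PAM disruption."""
        (site,) = find_sites(design_locus)
        cands = silent_disruption_candidates(
            design_locus, site, DesignParams(disruption_mode="pam")
        )
        assert cands


class TestSsodn:
    @pytest.mark.parametrize("arms,total", [((80, 80), 160), ((50, 50), 100)])
    def test_lengths_match_arm_sums(self, arms, total):
        built = make_locus(
            LocusSpec(seed=7, length=260, pams=(PlantedPam("TTTC", 100, "+"),))
        )
        locus = built.locus
        (site,) = find_sites(locus)
        cut = staggered_cut(site, 19)
        edit = correction_edit(locus, cut.nick_top - 3)
        t = design_ssodn(locus, edit, cut, arms)
        assert len(t.seq) == total == sum(t.arms)

    def test_cas12a_uses_non_target_strand(self, design_locus, design_cut):
        edit = correction_edit(design_locus, design_cut.nick_top - 3)
        t = design_ssodn(design_locus, edit, design_cut, (30, 30))
        assert t.strand_used == "non-target"
        assert t.seq in apply_edits(design_locus, [edit])  # substring of edited top

    def test_cas9_uses_target_strand(self):
        from lahrkit import SP_CAS9

        proto = "GATCAGATCCAGTACGATCA"
        locus = Locus("c9", "GCAGGCAT" * 5 + proto + "CGGT" + "GCAGGCAT" * 5)
        site = next(
            s for s in find_sites(locus, SP_CAS9) if s.strand == "+" and s.pam_interval[0] == 60
        )
        cut = staggered_cut(site)
        edit = correction_edit(locus, cut.nick_top - 3)
        t = design_ssodn(locus, edit, cut, (25, 25))
        assert t.strand_used == "target"
        assert t.seq == reverse_complement(
            apply_edits(locus, [edit])[cut.nick_top - 25 : cut.nick_top + 25]
        )

    def test_edit_outside_span_rejected(self, design_locus, design_cut):
        edit = correction_edit(design_locus, design_cut.nick_top - 40)
        with pytest.raises(PlacementError):
            design_ssodn(design_locus, edit, design_cut, (30, 30))


def _capr_locus(seed=11):
    built = make_locus(
        LocusSpec(
            seed=seed,
            length=160,
            pams=(PlantedPam("TTTC", 10, "+"), PlantedPam("TTTC", 140, "-")),
        )
    )
    return built.locus


class TestCapr:
    def test_replacement_round_trip(self):
        locus = _capr_locus()
        interval, repl = (70, 80), "GGATCCTTAA"
        design = design_capr(locus, interval, repl)
        got = simulate_capr(locus, design)
        assert got == locus.seq[: interval[0]] + repl + locus.seq[interval[1] :]

    def test_identity_replacement_restores_wild_type(self):
        locus = _capr_locus()
        interval = (70, 80)
        design = design_capr(locus, interval, locus.seq[slice(*interval)])
        assert simulate_capr(locus, design) == locus.seq

    def test_length_changing_replacement(self):
        locus = _capr_locus()
        interval, repl = (70, 80), "GGG"
        design = design_capr(locus, interval, repl)
        assert simulate_capr(locus, design) == locus.seq[:70] + repl + locus.seq[80:]

    def test_insert_overhangs_complement_genomic_ends(self):
        locus = _capr_locus()
        design = design_capr(locus, (70, 80), "GGATCCTTAA")
        lc, rc = design.left_cut, design.right_cut
        assert design.left_overhang == locus.seq[lc.cut_top_strand : lc.cut_bottom_strand]
        assert design.right_overhang == reverse_complement(
            locus.seq[rc.cut_top_strand : rc.cut_bottom_strand]
        )
        assert design.left_overhang != design.right_overhang or design.warnings

    def test_no_flanking_pair_raises(self):
        built = make_locus(LocusSpec(seed=3, length=120, pams=(PlantedPam("TTTC", 10, "+"),)))
        with pytest.raises(NoSiteError):
            design_capr(built.locus, (70, 80), "GG")

    def test_self_complementary_overhangs_warn(self):
        """Both cuts engineered to yield the palindromic overhang AATT:
        the insert orientation cannot be enforced."""
        proto_l = PROTOSPACER[:19] + "AATT"  # overhang bases 20-23
        proto_r = PROTOSPACER[:19] + "AATT"
        seq = (
            "GCAG"
            + "TTTC"
            + proto_l
            + "GCAGGCATGCAGGCAT"
            + reverse_complement("TTTC" + proto_r)
            + "GCAG"
        )
        locus = Locus("pal", seq)
        cuts_at = sorted(s.pam_interval[0] for s in find_sites(locus))
        design = design_capr(locus, (33, 40), locus.seq[33:40])
        assert design.warnings
        from lahrkit.errors import OrientationError

        with pytest.raises(OrientationError):
            design_capr(locus, (33, 40), locus.seq[33:40], strict=True)


class TestScoring:
    def _candidate(self, design_locus, design_cut, **param_kw):
        params = DesignParams(**param_kw)
        edit = correction_edit(design_locus, design_cut.nick_top - 3)
        report = enumerate_designs(design_locus, edit, params)
        assert len(report) >= 1
        return report[0], params

    def test_optimal_design_has_unit_components(self, design_locus, design_cut):
        cand, params = self._candidate(design_locus, design_cut, disruption_mode="pam")
        assert cand.components["distance"] == 1.0
        assert cand.components["arm"] == 1.0
        assert cand.components["total_len"] == 1.0
        assert cand.components["mid_arm"] > 0.5  # disruption near the nick
        assert cand.components["re_cut"] == 1.0

    def test_score_monotone_in_distance(self, design_locus, design_cut):
        def scored(d):
            edit = correction_edit(design_locus, design_cut.nick_top - 1 - d)
            params = DesignParams(distance_window=(0, 20))
            cand = Candidate(
                template=build_lahr_template(design_locus, design_cut, edit, params),
                site=design_cut.site,
                cut=design_cut,
                distance=d,
            )
            return score_candidate(cand, params).score

        assert scored(10) == scored(2)  # both inside the window
        assert scored(30) < scored(10)

    def test_extra_edit_near_blunt_end_scores_lower(self, design_locus, design_cut):
        """Silent-mutation incorporation drops toward the blunt end, so
        the mid-arm component must too."""
        correction = correction_edit(design_locus, design_cut.nick_top - 2)
        params = DesignParams()

        def with_extra_at(pos):
            extra = correction_edit(design_locus, pos)
            t = build_lahr_template(
                design_locus, design_cut, correction, params, extra_edits=[extra]
            )
            cand = Candidate(template=t, site=design_cut.site, cut=design_cut, distance=2)
            return score_candidate(cand, params).components["mid_arm"]

        near_nick = with_extra_at(design_cut.nick_top - 6)
        near_blunt = with_extra_at(design_cut.nick_top - 75)
        assert near_blunt < near_nick

    def test_ranking_is_deterministic(self, design_locus):
        edit = correction_edit(design_locus, staggered_cut(find_sites(design_locus)[0], 19).nick_top - 3)
        a = enumerate_designs(design_locus, edit, DesignParams())
        b = enumerate_designs(design_locus, edit, DesignParams())
        assert [(c.score, c.site.pam_interval) for c in a] == [
            (c.score, c.site.pam_interval) for c in b
        ]


class TestOligos:
    def test_blunt_template_oligos_are_reverse_complements(self, design_locus, design_cut):
        t = build_lahr_template(design_locus, design_cut, None, DesignParams(end_type="blunt"))
        top, bottom = template_to_oligos(t)
        assert bottom == reverse_complement(top)

    def test_overhang_template_bottom_longer_by_four(self, design_locus, design_cut):
        t = build_lahr_template(design_locus, design_cut, None, DesignParams())
        top, bottom = template_to_oligos(t)
        assert len(bottom) == len(top) + 4

    def test_capr_oligos_carry_one_overhang_each_end(self):
        locus = _capr_locus()
        design = design_capr(locus, (70, 80), "GGATCCTTAA")
        top, bottom = template_to_oligos(design)
        assert (top, bottom) == (design.insert_top, design.insert_bottom)
        # duplex bookkeeping: bottom = top - left overhang + right overhang
        lov = design.left_cut.cut_bottom_strand - design.left_cut.cut_top_strand
        rov = design.right_cut.cut_bottom_strand - design.right_cut.cut_top_strand
        assert len(bottom) == len(top) - lov + rov
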