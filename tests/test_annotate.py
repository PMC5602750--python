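"""Feature assignment, codon consequences, sequence context and windows."""

import itertools

import pytest
from Bio.Seq import Seq

import plastedit as pe
from plastedit.genome import reverse_complement

from conftest import build_toy_gene, cds_genomic_position, edit_site_at


class TestAssignFeature:
    def test_unannotated_position_is_igs(self):
        site = edit_site_at(500)
        ann = pe.assign_feature(site, [])
        assert ann.feature_class == "IGS"
        assert ann.label == "500"

    def test_trna_site_labelled_by_genomic_position(self):
        feats = [pe.FeatureRecord("trnM", "tRNA", [(400, 471)], "+")]
        ann = pe.assign_feature(edit_site_at(430), feats)
        assert ann.feature_class == "tRNA"
        assert ann.feature_id == "trnM"
        assert ann.label == "430"

    def test_conflicting_overlap_raises_with_names(self):
        feats = [
            pe.FeatureRecord("a", "CDS", [(400, 500)], "+"),
            pe.FeatureRecord("b", "tRNA", [(450, 520)], "+"),
        ]
        with pytest.raises(pe.AnnotationError, match="a.*b"):
            pe.assign_feature(edit_site_at(460), feats)

    def test_spliced_cds_offset_on_minus_strand_two_exon_gene(self):
        # exon structure must not affect the spliced offset: offset 56 of a
        # minus-strand gene with a 40+x exon split
        feat = pe.FeatureRecord("g", "CDS", [(1000, 1149), (1250, 1399)], "-")
        pos = cds_genomic_position(feat, 56)
        assert pos == 1399 - 56 + 1  # still in the 3'-genomic exon
        ann = pe.assign_feature(edit_site_at(pos, strand="-"), [feat])
        assert ann.cds_position == 56
        assert ann.label == "g-56"
        # an offset beyond the first transcript exon crosses the intron
        pos2 = cds_genomic_position(feat, 151)
        assert pos2 == 1149  # first base of the genomic-left exon
        assert pe.assign_feature(edit_site_at(pos2, strand="-"), [feat]).cds_position == 151


class TestCodonConsequence:
    def run_case(self, codon_index, codon, cds_offset_in_codon, expect, strand="+",
                 start_codon="ATG", edit_type=pe.C_TO_U):
        codons = {codon_index: codon} if codon_index > 1 else {}
        if codon_index == 1:
            start_codon = codon
        genome, feat = build_toy_gene(
            codons, n_codons=max(120, codon_index + 10),
            start_codon=start_codon, strand=strand,
        )
        cds_pos = (codon_index - 1) * 3 + cds_offset_in_codon
        site = edit_site_at(cds_genomic_position(feat, cds_pos), edit_type, strand)
        cons = pe.codon_consequence(site, feat, genome)
        assert cons.cds_position == cds_pos
        assert cons.codon_index == codon_index
        assert cons.codon_position == cds_offset_in_codon
        assert cons.effect == expect
        return cons

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_ser_to_leu_second_position(self, strand):
        cons = self.run_case(19, "TCA", 2, "nonsynonymous", strand=strand)
        assert (cons.ref_aa, cons.edited_aa) == ("S", "L")
        assert cons.ref_codon == "UCA" and cons.edited_codon == "UUA"
        assert cons.hydropathy_delta > 0  # Leu is more hydrophobic than Ser

    def test_thr_to_ile_increases_hydropathy(self):
        cons = self.run_case(19, "ACA", 2, "nonsynonymous")
        assert (cons.ref_aa, cons.edited_aa) == ("T", "I")
        assert cons.edited_codon == "AUA"
        assert cons.hydropathy_delta == pytest.approx(4.5 - (-0.7))

    def test_his_to_tyr_first_position(self):
        cons = self.run_case(195, "CAT", 1, "nonsynonymous")
        assert (cons.ref_aa, cons.edited_aa) == ("H", "Y")

    def test_third_position_silent(self):
        cons = self.run_case(112, "TTC", 3, "synonymous")
        assert cons.ref_aa == cons.edited_aa == "F"
        assert cons.hydropathy_delta == 0.0

    def test_acg_initiation_codon_becomes_start(self):
        cons = self.run_case(1, "ACG", 2, "start_created")
        assert cons.edited_codon == "AUG"

    def test_internal_acg_is_plain_nonsynonymous(self):
        cons = self.run_case(30, "ACG", 2, "nonsynonymous")
        assert (cons.ref_aa, cons.edited_aa) == ("T", "M")

    def test_caa_to_uaa_creates_stop(self):
        cons = self.run_case(40, "CAA", 1, "stop_created")
        assert cons.edited_aa == "*"
        assert cons.hydropathy_delta == 0.0

    def test_u_to_c_repairs_direction(self):
        # the reverse chemistry on a T: TTA (Leu) -> TCA (Ser)
        cons = self.run_case(25, "TTA", 2, "nonsynonymous", edit_type=pe.U_TO_C)
        assert (cons.ref_aa, cons.edited_aa) == ("L", "S")

    def test_base_mismatch_raises(self):
        genome, feat = build_toy_gene({20: "AAA"})
        site = edit_site_at(cds_genomic_position(feat, 58), pe.C_TO_U, "+")
        with pytest.raises(pe.AnnotationError):
            pe.codon_consequence(site, feat, genome)

    def test_agrees_with_whole_cds_translation(self):
        """Brute-force oracle: translating the fully edited CDS differs from
        the reference protein at exactly the annotated residue (or not at all
        when synonymous)."""
        for codon_index, codon, off in [(19, "TCA", 2), (7, "CCG", 1), (112, "TTC", 3),
                                        (40, "CAA", 1), (60, "GCT", 2)]:
            genome, feat = build_toy_gene({codon_index: codon})
            cds = feat.spliced_sequence(genome)
            cds_pos = (codon_index - 1) * 3 + off
            site = edit_site_at(cds_genomic_position(feat, cds_pos), pe.C_TO_U, "+")
            cons = pe.codon_consequence(site, feat, genome)
            edited_cds = cds[: cds_pos - 1] + "T" + cds[cds_pos:]
            ref_prot = str(Seq(cds).translate(table=1))
            new_prot = str(Seq(edited_cds).translate(table=1))
            diffs = [i for i, (a, b) in enumerate(zip(ref_prot, new_prot)) if a != b]
            if cons.effect == "synonymous":
                assert diffs == []
            else:
                assert diffs == [cons.codon_index - 1]
                assert new_prot[cons.codon_index - 1] == cons.edited_aa

    def test_every_nnc_to_nnu_is_synonymous(self):
        """Third-position C-to-U edits can never change the amino acid."""
        for i, nn in enumerate("".join(p) for p in itertools.product("ACGT", repeat=2)):
            cons = self.run_case(20 + i, nn + "C", 3, "synonymous")
            assert cons.ref_aa == cons.edited_aa


class TestNeighborContext:
    def test_point_mass_when_context_is_constructed(self):
        seq = "A" * 10 + "TCA" + "A" * 10 + "TCA" + "A" * 10
        genome = pe.ReferenceGenome("ctx", seq)
        sites = [
            pe.assign_feature(edit_site_at(12), []),
            pe.assign_feature(edit_site_at(25), []),
        ]
        ctx = pe.neighbor_context(sites, genome)
        m1 = ctx[(ctx["offset"] == -1)]
        p1 = ctx[(ctx["offset"] == 1)]
        assert m1.iloc[0]["base"] == "U" and m1.iloc[0]["frequency"] == 1.0
        assert p1.iloc[0]["base"] == "A" and p1.iloc[0]["frequency"] == 1.0

    def test_minus_strand_context_is_transcript_oriented(self):
        # plus-strand ...T G A...: a minus-strand edit at the G sees
        # upstream(-1) = complement(A) = U and downstream(+1) = complement(T) = A
        seq = "ACGTA" + "TGA" + "CCCGG"
        genome = pe.ReferenceGenome("ctx", seq)
        site = edit_site_at(7, pe.C_TO_U, "-")
        ctx = pe.neighbor_context([pe.assign_feature(site, [])], genome)
        lookup = {(r.offset, r.base): r.frequency for r in ctx.itertuples()}
        assert lookup[(-1, "U")] == 1.0
        assert lookup[(1, "A")] == 1.0

    def test_genome_end_site_excluded_and_frequencies_sum_to_one(self, demo_dataset, demo_calls):
        sites = [
            pe.assign_feature(s, demo_dataset.features)
            for s in demo_calls["leaf"]["sites"]
            if not s.homopolymer_flag
        ]
        ctx = pe.neighbor_context(sites, demo_dataset.genome)
        sums = ctx.groupby(["group", "offset"])["frequency"].sum()
        assert (abs(sums - 1.0) < 1e-9).all()
        assert set(ctx["group"]) == {"protein_coding", "non_protein_coding"}


class TestExtractWindow:
    def test_zero_window_is_the_edited_base(self):
        genome = pe.ReferenceGenome("w", "AAACAAA")
        w = pe.extract_window(edit_site_at(4), genome, 0, 0)
        assert w.unedited == "C" and w.edited == "T"
        assert w.site_index == 0 and not w.truncated

    def test_cis_element_window_shape(self):
        genome = pe.ReferenceGenome("w", "A" * 100 + "C" + "G" * 100)
        w = pe.extract_window(edit_site_at(101), genome, 30, 10)
        assert len(w.unedited) == 41
        assert w.site_index == 30
        assert w.unedited[30] == "C" and w.edited[30] == "T"

    def test_minus_strand_window_is_reverse_complement(self):
        seq = "ACGTACGTACGTGACGTACGTACGT"
        genome = pe.ReferenceGenome("w", seq)
        pos = 13  # plus-strand G; minus-strand C-to-U
        w = pe.extract_window(edit_site_at(pos, pe.C_TO_U, "-"), genome, 5, 5)
        plus_slice = genome.slice(pos - 5, pos + 5)
        assert w.unedited == reverse_complement(plus_slice)
        assert w.unedited[w.site_index] == "C"
        assert w.edited[w.site_index] == "T"

    def test_truncation_flagged_at_genome_edge(self):
        genome = pe.ReferenceGenome("w", "CAAAAA")
        w = pe.extract_window(edit_site_at(1), genome, 10, 2)
        assert w.truncated
        assert w.unedited == "CAA"


def test_annotate_sites_covers_all_classes(demo_dataset, demo_calls):
    ann = pe.annotate_sites(
        demo_calls["leaf"]["sites"], demo_dataset.features, demo_dataset.genome
    )
    classes = {a.feature_class for a in ann}
    assert {"CDS", "IGS"} <= classes
    for a in ann:
        if a.feature_class == "CDS":
            assert a.consequence is not None
            assert a.consequence.effect in pe.annotate.EFFECTS
            assert a.label == f"{a.feature_id}-{a.cds_position}"
        else:
            assert a.consequence is None
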