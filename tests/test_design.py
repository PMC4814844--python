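"""Cut-site prediction, layout rules, melting temperatures, dark probes."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dropquant import (
    AssayLayout,
    Guide,
    Interval,
    NucleasePair,
    NucleaseSpec,
    dark_probe_recommended,
    melting_temperature,
    predict_cut_sites,
    validate_layout,
)


class TestPredictCutSites:
    def test_plus_strand_crispr(self):
        spec = NucleaseSpec("crispr", guides=(Guide(Interval(100, 120), "+"),))
        assert predict_cut_sites(spec) == [117]

    def test_minus_strand_mirror(self):
        spec = NucleaseSpec("crispr", guides=(Guide(Interval(100, 120), "-"),))
        assert predict_cut_sites(spec) == [103]

    def test_talen_spacer_midpoint(self):
        spec = NucleaseSpec("talen", pair=NucleasePair(Interval(100, 118),
                                                       Interval(133, 151)))
        assert predict_cut_sites(spec) == [125]

    def test_dual_guides_one_site_each(self):
        spec = NucleaseSpec("crispr", guides=(
            Guide(Interval(100, 120), "+"), Guide(Interval(160, 180), "-")))
        assert predict_cut_sites(spec) == [117, 163]

    def test_overlapping_talen_arms_rejected(self):
        with pytest.raises(ValueError):
            NucleasePair(Interval(100, 130), Interval(125, 150))

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 500), st.integers(17, 23), st.integers(600, 1000))
    def test_strand_mirror_symmetry(self, start, length, locus_len):
        """Reverse-complementing the locus and mirroring coordinates maps
        the cut site accordingly."""
        plus = NucleaseSpec("crispr", guides=(Guide(Interval(start, start + length), "+"),))
        mirrored = NucleaseSpec("crispr", guides=(
            Guide(Interval(locus_len - start - length, locus_len - start), "-"),))
        (cut_plus,) = predict_cut_sites(plus)
        (cut_minus,) = predict_cut_sites(mirrored)
        assert cut_minus == locus_len - cut_plus


def base_layout(**overrides):
    kwargs = dict(
        amplicon=Interval(90, 310),
        fwd_primer=Interval(90, 110),
        rev_primer=Interval(290, 310),
        ref_probe=Interval(250, 270),
        hdr_probe=Interval(185, 205),
        nhej_probes=(Interval(190, 215),),
        cut_sites=(200,),
        donor_span=Interval(170, 230),
        edit_position=197,
    )
    kwargs.update(overrides)
    return AssayLayout(**kwargs)


class TestValidateLayout:
    def test_conforming_layout_passes(self):
        report = validate_layout(base_layout())
        assert report.passed, report.as_records()

    def test_flank_rule(self):
        # inner boundaries at 110 and 290 give 90/90 bp around cut 200
        report = validate_layout(base_layout())
        flanks = next(c for c in report.checks if c.rule == "cut_site_flanks")
        assert flanks.passed and "90/90" in flanks.message
        # amplicon stretched so a flank exceeds 125 bp
        wide = base_layout(amplicon=Interval(40, 310), fwd_primer=Interval(40, 60))
        assert not validate_layout(wide).checks[0].passed

    def test_primer_outside_donor_rule(self):
        ok = next(c for c in validate_layout(base_layout()).checks
                  if c.rule == "primer_outside_donor")
        assert ok.passed
        swallowed = base_layout(donor_span=Interval(90, 310))
        bad = next(c for c in validate_layout(swallowed).checks
                   if c.rule == "primer_outside_donor")
        assert not bad.passed

    def test_ref_probe_distance_rule(self):
        near_cut = base_layout(ref_probe=Interval(210, 230))
        bad = next(c for c in validate_layout(near_cut).checks
                   if c.rule == "ref_probe_distant")
        assert not bad.passed
        # a custom exclusion window can relax the default
        ok = next(c for c in validate_layout(
            base_layout(ref_probe=Interval(245, 265)), cut_exclusion_bp=30).checks
            if c.rule == "ref_probe_distant")
        assert ok.passed

    def test_nhej_probe_covers_cut(self):
        good = next(c for c in validate_layout(base_layout()).checks
                    if c.rule == "nhej_probe_covers_cut")
        assert good.passed
        off = base_layout(nhej_probes=(Interval(240, 260),))
        bad = next(c for c in validate_layout(off).checks
                   if c.rule == "nhej_probe_covers_cut")
        assert not bad.passed

    def test_hdr_probe_covers_edit(self):
        off = base_layout(hdr_probe=Interval(230, 250))
        bad = next(c for c in validate_layout(off).checks
                   if c.rule == "hdr_probe_covers_edit")
        assert not bad.passed

    def test_widening_amplicon_keeps_flanks_passing(self):
        """Symmetric widening never flips the flank rule pass -> fail while
        flanks stay <= 125 bp."""
        for pad in (0, 10, 20, 35):
            layout = base_layout(
                amplicon=Interval(90 - pad, 310 + pad),
                fwd_primer=Interval(90 - pad, 110 - pad),
                rev_primer=Interval(290 + pad, 310 + pad),
            )
            flank = 200 - (110 - pad)
            if flank <= 125:
                assert validate_layout(layout).checks[0].passed


class TestMeltingTemperature:
    def test_duplex_symmetry(self):
        seq = "AGCGTACCGGTTAGCCATGC"
        rc = seq[::-1].translate(str.maketrans("ACGT", "TGCA"))
        assert melting_temperature(seq) == pytest.approx(
            melting_temperature(rc), abs=1e-9)

    def test_gc_rich_melts_higher(self):
        assert melting_temperature("G" * 12) > melting_temperature("A" * 12)

    @pytest.mark.parametrize("seq", [
        "AGCGTACCGGTTAGCCATGC",
        "ATGCATGCATGCATGC",
        "TTTTAAAATTTTAAAA",
        "CGCGCGCGCGCG",
        "ACCTGGAGATCCGTTAAGGCAT",
    ])
    def test_matches_independent_nn_oracle(self, seq):
        """Within 0.5 degC of an independently implemented SantaLucia-1998
        nearest-neighbor calculation (Biopython's)."""
        from Bio.SeqUtils import MeltingTemp as mt

        reference = mt.Tm_NN(seq, nn_table=mt.DNA_NN3, Na=50, Mg=3, dNTPs=0,
                             saltcorr=5, dnac1=25, dnac2=25)
        assert melting_temperature(seq, oligo_conc_nM=50) == pytest.approx(
            reference, abs=0.5)

    def test_salt_raises_tm(self):
        seq = "AGCGTACCGGTTAGCCATGC"
        assert melting_temperature(seq, monovalent_mM=100) > melting_temperature(
            seq, monovalent_mM=50)

    def test_rejects_ambiguity_and_short(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGTNACGTACG")
        with pytest.raises(ValueError):
            melting_temperature("ACGT")


class TestDarkProbe:
    WT = "ACCTGGAGATCCGTTAAGGCAT"

    def probe_with_mismatches(self, k):
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        seq = list(self.WT)
        mid = len(seq) // 2
        for i in range(k):
            seq[mid + i] = flip[seq[mid + i]]
        return "".join(seq)

    def test_single_central_mismatch_recommended(self):
        recommended, why = dark_probe_recommended(self.probe_with_mismatches(1), self.WT)
        assert recommended
        assert "recommended" in why

    def test_many_mismatches_not_recommended(self):
        recommended, _ = dark_probe_recommended(self.probe_with_mismatches(4), self.WT)
        assert not recommended

    def test_margin_boundary_inclusive(self):
        probe = self.probe_with_mismatches(1)
        tm_matched = melting_temperature(probe)
        from dropquant.design import _tm_against_template
        tm_wt = _tm_against_template(probe, self.WT, 50.0, 3.0, 0.0, 50.0)
        at_margin = tm_matched - tm_wt
        recommended, _ = dark_probe_recommended(probe, self.WT, tm_margin_c=at_margin)
        assert recommended

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dark_probe_recommended("ACGTACGTAC", "ACGTACGT")
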