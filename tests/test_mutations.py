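"""Panel filtering, effect classification, splice consequence, intersection."""

import numpy as np
import pytest

from conftest import brute_force_filter, panel_frame, random_filter_panel
from steeproot.mutations import (
    CODING_IMPACT,
    EffectCall,
    FilterConfig,
    GeneModel,
    VariantRecord,
    classify_effect,
    filter_unique_mutations,
    intersect_allelic_candidates,
    splice_consequence,
    substitution_offset,
)

SAMPLES = [f"s{i}" for i in range(10)]


def one_variant(focal_dp_dv, other_dp_dv, qual=50.0):
    per = {"s0": focal_dp_dv}
    per.update({s: other_dp_dv for s in SAMPLES[1:]})
    return panel_frame([("chr1", 100, "G", "A", qual, per)], SAMPLES)


class TestFilter:
    def test_clean_private_homozygous_variant_retained(self):
        retained, rejected = filter_unique_mutations(one_variant((10, 9), (10, 0)), ["s0"])
        assert len(retained) == 1 and len(rejected) == 0

    def test_contaminated_other_sample_rejects(self):
        """DV/DP of 3/10 = 0.3 in a non-focal sample violates the 0.2 ceiling."""
        per = {"s0": (10, 9), "s1": (10, 3)}
        per.update({s: (10, 0) for s in SAMPLES[2:]})
        panel = panel_frame([("chr1", 100, "G", "A", 50.0, per)], SAMPLES)
        retained, rejected = filter_unique_mutations(panel, ["s0"])
        assert len(retained) == 0
        assert rejected["reject_reason"].iloc[0] == "other_ratio:s1"

    def test_shallow_focal_depth_rejects_regardless_of_ratio(self):
        retained, rejected = filter_unique_mutations(one_variant((4, 4), (10, 0)), ["s0"])
        assert len(retained) == 0
        assert rejected["reject_reason"].iloc[0] == "low_depth:s0"

    def test_zero_depth_is_untestable_not_an_exception(self):
        retained, rejected = filter_unique_mutations(one_variant((10, 9), (0, 0)), ["s0"])
        assert len(retained) == 0
        assert rejected["reject_reason"].str.startswith("ratio_undefined").all()

    def test_quality_gate_is_strict(self):
        retained, _ = filter_unique_mutations(one_variant((10, 9), (10, 0), qual=40.0), ["s0"])
        assert len(retained) == 0  # PHRED must exceed 40
        retained, _ = filter_unique_mutations(one_variant((10, 9), (10, 0), qual=40.01), ["s0"])
        assert len(retained) == 1

    def test_boundary_ratios_are_inclusive(self):
        retained, _ = filter_unique_mutations(one_variant((10, 8), (10, 2)), ["s0"])
        assert len(retained) == 1  # 0.8 and 0.2 exactly pass

    def test_filter_matches_brute_force_oracle(self, rng):
        cfg = FilterConfig()
        for _ in range(50):
            panel, samples = random_filter_panel(rng)
            retained, _ = filter_unique_mutations(panel, ["s0"], cfg, samples)
            assert retained["pos"].tolist() == brute_force_filter(panel, samples, ["s0"], cfg)

    def test_tightening_thresholds_never_adds_variants(self, rng):
        panel, samples = random_filter_panel(rng, n_variants=200)
        base, _ = filter_unique_mutations(panel, ["s0"], FilterConfig(), samples)
        for cfg in (
            FilterConfig(min_focal_ratio=0.9),
            FilterConfig(max_other_ratio=0.1),
            FilterConfig(min_dp=10),
            FilterConfig(min_qual=60),
        ):
            tighter, _ = filter_unique_mutations(panel, ["s0"], cfg, samples)
            assert set(tighter["pos"]) <= set(base["pos"])

    def test_focal_must_be_proper_subset_of_panel(self):
        panel = one_variant((10, 9), (10, 0))
        with pytest.raises(ValueError, match="focal"):
            filter_unique_mutations(panel, ["nope"])
        with pytest.raises(ValueError, match="non-focal"):
            filter_unique_mutations(panel, SAMPLES)


class TestEffectClassification:
    def test_missense_in_codon_two(self, toy_gene, toy_genome):
        """GCT -> GGT at codon 2: alanine to glycine."""
        v = VariantRecord("chrT", 5, "C", "G", 60.0)
        call = classify_effect(v, toy_gene, toy_genome)
        assert call.effect == "missense"
        assert call.protein_change == "A2G"
        assert call.codon_pos == 2

    def test_synonymous_third_position(self, toy_gene, toy_genome):
        """GCT -> GCC is still alanine."""
        v = VariantRecord("chrT", 22, "T", "C", 60.0)
        call = classify_effect(v, toy_gene, toy_genome)
        assert call.effect == "synonymous"

    def test_splice_acceptor_at_intron_final_base(self, toy_gene, toy_genome):
        v = VariantRecord("chrT", 21, "G", "A", 60.0)
        assert classify_effect(v, toy_gene, toy_genome).effect == "splice_acceptor"

    def test_splice_donor_at_intron_first_base(self, toy_gene, toy_genome):
        v = VariantRecord("chrT", 6, "G", "A", 60.0)
        assert classify_effect(v, toy_gene, toy_genome).effect == "splice_donor"

    def test_deep_intron_position_is_intronic(self, toy_gene, toy_genome):
        v = VariantRecord("chrT", 12, "T", "A", 60.0)
        assert classify_effect(v, toy_gene, toy_genome).effect == "intronic"

    def test_outside_gene_is_intergenic(self, toy_gene, toy_genome):
        v = VariantRecord("chrT", 28, "G", "A", 60.0)
        assert classify_effect(v, toy_gene, toy_genome).effect == "intergenic"

    def test_every_cds_snv_is_exactly_one_coding_class(self, toy_gene, toy_genome):
        coding = {"missense", "synonymous", "stop_gained"}
        cds_positions = [p for s, e in toy_gene.cds for p in range(s, e + 1)]
        for pos in cds_positions:
            ref = toy_genome["chrT"][pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                call = classify_effect(VariantRecord("chrT", pos, ref, alt, 60.0), toy_gene, toy_genome)
                assert call.effect in coding

    def test_strand_equivalence_under_reverse_complement(self, toy_gene, toy_genome):
        """Mirroring the genome and flipping the strand preserves protein changes."""
        comp = str.maketrans("ACGT", "TGCA")
        seq = toy_genome["chrT"]
        L = len(seq)
        mirrored = {"chrT": seq.translate(comp)[::-1]}
        flip = lambda interval: (L - interval[1] + 1, L - interval[0] + 1)
        gene_rc = GeneModel(
            "toy_rc", "chrT", "-",
            tuple(sorted(flip(e) for e in toy_gene.exons)),
            tuple(sorted(flip(c) for c in toy_gene.cds)),
        )
        for pos, ref, alt in ((5, "C", "G"), (22, "T", "C"), (4, "G", "T")):
            fwd = classify_effect(VariantRecord("chrT", pos, ref, alt, 60.0), toy_gene, toy_genome)
            rc = classify_effect(
                VariantRecord(
                    "chrT", L - pos + 1, ref.translate(comp), alt.translate(comp), 60.0
                ),
                gene_rc,
                mirrored,
            )
            assert (fwd.effect, fwd.protein_change) == (rc.effect, rc.protein_change)


class TestSpliceConsequence:
    def test_27_nt_shift_deletes_nine_residues_in_frame(self):
        sc = splice_consequence(27, 129)
        assert sc.in_frame
        assert sc.deletion_nt == 27
        assert sc.deleted_residues == (129, 137)

    def test_26_nt_shift_is_a_frameshift(self):
        sc = splice_consequence(26, 129)
        assert not sc.in_frame
        assert sc.deleted_residues is None

    def test_zero_shift_is_identity(self):
        sc = splice_consequence(0, 10)
        assert sc.in_frame and sc.deletion_nt == 0 and sc.deleted_residues is None

    def test_negative_shift_rejected(self):
        with pytest.raises(ValueError):
            splice_consequence(-3, 10)


class _Interval:
    def __init__(self, chrom, start, end):
        self.chrom, self.start, self.end = chrom, start, end


def call(gene, pos, effect="missense"):
    return EffectCall(VariantRecord("chr6", pos, "G", "A", 50.0), gene, effect)


class TestAllelicIntersection:
    def test_single_shared_gene_nominated(self):
        """Mutant A hits four genes, mutant B six variants, overlap only at g1."""
        iv = _Interval("chr6", 1, 10_000)
        a = [call("g1", 100), call("g2", 900), call("g3", 2000), call("g4", 3000)]
        b = [call("g1", 150)] + [call(f"h{i}", 4000 + i, "missense") for i in range(5)]
        assert intersect_allelic_candidates({"A": a, "B": b}, iv) == ["g1"]

    def test_disjoint_gene_sets_yield_nothing(self):
        iv = _Interval("chr6", 1, 10_000)
        assert intersect_allelic_candidates(
            {"A": [call("g1", 100)], "B": [call("g2", 200)]}, iv
        ) == []

    def test_non_coding_effects_do_not_count(self):
        iv = _Interval("chr6", 1, 10_000)
        a = [call("g1", 100, "synonymous")]
        b = [call("g1", 150)]
        assert intersect_allelic_candidates({"A": a, "B": b}, iv) == []

    def test_variants_outside_interval_ignored(self):
        iv = _Interval("chr6", 1, 120)
        a = [call("g1", 100), call("g2", 500)]
        b = [call("g1", 110), call("g2", 600)]
        assert intersect_allelic_candidates({"A": a, "B": b}, iv) == ["g1"]

    def test_matches_brute_force_set_intersection(self, rng):
        iv = _Interval("chr6", 0, 10**6)
        effects = sorted(CODING_IMPACT) + ["synonymous", "intronic"]
        for _ in range(30):
            calls = {
                m: [
                    call(f"g{rng.integers(8)}", int(rng.integers(1, 10**6)),
                         effects[rng.integers(len(effects))])
                    for _ in range(rng.integers(1, 15))
                ]
                for m in ("A", "B", "C")
            }
            expect = set.intersection(
                *(
                    {c.gene_id for c in cs if c.effect in CODING_IMPACT}
                    for cs in calls.values()
                )
            )
            assert set(intersect_allelic_candidates(calls, iv)) == expect

    def test_empty_interval_gives_empty_list(self):
        assert intersect_allelic_candidates({"A": [], "B": []}, None) == []


class TestSubstitutionOffset:
    @pytest.mark.parametrize("a,b,expect", [(306, 395, 89), (391, 395, 4), (395, 395, 0)])
    def test_printed_residue_separations(self, a, b, expect):
        assert substitution_offset(a, b) == expect

    def test_rejects_nonpositive_positions(self):
        with pytest.raises(ValueError):
            substitution_offset(0, 5)
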