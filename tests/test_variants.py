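"""Variant parsing, per-isoform consequences and ISA classification."""

import numpy as np
import pytest

import isoselect as iso
from isoselect.variants import (
    UnsupportedVariantError,
    VariantError,
    apply_variant,
    c_notation,
    isa_report,
)

from conftest import make_transcript
from oracles import mutate_spliced, oracle_category


class TestVariantRecord:
    def test_snv_normalisation_is_identity(self):
        v = iso.VariantRecord("chr1", 101, "C", "A")
        assert (v.pos0, v.nref, v.nalt) == (100, "C", "A")
        assert v.variant_class == "SNV"
        assert v.footprint == (100, 101)

    def test_anchored_insertion_trims_to_empty_ref(self):
        v = iso.VariantRecord("chr1", 10, "A", "AGG")
        assert (v.pos0, v.nref, v.nalt) == (10, "", "GG")
        assert v.variant_class == "insertion"
        assert v.footprint == (9, 10)  # the base after which insertion occurs

    def test_anchored_deletion_trims_left_aligned(self):
        v = iso.VariantRecord("chr1", 10, "ACT", "A")
        assert (v.pos0, v.nref, v.nalt) == (10, "CT", "")
        assert v.variant_class == "deletion"
        assert v.footprint == (10, 12)

    def test_shared_suffix_trimmed(self):
        v = iso.VariantRecord("chr1", 10, "CTT", "GTT")
        assert (v.pos0, v.nref, v.nalt) == (9, "C", "G")

    def test_empty_allele_rejected(self):
        with pytest.raises(VariantError):
            iso.VariantRecord("chr1", 10, "", "A")


class TestParseVariants:
    def test_vcf_parsing_splits_multiallelic(self, tmp_path):
        g = iso.GenomeSequence({"chr1": "AACGTACGTACG"})
        vcf = tmp_path / "v.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=12>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t3\t.\tC\tA,T\t.\tPASS\t.\n"
        )
        records = iso.parse_variants(vcf, g)
        assert [(v.pos, v.alt) for v in records] == [(3, "A"), (3, "T")]

    def test_reference_mismatch_rejected_with_log(self, tmp_path, caplog):
        g = iso.GenomeSequence({"chr1": "AACGTACGTACG"})
        vcf = tmp_path / "v.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=12>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t3\t.\tG\tA\t.\tPASS\t.\n"
        )
        assert iso.parse_variants(vcf, g) == []
        assert "mismatch" in caplog.text

    def test_clinvar_style_tsv(self, tmp_path):
        g = iso.GenomeSequence({"chr1": "AACGTACGTACG"})
        tsv = tmp_path / "v.tsv"
        tsv.write_text(
            "Chromosome\tPosition\tReferenceAllele\tAlternateAllele\t"
            "ClinicalSignificance\tCondition\n"
            "chr1\t3\tC\tA\tPathogenic\tToy disease\n"
        )
        (v,) = iso.parse_variants(tsv, g)
        assert (v.pos, v.ref, v.alt) == (3, "C", "A")
        assert v.significance == "Pathogenic"
        assert v.condition == "Toy disease"

    def test_simulated_vcf_roundtrips(self, sim, tmp_path):
        paths = sim.sim.write(tmp_path / "b")
        genome = iso.load_genome(paths["genome"])
        records = iso.parse_variants(paths["variants"], genome)
        assert len(records) == len(sim.sim.variants)
        got = {(v.contig, v.pos0, v.nref, v.nalt) for v in records}
        exp = {(v.contig, v.pos0, v.nref, v.nalt) for v in sim.sim.variants}
        assert got == exp


class TestApplyVariant:
    @pytest.fixture()
    def toy(self):
        seq = "AAATGAAACCCGGGTGATTTT"
        return make_transcript({"chr1": seq}, exons=((0, 21),), cds=(2, 17))

    def test_snv_changes_one_base(self, toy):
        t, g = toy
        app = apply_variant(t, g, iso.VariantRecord("chr1", 6, "A", "G"))
        assert app.applicable
        assert len(app.sequence) == t.length
        assert app.sequence[5] == "G"
        assert app.posmap == list(range(t.length))

    def test_insertion_shifts_downstream_positions(self, toy):
        t, g = toy
        v = iso.VariantRecord("chr1", 6, "A", "A" + "T" * 20)
        app = apply_variant(t, g, v)
        assert len(app.sequence) == t.length + 20
        assert app.posmap[5] == 5
        assert app.posmap[6] == 26

    def test_intronic_variant_leaves_spliced_sequence(self):
        seq = "ATGAAA" + "GTCCAG" + "CCCTGA"
        t, g = make_transcript({"chr1": seq}, exons=((0, 6), (12, 18)), cds=(0, 18))
        app = apply_variant(t, g, iso.VariantRecord("chr1", 8, "T", "A"))
        assert not app.applicable
        assert app.sequence == t.spliced_sequence(g)

    def test_exon_boundary_spanning_deletion_unsupported(self):
        seq = "ATGAAA" + "GTCCAG" + "CCCTGA"
        t, g = make_transcript({"chr1": seq}, exons=((0, 6), (12, 18)), cds=(0, 18))
        with pytest.raises(UnsupportedVariantError):
            apply_variant(t, g, iso.VariantRecord("chr1", 5, "AGTC", "A"))

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_exon_surgery_oracle(self, strand, sim):
        rng = np.random.default_rng(11)
        models = [t for t in sim.transcripts.values() if t.strand == strand]
        checked = 0
        while checked < 150:
            t = models[rng.integers(0, len(models))]
            span = (t.exons[0][0], t.exons[-1][1])
            pos0 = int(rng.integers(span[0], span[1] - 4))
            ref = sim.genome.fetch(t.contig, pos0, pos0 + int(rng.integers(1, 4)))
            kind = rng.integers(0, 3)
            if kind == 0:
                alt = "ACGT"[int(rng.integers(0, 4))]
                if alt == ref[0]:
                    continue
                v = iso.VariantRecord(t.contig, pos0 + 1, ref[0], alt)
            elif kind == 1:
                v = iso.VariantRecord(t.contig, pos0 + 1, ref, ref[0])
            else:
                v = iso.VariantRecord(t.contig, pos0 + 1, ref[0], ref[0] + "TTG")
            expected = mutate_spliced(sim.genome, t, v)
            try:
                app = apply_variant(t, sim.genome, v)
            except UnsupportedVariantError:
                assert expected == "unsupported"
                checked += 1
                continue
            assert expected != "unsupported"
            if expected is None:
                assert not app.applicable
            else:
                assert app.sequence == expected[0]
            checked += 1


class TestConsequencesWorkedExamples:
    """The printed worked cases: TRNT1-like and NAXE-like variants."""

    def _call(self, micro, gene, variant_id):
        v = next(v for v in micro.sim.variants if v.variant_id == variant_id)
        return iso.classify_isa(v, micro.pair(gene), micro.transcripts, micro.genome)

    def test_frameshift_insertion_spares_truncated_isoform(self, micro):
        call = self._call(micro, "TRNT1L", "TRNT1L_c74ins20")
        assert call.category == "annotated_only_LoF"
        ann = call.consequences["annotated"]
        assert ann.consequence == "frameshift"
        assert ann.p_notation == "p.Gln25Hisfs*6"
        assert ann.first_changed_residue == 25
        assert call.consequences["alternative"].consequence == "upstream_of_start"

    @pytest.mark.parametrize(
        "variant_id,p_ann",
        [("TRNT1L_c88A_T", "p.Met30Leu"), ("TRNT1L_c88A_G", "p.Met30Val")],
    )
    def test_alternative_start_codon_mutations(self, micro, variant_id, p_ann):
        call = self._call(micro, "TRNT1L", variant_id)
        assert call.category == "alternative_start_loss"
        assert call.consequences["annotated"].consequence == "missense"
        assert call.consequences["annotated"].p_notation == p_ann
        assert call.consequences["alternative"].consequence == "start_loss"

    def test_nonsense_between_starts(self, micro):
        call = self._call(micro, "NAXEL", "NAXEL_c128C_A")
        assert call.category == "annotated_only_LoF"
        ann = call.consequences["annotated"]
        assert (ann.consequence, ann.p_notation) == ("nonsense", "p.Ser43Ter")
        assert ann.c_notation == "c.128C>A"
        assert call.consequences["alternative"].consequence == "upstream_of_start"

    def test_isoform_specific_missense(self, micro):
        call = self._call(micro, "NAXEL", "NAXEL_c16C_T")
        assert call.category == "isoform_specific_missense"
        assert call.consequences["annotated"].p_notation == "p.Arg6Trp"

    def test_notation_regeneration_is_deterministic(self, micro):
        for gene, vid in (("TRNT1L", "TRNT1L_c74ins20"), ("NAXEL", "NAXEL_c128C_A")):
            a = self._call(micro, gene, vid)
            b = self._call(micro, gene, vid)
            for role in ("annotated", "alternative"):
                assert a.consequences[role].p_notation == b.consequences[role].p_notation
                assert a.consequences[role].c_notation == b.consequences[role].c_notation


class TestClassifyIsaProperties:
    def test_planted_truth_recovered(self, sim):
        pairs = {(p.gene_id, p.pair_type): p for p in sim.pairs}
        vmap = {(v.contig, v.pos, v.ref, v.alt): v for v in sim.sim.variants}
        for tv in sim.sim.truth["variants"]:
            v = vmap[(tv["contig"], tv["pos"], tv["ref"], tv["alt"])]
            for ptype, exp in tv["per_pair"].items():
                call = iso.classify_isa(
                    v, pairs[(tv["gene"], ptype)], sim.transcripts, sim.genome
                )
                assert call.category == exp["category"], (tv["design"], ptype)
                assert call.consequences["annotated"].consequence == exp["annotated"]
                assert (
                    call.consequences["alternative"].consequence == exp["alternative"]
                )

    def test_variant_5prime_of_alt_start_never_changes_alternative(self, sim):
        """Inter-start variants leave the short isoform's protein intact."""
        pairs = {(p.gene_id, p.pair_type): p for p in sim.pairs}
        vmap = {(v.contig, v.pos, v.ref, v.alt): v for v in sim.sim.variants}
        n = 0
        for tv in sim.sim.truth["variants"]:
            if tv["design"] not in (
                "nonsense_inter_start", "frameshift_inter_start",
                "insertion_before_alt_start", "missense_inter_start",
            ):
                continue
            v = vmap[(tv["contig"], tv["pos"], tv["ref"], tv["alt"])]
            pair = pairs[(tv["gene"], "truncation")]
            cc = iso.consequence_for_isoform(
                v, pair, "alternative", sim.transcripts, sim.genome
            )
            ann, alt = iso.build_pair_proteoforms(pair, sim.transcripts, sim.genome)
            assert cc.consequence == "upstream_of_start"
            assert cc.mutant_protein == alt.sequence
            n += 1
        assert n >= 10

    def test_each_variant_maps_to_exactly_one_category(self, sim):
        from isoselect.variants import ISA_CATEGORIES

        pairs = {(p.gene_id, p.pair_type): p for p in sim.pairs}
        for tv in sim.sim.truth["variants"]:
            v = next(
                x for x in sim.sim.variants
                if (x.contig, x.pos, x.ref, x.alt)
                == (tv["contig"], tv["pos"], tv["ref"], tv["alt"])
            )
            for ptype in tv["per_pair"]:
                call = iso.classify_isa(
                    v, pairs[(tv["gene"], ptype)], sim.transcripts, sim.genome
                )
                assert call.category in ISA_CATEGORIES

    def test_matches_brute_force_oracle_on_random_variants(self, sim):
        """Spot-check against the mutate-translate-compare oracle (the full
        1000-variant sweep runs in the acceptance suite)."""
        rng = np.random.default_rng(7)
        pairs = [p for p in sim.pairs]
        checked = 0
        while checked < 200:
            pair = pairs[rng.integers(0, len(pairs))]
            t = sim.transcripts[pair.transcript_id]
            v = _random_variant(rng, sim.genome, t)
            if v is None:
                continue
            expected = oracle_category(v, pair, sim.transcripts, sim.genome)
            if expected == "unsupported":
                with pytest.raises(UnsupportedVariantError):
                    iso.classify_isa(v, pair, sim.transcripts, sim.genome)
                checked += 1
                continue
            call = iso.classify_isa(v, pair, sim.transcripts, sim.genome)
            assert call.category == expected, str(v)
            checked += 1


def _random_variant(rng, genome, t):
    span = (t.exons[0][0], t.exons[-1][1])
    pos0 = int(rng.integers(span[0], span[1] - 24))
    kind = int(rng.integers(0, 4))
    base = genome.base(t.contig, pos0)
    if kind == 0:  # SNV
        alt = "ACGT"[int(rng.integers(0, 4))]
        if alt == base:
            return None
        return iso.VariantRecord(t.contig, pos0 + 1, base, alt)
    if kind == 1:  # short deletion
        n = int(rng.integers(1, 4))
        ref = genome.fetch(t.contig, pos0, pos0 + n + 1)
        return iso.VariantRecord(t.contig, pos0 + 1, ref, ref[0])
    if kind == 2:  # short insertion
        ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=int(rng.integers(1, 4))))
        return iso.VariantRecord(t.contig, pos0 + 1, base, base + ins)
    # 20-nt insertion (patient-allele style)
    ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=20))
    return iso.VariantRecord(t.contig, pos0 + 1, base, base + ins)


class TestIntersectAltStarts:
    def _starts(self):
        return [("chr1", 100, 103, "G1"), ("chr1", 200, 203, "G2")]

    def test_snv_inside_codon_hits(self):
        g = [("chr1", 100, 103, "G1")]
        v = iso.VariantRecord("chr1", 102, "A", "C")  # middle base, pos0=101
        hits = iso.intersect_alt_starts([v], g)
        assert [(h[0], h[1]) for h in hits] == [(v, "G1")]

    def test_snv_one_base_5prime_misses(self):
        v = iso.VariantRecord("chr1", 100, "A", "C")  # pos0=99, codon is [100,103)
        assert iso.intersect_alt_starts([v], self._starts()) == []

    def test_empty_variant_list(self):
        assert iso.intersect_alt_starts([], self._starts()) == []

    def test_deletion_footprint_spans_deleted_bases(self):
        v = iso.VariantRecord("chr1", 98, "AAAA", "A")  # deletes pos0 98..100
        hits = iso.intersect_alt_starts([v], self._starts())
        assert len(hits) == 1

    def test_insertion_footprint_is_single_anchor_base(self):
        # insertion after pos0 99 (between 99 and 100): footprint [99, 100)
        v = iso.VariantRecord("chr1", 100, "A", "ATT")
        assert iso.intersect_alt_starts([v], self._starts()) == []
        v2 = iso.VariantRecord("chr1", 101, "A", "ATT")  # after base 100: inside
        assert len(iso.intersect_alt_starts([v2], self._starts())) == 1


class TestIsaReport:
    def test_tallies_conserved_and_match_truth(self, sim):
        pairs = {(p.gene_id, p.pair_type): p for p in sim.pairs}
        calls = []
        for tv in sim.sim.truth["variants"]:
            v = next(
                x for x in sim.sim.variants
                if (x.contig, x.pos, x.ref, x.alt)
                == (tv["contig"], tv["pos"], tv["ref"], tv["alt"])
            )
            for ptype in tv["per_pair"]:
                calls.append(
                    iso.classify_isa(v, pairs[(tv["gene"], ptype)],
                                     sim.transcripts, sim.genome)
                )
        report = isa_report(calls)
        assert report["n_calls"] == len(calls)
        assert sum(report["by_category"].values()) == len(calls)
        nonzero = {k: v for k, v in report["by_category"].items() if v}
        assert nonzero == sim.sim.truth["tallies"]
        per_gene_total = sum(
            sum(c.values()) for c in report["per_gene"].values()
        )
        assert per_gene_total == len(calls)

    def test_empty_input_gives_all_zero_report(self):
        report = isa_report([])
        assert report["n_calls"] == 0
        assert all(v == 0 for v in report["by_category"].values())
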