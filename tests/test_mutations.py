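"""Variant effect classification, ancestral filtering, recurrence tallies,
genome binning, enrichment and the duplication-site heuristic."""

import numpy as np
import pytest
from Bio.Seq import Seq, reverse_complement

from dualmark.mutations import (
    CloneVariantCohort,
    GeneModel,
    MutationEffect,
    ReferenceGenome,
    VariantCall,
    ancestral_filter,
    classify_variant,
    cohort_hit_fraction,
    gene_enrichment,
    load_annotation,
    load_variants,
    merge_callsets,
    normalize_variant,
    select_duplication_sites,
    tallies_to_frame,
    tally_genes,
    window_bin,
    window_count,
)
from dualmark.synth import gen_escape_clones, gen_reference, write_clone_vcfs, write_reference


def oracle_classify(v, gene, genome):
    """Independent oracle: rebuild the full mutant CDS, translate both with
    Biopython, and derive the category from the protein diff and length change
    (same category precedence as the classifier)."""
    region = genome.sequence[gene.start - 1 : gene.end]
    offset = v.pos - gene.start
    mutant = region[:offset] + v.alt + region[offset + len(v.ref) :]
    if gene.strand == "-":
        region, mutant = reverse_complement(region), reverse_complement(mutant)
    if mutant[:3] != region[:3]:
        return MutationEffect.START_LOST
    shift = len(mutant) - len(region)
    if shift % 3 != 0:
        return MutationEffect.FRAMESHIFT
    if shift != 0:
        return MutationEffect.INFRAME_INDEL
    p_ref = str(Seq(region).translate(table=11))
    p_alt = str(Seq(mutant).translate(table=11))
    ref_stop = p_ref.index("*") if "*" in p_ref else len(p_ref)
    alt_stop = p_alt.index("*") if "*" in p_alt else len(p_alt)
    if alt_stop < ref_stop:
        return MutationEffect.STOP_GAINED
    if alt_stop > ref_stop:
        return MutationEffect.STOP_LOST
    if p_alt != p_ref:
        return MutationEffect.NONSYNONYMOUS
    return MutationEffect.SYNONYMOUS


@pytest.fixture()
def toy_gene():
    # +strand gene: ATG CAG GGC TGC TAA embedded with 4 bp flanks
    seq = "ACGT" + "ATGCAGGGCTGCTAA" + "TTAA"
    genome = ReferenceGenome(sequence=seq)
    gene = GeneModel(name="g", start=5, end=19, strand="+")
    return genome, gene


class TestClassifier:

    def test_start_lost(self, toy_gene):
        genome, gene = toy_gene
        v = VariantCall("c", 7, "G", "A")  # ATG -> ATA
        assert classify_variant(v, gene, genome) == MutationEffect.START_LOST

    def test_stop_gained(self, toy_gene):
        genome, gene = toy_gene
        v = VariantCall("c", 8, "C", "T")  # CAG -> TAG
        assert classify_variant(v, gene, genome) == MutationEffect.STOP_GAINED

    def test_stop_lost(self, toy_gene):
        genome, gene = toy_gene
        v = VariantCall("c", 17, "T", "C")  # TAA -> CAA
        assert classify_variant(v, gene, genome) == MutationEffect.STOP_LOST

    def test_synonymous_third_position(self, toy_gene):
        genome, gene = toy_gene
        v = VariantCall("c", 13, "C", "T")  # GGC -> GGT
        assert classify_variant(v, gene, genome) == MutationEffect.SYNONYMOUS

    def test_nonsynonymous(self, toy_gene):
        genome, gene = toy_gene
        v = VariantCall("c", 14, "T", "G")  # TGC -> GGC
        assert classify_variant(v, gene, genome) == MutationEffect.NONSYNONYMOUS

    def test_frameshift_one_bp_deletion(self, toy_gene):
        genome, gene = toy_gene
        v = VariantCall("c", 11, "GG", "G")
        assert classify_variant(v, gene, genome) == MutationEffect.FRAMESHIFT

    def test_inframe_insertion(self, toy_gene):
        genome, gene = toy_gene
        v = VariantCall("c", 10, "G", "GAAA")
        assert classify_variant(v, gene, genome) == MutationEffect.INFRAME_INDEL

    def test_outside_gene_is_intergenic(self, toy_gene):
        genome, gene = toy_gene
        v = VariantCall("c", 2, "C", "T")
        assert classify_variant(v, gene, genome) == MutationEffect.INTERGENIC

    def test_ref_mismatch_names_position(self, toy_gene):
        genome, gene = toy_gene
        with pytest.raises(ValueError, match="position 7"):
            classify_variant(VariantCall("c", 7, "T", "A"), gene, genome)

    def test_minus_strand_classification(self):
        # same gene on the minus strand
        orf = "ATGCAGGGCTGCTAA"
        seq = "ACGT" + reverse_complement(orf) + "TTAA"
        genome = ReferenceGenome(sequence=seq)
        gene = GeneModel(name="g", start=5, end=19, strand="-")
        # genomic position of the CAG codon's C: CDS index 3 -> genomic end-3 = 16
        v = VariantCall("c", 16, genome.sequence[15], "A")  # C(AG)->T on coding strand
        assert classify_variant(v, gene, genome) == MutationEffect.STOP_GAINED

    def test_matches_translate_and_diff_oracle(self, toy_annotation, variant_sampler):
        """Codon-level classifier agrees exactly with the whole-CDS
        translate-and-diff oracle on random SNVs and indels."""
        genome, genes = toy_annotation
        rng = np.random.default_rng(77)
        for _ in range(2000):
            gene, pos, ref, alt = variant_sampler(rng, genome, genes)
            v = VariantCall("c", pos, ref, alt)
            assert classify_variant(v, gene, genome) == oracle_classify(v, gene, genome)


class TestLoadingAndMerging:
    def test_annotation_round_trip(self, toy_annotation, tmp_path):
        genome, genes = toy_annotation
        paths = write_reference(genome, genes, tmp_path)
        genome2, genes2 = load_annotation(paths["fasta"], paths["gene_table"])
        assert genome2.sequence == genome.sequence
        assert genes2 == genes

    def test_out_of_range_gene_rejected(self, tmp_path):
        (tmp_path / "ref.fa").write_text(">r\nACGTACGT\n")
        (tmp_path / "genes.tsv").write_text(
            "name\tstart\tend\tstrand\tessential\ng1\t2\t20\t+\t0\n"
        )
        with pytest.raises(ValueError, match="g1"):
            load_annotation(tmp_path / "ref.fa", tmp_path / "genes.tsv")

    def test_vcf_round_trip_and_ref_check(self, toy_annotation, tmp_path):
        genome, genes = toy_annotation
        from dualmark.synth import CohortSpec

        spec = CohortSpec(
            n_clones=3, causal_genes=("gene0002",), passenger_rate=4.0,
            ancestral_variants=2, seed=8,
        )
        cohort = gen_escape_clones(spec, genome, genes)
        paths = write_clone_vcfs(cohort, genome, tmp_path / "vcf")
        back = load_variants(paths, reference=genome)
        assert back.n_clones == 3
        assert {
            k for c in back.clones.values() for k in c
        } == {k for c in cohort.clones.values() for k in c}

    def test_ref_mismatch_on_load(self, tmp_path):
        (tmp_path / "c.vcf").write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=r,length=8>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "r\t3\t.\tT\tA\t.\tPASS\t.\n"
        )
        with pytest.raises(ValueError, match="position 3"):
            load_variants([tmp_path / "c.vcf"], reference=ReferenceGenome("ACGTACGT"))

    def test_multiallelic_split(self, tmp_path):
        (tmp_path / "c.vcf").write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=r,length=8>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "r\t3\t.\tG\tA,T\t.\tPASS\t.\n"
        )
        cohort = load_variants([tmp_path / "c.vcf"], reference=ReferenceGenome("ACGTACGT"))
        assert cohort.n_calls == 2

    def test_consensus_rule(self):
        def mk(keys):
            c = CloneVariantCohort()
            for k in keys:
                c.add(VariantCall("clone1", *k))
            return c

        a, b, c = (1, "A", "T"), (5, "G", "C"), (9, "T", "G")
        callsets = [mk([a, b]), mk([a, c]), mk([a])]
        consensus = merge_callsets(callsets, min_callers=2)
        assert set(consensus.clones["clone1"]) == {a}
        union = merge_callsets(callsets, min_callers=1)
        assert set(union.clones["clone1"]) == {a, b, c}
        with pytest.raises(ValueError):
            merge_callsets(callsets, min_callers=4)

    def test_indel_left_alignment_merges_caller_representations(self):
        #     123456789
        seq = "ACGAAAGTC"
        # deleting any A of the run is the same event; both must left-align
        assert normalize_variant(4, "AA", "A", seq) == normalize_variant(5, "AA", "A", seq)
        assert normalize_variant(3, "GAA", "GA", seq) == (3, "GA", "G")


class TestAncestralFilter:
    def make_cohort(self, n=96):
        cohort = CloneVariantCohort()
        for i in range(n):
            clone = f"c{i}"
            cohort.add(VariantCall(clone, 100, "A", "T"))  # in all clones
            if i < 53:
                cohort.add(VariantCall(clone, 200, "C", "G"))  # 53/96
            if i < 2:
                cohort.add(VariantCall(clone, 300, "G", "A"))  # 2/96
        return cohort

    def test_majority_variants_are_ancestral(self):
        ancestral, filtered = ancestral_filter(self.make_cohort())
        assert (100, "A", "T") in ancestral
        assert (200, "C", "G") in ancestral  # 53/96 = 0.552 > 0.5
        assert (300, "G", "A") not in ancestral
        keys = {k for c in filtered.clones.values() for k in c}
        assert keys == {(300, "G", "A")}

    def test_threshold_is_configurable(self):
        ancestral, _ = ancestral_filter(self.make_cohort(), threshold_fraction=0.9)
        assert ancestral == [(100, "A", "T")]

    def test_needs_two_clones(self):
        c = CloneVariantCohort()
        c.add(VariantCall("only", 1, "A", "T"))
        with pytest.raises(ValueError):
            ancestral_filter(c)


class TestTalliesAndEnrichment:
    def test_distinct_total_genomes_hit(self, toy_annotation):
        genome, genes = toy_annotation
        g1 = genes[0]
        pos1, pos2 = g1.start + 4, g1.start + 7
        cohort = CloneVariantCohort()
        v1 = (pos1, genome.sequence[pos1 - 1], "T" if genome.sequence[pos1 - 1] != "T" else "C")
        v2 = (pos2, genome.sequence[pos2 - 1], "T" if genome.sequence[pos2 - 1] != "T" else "C")
        cohort.add(VariantCall("A", *v1))
        cohort.add(VariantCall("B", *v1))
        cohort.add(VariantCall("B", *v2))
        tallies = {t.gene: t for t in tally_genes(cohort, genes, genome)}
        t = tallies[g1.name]
        assert (t.distinct, t.total, t.genomes_hit) == (2, 3, 2)
        assert t.total >= t.distinct
        assert tallies[genes[1].name].distinct == 0

    def test_lof_fraction_counts_distinct_lof(self, toy_annotation):
        genome, genes = toy_annotation
        g = genes[0]  # + strand
        cohort = CloneVariantCohort()
        # start-lost SNV and a 1-bp frameshift: both LoF
        cohort.add(VariantCall("A", g.start, "A", "T"))
        anchor = g.start + 9
        cohort.add(
            VariantCall("A", anchor, genome.sequence[anchor - 1 : anchor + 1], genome.sequence[anchor - 1])
        )
        tallies = {t.gene: t for t in tally_genes(cohort, genes, genome)}
        assert tallies[g.name].lof_fraction == 1.0

    def test_conservation_across_bins_and_genes(self, default_cohort, toy_annotation):
        """Window-bin total equals retained cohort size equals gene totals
        plus intergenic calls."""
        genome, genes = toy_annotation
        cohort, _ = default_cohort
        _, filtered = ancestral_filter(cohort)
        bins = window_bin(filtered, genome.length, 2000)
        assert bins.sum() == filtered.n_calls
        tallies = tally_genes(filtered, genes, genome)
        gene_total = sum(t.total for t in tallies)
        tree_names = set()
        intergenic = filtered.n_calls - gene_total
        assert intergenic >= 0
        assert gene_total + intergenic == filtered.n_calls

    def test_boundary_position_goes_to_right_bin(self):
        cohort = CloneVariantCohort()
        cohort.add(VariantCall("c", 774_500, "A", "T"))
        cohort.add(VariantCall("c", 775_100, "A", "T"))
        cohort.add(VariantCall("c", 777_900, "A", "T"))
        cohort.add(VariantCall("c", 776_000, "A", "G"))  # exactly on a boundary
        bins = window_bin(cohort, 800_000, 2000)
        assert bins[774_000 // 2000] == 2
        assert bins[776_000 // 2000] == 2
        assert window_count(cohort, 774_000, 778_000) == 4

    def test_operon_share_example(self):
        """67 of 108 operon mutations in a 1266-bp gene out of (1266, 693, 429)
        bp: observed share 62.0%, length-expected share 53.0%."""
        genes = [
            GeneModel("tolA_like", 1, 1266, "+"),
            GeneModel("tolQ_like", 2001, 2693, "+"),
            GeneModel("tolR_like", 3001, 3429, "+"),
        ]
        from dualmark.mutations import GeneMutationTally

        tallies = [
            GeneMutationTally("tolA_like", 23, 67, 50, 0.87),
            GeneMutationTally("tolQ_like", 14, 25, 20, 0.71),
            GeneMutationTally("tolR_like", 8, 16, 14, 0.63),
        ]
        results = {e.gene: e for e in gene_enrichment(tallies, genes)}
        big = results["tolA_like"]
        assert round(100 * big.observed_share, 1) == 62.0
        assert round(100 * big.expected_share, 1) == 53.0
        assert big.rank == 1

    def test_two_equal_genes_closed_form_p(self):
        """All n scope mutations in one of two equal-length genes: the exact
        binomial p-value is 0.5^n."""
        genes = [GeneModel("a", 1, 300, "+"), GeneModel("b", 401, 700, "+")]
        from dualmark.mutations import GeneMutationTally

        n = 8
        tallies = [GeneMutationTally("a", n, n, n, 0.0), GeneMutationTally("b", 0, 0, 0, 0.0)]
        res = {e.gene: e for e in gene_enrichment(tallies, genes)}
        assert res["a"].p_value == pytest.approx(0.5**n, rel=1e-9)

    def test_null_counts_are_not_significant(self):
        genes = [GeneModel("a", 1, 600, "+"), GeneModel("b", 701, 1300, "+")]
        from dualmark.mutations import GeneMutationTally

        tallies = [GeneMutationTally("a", 10, 10, 5, 0.0), GeneMutationTally("b", 10, 10, 5, 0.0)]
        res = gene_enrichment(tallies, genes)
        assert all(e.p_value > 0.4 for e in res)

    def test_report_frame_columns(self, toy_annotation, default_cohort):
        genome, genes = toy_annotation
        cohort, _ = default_cohort
        _, filtered = ancestral_filter(cohort)
        tallies = tally_genes(filtered, genes, genome)
        df = tallies_to_frame(tallies, gene_enrichment(tallies, genes))
        assert {"gene", "distinct", "total", "genomes_hit", "lof_fraction",
                "expected_share", "observed_share", "p", "q", "rank"} <= set(df.columns)
        assert (df["total"] >= df["distinct"]).all()


class TestHitFractionAndDuplicationSites:
    def test_hit_fraction_and_complement(self, toy_annotation, default_cohort):
        genome, genes = toy_annotation
        cohort, spec = default_cohort
        _, filtered = ancestral_filter(cohort)
        frac, missing = cohort_hit_fraction(filtered, genes, list(spec.causal_genes))
        assert 0.0 <= frac <= 1.0
        assert len(missing) == cohort.n_clones - round(frac * cohort.n_clones)

    def test_empty_gene_set_zero(self, toy_annotation, default_cohort):
        genome, genes = toy_annotation
        cohort, _ = default_cohort
        frac, missing = cohort_hit_fraction(cohort, genes, [])
        assert frac == 0.0 and len(missing) == cohort.n_clones

    def test_duplication_site_arcs(self):
        """A candidate is accepted only when essential genes flank it on both
        circular arcs back to the source operon."""
        genome_length = 10_000
        source = GeneModel("operon", 1000, 1500, "+")
        genes = [
            source,
            GeneModel("ess1", 3000, 3300, "+", essential=True),
            GeneModel("ess2", 8000, 8300, "+", essential=True),
            GeneModel("noness", 6000, 6300, "+", essential=False),
        ]
        results = {r["position"]: r for r in select_duplication_sites(
            genes, source, [5000, 2000, 9000, 6100, 700], genome_length
        )}
        assert results[5000]["accepted"]  # ess1 on one arc, ess2 on the other
        assert not results[2000]["accepted"]  # near arc to source is empty
        assert not results[9000]["accepted"]  # ess2..source arc empty
        assert not results[6100]["accepted"] and "inside gene" in results[6100]["reason"]
        # 700: arcs are (1500 -> 700) containing both essentials and (700 -> 1000) empty
        assert not results[700]["accepted"]
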