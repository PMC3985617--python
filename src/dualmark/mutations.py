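"""Multi-clone escape-mutation diagnosis.

Counter-selection escape is diagnosed by re-sequencing many independent escape
clones and asking which genes are recurrently broken.  Given per-clone variant
calls (VCF), a reference genome (FASTA) and a gene table, this module:

* classifies each variant against its gene model (start-lost, frameshift,
  stop-gained, stop-lost, in-frame indel, nonsynonymous, synonymous,
  intergenic), on the coding strand, bacterial genetic code (NCBI table 11);
* filters *ancestral* variants — those carried by most clones are strain
  background, not escape mutations;
* tallies distinct mutations, total incidence and the loss-of-function (LoF)
  fraction per gene, bins mutations along the genome, and ranks genes by
  recurrence with a coding-length-normalized exact binomial enrichment test;
* scores the fraction of clones carrying >=1 mutation in a candidate gene set;
* applies the duplication-site heuristic: a safe destination for a rescue copy
  of an operon is separated from the wild-type copy by at least one essential
  gene on *both* arcs of the circular chromosome, so that single-crossover
  loop-out between the identical copies always deletes an essential gene.

Coordinates are 1-based inclusive at all interfaces (VCF convention); bins are
half-open from 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import reverse_complement
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceGenome",
    "GeneModel",
    "VariantCall",
    "CloneVariantCohort",
    "GeneMutationTally",
    "EnrichmentResult",
    "MutationEffect",
    "LOF_CATEGORIES",
    "load_annotation",
    "load_variants",
    "merge_callsets",
    "ancestral_filter",
    "classify_variant",
    "tally_genes",
    "window_bin",
    "window_count",
    "gene_enrichment",
    "cohort_hit_fraction",
    "select_duplication_sites",
    "normalize_variant",
]

# --- genetic code (bacterial, NCBI table 11) --------------------------------

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
CODON_TO_AA: dict[str, str] = dict(_TABLE11.forward_table)
for _stop in _TABLE11.stop_codons:
    CODON_TO_AA[_stop] = "*"


class MutationEffect:
    START_LOST = "start_lost"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    STOP_GAINED = "stop_gained"
    STOP_LOST = "stop_lost"
    NONSYNONYMOUS = "nonsynonymous"
    SYNONYMOUS = "synonymous"
    INTERGENIC = "intergenic"


LOF_CATEGORIES = frozenset(
    {MutationEffect.START_LOST, MutationEffect.FRAMESHIFT, MutationEffect.STOP_GAINED}
)

#: stop_gained in the first quarter of a CDS may be rescued by a downstream
#: in-frame start codon; reports carry this caveat flag.
EARLY_STOP_CAVEAT_FRACTION = 0.25


@dataclass(frozen=True)
class ReferenceGenome:
    """Single circular chromosome as an upper-case A/C/G/T string."""

    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError("empty reference sequence")
        bad = set(seq) - set("ACGT")
        if bad:
            raise ValueError(f"non-ACGT characters in reference: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """1-based inclusive slice."""
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class GeneModel:
    """A CDS: 1-based inclusive coordinates, strand, essentiality flag."""

    name: str
    start: int
    end: int
    strand: str
    essential: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.name}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.name}: strand must be + or -")

    @property
    def coding_length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int, ref_len: int = 1) -> bool:
        """True iff the variant's reference span lies fully inside the gene."""
        return self.start <= pos and pos + ref_len - 1 <= self.end


@dataclass(frozen=True)
class VariantCall:
    clone_id: str
    pos: int
    ref: str
    alt: str

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass
class CloneVariantCohort:
    """Per-clone variant sets keyed by (pos, ref, alt)."""

    clones: dict[str, dict[tuple, VariantCall]] = field(default_factory=dict)

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    @property
    def n_calls(self) -> int:
        return sum(len(v) for v in self.clones.values())

    def add(self, call: VariantCall) -> bool:
        """Add a call; returns False (and logs) on a within-clone duplicate."""
        clone = self.clones.setdefault(call.clone_id, {})
        if call.key in clone:
            logger.warning(
                "duplicate record in clone %s at %s; deduplicated", call.clone_id, call.key
            )
            return False
        clone[call.key] = call
        return True

    def carriers(self) -> dict[tuple, set]:
        """variant key -> set of clone ids carrying it."""
        out: dict[tuple, set] = {}
        for clone_id, calls in self.clones.items():
            for key in calls:
                out.setdefault(key, set()).add(clone_id)
        return out

    def all_calls(self):
        for calls in self.clones.values():
            yield from calls.values()


@dataclass
class GeneMutationTally:
    """Recurrence tally for one gene across the cohort.

    ``total`` is distinct mutations times incidence summed over variants;
    ``lof_fraction`` is the share of *distinct* mutations that are
    loss-of-function (start-lost, frameshift or stop-gained)."""

    gene: str
    distinct: int
    total: int
    genomes_hit: int
    lof_fraction: float
    incidence_by_variant: dict = field(default_factory=dict)
    category_by_variant: dict = field(default_factory=dict)
    early_stop_caveats: list = field(default_factory=list)


@dataclass
class EnrichmentResult:
    gene: str
    observed_share: float
    expected_share: float
    p_value: float
    q_value: float
    rank: int


# --- loading ----------------------------------------------------------------


def load_annotation(fasta_path, gene_table_path) -> tuple[ReferenceGenome, list[GeneModel]]:
    """Load a reference FASTA (first record) and a TSV gene table
    (columns name, start, end, strand, essential)."""
    record = next(SeqIO.parse(str(fasta_path), "fasta"))
    genome = ReferenceGenome(sequence=str(record.seq))
    table = pd.read_csv(gene_table_path, sep="\t")
    required = {"name", "start", "end", "strand", "essential"}
    if not required.issubset(table.columns):
        raise ValueError(f"gene table needs columns {sorted(required)}")
    genes = []
    for row in table.itertuples():
        if row.end > genome.length or row.start < 1:
            raise ValueError(
                f"gene {row.name} [{row.start}, {row.end}] outside genome "
                f"of length {genome.length}"
            )
        genes.append(
            GeneModel(
                name=str(row.name),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                essential=bool(int(row.essential)),
            )
        )
    return genome, genes


def normalize_variant(pos: int, ref: str, alt: str, sequence: str) -> tuple[int, str, str]:
    """Trim shared context and left-align indels so identical events from
    different callers share a key."""
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # left-shift anchored indels through repeats
    while (
        len(ref) != len(alt)
        and min(len(ref), len(alt)) == 1
        and ref[-1] == alt[-1]
        and pos > 1
    ):
        prev = sequence[pos - 2]
        ref, alt = prev + ref[:-1], prev + alt[:-1]
        pos -= 1
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def load_variants(
    vcf_paths,
    reference: ReferenceGenome | None = None,
    clone_ids: list[str] | None = None,
) -> CloneVariantCohort:
    """Load per-clone VCFs into a cohort.

    One path per clone; the clone id defaults to the file stem.  Multi-allelic
    records are split per ALT; duplicates within a clone are dropped with a
    warning; REF alleles are checked against the reference when given.
    """
    import pysam

    paths = [Path(p) for p in vcf_paths]
    if clone_ids is None:
        clone_ids = [p.name.removesuffix(".vcf").removesuffix(".vcf.gz") for p in paths]
    cohort = CloneVariantCohort()
    for clone_id, path in zip(clone_ids, paths):
        cohort.clones.setdefault(clone_id, {})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vf = pysam.VariantFile(str(path))
            for rec in vf.fetch() if vf.index is not None else vf:
                for alt in rec.alts or ():
                    pos, ref, alt_a = rec.pos, rec.ref.upper(), str(alt).upper()
                    if reference is not None:
                        observed = reference.slice(pos, pos + len(ref) - 1)
                        if observed != ref:
                            raise ValueError(
                                f"REF mismatch at position {pos} in {path.name}: "
                                f"VCF says {ref}, reference has {observed}"
                            )
                        pos, ref, alt_a = normalize_variant(
                            pos, ref, alt_a, reference.sequence
                        )
                    cohort.add(VariantCall(clone_id=clone_id, pos=pos, ref=ref, alt=alt_a))
            vf.close()
    return cohort


def merge_callsets(callsets: list[CloneVariantCohort], min_callers: int) -> CloneVariantCohort:
    """Consensus across variant callers: keep calls present in >= min_callers
    callsets (matched per clone on the (pos, ref, alt) key)."""
    if not callsets:
        raise ValueError("need at least one callset")
    if not 1 <= min_callers <= len(callsets):
        raise ValueError(
            f"min_callers must lie in [1, {len(callsets)}]; got {min_callers}"
        )
    merged = CloneVariantCohort()
    clone_ids = set().union(*(c.clones.keys() for c in callsets))
    for clone_id in sorted(clone_ids):
        support: dict[tuple, int] = {}
        for callset in callsets:
            for key in callset.clones.get(clone_id, {}):
                support[key] = support.get(key, 0) + 1
        merged.clones[clone_id] = {
            key: VariantCall(clone_id, *key)
            for key, n in support.items()
            if n >= min_callers
        }
    return merged


def ancestral_filter(
    cohort: CloneVariantCohort, threshold_fraction: float = 0.5
) -> tuple[list[tuple], CloneVariantCohort]:
    """Split off ancestral (strain-background) variants.

    A variant carried by more than ``threshold_fraction`` of clones predates
    the selection and cannot explain independent escape events; it is removed
    from the causal analysis and returned separately."""
    if cohort.n_clones < 2:
        raise ValueError("ancestral filtering needs at least 2 clones")
    n = cohort.n_clones
    ancestral = sorted(
        key for key, who in cohort.carriers().items() if len(who) / n > threshold_fraction
    )
    ancestral_set = set(ancestral)
    filtered = CloneVariantCohort(
        clones={
            clone_id: {k: v for k, v in calls.items() if k not in ancestral_set}
            for clone_id, calls in cohort.clones.items()
        }
    )
    return ancestral, filtered


# --- effect classification --------------------------------------------------


def _classify_cds(ref_cds: str, alt_cds: str) -> str:
    """Classify a coding-strand CDS edit by category precedence:
    start_lost > frameshift/inframe_indel > stop_gained > stop_lost >
    nonsynonymous > synonymous."""
    if alt_cds[:3] != ref_cds[:3]:
        return MutationEffect.START_LOST
    shift = len(alt_cds) - len(ref_cds)
    if shift % 3 != 0:
        return MutationEffect.FRAMESHIFT
    if shift != 0:
        return MutationEffect.INFRAME_INDEL
    gained = lost = changed = False
    for i in range(0, len(ref_cds) - 2, 3):
        rc, ac = ref_cds[i : i + 3], alt_cds[i : i + 3]
        if rc == ac:
            continue
        raa, aaa = CODON_TO_AA[rc], CODON_TO_AA[ac]
        if aaa == "*" and raa != "*":
            gained = True
        elif raa == "*" and aaa != "*":
            lost = True
        elif raa != aaa:
            changed = True
    if gained:
        return MutationEffect.STOP_GAINED
    if lost:
        return MutationEffect.STOP_LOST
    if changed:
        return MutationEffect.NONSYNONYMOUS
    return MutationEffect.SYNONYMOUS


def classify_variant(
    v: VariantCall, gene: GeneModel, ref: ReferenceGenome
) -> str:
    """Effect of a variant on a gene, evaluated on the coding strand.

    The gene's reference region is edited in place, both regions are oriented
    to the coding strand (reverse complement for minus-strand genes) and the
    resulting CDS pair is classified.  Variants not fully inside the gene are
    intergenic with respect to it.
    """
    observed = ref.slice(v.pos, v.pos + len(v.ref) - 1)
    if observed != v.ref:
        raise ValueError(
            f"REF mismatch at position {v.pos}: call says {v.ref}, reference has {observed}"
        )
    if not gene.contains(v.pos, len(v.ref)):
        return MutationEffect.INTERGENIC
    region = ref.slice(gene.start, gene.end)
    offset = v.pos - gene.start
    mutant = region[:offset] + v.alt + region[offset + len(v.ref) :]
    if gene.strand == "-":
        region, mutant = reverse_complement(region), reverse_complement(mutant)
    return _classify_cds(region, mutant)


def _build_gene_tree(genes: list[GeneModel]) -> IntervalTree:
    tree = IntervalTree()
    for g in genes:
        tree[g.start : g.end + 1] = g
    return tree


def _assign_gene(tree: IntervalTree, v: VariantCall) -> GeneModel | None:
    hits = [iv.data for iv in tree[v.pos] if iv.data.contains(v.pos, len(v.ref))]
    if not hits:
        return None
    # deterministic choice if gene models overlap
    return min(hits, key=lambda g: (g.start, g.name))


def _cds_fraction(gene: GeneModel, pos: int) -> float:
    if gene.strand == "+":
        return (pos - gene.start) / gene.coding_length
    return (gene.end - pos) / gene.coding_length


def tally_genes(
    cohort: CloneVariantCohort, genes: list[GeneModel], ref: ReferenceGenome
) -> list[GeneMutationTally]:
    """Per-gene recurrence tallies over the (ancestral-filtered) cohort.

    Every gene in the table gets a tally (zeros when unmutated).  Early
    premature stops (first quarter of the CDS) are flagged as potentially
    rescued by downstream in-frame starts."""
    tree = _build_gene_tree(genes)
    per_gene: dict[str, dict] = {
        g.name: {"carriers": {}, "categories": {}, "clones": set(), "gene": g}
        for g in genes
    }
    class_cache: dict[tuple, str] = {}
    for call in cohort.all_calls():
        gene = _assign_gene(tree, call)
        if gene is None:
            continue
        bucket = per_gene[gene.name]
        bucket["carriers"].setdefault(call.key, set()).add(call.clone_id)
        bucket["clones"].add(call.clone_id)
        cache_key = (gene.name, call.key)
        if cache_key not in class_cache:
            class_cache[cache_key] = classify_variant(call, gene, ref)
        bucket["categories"][call.key] = class_cache[cache_key]

    tallies = []
    for name, bucket in per_gene.items():
        incidence = {k: len(who) for k, who in bucket["carriers"].items()}
        distinct = len(incidence)
        total = sum(incidence.values())
        cats = bucket["categories"]
        lof = sum(1 for c in cats.values() if c in LOF_CATEGORIES)
        caveats = [
            k
            for k, c in cats.items()
            if c == MutationEffect.STOP_GAINED
            and _cds_fraction(bucket["gene"], k[0]) < EARLY_STOP_CAVEAT_FRACTION
        ]
        tallies.append(
            GeneMutationTally(
                gene=name,
                distinct=distinct,
                total=total,
                genomes_hit=len(bucket["clones"]),
                lof_fraction=lof / distinct if distinct else 0.0,
                incidence_by_variant=incidence,
                category_by_variant=cats,
                early_stop_caveats=sorted(caveats),
            )
        )
    return tallies


# --- genome-scale summaries -------------------------------------------------


def window_bin(
    cohort: CloneVariantCohort, genome_length: int, bin_size: int = 2000
) -> np.ndarray:
    """Histogram of retained mutations in half-open bins [k*size, (k+1)*size)
    along the genome (counting every per-clone incidence)."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    n_bins = -(-genome_length // bin_size)
    counts = np.zeros(n_bins, dtype=int)
    for call in cohort.all_calls():
        counts[call.pos // bin_size] += 1
    return counts


def window_count(cohort: CloneVariantCohort, start: int, end: int) -> int:
    """Mutations (with incidence) in the half-open window [start, end)."""
    return sum(1 for call in cohort.all_calls() if start <= call.pos < end)


def gene_enrichment(
    tallies: list[GeneMutationTally],
    genes: list[GeneModel],
    scope: list[str] | None = None,
) -> list[EnrichmentResult]:
    """Coding-length-normalized recurrence enrichment.

    Within the scope (a gene-name list, or all genes), each gene's expected
    mutation share is its coding length over the scope's total coding length;
    the observed share is its total mutations over the scope total.  The
    p-value is the one-sided exact binomial P(X >= observed); q-values are
    Benjamini-Hochberg across the scope.  Results are ranked by distinct
    mutations, then total, then LoF fraction (all descending).
    """
    by_name = {g.name: g for g in genes}
    tally_by_name = {t.gene: t for t in tallies}
    names = list(scope) if scope is not None else [g.name for g in genes]
    if not names:
        raise ValueError("empty enrichment scope")
    missing = [n for n in names if n not in by_name]
    if missing:
        raise ValueError(f"scope genes not in gene table: {missing}")
    lengths = np.array([by_name[n].coding_length for n in names], dtype=float)
    totals = np.array([tally_by_name[n].total if n in tally_by_name else 0 for n in names])
    n_total = int(totals.sum())
    expected = lengths / lengths.sum()
    if n_total > 0:
        observed = totals / n_total
        pvals = stats.binom.sf(totals - 1, n_total, expected)
    else:
        observed = np.zeros_like(expected)
        pvals = np.ones_like(expected)
    qvals = multipletests(pvals, method="fdr_bh")[1]

    def sort_key(name):
        t = tally_by_name.get(name)
        if t is None:
            return (0, 0, 0.0)
        return (t.distinct, t.total, t.lof_fraction)

    order = sorted(range(len(names)), key=lambda i: sort_key(names[i]), reverse=True)
    results = [None] * len(names)
    for rank, i in enumerate(order, start=1):
        results[i] = EnrichmentResult(
            gene=names[i],
            observed_share=float(observed[i]),
            expected_share=float(expected[i]),
            p_value=float(pvals[i]),
            q_value=float(qvals[i]),
            rank=rank,
        )
    return sorted(results, key=lambda r: r.rank)


def cohort_hit_fraction(
    cohort: CloneVariantCohort,
    genes: list[GeneModel],
    gene_set: list[str],
) -> tuple[float, list[str]]:
    """Fraction of clones with >=1 retained mutation in the gene set, plus the
    complement clone list (candidates for rare escape mechanisms)."""
    if cohort.n_clones == 0:
        raise ValueError("empty cohort")
    wanted = set(gene_set)
    tree = _build_gene_tree([g for g in genes if g.name in wanted])
    hit = set()
    for call in cohort.all_calls():
        if _assign_gene(tree, call) is not None:
            hit.add(call.clone_id)
    missing = sorted(set(cohort.clones) - hit)
    return len(hit) / cohort.n_clones, missing


# --- duplication-site heuristic --------------------------------------------


def _arc_contains_gene(arc_start: int, arc_end: int, gene: GeneModel, genome_length: int) -> bool:
    """True iff the gene lies entirely within the forward (circular) arc
    (arc_start, arc_end), endpoints excluded."""
    span = (arc_end - arc_start) % genome_length
    g_start = (gene.start - arc_start) % genome_length
    g_end = (gene.end - arc_start) % genome_length
    return 0 < g_start <= g_end < span


def select_duplication_sites(
    genes: list[GeneModel],
    source_locus: GeneModel,
    candidates: list[int],
    genome_length: int,
) -> list[dict]:
    """Screen candidate insertion sites for a duplicated operon.

    A candidate is accepted iff it lies outside every annotated gene and each
    of the two circular arcs between the candidate and the source locus
    contains at least one essential gene, so that recombination-mediated
    loop-out between the copies (in either direction) removes an essential
    gene and is selected against.
    Returns one record per candidate: {position, accepted, reason}.
    """
    essentials = [g for g in genes if g.essential and g.name != source_locus.name]
    results = []
    for pos in candidates:
        inside = [
            g for g in genes if g.contains(pos)
        ]
        if inside:
            results.append(
                {
                    "position": pos,
                    "accepted": False,
                    "reason": f"inside gene {inside[0].name}",
                }
            )
            continue
        # forward arc source->candidate and candidate->source
        arc1 = any(
            _arc_contains_gene(source_locus.end, pos, g, genome_length) for g in essentials
        )
        arc2 = any(
            _arc_contains_gene(pos, source_locus.start, g, genome_length)
            for g in essentials
        )
        if arc1 and arc2:
            results.append({"position": pos, "accepted": True, "reason": "ok"})
        else:
            side = "downstream" if not arc1 else "upstream"
            results.append(
                {
                    "position": pos,
                    "accepted": False,
                    "reason": f"no essential gene on the {side} arc to the source locus",
                }
            )
    return results


def tallies_to_frame(
    tallies: list[GeneMutationTally], enrichment: list[EnrichmentResult] | None = None
) -> pd.DataFrame:
    """Flat report table: gene, distinct, total, genomes_hit, lof_fraction and,
    when supplied, expected/observed shares with p and q values."""
    df = pd.DataFrame(
        {
            "gene": [t.gene for t in tallies],
            "distinct": [t.distinct for t in tallies],
            "total": [t.total for t in tallies],
            "genomes_hit": [t.genomes_hit for t in tallies],
            "lof_fraction": [t.lof_fraction for t in tallies],
        }
    )
    if enrichment is not None:
        edf = pd.DataFrame(
            {
                "gene": [e.gene for e in enrichment],
                "expected_share": [e.expected_share for e in enrichment],
                "observed_share": [e.observed_share for e in enrichment],
                "p": [e.p_value for e in enrichment],
                "q": [e.q_value for e in enrichment],
                "rank": [e.rank for e in enrichment],
            }
        )
        df = df.merge(edf, on="gene", how="left")
    return df.sort_values(
        ["distinct", "total", "lof_fraction"], ascending=False
    ).reset_index(drop=True)
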