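"""Synthetic inputs with the statistical structure the analyses assume.

Every analysis module in this package consumes standard files (FASTA, VCF,
TSV, CSV).  This module generates all of them from explicit parameter specs
and integer seeds, so the full pipeline is exercisable end to end without any
external download:

* a random circular genome whose genes are clean ORFs (ATG ... in-frame stop),
  alternating strands, with per-gene essentiality flags;
* an escape-clone cohort: each clone carries, with a set probability, at least
  one mutation in a designated causal gene set (loss-of-function with a set
  bias), plus Poisson passenger mutations placed uniformly per bp genome-wide
  and a block of ancestral variants shared by every clone;
* logistic-style growth quartets whose selective lag is set by the resistant
  inoculum fraction;
* Poisson colony counts for plating experiments;
* single-cycle genotype matrices drawn from a conversion model.

File-writing entry points also emit a ``manifest.json`` recording every
parameter, for provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .cosmage import ConversionModel, PopulationState, simulate_cycle
from .escape import PlatingExperiment
from .mutations import (
    CODON_TO_AA,
    CloneVariantCohort,
    GeneModel,
    ReferenceGenome,
    VariantCall,
)
from .selection import GrowthCurve

__all__ = [
    "CohortSpec",
    "GrowthSpec",
    "gen_reference",
    "gen_escape_clones",
    "gen_growth_quartet",
    "gen_plating",
    "gen_genotype_population",
    "write_reference",
    "write_clone_vcfs",
    "write_quartet_csv",
    "write_platings_tsv",
]

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [c for c, aa in CODON_TO_AA.items() if aa != "*"]


@dataclass(frozen=True)
class CohortSpec:
    """Structure of a synthetic escape cohort.

    Defaults mirror the structure of a 96-clone resequencing experiment in a
    mismatch-repair-deficient background: ~93% of clones carry at least one
    causal loss-of-function hit, ~30 passenger mutations per clone and 21
    ancestral strain-background variants shared by all clones.
    """

    n_clones: int = 96
    causal_genes: tuple[str, ...] = ()
    causal_hit_prob: float = 0.93
    causal_lof_bias: float = 0.75
    passenger_rate: float = 30.0
    ancestral_variants: int = 21
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("causal_hit_prob", "causal_lof_bias"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.passenger_rate < 0 or self.ancestral_variants < 0 or self.n_clones < 1:
            raise ValueError("counts and rates must be non-negative, n_clones >= 1")


@dataclass(frozen=True)
class GrowthSpec:
    """Parameters of a synthetic selection quartet.

    ``resistant_fraction`` is the fraction of the *control* (unrecombined)
    inoculum able to grow under selection — i.e. the leakiness of the
    counter-selection.  At 1 the control grows like the recombinant and the
    selection has failed (NSA ~ 0); at ~0 the control never grows within the
    horizon (NSA -> 1, censored).  ``recombinant_fraction`` is the selectable
    fraction of the recombinant inoculum (1 for a fully working selection).
    OD(t) = min(carrying_od, od_per_cell * n(t)) with exponential n(t) after
    the lag, plus Gaussian read noise.
    """

    n0: float = 1e6
    resistant_fraction: float = 1e-6
    recombinant_fraction: float = 1.0
    doubling_time: float = 30.0
    lag: float = 60.0
    carrying_od: float = 1.2
    od_per_cell: float = 1e-8
    noise_sd: float = 0.0
    horizon: float = 2880.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("resistant_fraction", "recombinant_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("n0", "doubling_time", "carrying_od", "od_per_cell", "horizon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# --- reference genome -------------------------------------------------------


def gen_reference(
    n_genes: int,
    codons_per_gene,
    intergenic_bp: int,
    essential_mask=None,
    seed: int = 0,
) -> tuple[ReferenceGenome, list[GeneModel]]:
    """Random circular genome of clean ORFs separated by random spacers.

    ``codons_per_gene`` counts sense codons including the ATG start (a stop
    codon is appended), and may be an int or a per-gene sequence.  Strands
    alternate +/-; ``essential_mask`` flags essential genes (default: none).
    """
    if n_genes < 1 or intergenic_bp < 0:
        raise ValueError("need n_genes >= 1 and intergenic_bp >= 0")
    rng = np.random.default_rng(seed)
    if np.isscalar(codons_per_gene):
        codon_counts = [int(codons_per_gene)] * n_genes
    else:
        codon_counts = [int(c) for c in codons_per_gene]
        if len(codon_counts) != n_genes:
            raise ValueError("codons_per_gene sequence length must equal n_genes")
    if essential_mask is None:
        essential_mask = [False] * n_genes

    def spacer() -> str:
        return "".join(rng.choice(list(_BASES), size=intergenic_bp))

    parts = [spacer()]
    genes: list[GeneModel] = []
    pos = intergenic_bp
    for i, n_codons in enumerate(codon_counts):
        if n_codons < 2:
            raise ValueError("genes need at least 2 codons (start + one more)")
        body = rng.choice(_SENSE_CODONS, size=n_codons - 1)
        orf = "ATG" + "".join(body) + str(rng.choice(_STOPS))
        strand = "+" if i % 2 == 0 else "-"
        embedded = orf if strand == "+" else reverse_complement(orf)
        genes.append(
            GeneModel(
                name=f"gene{i + 1:04d}",
                start=pos + 1,
                end=pos + len(orf),
                strand=strand,
                essential=bool(essential_mask[i]),
            )
        )
        parts.append(embedded)
        pos += len(orf)
        parts.append(spacer())
        pos += intergenic_bp
    return ReferenceGenome(sequence="".join(parts)), genes


def write_reference(
    genome: ReferenceGenome, genes: list[GeneModel], outdir, name: str = "synthetic_ref"
) -> dict:
    """Write FASTA + gene-table TSV (+ manifest); returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / f"{name}.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{name} synthetic circular genome\n")
        seq = genome.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    table = outdir / f"{name}_genes.tsv"
    pd.DataFrame(
        {
            "name": [g.name for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
            "essential": [int(g.essential) for g in genes],
        }
    ).to_csv(table, sep="\t", index=False)
    paths = {"fasta": str(fasta), "gene_table": str(table)}
    _manifest(outdir, {"generator": "gen_reference", "genome_length": genome.length,
                       "n_genes": len(genes), **paths})
    return paths


# --- escape cohort ----------------------------------------------------------


def _random_snv(seq: str, pos: int, rng: np.random.Generator) -> VariantCall:
    ref = seq[pos - 1]
    alt = rng.choice([b for b in _BASES if b != ref])
    return (pos, ref, str(alt))


def _cds_pos_to_genomic(gene: GeneModel, cds_index: int) -> int:
    """0-based CDS index -> 1-based genomic position."""
    if gene.strand == "+":
        return gene.start + cds_index
    return gene.end - cds_index


def _make_lof(gene: GeneModel, seq: str, rng: np.random.Generator):
    """One LoF variant in the gene: start-lost, frameshift (1-bp deletion) or
    premature stop via a single-base codon change."""
    kind = rng.choice(["start_lost", "frameshift", "stop_gained"])
    n_codons = gene.coding_length // 3
    if kind == "start_lost":
        cds_index = int(rng.integers(0, 3))
        pos = _cds_pos_to_genomic(gene, cds_index)
        return _random_snv(seq, pos, rng)
    if kind == "frameshift":
        # anchored 1-bp deletion strictly inside the CDS body
        cds_index = int(rng.integers(3, gene.coding_length - 3))
        pos = _cds_pos_to_genomic(gene, cds_index)
        anchor = pos - 1
        return (anchor, seq[anchor - 1 : pos], seq[anchor - 1])
    # stop_gained: find an internal codon one base away from a stop
    for _ in range(200):
        codon_i = int(rng.integers(1, n_codons - 1))
        if gene.strand == "+":
            codon = seq[gene.start - 1 + 3 * codon_i : gene.start + 2 + 3 * codon_i]
        else:
            codon = reverse_complement(
                seq[gene.end - 3 - 3 * codon_i : gene.end - 3 * codon_i]
            )
        options = []
        for within in range(3):
            for b in _BASES:
                if b == codon[within]:
                    continue
                mutant = codon[:within] + b + codon[within + 1 :]
                if mutant in _STOPS:
                    options.append((within, b))
        if options:
            within, b = options[int(rng.integers(0, len(options)))]
            pos = _cds_pos_to_genomic(gene, 3 * codon_i + within)
            ref = seq[pos - 1]
            alt = b if gene.strand == "+" else reverse_complement(b)
            return (pos, ref, alt)
    raise RuntimeError("no premature-stop candidate found; gene too short?")


def _make_nsnv(gene: GeneModel, seq: str, rng: np.random.Generator):
    """A nonsynonymous, non-stop, non-start SNV inside the gene."""
    n_codons = gene.coding_length // 3
    for _ in range(200):
        codon_i = int(rng.integers(1, n_codons - 1))
        within = int(rng.integers(0, 3))
        if gene.strand == "+":
            codon = seq[gene.start - 1 + 3 * codon_i : gene.start + 2 + 3 * codon_i]
        else:
            codon = reverse_complement(
                seq[gene.end - 3 - 3 * codon_i : gene.end - 3 * codon_i]
            )
        b = str(rng.choice([x for x in _BASES if x != codon[within]]))
        mutant = codon[:within] + b + codon[within + 1 :]
        if CODON_TO_AA[mutant] != "*" and CODON_TO_AA[mutant] != CODON_TO_AA[codon]:
            pos = _cds_pos_to_genomic(gene, 3 * codon_i + within)
            ref = seq[pos - 1]
            alt = b if gene.strand == "+" else reverse_complement(b)
            return (pos, ref, alt)
    raise RuntimeError("no nonsynonymous candidate found")


def gen_escape_clones(
    spec: CohortSpec, reference: ReferenceGenome, genes: list[GeneModel]
) -> CloneVariantCohort:
    """Simulate an escape-clone cohort as per-clone variant sets.

    Each clone: with probability ``causal_hit_prob``, one mutation in a causal
    gene (picked proportional to coding length; LoF with probability
    ``causal_lof_bias``, else a nonsynonymous SNV); Poisson(``passenger_rate``)
    passenger SNVs uniform per bp genome-wide; and the cohort-wide ancestral
    SNV block shared by every clone.
    """
    by_name = {g.name: g for g in genes}
    missing = [n for n in spec.causal_genes if n not in by_name]
    if missing:
        raise ValueError(f"causal genes not in gene table: {missing}")
    if spec.causal_hit_prob > 0 and not spec.causal_genes:
        raise ValueError("causal_hit_prob > 0 requires causal_genes")
    rng = np.random.default_rng(spec.seed)
    seq = reference.sequence

    ancestral = []
    taken = set()
    while len(ancestral) < spec.ancestral_variants:
        pos = int(rng.integers(1, reference.length + 1))
        if pos in taken:
            continue
        taken.add(pos)
        ancestral.append(_random_snv(seq, pos, rng))

    causal = [by_name[n] for n in spec.causal_genes]
    weights = None
    if causal:
        lens = np.array([g.coding_length for g in causal], dtype=float)
        weights = lens / lens.sum()

    cohort = CloneVariantCohort()
    for i in range(spec.n_clones):
        clone_id = f"clone{i + 1:03d}"
        calls = cohort.clones.setdefault(clone_id, {})

        def put(pos, ref, alt):
            v = VariantCall(clone_id, pos, ref, alt)
            calls.setdefault(v.key, v)  # silent dedup of chance collisions

        for pos, ref, alt in ancestral:
            put(pos, ref, alt)
        if causal and rng.random() < spec.causal_hit_prob:
            gene = causal[int(rng.choice(len(causal), p=weights))]
            if rng.random() < spec.causal_lof_bias:
                pos, ref, alt = _make_lof(gene, seq, rng)
            else:
                pos, ref, alt = _make_nsnv(gene, seq, rng)
            put(pos, ref, alt)
        n_pass = int(rng.poisson(spec.passenger_rate))
        if n_pass:
            positions = rng.integers(1, reference.length + 1, size=n_pass)
            refs = [seq[p - 1] for p in positions]
            alt_idx = rng.integers(0, 3, size=n_pass)
            for p, r, ai in zip(positions, refs, alt_idx):
                alts = [b for b in _BASES if b != r]
                put(int(p), r, alts[ai])
    return cohort


def write_clone_vcfs(
    cohort: CloneVariantCohort, reference: ReferenceGenome, outdir, contig: str = "synthetic_ref"
) -> list[str]:
    """Write one VCF 4.2 file per clone (+ manifest); returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for clone_id, calls in cohort.clones.items():
        path = outdir / f"{clone_id}.vcf"
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={contig},length={reference.length}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for key in sorted(calls):
                pos, ref, alt = key
                fh.write(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")
        paths.append(str(path))
    _manifest(outdir, {"generator": "write_clone_vcfs", "n_clones": cohort.n_clones,
                       "n_calls": cohort.n_calls, "contig": contig})
    return paths


# --- growth curves ----------------------------------------------------------


def _grow(
    n_start: float, spec: GrowthSpec, times: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    if n_start >= 1.0:  # below one founding cell the culture cannot grow
        # cap the exponent at carrying capacity to avoid overflow at long horizons
        doublings = np.clip(times - spec.lag, 0.0, None) / spec.doubling_time
        cap = np.log2(spec.carrying_od / (spec.od_per_cell * n_start))
        od = spec.od_per_cell * n_start * np.exp2(np.minimum(doublings, cap))
        od = np.minimum(spec.carrying_od, od)
    else:
        od = np.zeros_like(times)
    if spec.noise_sd > 0:
        od = od + rng.normal(0.0, spec.noise_sd, size=od.shape)
    return np.clip(od, 0.0, None)


def gen_growth_quartet(
    spec: GrowthSpec, sample_interval: float = 10.0
) -> dict[str, GrowthCurve]:
    """Four growth curves keyed RS/CS/RNS/CNS.

    Nonselective cultures grow from the full inoculum ``n0``; selective
    cultures grow from their resistant sub-inoculum, so their
    threshold-crossing time lags by ~``doubling_time * log2(1/fraction)``.
    The control's fraction is ``resistant_fraction`` (counter-selection
    leakiness); the recombinant's is ``recombinant_fraction``.  A zero
    fraction leaves that selective curve flat (censored by design).
    """
    if sample_interval <= 0:
        raise ValueError("sample_interval must be positive")
    rng = np.random.default_rng(spec.seed)
    times = np.arange(0.0, spec.horizon + sample_interval / 2, sample_interval)
    inocula = {
        "RS": spec.n0 * spec.recombinant_fraction,
        "CS": spec.n0 * spec.resistant_fraction,
        "RNS": spec.n0,
        "CNS": spec.n0,
    }
    return {
        cond: GrowthCurve(times, _grow(n, spec, times, rng), label=cond)
        for cond, n in inocula.items()
    }


def write_quartet_csv(curves: dict[str, GrowthCurve], path) -> None:
    frames = []
    for cond, c in curves.items():
        frames.append(
            pd.DataFrame(
                {"time_min": c.times, "od600": c.od, "label": c.label, "condition": cond}
            )
        )
    pd.concat(frames).to_csv(path, index=False)


# --- platings ---------------------------------------------------------------


def gen_plating(
    true_frequency: float,
    cells_plated: int,
    n_replicates: int,
    seed: int,
    agents: frozenset = frozenset({"colE1"}),
) -> list[PlatingExperiment]:
    """Replicate platings with Poisson(f * N) colony counts.

    Poisson rather than binomial: escape counts are small while N reaches
    1e10, where the two are indistinguishable and Poisson sampling is cheap.
    """
    if not 0.0 <= true_frequency <= 1.0:
        raise ValueError("true_frequency must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(true_frequency * cells_plated, size=n_replicates)
    counts = np.minimum(counts, cells_plated)
    return [
        PlatingExperiment(
            cells_plated=cells_plated,
            colonies=int(k),
            agents=agents,
            replicate_id=f"rep{i + 1}",
        )
        for i, k in enumerate(counts)
    ]


def write_platings_tsv(exps: list[PlatingExperiment], path, strain: str = "synthetic") -> None:
    pd.DataFrame(
        {
            "strain": strain,
            "agents": [",".join(sorted(e.agents)) for e in exps],
            "cells_plated": [e.cells_plated for e in exps],
            "colonies": [e.colonies for e in exps],
            "replicate": [e.replicate_id for e in exps],
        }
    ).to_csv(path, sep="\t", index=False)


# --- genotype matrices ------------------------------------------------------


def gen_genotype_population(model: ConversionModel, n: int, seed: int) -> pd.DataFrame:
    """n single-cycle conversion patterns as a clones × loci 0/1 DataFrame."""
    start = PopulationState(np.zeros((n, model.L), dtype=bool))
    pop = simulate_cycle(start, model, seed)
    return pd.DataFrame(
        pop.members.astype(int), columns=[f"locus{i + 1:02d}" for i in range(model.L)]
    )


def _manifest(outdir: Path, params: dict) -> None:
    path = Path(outdir) / "manifest.json"
    existing = {}
    if path.exists():
        existing = json.loads(path.read_text())
    existing[params.get("generator", "run")] = params
    path.write_text(json.dumps(existing, indent=2, default=str))
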