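import numpy as np
import pytest
from hypothesis import settings

from dualmark import synth

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def toy_annotation():
    """Small synthetic genome: 12 genes x 200 codons, alternating strands,
    every third gene essential."""
    genome, genes = synth.gen_reference(
        n_genes=12,
        codons_per_gene=200,
        intergenic_bp=150,
        essential_mask=[i % 3 == 0 for i in range(12)],
        seed=11,
    )
    return genome, genes


@pytest.fixture(scope="session")
def default_cohort(toy_annotation):
    """Cohort at the default spec: 96 clones, 93% causal hit probability,
    21 shared ancestral variants, ~30 passengers per clone."""
    genome, genes = toy_annotation
    spec = synth.CohortSpec(
        n_clones=96,
        causal_genes=("gene0002", "gene0003", "gene0004"),
        seed=202,
    )
    return synth.gen_escape_clones(spec, genome, genes), spec


@pytest.fixture(scope="session")
def variant_sampler():
    """Callable drawing a random SNV/indel inside a random gene."""
    return random_variant


def random_variant(rng, genome, genes):
    """A random SNV or short indel fully inside a random gene."""
    gene = genes[rng.integers(0, len(genes))]
    kind = rng.choice(["snv", "del", "ins"])
    if kind == "snv":
        pos = int(rng.integers(gene.start, gene.end + 1))
        ref = genome.sequence[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    elif kind == "del":
        width = int(rng.integers(1, 4))
        pos = int(rng.integers(gene.start, gene.end - width))
        ref = genome.sequence[pos - 1 : pos + width]
        alt = ref[0]
    else:
        pos = int(rng.integers(gene.start, gene.end))
        ref = genome.sequence[pos - 1]
        alt = ref + "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
    return gene, pos, ref, alt
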