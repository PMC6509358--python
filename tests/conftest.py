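import numpy as np
import pytest

from jellyseq import synthio
from jellyseq.formats import AlignedRead, AnnotatedReference, GeneFeature


@pytest.fixture(scope="session")
def toy_reference() -> AnnotatedReference:
    """Tiny hand-built reference: two bee genes, a gap, one viral genome."""
    sequences = {
        "bee_chr1": "ACGT" * 250,  # 1 kb
        "vdv1": "TTGC" * 100,  # 400 bp
    }
    features = [
        GeneFeature("geneA", "bee_chr1", 100, 400, "+", "protein_coding", (300, 250)),
        GeneFeature("tRNA1", "bee_chr1", 500, 580, "-", "tRNA", (80,)),
        GeneFeature("geneB", "bee_chr1", 700, 950, "-", "protein_coding", (250,)),
        GeneFeature("vdv1_genome", "vdv1", 0, 400, "+", "protein_coding", (400,)),
    ]
    species_of = {"bee_chr1": "apis", "vdv1": "vdv1"}
    return AnnotatedReference(sequences, features, species_of)


@pytest.fixture(scope="session")
def sim_reference() -> AnnotatedReference:
    """Simulated bee + virus reference at the generator's default scale."""
    return synthio.make_reference(synthio.ReferenceConfig(), seed=11)


@pytest.fixture(scope="session")
def default_sim(sim_reference) -> synthio.SimulatedReads:
    """Default-condition fragment simulation with planted duplexes."""
    loci = [
        f.gene_id
        for f in sim_reference.features
        if f.biotype == "protein_coding" and f.length >= 300
        and sim_reference.species_of[f.reference] == "apis"
    ][:3]
    config = synthio.SimConfig(
        seed=12,
        n_fragments=2000,
        duplex_loci=[synthio.DuplexLocus(locus=g, n_pairs=15) for g in loci],
    )
    return synthio.simulate_fragments(sim_reference, config)


def make_read(
    start: int,
    end: int,
    strand: str,
    fragment: str,
    mate: int = 1,
    reference: str = "chr",
    sample: str = "s1",
) -> AlignedRead:
    return AlignedRead(
        read_id=f"{fragment}/{mate}",
        fragment_id=fragment,
        mate=mate,
        reference=reference,
        start=start,
        end=end,
        strand=strand,
        sample=sample,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
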