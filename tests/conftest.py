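import numpy as np
import pytest

from crispri_screen import simulate as sim
from crispri_screen.design import design_library
from crispri_screen.genome import AnnotatedGenome, Feature, revcomp


def random_genome(rng: np.random.Generator, length: int, n_features: int, circular: bool = False) -> AnnotatedGenome:
    """Random genome with random non-overlapping CDS-like features."""
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
    feats = []
    cuts = sorted(rng.choice(length, size=min(2 * n_features, max(length - 1, 1)), replace=False))
    i = 0
    while len(feats) < n_features and i + 1 < len(cuts):
        s, e = int(cuts[i]), int(cuts[i + 1])
        if e - s >= 30:
            kind = ["CDS", "CDS", "CDS", "rRNA", "tRNA"][rng.integers(0, 5)]
            strand = "+" if rng.random() < 0.5 else "-"
            feats.append(Feature(locus_tag=f"f{len(feats)}", kind=kind, strand=strand, start=s, end=e))
        i += 2
    return AnnotatedGenome(id="rand", sequence=seq, circular=circular, features=feats)


@pytest.fixture(scope="session")
def toy_genome():
    """5 kb synthetic genome with 6 planted CDSs (3 per strand)."""
    genome, coords = sim.simulate_genome(n_genes=6, mean_gene_length=600, seed=42)
    return genome, coords


@pytest.fixture(scope="session")
def toy_library(toy_genome):
    genome, _ = toy_genome
    return design_library(genome)


@pytest.fixture(scope="session")
def small_screen():
    """Library + planted truth + simulated counts at modest depth."""
    genes = [f"gene_{i:03d}" for i in range(200)]
    cfg = sim.SimConfig(n_genes=200, guides_per_gene=10, depth=1_000_000, rng_seed=3)
    lib = sim.simulate_library(genes, cfg)
    truth = sim.plant_effects(genes, n_costly=10, n_essential=20, seed=3)
    counts = sim.simulate_screen_counts(lib, truth, cfg)
    return lib, truth, counts, cfg
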