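import numpy as np
import pytest

from ribodyn import profiles as pio
from ribodyn import simulate as synth


@pytest.fixture
def tiny_genes():
    """Three short genes with known codon content."""
    return pio.GeneSet.from_sequences(
        {
            "g1": "ATGGCTTAA",
            "g2": "ATGGCTGCTTAA",
            "g3": "ATG" + "GCT" * 5 + "TAA",
        }
    )


@pytest.fixture
def uniform_track(tiny_genes):
    counts = {
        gid: np.ones(tiny_genes.nt_length(gid)) for gid in tiny_genes
    }
    return pio.ProfileTrack(condition="c", replicate=None, counts=counts)


def make_geneset(n_codons: int, gid: str = "g1", seed: int = 0) -> pio.GeneSet:
    """Random sense-codon gene of the requested codon length."""
    from ribodyn.codons import SENSE_INDICES

    rng = np.random.default_rng(seed)
    return pio.GeneSet({gid: rng.choice(SENSE_INDICES, size=n_codons)})


@pytest.fixture
def sim_small():
    """Small deterministic simulation shared across tests."""
    cfg = synth.SynthConfig(
        n_genes=20,
        length_range=(70, 110),
        dwell={"GCT": 2.0, "CCA": 3.5, "GGC": 0.5},
        noise="none",
        depth=1000.0,
        seed=7,
    )
    genes = synth.generate_genes(cfg)
    track, rates = synth.simulate_density(genes, cfg)
    return cfg, genes, track, rates
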