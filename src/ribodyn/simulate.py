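"""Seeded synthetic genomes and paired ribosome-profiling tracks.

Generates genes with known codon dwell times and context effects, draws
footprint counts (deterministic or Poisson/multinomial), applies a
protocol-bias transformation that redistributes reads within a gene, and
derives a collision (disome-like) track from a monosome track.  All
outputs are bit-reproducible given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import codons as _cod
from .profiles import GeneSet, ProfileTrack

#: Minimum gene length (codons) that survives end-trimming plus a +/-20 window.
MIN_GENE_CODONS = 70


@dataclass
class ContextEffect:
    """Multiplicative dwell modifier active when all (offset, codon) pairs
    around the center codon match."""

    motif: dict[int, str]  # relative codon offset -> codon string
    effect: float

    def __post_init__(self):
        if self.effect <= 0:
            raise ValueError("context effect must be positive")
        for c in self.motif.values():
            if c not in _cod.CODON_INDEX:
                raise ValueError(f"invalid codon {c!r} in motif")


@dataclass
class SynthConfig:
    n_genes: int = 100
    length_range: tuple[int, int] = (80, 200)  # codons, inclusive
    codon_usage: Mapping[str, float] | None = None  # weights over sense codons
    dwell: Mapping[str, float] | None = None  # per-codon positive multiplier
    context_effects: Sequence[ContextEffect] = field(default_factory=list)
    noise: str = "poisson"  # 'none' | 'poisson'
    depth: float = 2000.0  # expected reads per gene
    bias: Mapping[str, float] | None = None  # per-codon distortion multipliers
    collision_threshold: float | None = None  # theta on the true rate
    collision_offset: int = 3  # upstream offset d (codons)
    seed: int = 0

    def __post_init__(self):
        if self.length_range[0] < MIN_GENE_CODONS:
            raise ValueError(
                f"minimum gene length must be >= {MIN_GENE_CODONS} codons "
                "(must survive end trims plus the model window)"
            )
        if self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid length range")
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"unknown noise mode {self.noise!r}")
        for m in (self.dwell, self.bias, self.codon_usage):
            if m is not None and any(v <= 0 for v in m.values()):
                raise ValueError("all multipliers/weights must be positive")

    def dwell_vector(self) -> np.ndarray:
        """Per-codon dwell multipliers indexed 0..63 (default 1.0)."""
        v = np.ones(64)
        if self.dwell:
            for c, x in self.dwell.items():
                v[_cod.CODON_INDEX[c]] = x
        return v

    def bias_vector(self) -> np.ndarray:
        v = np.ones(64)
        if self.bias:
            for c, x in self.bias.items():
                v[_cod.CODON_INDEX[c]] = x
        return v


def _rng(cfg: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def generate_genes(cfg: SynthConfig) -> GeneSet:
    """Genes start with ATG, end with a stop codon; internal codons are drawn
    from the configured usage weights over the 61 sense codons."""
    rng = _rng(cfg, 1)
    if cfg.codon_usage is None:
        weights = np.ones(len(_cod.SENSE_CODONS))
    else:
        weights = np.array([cfg.codon_usage.get(c, 0.0) for c in _cod.SENSE_CODONS])
        if weights.sum() <= 0:
            raise ValueError("codon usage has no positive weight on sense codons")
    p = weights / weights.sum()
    stop_idx = _cod.CODON_INDEX["TAA"]
    atg_idx = _cod.CODON_INDEX["ATG"]
    out: dict[str, np.ndarray] = {}
    width = max(4, len(str(max(cfg.n_genes, 1))))
    for i in range(cfg.n_genes):
        L = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        internal = rng.choice(_cod.SENSE_INDICES, size=L - 2, p=p)
        out[f"g{i:0{width}d}"] = np.concatenate(
            ([atg_idx], internal, [stop_idx])
        ).astype(np.int16)
    return GeneSet(out)


def true_rates(genes: GeneSet, cfg: SynthConfig) -> dict[str, np.ndarray]:
    """Latent per-codon occupancy rates: dwell(codon) x active context effects."""
    dwell = cfg.dwell_vector()
    rates: dict[str, np.ndarray] = {}
    for gid in genes:
        cod = genes.codon_indices(gid)
        r = dwell[cod].astype(np.float64)
        for ce in cfg.context_effects:
            offs = np.array(sorted(ce.motif))
            targets = np.array([_cod.CODON_INDEX[ce.motif[o]] for o in offs])
            for i in range(len(cod)):
                pos = i + offs
                if pos.min() < 0 or pos.max() >= len(cod):
                    continue
                if np.array_equal(cod[pos], targets):
                    r[i] *= ce.effect
        rates[gid] = r
    return rates


def _spread_to_nt(codon_reads: np.ndarray) -> np.ndarray:
    """Place each codon's reads on its middle nucleotide (0/1/0 weights)."""
    nt = np.zeros(3 * codon_reads.size)
    nt[1::3] = codon_reads
    return nt


def simulate_density(
    genes: GeneSet, cfg: SynthConfig, condition: str = "synthetic"
) -> tuple[ProfileTrack, dict[str, np.ndarray]]:
    """Allocate reads along each gene in proportion to its true rates.

    noise='none': reads are exactly depth * rate / sum(rate) (real-valued).
    noise='poisson': gene total ~ Poisson(depth), split multinomially.
    Returns the nucleotide-level track and the ground-truth rates.
    """
    rates = true_rates(genes, cfg)
    rng = _rng(cfg, 2)
    counts: dict[str, np.ndarray] = {}
    for gid in genes:
        r = rates[gid]
        p = r / r.sum()
        if cfg.noise == "none":
            codon_reads = cfg.depth * p
        else:
            total = rng.poisson(cfg.depth)
            codon_reads = rng.multinomial(total, p).astype(np.float64)
        counts[gid] = _spread_to_nt(codon_reads)
    return ProfileTrack(condition=condition, replicate=None, counts=counts), rates


def apply_technical_bias(
    track: ProfileTrack, cfg: SynthConfig, genes: GeneSet, condition: str | None = None
) -> ProfileTrack:
    """Multiply codon reads by bias(codon), renormalizing to preserve each
    gene's total (protocol bias redistributes reads, it does not create them)."""
    bias = cfg.bias_vector()
    counts: dict[str, np.ndarray] = {}
    for gid in track.gene_ids:
        v = track.counts[gid]
        codon_reads = v.reshape(-1, 3).sum(axis=1)
        total = codon_reads.sum()
        b = bias[genes.codon_indices(gid)]
        distorted = codon_reads * b
        s = distorted.sum()
        if total > 0 and s > 0:
            distorted *= total / s
        counts[gid] = _spread_to_nt(distorted)
    return ProfileTrack(
        condition=condition or f"{track.condition}_biased",
        replicate=track.replicate,
        counts=counts,
    )


def simulate_collisions(
    track: ProfileTrack,
    cfg: SynthConfig,
    genes: GeneSet,
    rates: dict[str, np.ndarray],
    condition: str = "disome",
) -> ProfileTrack:
    """Disome-like track: signal at codon i = mono(i) * [rate(i) > theta] *
    mono(i-d), renormalized per gene to the monosome total."""
    if cfg.collision_threshold is None:
        raise ValueError("collision_threshold (theta) is not set")
    d = cfg.collision_offset
    counts: dict[str, np.ndarray] = {}
    for gid in track.gene_ids:
        mono = track.counts[gid].reshape(-1, 3).sum(axis=1)
        L = mono.size
        if d >= L:
            raise ValueError(f"collision offset {d} >= gene length {L} (gene {gid})")
        stall = rates[gid] > cfg.collision_threshold
        upstream = np.zeros(L)
        upstream[d:] = mono[:-d] if d > 0 else mono
        dis = mono * stall * upstream
        s = dis.sum()
        if s > 0:
            dis *= mono.sum() / s
        counts[gid] = _spread_to_nt(dis)
    return ProfileTrack(condition=condition, replicate=None, counts=counts)


def write_truth_table(rates: dict[str, np.ndarray], path) -> None:
    """Ground-truth TSV (gene_id, codon_index, true_rate) for test harnesses."""
    with open(path, "w") as fh:
        fh.write("gene_id\tcodon_index\ttrue_rate\n")
        for gid, r in rates.items():
            for i, x in enumerate(r):
                fh.write(f"{gid}\t{i}\t{x:.6f}\n")
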