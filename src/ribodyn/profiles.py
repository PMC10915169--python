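"""Coding-sequence and footprint-track ingestion, codon densities, pause
scores and model-ready window datasets.

Coordinates are 0-based nucleotide positions within the CDS; counts are
assumed pre-assigned to a single ribosome-site position per footprint.
The first and last ``TRIM`` codons of every gene are excluded from all
density statistics (atypical initiation/termination signal).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import codons as _cod

logger = logging.getLogger(__name__)

#: Codons trimmed at each gene end for density statistics.
TRIM = 10

#: Mean reads/nt retention thresholds by organism preset.
COVERAGE_PRESETS = {"prok": 0.5, "euk": 5.0}


class InvalidCdsError(ValueError):
    """A CDS record violates the alphabet or frame rules."""


class DuplicateGeneIdError(ValueError):
    """Two records share a gene identifier."""


class ProfileFormatError(ValueError):
    """A profile table violates the dialect or its coordinate bounds."""


class TransformError(ValueError):
    """An operation received a density in the wrong transform state."""


# ---------------------------------------------------------------------------
# GeneSet
# ---------------------------------------------------------------------------


class GeneSet:
    """Ordered collection of genes, each an in-frame codon sequence."""

    def __init__(self, codon_indices: Mapping[str, np.ndarray]):
        self._idx: dict[str, np.ndarray] = {}
        for gid, arr in codon_indices.items():
            a = np.asarray(arr, dtype=np.int16)
            if a.ndim != 1 or a.size == 0:
                raise InvalidCdsError(f"gene {gid!r}: empty or non-1D codon array")
            if a.min() < 0 or a.max() > 63:
                raise InvalidCdsError(f"gene {gid!r}: codon index out of range")
            self._idx[gid] = a

    @classmethod
    def from_sequences(cls, sequences: Mapping[str, str]) -> "GeneSet":
        out: dict[str, np.ndarray] = {}
        for gid, seq in sequences.items():
            seq = seq.upper().replace("U", "T")
            bad = set(seq) - set(_cod.NUCLEOTIDES)
            if bad:
                raise InvalidCdsError(
                    f"gene {gid!r}: invalid characters {sorted(bad)}"
                )
            if len(seq) % 3:
                raise InvalidCdsError(
                    f"gene {gid!r}: length {len(seq)} nt is not divisible by 3"
                )
            out[gid] = _cod.encode(_cod.codons_of(seq))
        return cls(out)

    # -- mapping-ish surface -------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return list(self._idx)

    def __len__(self) -> int:
        return len(self._idx)

    def __contains__(self, gid: str) -> bool:
        return gid in self._idx

    def __iter__(self):
        return iter(self._idx)

    def codon_indices(self, gid: str) -> np.ndarray:
        return self._idx[gid]

    def codons(self, gid: str) -> list[str]:
        return _cod.decode(self._idx[gid])

    def length_codons(self, gid: str) -> int:
        return int(self._idx[gid].size)

    def nt_length(self, gid: str) -> int:
        return 3 * self.length_codons(gid)

    def sequence(self, gid: str) -> str:
        return "".join(self.codons(gid))

    def subset(self, ids: Iterable[str]) -> "GeneSet":
        return GeneSet({g: self._idx[g] for g in ids})


def read_cds_fasta(path) -> GeneSet:
    """Read CDS records (one per gene, sense strand) into a :class:`GeneSet`.

    Sequences are upper-cased and U is mapped to T.  A record whose length
    is not a multiple of 3, or containing a non-ACGTU character, raises
    :class:`InvalidCdsError` naming the record; duplicate ids raise
    :class:`DuplicateGeneIdError`.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise DuplicateGeneIdError(f"duplicate gene id {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    return GeneSet.from_sequences(seqs)


def write_cds_fasta(genes: GeneSet, path) -> None:
    with open(path, "w") as fh:
        for gid in genes:
            fh.write(f">{gid}\n{genes.sequence(gid)}\n")


# ---------------------------------------------------------------------------
# ProfileTrack
# ---------------------------------------------------------------------------


@dataclass
class ProfileTrack:
    """Per-nucleotide footprint counts for one condition/replicate."""

    condition: str
    replicate: str | None
    counts: dict[str, np.ndarray]

    def __post_init__(self):
        for gid, v in self.counts.items():
            v = np.asarray(v, dtype=np.float64)
            if (v < 0).any():
                raise ProfileFormatError(f"gene {gid!r}: negative count")
            self.counts[gid] = v

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts)

    def mean_reads_per_nt(self, gid: str) -> float:
        v = self.counts[gid]
        return float(v.sum() / v.size)


PROFILE_COLUMNS = ("gene_id", "position", "count")


def read_profile_table(
    path, condition: str, replicate: str | None = None, genes: GeneSet | None = None
) -> ProfileTrack:
    """Read the tab-separated (gene_id, position, count) dialect.

    Unlisted positions are zero.  When a :class:`GeneSet` is supplied the
    vectors are sized to the CDS and positions are bounds-checked;
    otherwise each vector extends to the largest listed position.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if tuple(df.columns) != PROFILE_COLUMNS:
        raise ProfileFormatError(
            f"expected header {PROFILE_COLUMNS}, found {tuple(df.columns)}"
        )
    if len(df) and (df["count"] < 0).any():
        bad = df[df["count"] < 0].iloc[0]
        raise ProfileFormatError(
            f"negative count for gene {bad.gene_id!r} position {int(bad.position)}"
        )
    counts: dict[str, np.ndarray] = {}
    for gid, grp in df.groupby("gene_id", sort=False):
        pos = grp["position"].to_numpy(dtype=np.int64)
        if (pos < 0).any():
            raise ProfileFormatError(f"gene {gid!r}: negative position")
        if genes is not None:
            if gid not in genes:
                raise ProfileFormatError(f"gene {gid!r} not in the supplied GeneSet")
            n = genes.nt_length(gid)
            if (pos >= n).any():
                p = int(pos[pos >= n][0])
                raise ProfileFormatError(
                    f"gene {gid!r}: position {p} >= CDS length {n}"
                )
        else:
            n = int(pos.max()) + 1
        v = np.zeros(n, dtype=np.float64)
        np.add.at(v, pos, grp["count"].to_numpy(dtype=np.float64))
        counts[gid] = v
    return ProfileTrack(condition=condition, replicate=replicate, counts=counts)


def write_profile_table(track: ProfileTrack, path, sparse: bool = True) -> None:
    """Write the TSV dialect (zero positions omitted when ``sparse``)."""
    with open(path, "w") as fh:
        fh.write("\t".join(PROFILE_COLUMNS) + "\n")
        for gid in track.gene_ids:
            v = track.counts[gid]
            positions = np.nonzero(v)[0] if sparse else np.arange(v.size)
            for p in positions:
                c = v[p]
                text = f"{int(c)}" if float(c).is_integer() else f"{c:.6f}"
                fh.write(f"{gid}\t{p}\t{text}\n")


def average_replicates(tracks: Sequence[ProfileTrack]) -> ProfileTrack:
    """Element-wise mean per nucleotide across replicate tracks."""
    if not tracks:
        raise ValueError("no tracks supplied")
    cond = tracks[0].condition
    if any(t.condition != cond for t in tracks):
        raise ValueError("tracks have mixed conditions")
    ref_genes = set(tracks[0].counts)
    for t in tracks[1:]:
        if set(t.counts) != ref_genes:
            diff = sorted(set(t.counts) ^ ref_genes)
            raise ValueError(f"mismatched gene coverage, symmetric difference {diff}")
    counts = {
        gid: np.mean([t.counts[gid] for t in tracks], axis=0)
        for gid in tracks[0].counts
    }
    return ProfileTrack(condition=cond, replicate=None, counts=counts)


# ---------------------------------------------------------------------------
# Gene filtering
# ---------------------------------------------------------------------------


def filter_genes(
    genes: GeneSet,
    track: ProfileTrack,
    min_len_nt: int = 200,
    min_reads_per_nt: float = COVERAGE_PRESETS["prok"],
    preset: str | None = None,
) -> GeneSet:
    """Retain genes with CDS length >= ``min_len_nt`` and mean reads/nt >=
    threshold (boundary inclusive).  ``preset`` in {'prok','euk'} overrides
    ``min_reads_per_nt``."""
    if preset is not None:
        min_reads_per_nt = COVERAGE_PRESETS[preset]
    kept = []
    for gid in genes:
        if gid not in track.counts:
            raise ValueError(f"track does not cover gene {gid!r}")
        if genes.nt_length(gid) < min_len_nt:
            continue
        if track.mean_reads_per_nt(gid) >= min_reads_per_nt:
            kept.append(gid)
    if not kept:
        warnings.warn("filter_genes retained no genes", stacklevel=2)
    logger.info(
        "filter_genes: %d/%d retained (min_len_nt=%d, min_reads_per_nt=%g%s)",
        len(kept), len(genes), min_len_nt, min_reads_per_nt,
        f", preset={preset}" if preset else "",
    )
    return genes.subset(kept)


def top_genes_by_density(genes: GeneSet, track: ProfileTrack, n: int) -> GeneSet:
    """The ``n`` genes with the highest mean reads/nt (ties: lexicographic id)."""
    if n > len(genes):
        raise ValueError(f"n={n} exceeds gene count {len(genes)}")
    order = sorted(genes, key=lambda g: (-track.mean_reads_per_nt(g), g))
    return genes.subset(order[:n])


# ---------------------------------------------------------------------------
# Codon densities
# ---------------------------------------------------------------------------


@dataclass
class CodonDensity:
    """Per-codon density vectors under a named transform."""

    values: dict[str, np.ndarray]
    transform: str = "raw"  # raw | gene_mean_normalized | log

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values)


def codon_density(track: ProfileTrack, genes: GeneSet) -> CodonDensity:
    """Sum the three nucleotide counts of each codon (transform='raw')."""
    out: dict[str, np.ndarray] = {}
    for gid in genes:
        v = track.counts[gid]
        n = genes.nt_length(gid)
        if v.size != n:
            raise ValueError(
                f"gene {gid!r}: track length {v.size} != CDS length {n}"
            )
        out[gid] = v.reshape(-1, 3).sum(axis=1)
    return CodonDensity(values=out, transform="raw")


def _retained(v: np.ndarray, trim: int = TRIM) -> np.ndarray:
    return v[trim : v.size - trim]


def normalize(cd: CodonDensity, trim: int = TRIM) -> CodonDensity:
    """Divide each gene by its mean over retained codons (linear scale).

    Genes whose retained mean is zero are dropped with a warning.
    """
    if cd.transform != "raw":
        raise TransformError(f"expected raw densities, got {cd.transform!r}")
    out: dict[str, np.ndarray] = {}
    for gid, v in cd.values.items():
        m = _retained(v, trim).mean() if v.size > 2 * trim else 0.0
        if m <= 0:
            warnings.warn(f"gene {gid!r} dropped: zero retained density", stacklevel=2)
            continue
        out[gid] = v / m
    return CodonDensity(values=out, transform="gene_mean_normalized")


def normalize_and_log(
    cd: CodonDensity, pseudocount: float = 0.5, trim: int = TRIM
) -> CodonDensity:
    """log2(value / gene-mean-over-retained-codons + pseudocount)."""
    norm = normalize(cd, trim=trim)
    out = {gid: np.log2(v + pseudocount) for gid, v in norm.values.items()}
    return CodonDensity(values=out, transform="log")


# ---------------------------------------------------------------------------
# Pause scores
# ---------------------------------------------------------------------------


def _zscore(s: pd.Series) -> pd.Series:
    x = s.dropna()
    if len(x) == 0:
        return s * np.nan
    sd = x.std(ddof=0)
    # relative guard: an all-equal vector may carry ~1e-16 rounding noise
    if sd <= 1e-12 * max(1.0, abs(x.mean())):
        z = pd.Series(0.0, index=x.index)
    else:
        z = (x - x.mean()) / sd
    return z.reindex(s.index)


@dataclass
class PauseScoreTable:
    """Instance-level pause scores plus codon-type and amino-acid summaries."""

    instances: pd.DataFrame  # gene, codon_index, codon, score
    codon_scores: pd.Series  # mean score per sense codon (NaN when absent)
    codon_z: pd.Series
    aa_scores: pd.Series  # mean score per amino acid
    aa_z: pd.Series


def pause_scores(cd: CodonDensity, genes: GeneSet, trim: int = TRIM) -> PauseScoreTable:
    """Instance score = codon density / mean retained density of its gene.

    Per-codon-type means are taken over all instances and z-scored across
    the 61 sense codons; amino-acid scores aggregate synonymous codons
    before z-scoring.  Stop codons are excluded from z-scoring.
    """
    if cd.transform != "raw":
        raise TransformError(f"expected raw densities, got {cd.transform!r}")
    rows = []
    for gid, v in cd.values.items():
        if v.size <= 2 * trim:
            continue
        ret = _retained(v, trim)
        m = ret.mean()
        if m <= 0:
            warnings.warn(f"gene {gid!r} skipped: zero retained density", stacklevel=2)
            continue
        idx = np.arange(trim, v.size - trim)
        cods = [_cod.CODONS[i] for i in genes.codon_indices(gid)[idx]]
        rows.append(
            pd.DataFrame(
                {"gene": gid, "codon_index": idx, "codon": cods, "score": ret / m}
            )
        )
    if not rows:
        raise ValueError("no gene yielded pause-score instances")
    inst = pd.concat(rows, ignore_index=True)

    by_codon = inst.groupby("codon")["score"].mean()
    codon_scores = by_codon.reindex(_cod.SENSE_CODONS)
    codon_z = _zscore(codon_scores)

    sense = inst[~inst["codon"].isin(_cod.STOP_CODONS)].copy()
    sense["aa"] = sense["codon"].map(_cod.CODON_TO_AA)
    aa_scores = sense.groupby("aa")["score"].mean().reindex(_cod.AMINO_ACIDS)
    aa_z = _zscore(aa_scores)

    return PauseScoreTable(
        instances=inst,
        codon_scores=codon_scores,
        codon_z=codon_z,
        aa_scores=aa_scores,
        aa_z=aa_z,
    )


# ---------------------------------------------------------------------------
# Window dataset
# ---------------------------------------------------------------------------


@dataclass
class WindowDataset:
    """(codon window, reference-density window, target) training instances."""

    seq: np.ndarray  # (n, 2W+1) int16 codon indices
    ref: np.ndarray  # (n, 2W+1) float64 log-scale reference densities
    target: np.ndarray  # (n,) float64
    gene: np.ndarray  # (n,) object — gene ids
    center_index: np.ndarray  # (n,) int64
    W: int
    ref_transform: str = "log"
    target_transform: str = "gene_mean_normalized"

    def __len__(self) -> int:
        return int(self.seq.shape[0])

    def take(self, idx: np.ndarray) -> "WindowDataset":
        return WindowDataset(
            seq=self.seq[idx],
            ref=self.ref[idx],
            target=self.target[idx],
            gene=self.gene[idx],
            center_index=self.center_index[idx],
            W=self.W,
            ref_transform=self.ref_transform,
            target_transform=self.target_transform,
        )


def valid_centers(length_codons: int, W: int, trim: int = TRIM) -> range:
    """Centers whose +/-W context fits the CDS and that survive the trim."""
    lo = max(trim, W)
    hi = length_codons - 1 - max(trim, W)
    return range(lo, hi + 1)


def build_windows(
    genes: GeneSet,
    ref_cd: CodonDensity,
    target_cd: CodonDensity,
    W: int = 20,
    trim: int = TRIM,
) -> WindowDataset:
    """One instance per retained codon with a full +/-W context.

    ``ref_cd`` must be log-transformed; the target transform is recorded
    on the dataset.  Genes shorter than 2*max(W, trim)+1 codons contribute
    no instances.
    """
    if W < 1:
        raise ValueError("W must be >= 1")
    if ref_cd.transform != "log":
        raise TransformError(
            f"reference density must be log-transformed, got {ref_cd.transform!r}"
        )
    seqs, refs, targets, gids, centers = [], [], [], [], []
    for gid in genes:
        if gid not in ref_cd.values or gid not in target_cd.values:
            continue
        L = genes.length_codons(gid)
        cs = valid_centers(L, W, trim)
        if len(cs) == 0:
            logger.info("gene %s too short for W=%d: no instances", gid, W)
            continue
        cod = genes.codon_indices(gid)
        rv = ref_cd.values[gid]
        tv = target_cd.values[gid]
        for c in cs:
            seqs.append(cod[c - W : c + W + 1])
            refs.append(rv[c - W : c + W + 1])
            targets.append(tv[c])
            gids.append(gid)
            centers.append(c)
    n = len(seqs)
    return WindowDataset(
        seq=np.array(seqs, dtype=np.int16).reshape(n, 2 * W + 1),
        ref=np.array(refs, dtype=np.float64).reshape(n, 2 * W + 1),
        target=np.array(targets, dtype=np.float64),
        gene=np.array(gids, dtype=object),
        center_index=np.array(centers, dtype=np.int64),
        W=W,
        ref_transform=ref_cd.transform,
        target_transform=target_cd.transform,
    )


# ---------------------------------------------------------------------------
# Dataset splitting
# ---------------------------------------------------------------------------


@dataclass
class DatasetSplit:
    mode: str  # 'fraction' | 'kfold'
    seed: int
    assignment: np.ndarray  # (n,) labels: 'train'/'val'/'test' or fold ints

    def indices(self, label) -> np.ndarray:
        return np.nonzero(self.assignment == label)[0]


def split_dataset(
    ds: WindowDataset,
    mode: str = "fraction",
    seed: int = 0,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    k: int | None = None,
) -> DatasetSplit:
    """Deterministic shuffle-split: 70/15/15 fractions or k near-equal folds."""
    n = len(ds)
    if n == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    if mode == "fraction":
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        labels = np.empty(n, dtype=object)
        labels[perm[:n_train]] = "train"
        labels[perm[n_train : n_train + n_val]] = "val"
        labels[perm[n_train + n_val :]] = "test"
        return DatasetSplit(mode="fraction", seed=seed, assignment=labels)
    if mode == "kfold":
        if k is None or k < 2:
            raise ValueError("kfold mode requires k >= 2")
        if k > n:
            raise ValueError(f"k={k} exceeds instance count {n}")
        labels = np.empty(n, dtype=np.int64)
        for f, fold in enumerate(np.array_split(perm, k)):
            labels[fold] = f
        return DatasetSplit(mode="kfold", seed=seed, assignment=labels)
    raise ValueError(f"unknown split mode {mode!r}")


# ---------------------------------------------------------------------------
# TSV export
# ---------------------------------------------------------------------------


def export_codon_density(cd: CodonDensity, path) -> None:
    """Write (gene_id, codon_index, value) with 6-decimal fixed point."""
    with open(path, "w") as fh:
        fh.write("gene_id\tcodon_index\tvalue\n")
        for gid, v in cd.values.items():
            for i, x in enumerate(v):
                fh.write(f"{gid}\t{i}\t{x:.6f}\n")


def export_pause_scores(table: PauseScoreTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcodon_index\tvalue\n")
        for row in table.instances.itertuples(index=False):
            fh.write(f"{row.gene}\t{row.codon_index}\t{row.score:.6f}\n")
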