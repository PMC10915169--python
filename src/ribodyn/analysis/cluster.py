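"""K-means clustering of SIS profiles and per-cluster codon enrichment."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .. import codons as _cod
from .sis import SISProfile, sis_matrix

P_FLOOR = 1e-300


@dataclass
class ClusterSet:
    k: int
    labels: np.ndarray  # (n_profiles,) in 0..k-1
    centers: np.ndarray  # (k, 2W+1) mean profile per cluster
    inertia_curve: dict[int, float]  # candidate k -> inertia
    seed: int
    imputed: bool  # True when NaN positions were zero-filled


def _elbow_k(inertia: dict[int, float]) -> int:
    """Maximum second difference of the inertia curve."""
    ks = sorted(inertia)
    if len(ks) < 3:
        return ks[0]
    best_k, best_d2 = ks[1], -np.inf
    for i in range(1, len(ks) - 1):
        d2 = inertia[ks[i - 1]] - 2 * inertia[ks[i]] + inertia[ks[i + 1]]
        if d2 > best_d2:
            best_k, best_d2 = ks[i], d2
    return best_k


def cluster_sis(
    profiles: list[SISProfile],
    k: int | None = None,
    seed: int = 0,
    k_range: tuple[int, int] = (2, 15),
) -> ClusterSet:
    """K-means over SIS profiles; k chosen by the elbow (maximum second
    difference of inertia over ``k_range``) unless given.  Deterministic
    given identical inputs and seed."""
    X = sis_matrix(profiles)
    imputed = bool(np.isnan(X).any())
    X = np.nan_to_num(X, nan=0.0)
    n = X.shape[0]
    if k is not None and k > n:
        raise ValueError(f"k={k} exceeds number of profiles {n}")

    if np.allclose(X, X[0]):
        warnings.warn("all profiles identical; degenerate clustering k=1",
                      stacklevel=2)
        return ClusterSet(
            k=1, labels=np.zeros(n, dtype=np.int64), centers=X[:1].copy(),
            inertia_curve={1: 0.0}, seed=seed, imputed=imputed,
        )

    inertia: dict[int, float] = {}
    if k is None:
        lo, hi = k_range
        hi = min(hi, n - 1) if n > 2 else lo
        for kk in range(lo, hi + 1):
            km = KMeans(n_clusters=kk, random_state=seed, n_init=10).fit(X)
            inertia[kk] = float(km.inertia_)
        k = _elbow_k(inertia)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(X)
    inertia[k] = float(km.inertia_)
    labels = km.labels_.astype(np.int64)
    centers = np.vstack([X[labels == c].mean(axis=0) for c in range(k)])
    return ClusterSet(
        k=k, labels=labels, centers=centers, inertia_curve=inertia,
        seed=seed, imputed=imputed,
    )


def cluster_codon_enrichment(
    clusters: ClusterSet,
    site_sequences: np.ndarray,
    n_background: int = 1000,
    seed: int = 0,
    background: str = "uniform",
    usage_weights: np.ndarray | None = None,
) -> dict[int, pd.DataFrame]:
    """Per-cluster signed enrichment scores, codon x relative position.

    For each sense codon and window position, the 0/1 occurrence
    indicators across the cluster's sites are compared with those of
    ``n_background`` random codon sequences by a two-sample t-test; the
    score is sign(cluster mean - background mean) * -log10(p) with the
    p-value floored at 1e-300.  Clusters with fewer than 3 sites yield an
    all-NaN matrix.  Background sampling is uniform over sense codons by
    default, or proportional to ``usage_weights``.
    """
    site_sequences = np.asarray(site_sequences)
    if site_sequences.shape[0] != clusters.labels.size:
        raise ValueError("site_sequences and cluster labels differ in length")
    L = site_sequences.shape[1]
    W = (L - 1) // 2
    positions = np.arange(-W, L - W)
    rng = np.random.default_rng(seed)
    if background == "uniform":
        p = None
    elif background == "usage":
        if usage_weights is None:
            raise ValueError("usage background requires usage_weights")
        p = usage_weights / usage_weights.sum()
    else:
        raise ValueError(f"unknown background mode {background!r}")
    bg = rng.choice(_cod.SENSE_INDICES, size=(n_background, L), p=p)

    out: dict[int, pd.DataFrame] = {}
    for c in range(clusters.k):
        rows = site_sequences[clusters.labels == c]
        mat = np.full((len(_cod.SENSE_CODONS), L), np.nan)
        if rows.shape[0] >= 3:
            for ci, codon in enumerate(_cod.SENSE_CODONS):
                tgt = _cod.CODON_INDEX[codon]
                occ = (rows == tgt).astype(np.float64)
                occ_bg = (bg == tgt).astype(np.float64)
                t, pv = stats.ttest_ind(occ, occ_bg, axis=0)
                pv = np.where(np.isnan(pv), 1.0, pv)
                pv = np.maximum(pv, P_FLOOR)
                sign = np.sign(occ.mean(axis=0) - occ_bg.mean(axis=0))
                mat[ci] = sign * (-np.log10(pv))
        out[c] = pd.DataFrame(mat, index=list(_cod.SENSE_CODONS), columns=positions)
    return out


def write_cluster_labels(clusters: ClusterSet, site_ids: list[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("site_id\tcluster\n")
        for sid, lab in zip(site_ids, clusters.labels):
            fh.write(f"{sid}\t{int(lab)}\n")
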