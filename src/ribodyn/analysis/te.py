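"""Translation efficiency and positional codon enrichment."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ..profiles import GeneSet


def translation_efficiency(
    rd_by_gene: Mapping[str, float], fpkm_by_gene: Mapping[str, float]
) -> pd.DataFrame:
    """TE = mean ribosome density / mRNA abundance, on the gene intersection.

    Genes with FPKM = 0 are excluded; the count of exclusions is stored in
    ``df.attrs['n_excluded_zero_fpkm']``.
    """
    common = sorted(set(rd_by_gene) & set(fpkm_by_gene))
    if not common:
        raise ValueError("no genes shared between density and FPKM inputs")
    rows = [(g, rd_by_gene[g], fpkm_by_gene[g]) for g in common]
    df = pd.DataFrame(rows, columns=["gene_id", "rd", "fpkm"])
    n_zero = int((df["fpkm"] == 0).sum())
    df = df[df["fpkm"] > 0].reset_index(drop=True)
    df["te"] = df["rd"] / df["fpkm"]
    df.attrs["n_excluded_zero_fpkm"] = n_zero
    return df


def _window_codon_counts(
    genes: GeneSet, ids: Sequence[str], codon: str, window: int, first_n: int
) -> np.ndarray:
    """Per-gene codon counts in each ``window``-codon bin over the first
    ``first_n`` codons -> array (len(ids), first_n // window)."""
    from ..codons import CODON_INDEX

    target = CODON_INDEX[codon]
    n_windows = first_n // window
    out = np.zeros((len(ids), n_windows), dtype=np.float64)
    for r, gid in enumerate(ids):
        cod = genes.codon_indices(gid)[:first_n]
        hits = np.nonzero(cod == target)[0]
        for h in hits:
            out[r, h // window] += 1
    return out


def positional_codon_enrichment(
    genes: GeneSet,
    gene_group: Sequence[str],
    background_pool: Sequence[str],
    codon: str,
    window: int = 10,
    first_n_codons: int = 100,
    n_resample: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Windowed codon-count enrichment of a gene group vs matched random
    samples from a background pool.

    For each ``window``-codon bin over the first ``first_n_codons``, the
    per-gene counts of ``codon`` in the group are compared with those of a
    size-matched random sample (``n_resample`` samples pooled) drawn from
    the background, via a two-sample t-test.  Returns one row per window
    with the group/background means, t statistic and p-value.
    """
    if len(gene_group) < 3:
        raise ValueError("gene group must contain at least 3 genes")
    rng = np.random.default_rng(seed)
    grp = _window_codon_counts(genes, gene_group, codon, window, first_n_codons)
    pool = list(background_pool)
    samples = []
    for _ in range(max(n_resample, 1)):
        pick = rng.choice(len(pool), size=len(gene_group), replace=False)
        samples.append(
            _window_codon_counts(
                genes, [pool[i] for i in pick], codon, window, first_n_codons
            )
        )
    bg = np.vstack(samples)
    rows = []
    for w in range(grp.shape[1]):
        t, p = stats.ttest_ind(grp[:, w], bg[:, w])
        if np.isnan(t):  # both samples constant
            t, p = (0.0, 1.0) if grp[:, w].mean() == bg[:, w].mean() else (np.inf, 0.0)
        rows.append(
            {
                "window": w,
                "codon_start": w * window,
                "group_mean": grp[:, w].mean(),
                "background_mean": bg[:, w].mean(),
                "t": float(t),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)
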