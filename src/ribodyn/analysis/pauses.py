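"""Differential (condition-dependent) pause-site detection.

Per retained codon a 2x2 contingency table contrasts the reads at that
position against the rest of the gene, case vs control; sites are flagged
at two-sided Fisher p < alpha with odds ratio > 1 (enrichment in the case
condition).  Benjamini-Hochberg q-values are reported for information
only and never used for flagging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ..profiles import TRIM, CodonDensity, GeneSet, TransformError


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on [[a, b], [c, d]].

    Returns (odds_ratio, p).  The p-value sums hypergeometric
    probabilities of all tables with the observed margins whose
    probability does not exceed the observed one (relative tolerance
    1e-7).  OR = ad/bc; +inf when bc = 0 and ad > 0, NaN when both
    products are 0.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("contingency table has a negative cell")
    if not np.allclose(t, np.round(t)):
        raise ValueError("contingency table must contain integers")
    t = np.round(t).astype(np.int64)
    if t.sum() == 0:
        raise ValueError("all-zero contingency table")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    ad, bc = a * d, b * c
    if bc == 0:
        odds = np.inf if ad > 0 else np.nan
    else:
        odds = ad / bc
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return odds, float(p)


@dataclass
class PauseSite:
    gene: str
    codon_index: int
    odds_ratio: float
    p_value: float
    q_value: float
    table: tuple[int, int, int, int]  # a, b, c, d


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def detect_pause_sites(
    ctrl_cd: CodonDensity,
    case_cd: CodonDensity,
    genes: GeneSet,
    alpha: float = 0.001,
    trim: int = TRIM,
) -> list[PauseSite]:
    """Flag retained codons with p < alpha and OR > 1 (case enrichment).

    Both densities must be raw (count scale); replicate-averaged fractional
    counts are rounded half-up to integers for the exact test.  Gene
    totals are taken over retained codons.  Results are sorted by p-value.
    """
    for cd, name in ((ctrl_cd, "control"), (case_cd, "case")):
        if cd.transform != "raw":
            raise TransformError(f"{name} density must be raw, got {cd.transform!r}")
    records = []  # (gene, idx, a, b, c, d, odds, p)
    for gid in genes:
        if gid not in ctrl_cd.values or gid not in case_cd.values:
            warnings.warn(f"gene {gid!r} missing from a condition; skipped",
                          stacklevel=2)
            continue
        ctrl = np.floor(ctrl_cd.values[gid] + 0.5).astype(np.int64)
        case = np.floor(case_cd.values[gid] + 0.5).astype(np.int64)
        L = genes.length_codons(gid)
        if L <= 2 * trim:
            continue
        sl = slice(trim, L - trim)
        ctrl_r, case_r = ctrl[sl], case[sl]
        ctot, katot = int(ctrl_r.sum()), int(case_r.sum())
        if ctot == 0 or katot == 0:
            continue
        for j in np.nonzero(ctrl_r + case_r)[0]:
            a, c = int(case_r[j]), int(ctrl_r[j])
            tbl = [[a, katot - a], [c, ctot - c]]
            odds, p = fisher_exact_2x2(tbl)
            records.append(
                (gid, trim + int(j), a, katot - a, c, ctot - c, odds, p)
            )
    if not records:
        return []
    pvals = np.array([r[7] for r in records])
    qvals = _bh_qvalues(pvals)
    sites = [
        PauseSite(
            gene=r[0], codon_index=r[1], odds_ratio=r[6], p_value=r[7],
            q_value=float(q), table=(r[2], r[3], r[4], r[5]),
        )
        for r, q in zip(records, qvals)
        if r[7] < alpha and r[6] > 1
    ]
    sites.sort(key=lambda s: s.p_value)
    return sites


def write_pause_sites(sites: list[PauseSite], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tcodon_index\ta\tb\tc\td\todds_ratio\tp\tq\n")
        for s in sites:
            a, b, c, d = s.table
            fh.write(
                f"{s.gene}\t{s.codon_index}\t{a}\t{b}\t{c}\t{d}\t"
                f"{s.odds_ratio:.6g}\t{s.p_value:.6g}\t{s.q_value:.6g}\n"
            )
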