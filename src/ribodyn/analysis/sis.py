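"""In silico mutagenesis: sequence impact scores (SIS).

A fixed-length window slides across a model input at one-codon steps; at
each placement the windowed codons are replaced by ``n_samples`` random
sense-codon sequences and SIS = RD - RD', the observed prediction minus
the mutant average.  Per-codon SIS averages over the placements covering
that codon (edge codons are covered by fewer placements).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import codons as _cod


@dataclass
class SISProfile:
    """Per-position sequence impact scores around one site."""

    site_id: str
    positions: np.ndarray  # relative codon offsets -W..+W
    sis: np.ndarray  # (2W+1,) mean SIS per codon; NaN where uncovered
    n_windows: np.ndarray  # placements covering each position
    rd: float  # unmutated prediction
    window_sis: np.ndarray  # (n_placements,) SIS per window placement


def compute_sis(
    model,
    seq_window: np.ndarray,
    ref_window: np.ndarray,
    mut_window: int = 10,
    n_samples: int = 100,
    rng_seed: int = 0,
    site_id: str = "site",
) -> SISProfile:
    """SIS profile for one (sequence, reference) instance.

    ``model`` must expose ``predict_arrays(seq, ref) -> (n,) array``
    (satisfied by :class:`~ribodyn.nn.train.TrainedModel`).  Mutant codons
    are drawn uniformly from the 61 sense codons.
    """
    seq = np.asarray(seq_window, dtype=np.int16)
    ref = np.asarray(ref_window, dtype=np.float64)
    L = seq.size
    if ref.size != L:
        raise ValueError("sequence and reference windows differ in length")
    if not 1 <= mut_window <= L:
        raise ValueError(f"mut_window must be in 1..{L}")
    rng = np.random.default_rng(rng_seed)
    n_place = L - mut_window + 1

    rd = float(model.predict_arrays(seq[None, :], ref[None, :])[0])

    # one batch with every placement x sample
    seq_batch = np.tile(seq, (n_place * n_samples, 1))
    muts = rng.choice(_cod.SENSE_INDICES, size=(n_place, n_samples, mut_window))
    for s in range(n_place):
        rows = slice(s * n_samples, (s + 1) * n_samples)
        seq_batch[rows, s : s + mut_window] = muts[s]
    ref_batch = np.tile(ref, (n_place * n_samples, 1))
    preds = np.asarray(model.predict_arrays(seq_batch, ref_batch), dtype=np.float64)
    rd_prime = preds.reshape(n_place, n_samples).mean(axis=1)
    window_sis = rd - rd_prime

    sis = np.full(L, np.nan)
    n_windows = np.zeros(L, dtype=np.int64)
    acc = np.zeros(L)
    for s in range(n_place):
        acc[s : s + mut_window] += window_sis[s]
        n_windows[s : s + mut_window] += 1
    covered = n_windows > 0
    sis[covered] = acc[covered] / n_windows[covered]

    W = (L - 1) // 2
    return SISProfile(
        site_id=site_id,
        positions=np.arange(-W, L - W),
        sis=sis,
        n_windows=n_windows,
        rd=rd,
        window_sis=window_sis,
    )


def sis_matrix(profiles: list[SISProfile]) -> np.ndarray:
    """Stack profiles into a (n_sites, 2W+1) matrix (NaN where uncovered)."""
    if not profiles:
        raise ValueError("no profiles")
    return np.vstack([p.sis for p in profiles])


def write_sis_matrix(profiles: list[SISProfile], path) -> None:
    with open(path, "w") as fh:
        pos = profiles[0].positions
        fh.write("site_id\t" + "\t".join(str(p) for p in pos) + "\n")
        for p in profiles:
            vals = "\t".join("NA" if np.isnan(v) else f"{v:.6f}" for v in p.sis)
            fh.write(f"{p.site_id}\t{vals}\n")
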