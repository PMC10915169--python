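"""Folding-energy interface: external RNAfold when available, otherwise a
deterministic toy stub.

The stub is NOT a thermodynamic model.  It scans a single hairpin-like
stem by pairing position i with position n-1-i and scores -2 kcal/mol per
Watson-Crick pair — enough to give structured sequences reproducibly
lower energies than unstructured ones in tests.
"""

from __future__ import annotations

import shutil
import subprocess

from ..codons import complement

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def _stub_energy(seq: str) -> float:
    seq = seq.upper().replace("U", "T")
    n = len(seq)
    pairs = sum(1 for i in range(n // 2) if (seq[i], seq[n - 1 - i]) in _PAIRS)
    return -2.0 * pairs


def _rnafold_energy(seq: str) -> float:
    exe = shutil.which("RNAfold")
    if exe is None:
        raise RuntimeError(
            "RNAfold executable not found; use engine='stub' instead"
        )
    res = subprocess.run(
        [exe, "--noPS"], input=seq + "\n", capture_output=True, text=True, check=True
    )
    # last line: "....structure.... ( -1.20)"
    line = res.stdout.strip().splitlines()[-1]
    return float(line.rsplit("(", 1)[1].rstrip(")").strip())


def folding_energy(nt_sequence: str, engine: str = "stub") -> dict:
    """Folding free energy (kcal/mol) of a nucleotide sequence.

    Returns {'energy': float, 'engine': str}.  ``engine`` is 'stub'
    (bundled deterministic toy) or 'rnafold' (external binary, errors when
    absent)."""
    if engine == "stub":
        return {"energy": _stub_energy(nt_sequence), "engine": "stub"}
    if engine == "rnafold":
        return {"energy": _rnafold_energy(nt_sequence), "engine": "rnafold"}
    raise ValueError(f"unknown folding engine {engine!r}")
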