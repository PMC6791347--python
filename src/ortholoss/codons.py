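"""Codon-level constants and small sequence utilities.

The standard genetic code throughout; the three stop codons (TAA, TAG,
TGA) are excluded from the 61-state sense-codon alphabet used by the
substitution model.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Seq import Seq

BASES = "TCAG"
PURINES = frozenset("AG")
STOP_CODONS = ("TAA", "TAG", "TGA")

ALL_CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_STATES = len(SENSE_CODONS)  # 61

AMINO_ACID = {c: str(Seq(c).translate()) for c in SENSE_CODONS}


def _is_transition(a: str, b: str) -> bool:
    return (a in PURINES) == (b in PURINES)


def _build_structure() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean 61x61 masks: single-nt neighbours, transitions, nonsynonymous."""
    n = N_STATES
    neighbour = np.zeros((n, n), dtype=bool)
    transition = np.zeros((n, n), dtype=bool)
    nonsyn = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            neighbour[i, j] = True
            a, b = diffs[0]
            transition[i, j] = _is_transition(a, b)
            nonsyn[i, j] = AMINO_ACID[ci] != AMINO_ACID[cj]
    return neighbour, transition, nonsyn


NEIGHBOUR_MASK, TRANSITION_MASK, NONSYN_MASK = _build_structure()

COMPLEMENT = str.maketrans("ACGTNacgtn-", "TGCANtgcan-")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    return str(Seq(cds).translate())


def codons_of(seq: str) -> list[str]:
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def has_internal_stop(cds: str) -> bool:
    cods = codons_of(cds)
    return any(c in STOP_CODONS for c in cods[:-1])


def random_sense_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Uniform random stop-free coding sequence of ``n_codons`` codons."""
    idx = rng.integers(0, N_STATES, size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def n_runs(seq: str, min_len: int = 1) -> list[tuple[int, int]]:
    """Maximal runs of N (0-based half-open intervals) of length >= min_len."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, b in enumerate(seq.upper()):
        if b == "N":
            if start is None:
                start = i
        elif start is not None:
            if i - start >= min_len:
                runs.append((start, i))
            start = None
    if start is not None and len(seq) - start >= min_len:
        runs.append((start, len(seq)))
    return runs
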