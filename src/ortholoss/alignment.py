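"""Gap-aware codon alignment container.

Sequences are stored as gapped nucleotide strings whose length is a
multiple of three; every column triple is one codon site.  Symbols other
than ``ACGT`` (gaps ``-``, missing ``?``, assembly ``N``) make the whole
codon ambiguous, and stop codons are likewise treated as missing data —
the convention used when eroded sequences enter a selection analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import CODON_INDEX, STOP_CODONS


@dataclass
class CodonAlignment:
    taxa: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.seqs):
            raise ValueError("taxa/seqs length mismatch")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError(f"unequal aligned lengths: {sorted(lengths)}")
        if self.seqs and len(self.seqs[0]) % 3:
            raise ValueError("aligned length not a multiple of 3")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_codons(self) -> int:
        return len(self.seqs[0]) // 3 if self.seqs else 0

    def sequence(self, taxon: str) -> str:
        return self.seqs[self.taxa.index(taxon)]

    def codon_states(self) -> np.ndarray:
        """(n_taxa, n_codons) int matrix of sense-codon indices, -1 = ambiguous."""
        out = np.full((self.n_taxa, self.n_codons), -1, dtype=np.int64)
        for i, seq in enumerate(self.seqs):
            s = seq.upper()
            for k in range(self.n_codons):
                cod = s[3 * k : 3 * k + 3]
                if cod in CODON_INDEX:
                    out[i, k] = CODON_INDEX[cod]
        return out

    def pairwise_identity(self, a: str, b: str) -> float:
        """Nucleotide identity over columns where both have a residue."""
        sa, sb = self.sequence(a).upper(), self.sequence(b).upper()
        same = tot = 0
        for x, y in zip(sa, sb):
            if x in "ACGT" and y in "ACGT":
                tot += 1
                same += x == y
        return same / tot if tot else float("nan")

    def mean_pairwise_identity(self) -> float:
        vals = [
            self.pairwise_identity(self.taxa[i], self.taxa[j])
            for i in range(self.n_taxa)
            for j in range(i + 1, self.n_taxa)
        ]
        vals = [v for v in vals if v == v]
        return float(np.mean(vals)) if vals else float("nan")

    # -- IO -------------------------------------------------------------
    @classmethod
    def from_fasta(cls, path: str | Path) -> "CodonAlignment":
        recs = list(SeqIO.parse(str(path), "fasta"))
        return cls([r.id for r in recs], [str(r.seq).upper() for r in recs])

    def to_fasta(self, path: str | Path) -> None:
        recs = [
            SeqRecord(Seq(s), id=t, description="") for t, s in zip(self.taxa, self.seqs)
        ]
        SeqIO.write(recs, str(path), "fasta")


def mask_stops(seq: str) -> str:
    """Replace in-frame stop codons with the missing-data codon ``???``."""
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        cod = seq[i : i + 3].upper()
        out.append("???" if cod in STOP_CODONS else seq[i : i + 3])
    return "".join(out) + seq[len(seq) - len(seq) % 3 :]
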