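"""Genomic locus slice: a contig/scaffold interval with strand and N-runs."""

from __future__ import annotations

from dataclasses import dataclass, field

from .codons import n_runs as _find_n_runs
from .codons import revcomp


@dataclass
class GenomicLocus:
    """A slice of a contig with coordinates, strand, and assembly-gap record.

    ``start``/``end`` are 0-based half-open coordinates of the slice on
    its source contig; ``seq`` is the plus-strand sequence of the slice
    as stored (already reverse-complemented when ``strand`` is '-').
    """

    name: str
    seq: str
    contig: str = ""
    start: int = 0
    end: int = -1
    strand: str = "+"
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end < 0:
            self.end = self.start + len(self.seq)
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def n_run_intervals(self) -> list[tuple[int, int]]:
        """Maximal runs of N in ``seq`` (0-based half-open)."""
        return _find_n_runs(self.seq)

    def reverse_complement(self) -> "GenomicLocus":
        return GenomicLocus(
            name=self.name,
            seq=revcomp(self.seq),
            contig=self.contig,
            start=self.start,
            end=self.end,
            strand="-" if self.strand == "+" else "+",
            notes=list(self.notes),
        )
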