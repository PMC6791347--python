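"""Locus orthology via neighbor-gene synteny and anchor pairs.

Queries (neighbor genes of the focal locus) are aligned locally against
both strands of every target contig with affine-gap Smith–Waterman
using megablast-like scores (match 2, mismatch -3, gap open 5, gap
extend 2).  The best hit per gene is ranked lexicographically by
(query coverage, percent identity), with deterministic tie-breaks:
longer alignment, then contig name, then smaller start.  A synteny map
orders the hits along each contig; the inter-anchor interval defines
the candidate region for the focal gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

from .codons import revcomp
from .locus import GenomicLocus

logger = logging.getLogger(__name__)


class SyntenyError(ValueError):
    pass


class RegionNotResolvable(SyntenyError):
    """Anchors on different contigs: fall back to a direct CDS search."""


@dataclass
class GeneHit:
    """Best local-alignment hit of one query gene on a target genome."""

    query_gene: str
    target_contig: str
    start: int  # 0-based half-open on the contig plus strand
    end: int
    strand: str
    percent_identity: float
    query_coverage: float
    aln_length: int = 0
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise SyntenyError("hit interval must satisfy start < end")
        if not (0 <= self.percent_identity <= 100 and 0 <= self.query_coverage <= 100):
            raise SyntenyError("identity/coverage out of [0, 100]")

    @property
    def rank_key(self) -> tuple:
        # maximize coverage, identity, length; minimize name, start
        return (
            -self.query_coverage,
            -self.percent_identity,
            -self.aln_length,
            self.target_contig,
            self.start,
        )


@dataclass
class SyntenyMap:
    """Per-contig coordinate-sorted gene hits plus the focal-gene flag."""

    hits_by_contig: dict[str, list[GeneHit]]
    absent: list[str] = field(default_factory=list)
    focal_gene_present: bool = False

    def order_on(self, contig: str) -> list[str]:
        return [h.query_gene for h in self.hits_by_contig.get(contig, [])]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tcontig\tstart\tend\tstrand\tidentity\tcoverage\n")
            for contig in sorted(self.hits_by_contig):
                for h in self.hits_by_contig[contig]:
                    fh.write(
                        f"{h.query_gene}\t{contig}\t{h.start + 1}\t{h.end}\t{h.strand}\t"
                        f"{h.percent_identity:.2f}\t{h.query_coverage:.2f}\n"
                    )
            for g in self.absent:
                fh.write(f"{g}\t.\t0\t0\t.\t0.00\t0.00\n")

    def to_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for contig in sorted(self.hits_by_contig):
                for h in self.hits_by_contig[contig]:
                    fh.write(
                        f"{contig}\tortholoss\tmatch\t{h.start + 1}\t{h.end}\t"
                        f"{h.score:.1f}\t{h.strand}\t.\tID={h.query_gene};"
                        f"identity={h.percent_identity:.2f};coverage={h.query_coverage:.2f}\n"
                    )


def _aligner() -> Align.PairwiseAligner:
    m = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            m[a, b] = 2.0 if a == b else -3.0
    # N row/column stays 0: wildcard at zero score
    al = Align.PairwiseAligner()
    al.substitution_matrix = m
    al.mode = "local"
    al.open_gap_score = -5.0
    al.extend_gap_score = -2.0
    return al


_LOCAL = _aligner()


def _hit_from_alignment(aln, query_gene, contig_name, contig_len, strand, query_len) -> GeneHit:
    tgt, qry = str(aln[0]), str(aln[1])
    matches = sum(
        1 for a, b in zip(tgt.upper(), qry.upper()) if a == b and a in "ACGT"
    )
    cols = sum(1 for a, b in zip(tgt, qry) if a != "-" and b != "-")
    identity = 100.0 * matches / cols if cols else 0.0
    qs, qe = int(aln.coordinates[1, 0]), int(aln.coordinates[1, -1])
    coverage = 100.0 * (qe - qs) / query_len
    ts, te = int(aln.coordinates[0, 0]), int(aln.coordinates[0, -1])
    if strand == "-":
        ts, te = contig_len - te, contig_len - ts
    return GeneHit(
        query_gene=query_gene,
        target_contig=contig_name,
        start=ts,
        end=te,
        strand=strand,
        percent_identity=identity,
        query_coverage=coverage,
        aln_length=len(tgt),
        score=float(aln.score),
    )


def best_hit(
    query_gene: str,
    query_seq: str,
    target_contigs: dict[str, str],
    min_identity: float = 70.0,
    min_coverage: float = 50.0,
) -> GeneHit | None:
    """Best local hit of ``query_seq`` over both strands of all contigs.

    Candidates are ranked by (query coverage, percent identity)
    lexicographically; hits below either threshold yield ``None``.
    """
    if not query_seq:
        raise SyntenyError("empty query sequence")
    if not target_contigs:
        raise SyntenyError("empty contig set")
    query = query_seq.upper()
    candidates: list[GeneHit] = []
    for contig_name in sorted(target_contigs):
        seq = target_contigs[contig_name].upper()
        if not seq:
            continue
        for strand in "+-":
            target = seq if strand == "+" else revcomp(seq)
            try:
                alns = _LOCAL.align(target, query)
                top = alns[0]
            except (IndexError, ValueError):
                continue
            if top.score <= 0:
                continue
            candidates.append(
                _hit_from_alignment(top, query_gene, contig_name, len(seq), strand, len(query))
            )
    candidates = [
        h
        for h in candidates
        if h.percent_identity >= min_identity and h.query_coverage >= min_coverage
    ]
    if not candidates:
        return None
    return min(candidates, key=lambda h: h.rank_key)


def build_synteny_map(
    reference_neighbors: list[tuple[str, str]],
    target_genome: dict[str, str],
    focal_gene: tuple[str, str] | None = None,
    min_identity: float = 70.0,
    min_coverage: float = 50.0,
) -> SyntenyMap:
    """One best hit per ordered neighbor gene, sorted per contig.

    ``reference_neighbors`` is ordered by reference coordinate; genes
    without an above-threshold hit are recorded as absent.
    """
    hits: dict[str, list[GeneHit]] = {}
    absent: list[str] = []
    for name, seq in reference_neighbors:
        h = best_hit(name, seq, target_genome, min_identity, min_coverage)
        if h is None:
            absent.append(name)
        else:
            hits.setdefault(h.target_contig, []).append(h)
    for contig in hits:
        hits[contig].sort(key=lambda h: (h.start, h.end, h.query_gene))
    focal_present = False
    if focal_gene is not None:
        focal_present = (
            best_hit(focal_gene[0], focal_gene[1], target_genome, min_identity, min_coverage)
            is not None
        )
    return SyntenyMap(hits_by_contig=hits, absent=absent, focal_gene_present=focal_present)


def locate_target_region(
    upstream_anchor_hit: GeneHit,
    downstream_anchor_hit: GeneHit,
    target_contigs: dict[str, str],
    padding_nt: int = 0,
) -> GenomicLocus:
    """Inter-anchor interval expanded by ``padding_nt``, clipped to the
    contig; strand follows the anchors' orientation.

    Anchors on different contigs raise :class:`RegionNotResolvable`
    (the caller's fallback is a direct CDS search against the contigs).
    """
    up, down = upstream_anchor_hit, downstream_anchor_hit
    if up.target_contig != down.target_contig:
        raise RegionNotResolvable(
            "anchors on different contigs; region not resolvable — "
            "fall back to direct CDS search"
        )
    contig = target_contigs[up.target_contig]
    if up.strand != down.strand:
        logger.warning(
            "anchor hits on opposite strands (%s vs %s); using '+' for the region",
            up.strand,
            down.strand,
        )
        strand = "+"
    else:
        strand = up.strand
    inner_start = min(up.end, down.end)
    inner_end = max(up.start, down.start)
    start = max(0, inner_start - padding_nt)
    end = min(len(contig), inner_end + padding_nt)
    if start >= end:
        raise SyntenyError(
            f"empty inter-anchor interval ({inner_start}, {inner_end}) with padding {padding_nt}"
        )
    seq = contig[start:end]
    if strand == "-":
        seq = revcomp(seq)
    return GenomicLocus(
        name=f"{up.target_contig}:{start}-{end}",
        seq=seq,
        contig=up.target_contig,
        start=start,
        end=end,
        strand=strand,
    )
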