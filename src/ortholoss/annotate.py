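"""Reference-guided CDS reconstruction and inactivating-mutation calling.

A reference single-exon gene (CDS, optionally UTR-flanked) is mapped
onto a genomic region by semi-global affine alignment (reference
end-gaps free, N wildcard), the target coding sequence is reconstructed
in the reference frame, and ORF-abolishing lesions — frameshift indels,
in-frame premature stop codons, and abrupt-identity-drop truncations —
are called at reference-projected coordinates.  The same machinery
builds the missing-data-aware codon alignment consumed by the
selection analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .alignment import CodonAlignment
from .codons import STOP_CODONS, codons_of, has_internal_stop, revcomp, translate
from .locus import GenomicLocus
from .variants import left_normalize_deletion, left_normalize_insertion

logger = logging.getLogger(__name__)

INTACT = "intact"
ERODED = "eroded"
INCONCLUSIVE = "inconclusive"


class AnnotationError(ValueError):
    pass


class NoOrthologDetected(AnnotationError):
    pass


@dataclass
class ReferenceGene:
    """Intact single-exon reference gene used to guide annotation."""

    name: str
    cds: str
    utr5: str = ""
    utr3: str = ""
    taxon: str = ""

    def __post_init__(self) -> None:
        self.cds = self.cds.upper()
        self.utr5 = self.utr5.upper()
        self.utr3 = self.utr3.upper()
        if len(self.cds) % 3:
            raise AnnotationError("reference CDS length must be divisible by 3")
        if self.cds[-3:] not in STOP_CODONS:
            raise AnnotationError("reference CDS must end in a stop codon")
        if has_internal_stop(self.cds):
            raise AnnotationError("reference CDS contains an internal stop codon")

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3

    @property
    def full_query(self) -> str:
        return self.utr5 + self.cds + self.utr3


@dataclass
class InactivatingMutation:
    """A typed ORF-abolishing lesion at a reference-projected coordinate.

    ``ref_coord`` is 1-based on the reference CDS (first deleted base;
    base 5' of an insertion; first base of a stop codon).  ``alt_allele``
    / ``ref_allele`` and ``region_coord`` (0-based on the oriented
    region sequence) let reads be scored against the two haplotypes.
    """

    kind: str  # frameshift_insertion | frameshift_deletion | premature_stop | truncation
    ref_coord: int
    length_nt: int = 0
    codon_index: int = 0
    orf_fraction: float = 0.0
    compensated: bool = False
    region_coord: int = -1
    ref_allele: str = ""
    alt_allele: str = ""
    taxon: str = ""
    read_validation_status: str = ""

    def key(self) -> tuple[str, int, int]:
        """Lesion-homology identity: kind, coordinate and length."""
        return (self.kind, self.ref_coord, self.length_nt)


# ----------------------------------------------------------------------
# reference mapping
# ----------------------------------------------------------------------

def _map_aligner() -> Align.PairwiseAligner:
    m = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            m[a, b] = 1.0 if a == b else -2.0
    al = Align.PairwiseAligner()
    al.substitution_matrix = m
    al.mode = "local"  # clips non-homologous flanks and fragmented ends
    al.open_gap_score = -12.0
    al.extend_gap_score = -3.0
    return al


_MAPPER = _map_aligner()

_UNCOVERED = "."  # internal marker for reference positions outside the aligned span


@dataclass
class MappedAlignment:
    """Reference-vs-region pairwise alignment with CDS projection."""

    reference: ReferenceGene
    region: GenomicLocus
    strand_used: str
    ref_aln: str
    tgt_aln: str
    target_seq: str  # region sequence in the orientation that aligned
    score: float
    # per reference-CDS position (0-based): target base, '-' for internal
    # deletion, '.' for uncovered; parallel region coordinate (-1 where gap)
    target_at_ref: list[str] = field(default_factory=list)
    region_coord_at_ref: list[int] = field(default_factory=list)
    insertions: list[tuple[int, str, int]] = field(default_factory=list)
    # (ref CDS pos0 before which insertion sits, inserted string, region coord)

    @property
    def coverage(self) -> float:
        """Fraction of reference CDS positions inside the aligned span."""
        n = len(self.target_at_ref)
        return sum(1 for b in self.target_at_ref if b != _UNCOVERED) / n if n else 0.0

    @property
    def unambiguous_coverage(self) -> float:
        """Fraction of reference CDS positions aligned to a real base."""
        n = len(self.target_at_ref)
        return sum(1 for b in self.target_at_ref if b in "ACGT") / n if n else 0.0

    @property
    def n_fraction(self) -> float:
        """Fraction of covered CDS columns whose region base is N."""
        covered = [b for b in self.target_at_ref if b != _UNCOVERED]
        return sum(1 for b in covered if b == "N") / len(covered) if covered else 0.0

    def covered_ref_intervals(self) -> list[tuple[int, int]]:
        """1-based inclusive reference-CDS intervals aligned to real bases."""
        out: list[tuple[int, int]] = []
        start = None
        for i, b in enumerate(self.target_at_ref):
            if b in "ACGT":
                if start is None:
                    start = i
            elif start is not None:
                out.append((start + 1, i))
                start = None
        if start is not None:
            out.append((start + 1, len(self.target_at_ref)))
        return out

    def reconstructed_cds(self) -> str:
        """Target CDS projected into the reference frame.

        Reference-length string: aligned bases as-is, internal deletions
        as ``-``, uncovered stretches as ``?`` (frameshift insertions are
        omitted, restoring the reference frame)."""
        return "".join("?" if b == _UNCOVERED else b for b in self.target_at_ref)


def map_reference_cds(
    reference: ReferenceGene,
    region: GenomicLocus,
    min_coverage: float = 0.2,
) -> MappedAlignment:
    """Map the UTR-flanked reference gene onto a region, better strand wins.

    Affine local alignment so that non-homologous flanks, truncation
    junk and fragmented ends are clipped rather than force-aligned; N in
    the region matches any base at zero score.  Raises
    :class:`NoOrthologDetected` when the aligned span covers less than
    ``min_coverage`` of the reference CDS.
    """
    if not region.seq:
        raise AnnotationError("empty region")
    query = reference.full_query
    best = None
    for strand in "+-":
        target = region.seq.upper() if strand == "+" else revcomp(region.seq.upper())
        try:
            aln = _MAPPER.align(target, query)[0]
        except (IndexError, ValueError):
            continue
        if best is None or aln.score > best[0].score:
            best = (aln, strand, target)
    if best is None:
        raise NoOrthologDetected("no local alignment found: no ortholog detected")
    aln, strand, target = best
    tgt_gapped, ref_gapped = str(aln[0]), str(aln[1])
    mapped = MappedAlignment(
        reference=reference,
        region=region,
        strand_used=strand,
        ref_aln=ref_gapped,
        tgt_aln=tgt_gapped,
        target_seq=target,
        score=float(aln.score),
    )
    _project_cds(mapped, ref_start=int(aln.coordinates[1, 0]), tgt_start=int(aln.coordinates[0, 0]))
    if mapped.coverage < min_coverage:
        raise NoOrthologDetected(
            f"aligned span covers {mapped.coverage:.2f} of the reference CDS "
            f"(< {min_coverage}): no ortholog detected"
        )
    return mapped


def _project_cds(m: MappedAlignment, ref_start: int = 0, tgt_start: int = 0) -> None:
    """Fill per-reference-CDS-position projections from the gapped pair.

    ``ref_start`` / ``tgt_start`` are the ungapped offsets of the local
    alignment on the full query and oriented target; reference CDS
    positions outside the aligned span stay uncovered.
    """
    ref, tgt = m.ref_aln, m.tgt_aln
    cds_lo = len(m.reference.utr5)
    cds_hi = cds_lo + len(m.reference.cds)

    target_at_ref = [_UNCOVERED] * len(m.reference.cds)
    coord_at_ref = [-1] * len(m.reference.cds)
    insertions: list[tuple[int, str, int]] = []
    rp = ref_start  # position on the full query
    tp = tgt_start  # position on the oriented target
    pending_ins: list[str] = []
    pending_coord = -1
    for rb, tb in zip(ref, tgt):
        if rb != "-" and pending_ins:
            p0 = rp - cds_lo
            if 0 < p0 < len(m.reference.cds):
                insertions.append((p0, "".join(pending_ins), pending_coord))
            pending_ins = []
        if rb != "-" and tb != "-":
            if cds_lo <= rp < cds_hi:
                target_at_ref[rp - cds_lo] = tb.upper()
                coord_at_ref[rp - cds_lo] = tp
            rp += 1
            tp += 1
        elif rb != "-":  # target gap: deletion inside the aligned span
            if cds_lo <= rp < cds_hi:
                target_at_ref[rp - cds_lo] = "-"
            rp += 1
        elif tb != "-":  # reference gap: insertion in target
            if not pending_ins:
                pending_coord = tp
            pending_ins.append(tb.upper())
            tp += 1
    m.target_at_ref = target_at_ref
    m.region_coord_at_ref = coord_at_ref
    m.insertions = insertions


# ----------------------------------------------------------------------
# mutation calling
# ----------------------------------------------------------------------

def call_inactivating_mutations(
    aln: MappedAlignment, min_coverage: float = 0.2
) -> list[InactivatingMutation]:
    """Call frameshift indels and in-frame premature stops.

    Indels with length not divisible by 3 inside the CDS are emitted as
    frameshifts (left-normalized coordinates).  Stops are read on
    reference-frame codons of the reconstructed target — the frame
    obtained once the reported frameshift columns are removed — so gap,
    N and uncovered columns never produce stop calls.  Frameshift runs
    whose running net offset returns to zero are flagged compensated
    but still reported.
    """
    if aln.coverage < min_coverage:
        raise AnnotationError(
            f"alignment covers {aln.coverage:.2f} < {min_coverage} of the reference CDS"
        )
    ref_cds = aln.reference.cds
    n_codons = aln.reference.n_codons
    muts: list[InactivatingMutation] = []

    # deletions: maximal '-' runs in the reference projection
    i = 0
    L = len(aln.target_at_ref)
    while i < L:
        if aln.target_at_ref[i] == "-":
            j = i
            while j < L and aln.target_at_ref[j] == "-":
                j += 1
            run = j - i
            if run % 3:
                norm = left_normalize_deletion(ref_cds, i, run)
                after = next(
                    (aln.region_coord_at_ref[k] for k in range(j, L) if aln.region_coord_at_ref[k] >= 0),
                    -1,
                )
                muts.append(
                    InactivatingMutation(
                        kind="frameshift_deletion",
                        ref_coord=norm + 1,
                        length_nt=run,
                        region_coord=after,
                        ref_allele=ref_cds[norm : norm + run],
                        alt_allele="",
                    )
                )
            i = j
        else:
            i += 1

    # insertions
    for p0, ins, coord in aln.insertions:
        if len(ins) % 3 == 0:
            continue
        norm_pos, norm_ins = left_normalize_insertion(ref_cds, p0, ins)
        shift = p0 - norm_pos
        muts.append(
            InactivatingMutation(
                kind="frameshift_insertion",
                ref_coord=norm_pos,
                length_nt=len(ins),
                region_coord=max(coord - shift, 0),
                ref_allele="",
                alt_allele=norm_ins,
            )
        )

    # premature stops on reference-frame codons
    for k in range(n_codons - 1):  # terminal reference codon never premature
        cod = "".join(aln.target_at_ref[3 * k : 3 * k + 3])
        if any(b not in "ACGT" for b in cod):
            continue
        if cod in STOP_CODONS:
            muts.append(
                InactivatingMutation(
                    kind="premature_stop",
                    ref_coord=3 * k + 1,
                    codon_index=k + 1,
                    orf_fraction=(k + 1) / n_codons,
                    region_coord=aln.region_coord_at_ref[3 * k],
                    ref_allele=ref_cds[3 * k : 3 * k + 3],
                    alt_allele=cod,
                )
            )

    muts.sort(key=lambda m: m.ref_coord)

    # compensated-frameshift flagging: net offset returning to 0 (mod 3)
    net = 0
    group: list[InactivatingMutation] = []
    for m in muts:
        if m.kind == "frameshift_insertion":
            net += m.length_nt
        elif m.kind == "frameshift_deletion":
            net -= m.length_nt
        else:
            continue
        group.append(m)
        if net % 3 == 0 and len(group) > 1:
            for g in group:
                g.compensated = True
            group, net = [], 0
    return muts


# ----------------------------------------------------------------------
# truncation detection
# ----------------------------------------------------------------------

@dataclass
class TruncationCall:
    """Abrupt identity-collapse breakpoint (1-based reference CDS coord)."""

    ref_coord: int
    inconclusive: bool = False
    high_identity: float = 0.0
    low_identity: float = 0.0

    def as_mutation(self) -> InactivatingMutation:
        return InactivatingMutation(kind="truncation", ref_coord=self.ref_coord)


def detect_truncation(
    aln: MappedAlignment,
    window_nt: int = 60,
    step_nt: int = 15,
    high_thr: float = 70.0,
    low_thr: float = 30.0,
) -> TruncationCall | None:
    """Sliding-window identity over the reference CDS; a truncation is
    the first >=high to <low transition sustained for two windows.

    Windows dominated by N are not evidence of sequence divergence:
    if the low windows are mostly N the call is flagged inconclusive.
    """
    if window_nt < 30:
        raise AnnotationError("window_nt must be >= 30")
    ref_cds = aln.reference.cds
    L = len(ref_cds)
    if L < window_nt:
        logger.warning("alignment shorter than one window; truncation scan skipped")
        return None
    match = np.zeros(L)
    is_n = np.zeros(L)
    for i, b in enumerate(aln.target_at_ref):
        if b == "N":
            is_n[i] = 1
        elif b in "ACGT" and b == ref_cds[i]:
            match[i] = 1
    starts = list(range(0, L - window_nt + 1, step_nt))
    ident = np.array([100.0 * match[s : s + window_nt].mean() for s in starts])
    nfrac = np.array([is_n[s : s + window_nt].mean() for s in starts])
    # first sustained low stretch (two consecutive windows)
    low_idx = next(
        (w for w in range(len(starts) - 1) if ident[w] < low_thr and ident[w + 1] < low_thr),
        None,
    )
    if low_idx is None:
        return None
    # abrupt collapse: high identity before, never recovering after
    if not (ident[:low_idx] >= high_thr).any() or (ident[low_idx:] >= high_thr).any():
        return None
    masked = bool(nfrac[low_idx] > 0.5 and nfrac[low_idx + 1] > 0.5)
    # the unaligned region tail: if it is mostly N, a low-identity end
    # reflects an assembly gap, not diverged sequence
    last_coord = max((c for c in aln.region_coord_at_ref if c >= 0), default=-1)
    tail = aln.target_seq[last_coord + 1 :] if last_coord >= 0 else ""
    tail_is_n = bool(tail) and tail.upper().count("N") / len(tail) > 0.5
    span = range(starts[low_idx], min(starts[low_idx + 1] + window_nt, L))
    covered = [aln.target_at_ref[i] != _UNCOVERED for i in span]
    uncovered_gap = tail_is_n and sum(covered) / len(covered) < 0.5
    return TruncationCall(
        ref_coord=starts[low_idx] + 1,
        inconclusive=masked or uncovered_gap,
        high_identity=float(ident[:low_idx].max()),
        low_identity=float(ident[low_idx]),
    )


# ----------------------------------------------------------------------
# coding status
# ----------------------------------------------------------------------

def classify_coding_status(
    mutations: list[InactivatingMutation],
    aln: MappedAlignment,
    min_unambiguous_coverage: float = 0.9,
) -> str:
    """intact / eroded / inconclusive.

    Inconclusive when too little of the reference CDS aligns to real
    (non-N) sequence — the fragmented-assembly case; otherwise eroded
    as soon as one lesion is present.  A truncation call is positive
    evidence (the lost span is replaced by unrelated sequence, not by
    missing data — N-masked drops are never reported as truncations),
    so it yields eroded even though it also depresses coverage.
    """
    if any(m.kind == "truncation" for m in mutations):
        return ERODED
    if aln.unambiguous_coverage < min_unambiguous_coverage:
        return INCONCLUSIVE
    return ERODED if mutations else INTACT


# ----------------------------------------------------------------------
# translation alignment
# ----------------------------------------------------------------------

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _aa_score(a: str, b: str) -> float:
    if a == "-" or b == "-":
        return 0.0
    try:
        return float(_BLOSUM62[a, b])
    except (KeyError, IndexError):
        return 0.0


def _codon_units(taxon: str, seq: str) -> list[str]:
    if len(seq) % 3:
        raise AnnotationError(
            f"sequence for {taxon!r} is not reducible to frame-consistent triplets "
            f"(length {len(seq)})"
        )
    units = []
    for cod in codons_of(seq.upper()):
        if any(b not in "ACGT" for b in cod) or cod in STOP_CODONS:
            units.append("???")  # gaps, Ns and stops recorded as missing
        else:
            units.append(cod)
    return units


def _protein(units: list[str]) -> str:
    return "".join("X" if u == "???" else translate(u) for u in units)


def _pairwise_pdist(p1: str, p2: str) -> float:
    al = Align.PairwiseAligner()
    al.substitution_matrix = _BLOSUM62
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    al.mode = "global"
    a = al.align(p1.replace("*", "X"), p2.replace("*", "X"))[0]
    s1, s2 = str(a[0]), str(a[1])
    same = sum(1 for x, y in zip(s1, s2) if x == y and x != "-")
    cols = sum(1 for x, y in zip(s1, s2) if x != "-" and y != "-")
    return 1.0 - same / cols if cols else 1.0


def _nj_merge_order(names: list[str], D: np.ndarray) -> list[tuple]:
    """Neighbor-joining guide topology as nested tuples of indices."""
    active = {i: (i,) for i in range(len(names))}
    D = D.copy().astype(float)
    idx = list(range(len(names)))
    while len(idx) > 2:
        n = len(idx)
        r = {i: sum(D[i, j] for j in idx if j != i) for i in idx}
        best, bi, bj = None, None, None
        for a in range(n):
            for b in range(a + 1, n):
                i, j = idx[a], idx[b]
                q = (n - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best - 1e-12:
                    best, bi, bj = q, i, j
        new = max(active) + 1
        node = (active[bi], active[bj])
        D = np.pad(D, ((0, new + 1 - D.shape[0]), (0, new + 1 - D.shape[1])))
        for k in idx:
            if k in (bi, bj):
                continue
            D[new, k] = D[k, new] = 0.5 * (D[bi, k] + D[bj, k] - D[bi, bj])
        idx = [k for k in idx if k not in (bi, bj)] + [new]
        active[new] = node
        del active[bi], active[bj]
    if len(idx) == 2:
        return [(active[idx[0]], active[idx[1]])]
    return [active[idx[0]]]


def _flatten(node) -> list[int]:
    if isinstance(node, tuple) and len(node) == 1:
        return [node[0]]
    if isinstance(node, int):
        return [node]
    out = []
    for child in node:
        out.extend(_flatten(child))
    return out


def _profile_align(
    prof1: list[list[str]], prof2: list[list[str]], gap_open: float = -11.0, gap_ext: float = -1.0
) -> tuple[list[list[str]], list[list[str]]]:
    """Affine-gap profile-profile alignment of codon-unit rows.

    Column score is the mean pairwise BLOSUM62 score of the translated
    residues across the two profiles.
    """
    a1 = ["".join("X" if u == "???" else translate(u) if u != "---" else "-" for u in row) for row in prof1]
    a2 = ["".join("X" if u == "???" else translate(u) if u != "---" else "-" for u in row) for row in prof2]
    n, m = len(a1[0]), len(a2[0])
    col1 = [[s[i] for s in a1] for i in range(n)]
    col2 = [[s[j] for s in a2] for j in range(m)]
    S = np.zeros((n, m))
    for i in range(n):
        for j in range(m):
            S[i, j] = np.mean([_aa_score(x, y) for x in col1[i] for y in col2[j]])
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in prof2 (consume prof1)
    Y = np.full((n + 1, m + 1), NEG)  # gap in prof1
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_ext
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_ext
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + S[i - 1, j - 1]
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_ext)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_ext)
    # traceback
    i, j = n, m
    state = int(np.argmax([M[n, m], X[n, m], Y[n, m]]))
    path: list[str] = []
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            path.append("M")
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            state = int(np.argmax(prev))
            i, j = i - 1, j - 1
        elif state == 1 and i > 0:
            path.append("X")
            state = 0 if M[i - 1, j] + gap_open >= X[i - 1, j] + gap_ext else 1
            i -= 1
        elif state == 2 and j > 0:
            path.append("Y")
            state = 0 if M[i, j - 1] + gap_open >= Y[i, j - 1] + gap_ext else 2
            j -= 1
        elif i > 0:
            path.append("X")
            i -= 1
        else:
            path.append("Y")
            j -= 1
    path.reverse()
    out1 = [[] for _ in prof1]
    out2 = [[] for _ in prof2]
    i = j = 0
    for op in path:
        if op == "M":
            for r, row in enumerate(prof1):
                out1[r].append(row[i])
            for r, row in enumerate(prof2):
                out2[r].append(row[j])
            i += 1
            j += 1
        elif op == "X":
            for r, row in enumerate(prof1):
                out1[r].append(row[i])
            for r in range(len(prof2)):
                out2[r].append("---")
            i += 1
        else:
            for r in range(len(prof1)):
                out1[r].append("---")
            for r, row in enumerate(prof2):
                out2[r].append(row[j])
            j += 1
    return out1, out2


def translation_align(cds_map: dict[str, str]) -> CodonAlignment:
    """Codon-aware multiple alignment via progressive protein alignment.

    Inputs are frame-consistent CDS strings (frameshift indels already
    omitted; ``-``/``?``/N allowed and treated, like stop codons, as the
    missing codon ``???``).  Proteins are aligned progressively under
    BLOSUM62 along a neighbor-joining guide tree built from pairwise
    p-distances, then back-threaded to codons (protein gap -> ``---``).
    """
    taxa = list(cds_map)
    if not taxa:
        raise AnnotationError("empty input")
    units = {t: _codon_units(t, cds_map[t]) for t in taxa}
    if len(taxa) == 1:
        t = taxa[0]
        return CodonAlignment([t], ["".join(units[t])])
    prots = {t: _protein(units[t]) for t in taxa}
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _pairwise_pdist(prots[taxa[i]], prots[taxa[j]])
    order = _nj_merge_order(taxa, D)

    def build(node) -> tuple[list[int], list[list[str]]]:
        if isinstance(node, tuple) and len(node) == 1 and isinstance(node[0], int):
            i = node[0]
            return [i], [list(units[taxa[i]])]
        if isinstance(node, int):
            return [node], [list(units[taxa[node]])]
        (li, lp) = build(node[0])
        (ri, rp) = build(node[1])
        ap, bp = _profile_align(lp, rp)
        return li + ri, ap + bp

    root = order[0]
    idxs, rows = build(root)
    out_taxa = [taxa[i] for i in idxs]
    seqs = ["".join(row) for row in rows]
    # keep input order
    reorder = sorted(range(len(out_taxa)), key=lambda k: taxa.index(out_taxa[k]))
    return CodonAlignment([out_taxa[k] for k in reorder], [seqs[k] for k in reorder])


def annotation_gff3(
    alns: dict[str, MappedAlignment],
    muts_by_taxon: dict[str, list[InactivatingMutation]],
    path: str | Path,
) -> None:
    """GFF3 of reconstructed CDS spans and called lesions, 1-based on
    each taxon's oriented region sequence."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for taxon in sorted(alns):
            aln = alns[taxon]
            coords = [c for c in aln.region_coord_at_ref if c >= 0]
            if not coords:
                continue
            strand = aln.strand_used
            fh.write(
                f"{taxon}\tortholoss\tCDS\t{min(coords) + 1}\t{max(coords) + 1}\t.\t{strand}\t0\t"
                f"ID={taxon}_cds;reference={aln.reference.name};"
                f"coverage={aln.coverage:.3f}\n"
            )
            for i, m in enumerate(muts_by_taxon.get(taxon, [])):
                if m.region_coord < 0:
                    continue
                end = m.region_coord + max(len(m.alt_allele), 1)
                fh.write(
                    f"{taxon}\tortholoss\tsequence_alteration\t{m.region_coord + 1}\t{end}\t.\t{strand}\t.\t"
                    f"ID={taxon}_mut{i + 1};kind={m.kind};ref_coord={m.ref_coord}\n"
                )


def mutation_table(muts_by_taxon: dict[str, list[InactivatingMutation]], path: str | Path) -> None:
    """TSV report: taxon, kind, ref_coord, length_nt, codon_index,
    orf_fraction, compensated, validation status."""
    with open(path, "w") as fh:
        fh.write(
            "taxon\tkind\tref_coord\tlength_nt\tcodon_index\torf_fraction\t"
            "compensated\tread_validation_status\n"
        )
        for taxon, muts in muts_by_taxon.items():
            for m in muts:
                fh.write(
                    f"{taxon}\t{m.kind}\t{m.ref_coord}\t{m.length_nt}\t{m.codon_index}\t"
                    f"{m.orf_fraction:.4f}\t{int(m.compensated)}\t{m.read_validation_status or '.'}\n"
                )
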