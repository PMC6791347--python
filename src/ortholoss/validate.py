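"""Validation of called mutations against raw sequencing reads.

Each read is scored against two haplotype sequences — the region as
assembled (carrying the mutation) and the same region with the mutation
reverted to the reference allele.  A read is informative if it spans
the mutation site with enough anchor on each side and aligns strictly
better (lower edit distance) to one haplotype.  The support fraction
over informative reads yields confirmed / refuted / polymorphic /
no_data verdicts; the ~50% split of a segregating loss allele lands in
the polymorphic band.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import edlib

from .annotate import InactivatingMutation, MappedAlignment
from .codons import revcomp
from .simulate import SimRead


class ValidationError(ValueError):
    pass


CONFIRMED = "confirmed"
REFUTED = "refuted"
POLYMORPHIC = "polymorphic"
NO_DATA = "no_data"
CONFLICT = "conflict"


@dataclass
class ValidationVerdict:
    mutation: InactivatingMutation
    n_support: int
    n_contradict: int
    verdict: str

    @property
    def support_fraction(self) -> float:
        tot = self.n_support + self.n_contradict
        return self.n_support / tot if tot else float("nan")


def _haplotypes(mutation: InactivatingMutation, region_seq: str) -> tuple[str, str, int, int]:
    """(mutant, wildtype, site_start, site_end_on_wild) around the call.

    The assembled region carries the mutant allele at
    ``region_coord``; reverting substitutes the reference allele.
    """
    rc = mutation.region_coord
    if rc < 0 or rc > len(region_seq):
        raise ValidationError(
            f"mutation region coordinate {rc} outside region of length {len(region_seq)}"
        )
    alt, ref = mutation.alt_allele, mutation.ref_allele
    if region_seq[rc : rc + len(alt)].upper() != alt.upper():
        raise ValidationError(
            f"region does not carry the expected mutant allele at {rc} "
            f"({region_seq[rc : rc + len(alt)]!r} != {alt!r})"
        )
    wild = region_seq[:rc] + ref + region_seq[rc + len(alt) :]
    return region_seq, wild, rc, rc + max(len(alt), len(ref))


def _read_span_distance(read: str, hap: str, lo: int, hi: int) -> tuple[int, bool]:
    """Best edit distance of the read on the haplotype, and whether the
    best placement spans [lo, hi)."""
    best = None
    spans = False
    for r in (read, revcomp(read)):
        res = edlib.align(r, hap, mode="HW", task="locations")
        d = res["editDistance"]
        if d < 0:
            continue
        if best is None or d < best:
            best = d
            spans = any(s <= lo and e + 1 >= hi for s, e in res["locations"])
        elif d == best and not spans:
            spans = spans or any(s <= lo and e + 1 >= hi for s, e in res["locations"])
    return (best if best is not None else 10**9), spans


def validate_mutation(
    mutation: InactivatingMutation,
    region: str | MappedAlignment,
    reads: list[SimRead],
    flank_nt: int = 30,
    min_reads: int = 3,
    conf_thr: float = 0.8,
) -> ValidationVerdict:
    """Score reads against the mutant and reverted haplotype windows.

    A read is informative if it covers the mutation with at least
    ``flank_nt / 2`` anchored on each side and scores strictly better
    on one haplotype.  Verdicts: fewer than ``min_reads`` informative
    reads -> no_data; support fraction >= ``conf_thr`` -> confirmed;
    <= 1 - ``conf_thr`` -> refuted; otherwise polymorphic.
    """
    if flank_nt < 10:
        raise ValidationError("flank_nt must be >= 10")
    region_seq = region.target_seq if isinstance(region, MappedAlignment) else region
    region_seq = region_seq.upper()
    mut_hap, wild_hap, lo, _ = _haplotypes(mutation, region_seq)
    anchor = flank_nt // 2
    mut_hi = lo + len(mutation.alt_allele)
    wild_hi = lo + len(mutation.ref_allele)
    n_support = n_contradict = 0
    for read in reads:
        seq = read.seq.upper() if isinstance(read, SimRead) else str(read).upper()
        d_mut, span_mut = _read_span_distance(seq, mut_hap, lo - anchor, mut_hi + anchor)
        d_wild, span_wild = _read_span_distance(seq, wild_hap, lo - anchor, wild_hi + anchor)
        if d_mut < d_wild and span_mut:
            n_support += 1
        elif d_wild < d_mut and span_wild:
            n_contradict += 1
    total = n_support + n_contradict
    if total < min_reads:
        verdict = NO_DATA
    else:
        frac = n_support / total
        if frac >= conf_thr:
            verdict = CONFIRMED
        elif frac <= 1.0 - conf_thr:
            verdict = REFUTED
        else:
            verdict = POLYMORPHIC
    return ValidationVerdict(mutation, n_support, n_contradict, verdict)


@dataclass
class ConsensusVerdict:
    mutation: InactivatingMutation
    per_set: dict[str, ValidationVerdict]
    consensus: str


def validate_all(
    mutations: list[InactivatingMutation],
    region: str | MappedAlignment,
    read_sets: dict[str, list[SimRead]],
    **kwargs,
) -> list[ConsensusVerdict]:
    """Per-read-set verdicts plus a consensus for each mutation.

    Consensus: confirmed only if no set refutes and at least one
    confirms; a confirm/refute disagreement is flagged as conflict;
    any polymorphic set makes the consensus polymorphic.
    """
    if not read_sets:
        raise ValidationError("at least one read set is required")
    out: list[ConsensusVerdict] = []
    for mut in mutations:
        per = {name: validate_mutation(mut, region, reads, **kwargs) for name, reads in read_sets.items()}
        verdicts = {v.verdict for v in per.values()}
        if CONFIRMED in verdicts and REFUTED in verdicts:
            consensus = CONFLICT
        elif POLYMORPHIC in verdicts:
            consensus = POLYMORPHIC
        elif CONFIRMED in verdicts:
            consensus = CONFIRMED
        elif REFUTED in verdicts:
            consensus = REFUTED
        else:
            consensus = NO_DATA
        mut.read_validation_status = consensus
        out.append(ConsensusVerdict(mut, per, consensus))
    return out


def verdict_table(verdicts: list[ConsensusVerdict], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tref_coord\tset\tn_support\tn_contradict\tsupport_fraction\tverdict\n")
        for cv in verdicts:
            for name, v in cv.per_set.items():
                frac = f"{v.support_fraction:.3f}" if v.n_support + v.n_contradict else "."
                fh.write(
                    f"{cv.mutation.kind}\t{cv.mutation.ref_coord}\t{name}\t"
                    f"{v.n_support}\t{v.n_contradict}\t{frac}\t{v.verdict}\n"
                )
            fh.write(
                f"{cv.mutation.kind}\t{cv.mutation.ref_coord}\tconsensus\t.\t.\t.\t{cv.consensus}\n"
            )
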