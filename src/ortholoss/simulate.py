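"""Synthetic loci with known ground truth.

Generates everything the analysis consumes — coding sequences evolved
on a tree under the GY94 process with per-branch-category omega,
lineage-specific inactivating lesions (short frameshift indels,
nonsense substitutions), anchored genomic loci with assembly gaps, and
sequencing reads drawn from one or a mixture of alleles — together with
truth records so every downstream stage can be checked exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import CodonAlignment
from .codons import CODON_INDEX, N_STATES, SENSE_CODONS, STOP_CODONS, revcomp
from .codonmodel import TransitionKernel
from .locus import GenomicLocus
from .trees import BACKGROUND, LabeledTree
from .variants import left_normalize_deletion, left_normalize_insertion


class SimulationError(ValueError):
    pass


# ----------------------------------------------------------------------
# CDS evolution under GY94
# ----------------------------------------------------------------------

@dataclass
class EvolutionSpec:
    """Conditions for evolving a coding sequence down a tree.

    Branch lengths are expected substitutions per codon.  ``omega`` maps
    branch-category labels (``#tag`` in the Newick) to dN/dS; untagged
    branches use the background category.  ``codon_freqs`` defaults to
    uniform over the 61 sense codons.
    """

    tree: LabeledTree | str
    omega: dict[str, float]
    kappa: float
    root_cds: str
    seed: int
    codon_freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if isinstance(self.tree, str):
            self.tree = LabeledTree.from_newick(self.tree)
        if self.codon_freqs is None:
            self.codon_freqs = np.full(N_STATES, 1.0 / N_STATES)
        self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
        if abs(self.codon_freqs.sum() - 1.0) > 1e-12:
            raise SimulationError("codon_freqs must sum to 1")
        if self.kappa <= 0:
            raise SimulationError("kappa must be positive")
        if any(w < 0 for w in self.omega.values()):
            raise SimulationError("omega must be nonnegative")
        if len(self.root_cds) % 3:
            raise SimulationError("root_cds length must be divisible by 3")
        if any(
            self.root_cds[i : i + 3].upper() in STOP_CODONS
            for i in range(0, len(self.root_cds), 3)
        ):
            raise SimulationError("root_cds contains an internal stop codon")


def simulate_cds_evolution(spec: EvolutionSpec) -> tuple[dict[str, str], CodonAlignment]:
    """Evolve ``root_cds`` over the tree; returns leaf CDSs and the true
    (indel-free, hence trivially columnar) codon alignment.

    Each branch uses the exact transition matrix ``expm(Q * t)`` of its
    category's scaled GY94 generator; sites are independent.
    """
    tree: LabeledTree = spec.tree  # type: ignore[assignment]
    if len(tree.taxa) < 2:
        raise SimulationError("tree must have at least 2 leaves")
    rng = np.random.default_rng(spec.seed)
    root_states = np.array([CODON_INDEX[spec.root_cds[i : i + 3].upper()] for i in range(0, len(spec.root_cds), 3)])

    kernels: dict[str, TransitionKernel] = {}

    def kernel(cat: str) -> TransitionKernel:
        if cat not in kernels:
            if cat not in spec.omega:
                raise SimulationError(f"no omega for branch category {cat!r}")
            kernels[cat] = TransitionKernel(spec.kappa, spec.omega[cat], spec.codon_freqs)
        return kernels[cat]

    leaf_seqs: dict[str, str] = {}
    states_at = {id(tree.tree.seed_node): root_states}
    for nd in tree.tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        t = nd.edge.length if nd.edge.length is not None else 0.0
        parent_states = states_at[id(nd.parent_node)]
        if t <= 0:
            child = parent_states.copy()
        else:
            P = kernel(getattr(nd.edge, "category", BACKGROUND)).probs(t)
            cum = np.cumsum(P, axis=1)
            u = rng.random(len(parent_states))
            child = np.array(
                [
                    int(np.searchsorted(cum[s], uu * cum[s, -1], side="right"))
                    for s, uu in zip(parent_states, u)
                ]
            )
            np.clip(child, 0, N_STATES - 1, out=child)
        states_at[id(nd)] = child
        if nd.is_leaf():
            leaf_seqs[nd.taxon.label] = "".join(SENSE_CODONS[s] for s in child)
    taxa = list(leaf_seqs)
    aln = CodonAlignment(taxa, [leaf_seqs[t] for t in taxa])
    return leaf_seqs, aln


# ----------------------------------------------------------------------
# lesion injection
# ----------------------------------------------------------------------

@dataclass
class LesionSpec:
    """A planned inactivating lesion.

    ``position_frac`` locates the lesion as a fraction of CDS length;
    indels carry ``length_nt`` (1 or 2 by default — the sizes seen in
    eroded loci), nonsense lesions do not.
    """

    kind: str  # deletion | insertion | nonsense
    position_frac: float
    length_nt: int | None = None
    branch: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "insertion", "nonsense"):
            raise SimulationError(f"unknown lesion kind {self.kind!r}")
        if not 0.0 <= self.position_frac <= 1.0:
            raise SimulationError("position_frac must be in [0, 1]")
        if self.kind == "nonsense":
            if self.length_nt is not None:
                raise SimulationError("nonsense lesions carry no length_nt")
        else:
            if self.length_nt is None or self.length_nt < 1:
                raise SimulationError("indel lesions need positive length_nt")


@dataclass
class TruthLesion:
    """Ground-truth record of one injected lesion (reference-CDS coords).

    ``ref_coord`` is 1-based: first deleted base for deletions, the base
    immediately 5' of the insertion point for insertions, first base of
    the stop codon for nonsense.  Indel coordinates are left-normalized.
    """

    kind: str  # frameshift_deletion | frameshift_insertion | premature_stop
    ref_coord: int
    length_nt: int = 0
    codon_index: int = 0
    inserted: str = ""


def _nearest_stop(codon: str) -> str:
    best, best_d = None, 4
    for stop in STOP_CODONS:  # TAA first: deterministic tie-break
        d = sum(a != b for a, b in zip(codon, stop))
        if d < best_d:
            best, best_d = stop, d
    return best


def inject_lesions(
    cds: str, lesions: list[LesionSpec], seed: int = 0
) -> tuple[str, list[TruthLesion]]:
    """Apply lesions left-to-right with coordinate bookkeeping.

    Nonsense lesions substitute the fewest nucleotides turning the codon
    at ``floor(position_frac * n_codons)`` into a stop (ties -> TAA).
    Overlapping lesions are rejected.
    """
    rng = np.random.default_rng(seed)
    n = len(cds)
    n_codons = n // 3
    # deletion occupies [pos, pos+len); a nonsense lesion its codon;
    # an insertion is a point event at pos (width 1 for overlap checks)
    placed: list[tuple[int, int, LesionSpec]] = []
    for les in lesions:
        if les.kind == "nonsense":
            ci = min(int(les.position_frac * n_codons), n_codons - 1)
            placed.append((3 * ci, 3 * ci + 3, les))
        elif les.kind == "deletion":
            pos = min(int(les.position_frac * n), n - les.length_nt)
            placed.append((pos, pos + les.length_nt, les))
        else:
            pos = min(int(les.position_frac * n), n)
            placed.append((pos, pos + 1, les))
    placed.sort(key=lambda x: (x[0], x[1]))
    for (s1, e1, _), (s2, e2, _) in zip(placed, placed[1:]):
        if s2 < e1:
            raise SimulationError(f"overlapping lesions at {s1} and {s2}")

    out = cds
    offset = 0
    truths: list[TruthLesion] = []
    for start, _end, les in placed:
        if les.kind == "deletion":
            out = out[: start + offset] + out[start + offset + les.length_nt :]
            norm = left_normalize_deletion(cds, start, les.length_nt)
            truths.append(
                TruthLesion("frameshift_deletion", norm + 1, length_nt=les.length_nt)
            )
            offset -= les.length_nt
        elif les.kind == "insertion":
            ins = "".join(rng.choice(list("ACGT"), size=les.length_nt))
            out = out[: start + offset] + ins + out[start + offset :]
            norm_pos, norm_ins = left_normalize_insertion(cds, start, ins)
            truths.append(
                TruthLesion(
                    "frameshift_insertion", norm_pos, length_nt=les.length_nt, inserted=norm_ins
                )
            )
            offset += les.length_nt
        else:
            ci = start // 3
            codon = cds[start : start + 3]
            stop = _nearest_stop(codon.upper())
            out = out[: start + offset] + stop + out[start + offset + 3 :]
            truths.append(
                TruthLesion("premature_stop", start + 1, codon_index=ci + 1)
            )
    truths.sort(key=lambda t: t.ref_coord)
    return out, truths


# ----------------------------------------------------------------------
# locus assembly
# ----------------------------------------------------------------------

@dataclass
class LocusTruth:
    """Everything known by construction about a synthetic locus."""

    taxon: str
    cds: str
    cds_interval: tuple[int, int]  # 0-based half-open, in final locus coords
    strand: str
    lesions: list[TruthLesion] = field(default_factory=list)
    flank_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)
    n_run_intervals: list[tuple[int, int]] = field(default_factory=list)


def _random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=length)) if length > 0 else ""


def build_locus(
    cds: str,
    flank_genes_up: list[tuple[str, str]] | None = None,
    flank_genes_down: list[tuple[str, str]] | None = None,
    intergenic_length: int = 300,
    n_runs: list[tuple[int, int]] | None = None,
    strand: str = "+",
    fragment_cds: bool = False,
    taxon: str = "taxon",
    lesions: list[TruthLesion] | None = None,
    utr5: str = "",
    utr3: str = "",
    seed: int = 0,
) -> tuple[GenomicLocus, LocusTruth]:
    """Assemble a contiguous locus: upstream flank genes, intergenic
    spacers, the UTR-flanked CDS, then downstream flank genes.

    ``utr5``/``utr3`` sit immediately adjacent to the CDS (homologous
    UTRs anchor reference mapping across the CDS boundaries).  ``n_runs``
    are 0-based half-open intervals in plus-strand locus coordinates
    masked to N; overlapping the CDS is an error unless ``fragment_cds``
    is set (emulating 5'/3' assembly gaps).  With ``strand='-'`` the
    stored sequence is the reverse complement of the plus-strand
    construction and truth coordinates are flipped.
    """
    rng = np.random.default_rng(seed)
    flank_genes_up = flank_genes_up or []
    flank_genes_down = flank_genes_down or []
    parts: list[str] = []
    flank_intervals: dict[str, tuple[int, int]] = {}
    pos = 0

    def push(segment: str, name: str | None = None) -> None:
        nonlocal pos
        if name is not None:
            flank_intervals[name] = (pos, pos + len(segment))
        parts.append(segment)
        pos += len(segment)

    for name, seq in flank_genes_up:
        push(seq, name)
        push(_random_dna(intergenic_length, rng))
    push(utr5)
    cds_start = pos
    push(cds)
    cds_end = pos
    push(utr3)
    for name, seq in flank_genes_down:
        push(_random_dna(intergenic_length, rng))
        push(seq, name)
    plus = "".join(parts)

    applied_runs: list[tuple[int, int]] = []
    if n_runs:
        chars = list(plus)
        for a, b in n_runs:
            a, b = max(0, a), min(len(plus), b)
            if a >= b:
                continue
            if not fragment_cds and a < cds_end and b > cds_start:
                raise SimulationError(
                    f"N-run ({a},{b}) overlaps the CDS and fragment_cds is off"
                )
            chars[a:b] = "N" * (b - a)
            applied_runs.append((a, b))
        plus = "".join(chars)

    L = len(plus)
    if strand == "-":
        seq = revcomp(plus)
        flip = lambda iv: (L - iv[1], L - iv[0])
        truth = LocusTruth(
            taxon=taxon,
            cds=cds,
            cds_interval=flip((cds_start, cds_end)),
            strand="-",
            lesions=list(lesions or []),
            flank_intervals={k: flip(v) for k, v in flank_intervals.items()},
            n_run_intervals=[flip(iv) for iv in applied_runs],
        )
    else:
        seq = plus
        truth = LocusTruth(
            taxon=taxon,
            cds=cds,
            cds_interval=(cds_start, cds_end),
            strand="+",
            lesions=list(lesions or []),
            flank_intervals=flank_intervals,
            n_run_intervals=applied_runs,
        )
    locus = GenomicLocus(name=f"{taxon}_locus", seq=seq, contig=f"{taxon}_contig", strand="+")
    return locus, truth


# ----------------------------------------------------------------------
# reads
# ----------------------------------------------------------------------

@dataclass
class SimRead:
    name: str
    seq: str

    @property
    def qual(self) -> str:
        return "I" * len(self.seq)


def simulate_reads(
    alleles: dict[str, str] | str | GenomicLocus,
    depth: float,
    read_len: int,
    error_rate: float = 0.0,
    allele_mix: dict[str, float] | None = None,
    seed: int = 0,
) -> list[SimRead]:
    """Uniform-start single-end reads from one allele or a mixture.

    ``depth`` is the target mean per-base coverage.  Substitution errors
    are applied per base at ``error_rate``; no indel errors.
    """
    if isinstance(alleles, GenomicLocus):
        alleles = {"allele0": alleles.seq}
    elif isinstance(alleles, str):
        alleles = {"allele0": alleles}
    if depth <= 0:
        raise SimulationError("depth must be positive")
    if allele_mix is None:
        allele_mix = {k: 1.0 / len(alleles) for k in alleles}
    if abs(sum(allele_mix.values()) - 1.0) > 1e-9:
        raise SimulationError("allele_mix fractions must sum to 1")
    for name, seq in alleles.items():
        if read_len > len(seq):
            raise SimulationError(
                f"read_len {read_len} exceeds allele {name!r} length {len(seq)}"
            )
    rng = np.random.default_rng(seed)
    mean_len = np.mean([len(s) for s in alleles.values()])
    n_reads = int(math.ceil(depth * mean_len / read_len))
    names = list(allele_mix)
    probs = np.array([allele_mix[k] for k in names])
    picks = rng.choice(len(names), size=n_reads, p=probs)
    reads: list[SimRead] = []
    bases = np.frombuffer(b"ACGT", dtype="S1")
    for i, a in enumerate(picks):
        src = alleles[names[a]]
        start = int(rng.integers(0, len(src) - read_len + 1))
        r = src[start : start + read_len]
        if error_rate > 0:
            arr = np.frombuffer(r.encode(), dtype="S1").copy()
            errs = np.nonzero(rng.random(read_len) < error_rate)[0]
            for e in errs:
                choices = [b for b in bases if b != arr[e]]
                arr[e] = choices[rng.integers(0, len(choices))]
            r = arr.tobytes().decode()
        reads.append(SimRead(name=f"read{i}|{names[a]}|{start}", seq=r))
    return reads


# ----------------------------------------------------------------------
# plain-text IO
# ----------------------------------------------------------------------

def write_fasta(records: dict[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: list[SimRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{r.qual}\n")


def read_fastq(path: str | Path) -> list[SimRead]:
    """Plain or gzipped FASTQ."""
    path = str(path)
    if path.endswith(".gz"):
        import gzip

        with gzip.open(path, "rt") as fh:
            return [SimRead(r.id, str(r.seq).upper()) for r in SeqIO.parse(fh, "fastq")]
    return [SimRead(r.id, str(r.seq).upper()) for r in SeqIO.parse(path, "fastq")]


def write_truth_table(truths: dict[str, LocusTruth], path: str | Path) -> None:
    """TSV truth sidecar: taxon, kind, ref_coord, length_nt, codon_index."""
    with open(path, "w") as fh:
        fh.write("taxon\tkind\tref_coord\tlength_nt\tcodon_index\tstrand\tcds_start\tcds_end\n")
        for taxon, tr in truths.items():
            if not tr.lesions:
                fh.write(
                    f"{taxon}\tnone\t0\t0\t0\t{tr.strand}\t{tr.cds_interval[0]}\t{tr.cds_interval[1]}\n"
                )
            for les in tr.lesions:
                fh.write(
                    f"{taxon}\t{les.kind}\t{les.ref_coord}\t{les.length_nt}\t"
                    f"{les.codon_index}\t{tr.strand}\t{tr.cds_interval[0]}\t{tr.cds_interval[1]}\n"
                )
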