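"""Bundled deterministic fixtures.

Each fixture writes a complete, self-consistent file bundle — anchored
loci, reference gene, species tree with branch categories, reads, and
truth records — reproducing a characteristic configuration of gene
erosion:

``cetacea``
    Fifteen taxa on a whale-like topology.  A 2-nt deletion shared by
    all toothed whales except the sperm whale, which carries a private
    mid-gene stop and a 1-nt insertion near the end; a 1-nt deletion
    shared by three of four baleen whales with the fourth 5'-fragmented
    by Ns; one taxon with private extra lesions and a truncated second
    half; intact outgroups.  Three independent losses by construction.
``polymorphic_pika``
    One taxon, a premature stop segregating 50/50 in its reads.
``truncation``
    A locus whose second half is replaced by unrelated sequence.
``clean``
    All taxa intact; nothing to find.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codons import random_sense_cds
from .events import cetacean_category_scheme, label_branch_categories
from .locus import GenomicLocus
from .simulate import (
    EvolutionSpec,
    LesionSpec,
    LocusTruth,
    SimRead,
    build_locus,
    inject_lesions,
    simulate_cds_evolution,
    simulate_reads,
    write_fasta,
    write_fastq,
    write_truth_table,
)

FIXTURE_NAMES = ("cetacea", "polymorphic_pika", "truncation", "clean")

MYSTICETI = ["bowhead", "gray", "antarctic_minke", "minke"]
ODONTOCETI_NON_SPERM = [
    "yangtze_river_dolphin",
    "beluga",
    "finless_porpoise",
    "killer_whale",
    "pacific_white_sided_dolphin",
    "bottlenose_dolphin",
    "humpback_dolphin",
]
SPERM = "sperm_whale"
OUTGROUPS = ["hippo", "cattle", "human"]

CETACEAN_NEWICK = (
    "(human:0.08,(cattle:0.06,(hippo:0.05,((bowhead:0.02,(gray:0.02,"
    "(antarctic_minke:0.015,minke:0.015):0.01):0.01):0.02,(sperm_whale:0.03,"
    "(yangtze_river_dolphin:0.02,(beluga:0.015,(finless_porpoise:0.015,"
    "(killer_whale:0.01,(pacific_white_sided_dolphin:0.01,(bottlenose_dolphin:0.008,"
    "humpback_dolphin:0.008):0.005):0.005):0.005):0.005):0.005):0.01):0.02):0.02):0.02):0.02);"
)

# omegas used to evolve the fixture CDSs: purifying while the gene is
# functional, relaxed on post-loss branches
CETACEAN_TRUE_OMEGA = {
    "functional": 0.1,
    "cetacean_stem": 0.12,
    "mysticeti_stem": 0.8,
    "odontoceti_stem": 0.2,
    "sperm_whale_ancestor": 0.35,
    "mysticeti": 0.6,
    "odontoceti": 0.5,
}

N_CODONS = 480  # 1440 nt, the length scale of a dopamine-receptor CDS


@dataclass
class FixtureBundle:
    """In-memory fixture: everything the pipeline consumes."""

    name: str
    reference_name: str
    reference_cds: str  # includes the terminal stop codon
    reference_utr5: str
    reference_utr3: str
    tree_newick: str
    loci: dict[str, GenomicLocus]
    truths: dict[str, LocusTruth]
    read_sets: dict[str, dict[str, list[SimRead]]] = field(default_factory=dict)
    anchors: dict[str, str] = field(default_factory=dict)
    expected: dict = field(default_factory=dict)
    stages: dict[str, bool] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(
            {
                f"{self.reference_name}|utr5={len(self.reference_utr5)}|utr3={len(self.reference_utr3)}": self.reference_utr5
                + self.reference_cds
                + self.reference_utr3
            },
            outdir / "reference.fasta",
        )
        write_fasta({t: loc.seq for t, loc in self.loci.items()}, outdir / "loci.fasta")
        if self.anchors:
            write_fasta(self.anchors, outdir / "anchors.fasta")
        (outdir / "tree.nwk").write_text(self.tree_newick + "\n")
        write_truth_table(self.truths, outdir / "truth.tsv")
        if self.read_sets:
            reads_dir = outdir / "reads"
            reads_dir.mkdir(exist_ok=True)
            for taxon, sets in self.read_sets.items():
                for set_name, reads in sets.items():
                    write_fastq(reads, reads_dir / f"{taxon}.{set_name}.fastq")
        (outdir / "expected.json").write_text(json.dumps(self.expected, indent=1) + "\n")
        config = {
            "reference": {
                "fasta": "reference.fasta",
                "utr5_len": len(self.reference_utr5),
                "utr3_len": len(self.reference_utr3),
            },
            "loci_fasta": "loci.fasta",
            "tree": "tree.nwk",
            "reads_dir": "reads" if self.read_sets else None,
            "anchors_fasta": "anchors.fasta" if self.anchors else None,
        }
        if self.stages:
            config["stages"] = dict(self.stages)
        import yaml

        (outdir / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
        return outdir


def _anchor_genes(rng: np.random.Generator) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    up = [("anchor_up", "".join(rng.choice(list("ACGT"), size=900)))]
    down = [("anchor_down", "".join(rng.choice(list("ACGT"), size=900)))]
    return up, down


def make_cetacea(seed: int = 0) -> FixtureBundle:
    rng = np.random.default_rng(seed)
    labeled = label_branch_categories(
        CETACEAN_NEWICK,
        cetacean_category_scheme(MYSTICETI, ODONTOCETI_NON_SPERM, SPERM),
    )
    root_cds = random_sense_cds(N_CODONS - 1, rng)
    spec = EvolutionSpec(
        tree=labeled,
        omega=CETACEAN_TRUE_OMEGA,
        kappa=2.5,
        root_cds=root_cds,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    seqs, _aln = simulate_cds_evolution(spec)
    # reference: the cattle sequence, UTR-flanked, with the terminal stop
    ref_core = seqs["cattle"]
    utr5 = "".join(rng.choice(list("ACGT"), size=150))
    utr3 = "".join(rng.choice(list("ACGT"), size=150))

    lesion_plan: dict[str, list[LesionSpec]] = {t: [] for t in seqs}
    for t in ODONTOCETI_NON_SPERM:
        lesion_plan[t].append(LesionSpec(kind="deletion", position_frac=0.36, length_nt=2))
    lesion_plan[SPERM] = [
        LesionSpec(kind="nonsense", position_frac=0.49),
        LesionSpec(kind="insertion", position_frac=0.93, length_nt=1),
    ]
    for t in ["bowhead", "gray", "antarctic_minke"]:
        lesion_plan[t].append(LesionSpec(kind="deletion", position_frac=0.09, length_nt=1))
    # private extras echoing the non-conserved lesions seen in real loci
    lesion_plan["yangtze_river_dolphin"].append(LesionSpec(kind="nonsense", position_frac=0.62))
    lesion_plan["finless_porpoise"].append(LesionSpec(kind="nonsense", position_frac=0.52))
    lesion_plan["beluga"].append(LesionSpec(kind="deletion", position_frac=0.05, length_nt=1))
    lesion_plan["antarctic_minke"].append(LesionSpec(kind="insertion", position_frac=0.55, length_nt=2))
    lesion_plan["gray"].append(LesionSpec(kind="insertion", position_frac=0.2, length_nt=1))

    up, down = _anchor_genes(rng)
    loci: dict[str, GenomicLocus] = {}
    truths: dict[str, LocusTruth] = {}
    cds_len = len(root_cds) + 3
    for taxon, cds in seqs.items():
        full_cds = cds + "TAA"
        mutant, truth_lesions = inject_lesions(
            full_cds, lesion_plan[taxon], seed=seed * 1000 + zlib.crc32(taxon.encode()) % 997
        )
        n_run = None
        fragment = False
        if taxon == "minke":
            # 5'-end assembly gap over the first fifth of the CDS
            fragment = True
        locus, truth = build_locus(
            mutant,
            up,
            down,
            intergenic_length=250,
            strand="-" if taxon in ("beluga", "gray") else "+",
            taxon=taxon,
            lesions=truth_lesions,
            utr5=utr5,
            utr3=utr3,
            seed=seed * 131 + len(taxon),
        )
        if taxon == "minke":
            a, b = truth.cds_interval
            # truth built on '+' strand here (minke is '+')
            gap = (a - 30, a + int(0.2 * cds_len))
            chars = list(locus.seq)
            chars[gap[0] : gap[1]] = "N" * (gap[1] - gap[0])
            locus.seq = "".join(chars)
            truth.n_run_intervals.append(gap)
        loci[taxon] = locus
        truths[taxon] = truth

    # reads: confirmable lesions for a couple of taxa, two sets each
    read_sets: dict[str, dict[str, list[SimRead]]] = {}
    for taxon in ("sperm_whale", "killer_whale"):
        read_sets[taxon] = {
            f"sra{k}": simulate_reads(
                loci[taxon].seq, depth=25, read_len=100, error_rate=0.002,
                seed=seed * 7919 + 31 * k + len(taxon),
            )
            for k in (1, 2)
        }

    return FixtureBundle(
        name="cetacea",
        reference_name="cattle_reference",
        reference_cds=ref_core + "TAA",
        reference_utr5=utr5,
        reference_utr3=utr3,
        tree_newick=labeled.to_newick(),
        loci=loci,
        truths=truths,
        read_sets=read_sets,
        anchors={"anchor_up": up[0][1], "anchor_down": down[0][1]},
        expected={"loss_events": 3, "eroded": 11, "inconclusive": ["minke"]},
    )


def make_polymorphic_pika(seed: int = 0) -> FixtureBundle:
    rng = np.random.default_rng(seed + 17)
    root = random_sense_cds(399, rng)
    wild_cds = root + "TAA"
    mutant_cds, lesions = inject_lesions(
        wild_cds, [LesionSpec(kind="nonsense", position_frac=0.5)], seed=seed
    )
    utr5 = "".join(rng.choice(list("ACGT"), size=120))
    utr3 = "".join(rng.choice(list("ACGT"), size=120))
    up, down = _anchor_genes(rng)
    locus, truth = build_locus(
        mutant_cds, up, down, taxon="pika", lesions=lesions, utr5=utr5, utr3=utr3, seed=seed + 3
    )
    wild_locus, _ = build_locus(wild_cds, up, down, taxon="pika_wild", utr5=utr5, utr3=utr3, seed=seed + 3)
    mix = {"mutant": 0.5, "wild": 0.5}
    reads = {
        f"sra{k}": simulate_reads(
            {"mutant": locus.seq, "wild": wild_locus.seq},
            depth=50,
            read_len=150,
            error_rate=0.0,
            allele_mix=mix,
            seed=seed * 97 + k,
        )
        for k in (1, 2, 3)
    }
    return FixtureBundle(
        name="polymorphic_pika",
        reference_name="reference",
        reference_cds=wild_cds,
        reference_utr5=utr5,
        reference_utr3=utr3,
        tree_newick="(pika:0.1,outgroup:0.1);",
        loci={"pika": locus},
        truths={"pika": truth},
        read_sets={"pika": reads},
        anchors={"anchor_up": up[0][1], "anchor_down": down[0][1]},
        expected={"verdict": "polymorphic", "support_fraction": 0.5},
        stages={"selection": False},
    )


def make_truncation(seed: int = 0) -> FixtureBundle:
    rng = np.random.default_rng(seed + 29)
    root = random_sense_cds(399, rng)
    cds = root + "TAA"
    utr5 = "".join(rng.choice(list("ACGT"), size=120))
    utr3 = "".join(rng.choice(list("ACGT"), size=120))
    up, down = _anchor_genes(rng)
    locus, truth = build_locus(cds, up, down, taxon="trunc", utr5=utr5, utr3=utr3, seed=seed + 5)
    a, b = truth.cds_interval
    mid = a + (b - a) // 2
    chars = list(locus.seq)
    repl = rng.choice(list("ACGT"), size=len(chars) - mid)
    chars[mid:] = list(repl)
    locus.seq = "".join(chars)
    return FixtureBundle(
        name="truncation",
        reference_name="reference",
        reference_cds=cds,
        reference_utr5=utr5,
        reference_utr3=utr3,
        tree_newick="(trunc:0.1,outgroup:0.1);",
        loci={"trunc": locus},
        truths={"trunc": truth},
        anchors={"anchor_up": up[0][1], "anchor_down": down[0][1]},
        expected={"truncation_near_frac": 0.5},
        stages={"validate": False, "selection": False},
    )


def make_clean(seed: int = 0) -> FixtureBundle:
    rng = np.random.default_rng(seed + 41)
    labeled = label_branch_categories(
        CETACEAN_NEWICK,
        cetacean_category_scheme(MYSTICETI, ODONTOCETI_NON_SPERM, SPERM),
    )
    root_cds = random_sense_cds(N_CODONS - 1, rng)
    spec = EvolutionSpec(
        tree=labeled,
        omega={c: 0.1 for c in CETACEAN_TRUE_OMEGA},
        kappa=2.5,
        root_cds=root_cds,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    seqs, _ = simulate_cds_evolution(spec)
    utr5 = "".join(rng.choice(list("ACGT"), size=150))
    utr3 = "".join(rng.choice(list("ACGT"), size=150))
    up, down = _anchor_genes(rng)
    loci, truths = {}, {}
    for taxon, cds in seqs.items():
        locus, truth = build_locus(cds + "TAA", up, down, taxon=taxon, utr5=utr5, utr3=utr3, seed=seed + len(taxon))
        loci[taxon] = locus
        truths[taxon] = truth
    return FixtureBundle(
        name="clean",
        reference_name="cattle_reference",
        reference_cds=seqs["cattle"] + "TAA",
        reference_utr5=utr5,
        reference_utr3=utr3,
        tree_newick=labeled.to_newick(),
        loci=loci,
        truths=truths,
        anchors={"anchor_up": up[0][1], "anchor_down": down[0][1]},
        expected={"loss_events": 0, "eroded": 0},
        stages={"validate": False, "selection": False},
    )


_MAKERS = {
    "cetacea": make_cetacea,
    "polymorphic_pika": make_polymorphic_pika,
    "truncation": make_truncation,
    "clean": make_clean,
}


def make_fixture(name: str, outdir: str | Path | None = None, seed: int = 0) -> FixtureBundle:
    """Build a bundled fixture; optionally write its file bundle."""
    if name not in _MAKERS:
        raise ValueError(f"unknown fixture {name!r}; options: {', '.join(FIXTURE_NAMES)}")
    bundle = _MAKERS[name](seed=seed)
    if outdir is not None:
        bundle.write(outdir)
    return bundle
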