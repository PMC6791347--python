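"""End-to-end orchestration: synteny -> annotate -> validate -> events
-> selection, with every intermediate written as a plain file.

The pipeline mirrors how gene-loss studies proceed: locus orthology is
established from anchor genes, the reference gene is mapped onto each
locus and screened for inactivating mutations, calls are validated
against reads where available, shared lesions are placed on the species
tree to count independent losses, and branch-category dN/dS tests ask
whether the gene evolved under purifying selection before loss and
neutrally after.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotate import (
    INCONCLUSIVE,
    InactivatingMutation,
    MappedAlignment,
    NoOrthologDetected,
    ReferenceGene,
    annotation_gff3,
    call_inactivating_mutations,
    classify_coding_status,
    detect_truncation,
    mutation_table,
    translation_align,
)
from .codonmodel import CodonBranchModel
from .events import build_mutation_matrix, count_independent_losses
from .locus import GenomicLocus
from .simulate import read_fasta, read_fastq, write_fasta
from .synteny import RegionNotResolvable, best_hit, locate_target_region
from .trees import BACKGROUND, LabeledTree
from .validate import validate_all, verdict_table

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Validated run configuration (paths resolved against ``base_dir``)."""

    base_dir: Path
    run_dir: Path
    reference_fasta: Path
    utr5_len: int
    utr3_len: int
    loci_fasta: Path
    tree: Path
    reads_dir: Path | None = None
    anchors_fasta: Path | None = None
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "synteny": True,
            "annotate": True,
            "validate": True,
            "events": True,
            "selection": True,
        }
    )
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, run_dir: str | Path | None = None) -> "RunConfig":
        path = Path(path)
        base = path.parent
        cfg = yaml.safe_load(path.read_text()) or {}
        ref = cfg.get("reference", {})
        stages = {
            "synteny": True,
            "annotate": True,
            "validate": True,
            "events": True,
            "selection": True,
        }
        stages.update(cfg.get("stages", {}))
        rc = cls(
            base_dir=base,
            run_dir=Path(run_dir) if run_dir else base / "run",
            reference_fasta=base / ref.get("fasta", "reference.fasta"),
            utr5_len=int(ref.get("utr5_len", 0)),
            utr3_len=int(ref.get("utr3_len", 0)),
            loci_fasta=base / cfg.get("loci_fasta", "loci.fasta"),
            tree=base / cfg.get("tree", "tree.nwk"),
            reads_dir=(base / cfg["reads_dir"]) if cfg.get("reads_dir") else None,
            anchors_fasta=(base / cfg["anchors_fasta"]) if cfg.get("anchors_fasta") else None,
            stages=stages,
            params=cfg.get("params", {}) or {},
        )
        rc.validate()
        return rc

    def validate(self) -> None:
        if any(self.stages.values()):
            for p, needed in (
                (self.reference_fasta, self.stages.get("annotate")),
                (self.loci_fasta, True),
                (self.tree, self.stages.get("events") or self.stages.get("selection")),
            ):
                if needed and not Path(p).exists():
                    raise PipelineError(f"required input missing: {p}")

    def effective_params(self) -> dict:
        defaults = {
            "min_identity": 70.0,
            "min_coverage": 50.0,
            "anchor_padding": 200,
            "map_min_coverage": 0.2,
            "min_unambiguous_coverage": 0.9,
            "truncation_window": 60,
            "truncation_step": 15,
            "truncation_high": 70.0,
            "truncation_low": 30.0,
            "flank_nt": 30,
            "min_reads": 3,
            "conf_thr": 0.8,
        }
        defaults.update(self.params)
        return defaults


def load_reference(config: RunConfig) -> ReferenceGene:
    recs = read_fasta(config.reference_fasta)
    if len(recs) != 1:
        raise PipelineError("reference FASTA must contain exactly one record")
    name, seq = next(iter(recs.items()))
    base = name.split("|")[0]
    u5, u3 = config.utr5_len, config.utr3_len
    cds = seq[u5 : len(seq) - u3] if u3 else seq[u5:]
    return ReferenceGene(name=base, cds=cds, utr5=seq[:u5], utr3=seq[len(seq) - u3 :] if u3 else "")


@dataclass
class RunReport:
    """Machine-readable outcome of one pipeline run."""

    statuses: dict[str, str] = field(default_factory=dict)
    mutations: dict[str, list[dict]] = field(default_factory=dict)
    verdicts: dict[str, list[dict]] = field(default_factory=dict)
    loss_event_count: int | None = None
    event_clades: list[list[str]] = field(default_factory=list)
    selection: list[dict] = field(default_factory=list)
    completed_stages: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "statuses": dict(sorted(self.statuses.items())),
            "mutations": {t: self.mutations[t] for t in sorted(self.mutations)},
            "verdicts": {t: self.verdicts[t] for t in sorted(self.verdicts)},
            "loss_event_count": self.loss_event_count,
            "event_clades": sorted(sorted(c) for c in self.event_clades),
            "selection": self.selection,
            "completed_stages": self.completed_stages,
            "warnings": self.warnings,
        }
        return json.dumps(payload, indent=1, sort_keys=False) + "\n"


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages in dependency order.

    Every intermediate lands in ``config.run_dir``; a stage failure
    aborts with the stage name and downstream stages are skipped.
    """
    run_dir = Path(config.run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    params = config.effective_params()
    report = RunReport()
    stage = "setup"
    try:
        loci_raw = read_fasta(config.loci_fasta)
        loci = {t: GenomicLocus(name=t, seq=s, contig=t) for t, s in loci_raw.items()}
        reference = load_reference(config) if config.stages.get("annotate") else None

        # ---------------- synteny ------------------------------------
        regions: dict[str, GenomicLocus] = dict(loci)
        if config.stages.get("synteny") and config.anchors_fasta:
            stage = "synteny"
            anchors = read_fasta(config.anchors_fasta)
            names = sorted(anchors)
            rows = []
            for taxon, locus in loci.items():
                contigs = {locus.contig: locus.seq}
                hits = {
                    n: best_hit(n, anchors[n], contigs, params["min_identity"], params["min_coverage"])
                    for n in names
                }
                got = [h for h in hits.values() if h is not None]
                if len(got) >= 2:
                    try:
                        region = locate_target_region(
                            got[0], got[1], contigs, padding_nt=params["anchor_padding"]
                        )
                        regions[taxon] = region
                    except RegionNotResolvable as exc:
                        report.warnings.append(f"synteny:{taxon}: {exc}")
                for n, h in hits.items():
                    rows.append(
                        f"{taxon}\t{n}\t"
                        + (f"{h.start}\t{h.end}\t{h.strand}\t{h.percent_identity:.1f}\t{h.query_coverage:.1f}"
                           if h else ".\t.\t.\t.\t.")
                    )
            (run_dir / "synteny.tsv").write_text(
                "taxon\tanchor\tstart\tend\tstrand\tidentity\tcoverage\n" + "\n".join(rows) + "\n"
            )
            report.completed_stages.append("synteny")

        # ---------------- annotate -----------------------------------
        muts_by_taxon: dict[str, list[InactivatingMutation]] = {}
        alns: dict[str, MappedAlignment] = {}
        if config.stages.get("annotate"):
            stage = "annotate"
            recon: dict[str, str] = {}
            for taxon, region in regions.items():
                try:
                    aln = map_reference(reference, region, params)
                except NoOrthologDetected as exc:
                    report.warnings.append(f"annotate:{taxon}: {exc}")
                    report.statuses[taxon] = INCONCLUSIVE
                    muts_by_taxon[taxon] = []
                    continue
                alns[taxon] = aln
                muts = call_inactivating_mutations(aln, params["map_min_coverage"])
                trunc = detect_truncation(
                    aln,
                    params["truncation_window"],
                    params["truncation_step"],
                    params["truncation_high"],
                    params["truncation_low"],
                )
                if trunc is not None and not trunc.inconclusive:
                    muts.append(trunc.as_mutation())
                for m in muts:
                    m.taxon = taxon
                muts_by_taxon[taxon] = muts
                report.statuses[taxon] = classify_coding_status(
                    muts, aln, params["min_unambiguous_coverage"]
                )
                recon[taxon] = aln.reconstructed_cds()
            mutation_table(muts_by_taxon, run_dir / "mutations.tsv")
            annotation_gff3(alns, muts_by_taxon, run_dir / "annotation.gff3")
            with open(run_dir / "statuses.tsv", "w") as fh:
                fh.write("taxon\tstatus\n")
                for t in sorted(report.statuses):
                    fh.write(f"{t}\t{report.statuses[t]}\n")
            if recon:
                write_fasta(recon, run_dir / "reconstructed_cds.fasta")
            report.mutations = {
                t: [
                    {
                        "kind": m.kind,
                        "ref_coord": m.ref_coord,
                        "length_nt": m.length_nt,
                        "codon_index": m.codon_index,
                    }
                    for m in ms
                ]
                for t, ms in muts_by_taxon.items()
            }
            report.completed_stages.append("annotate")

        # ---------------- validate -----------------------------------
        if config.stages.get("validate") and muts_by_taxon:
            stage = "validate"
            all_verdicts = []
            for taxon, muts in muts_by_taxon.items():
                testable = [m for m in muts if m.kind != "truncation" and m.region_coord >= 0]
                read_sets = _read_sets_for(config.reads_dir, taxon)
                if not read_sets:
                    for m in testable:
                        m.read_validation_status = "no_data"
                    report.verdicts[taxon] = [
                        {"kind": m.kind, "ref_coord": m.ref_coord, "verdict": "no_data"}
                        for m in testable
                    ]
                    if testable:
                        report.warnings.append(f"validate:{taxon}: no read sets found")
                    continue
                cvs = validate_all(
                    testable,
                    alns[taxon],
                    read_sets,
                    flank_nt=params["flank_nt"],
                    min_reads=params["min_reads"],
                    conf_thr=params["conf_thr"],
                )
                all_verdicts.extend(cvs)
                report.verdicts[taxon] = [
                    {"kind": cv.mutation.kind, "ref_coord": cv.mutation.ref_coord, "verdict": cv.consensus}
                    for cv in cvs
                ]
            if all_verdicts:
                verdict_table(all_verdicts, run_dir / "verdicts.tsv")
            report.completed_stages.append("validate")

        # ---------------- events -------------------------------------
        if config.stages.get("events") and muts_by_taxon:
            stage = "events"
            tree = LabeledTree.from_newick(Path(config.tree).read_text())
            covered = {
                t: alns[t].covered_ref_intervals() for t in alns if report.statuses.get(t) == INCONCLUSIVE
            }
            matrix = build_mutation_matrix(muts_by_taxon, report.statuses, covered or None)
            matrix.to_tsv(run_dir / "mutation_matrix.tsv")
            events = count_independent_losses(matrix, tree)
            events.to_tsv(run_dir / "loss_events.tsv")
            report.loss_event_count = events.count
            report.event_clades = [sorted(c) for c in events.event_clades]
            report.completed_stages.append("events")

        # ---------------- selection ----------------------------------
        if config.stages.get("selection") and muts_by_taxon:
            stage = "selection"
            tree = LabeledTree.from_newick(Path(config.tree).read_text())
            usable = {
                t: alns[t].reconstructed_cds() for t in alns if t in tree.taxa
            }
            dropped = [t for t in tree.taxa if t not in usable]
            pruned = tree
            if dropped:
                pruned = tree.copy()
                pruned.tree.retain_taxa_with_labels(list(usable))
            aln = translation_align(usable)
            aln.to_fasta(run_dir / "codon_alignment.fasta")
            model = CodonBranchModel(aln, pruned)
            rows = []
            for cat in sorted(model.categories):
                if cat == BACKGROUND:
                    continue
                tr = model.fit_two_ratio(cat)
                rows.append(
                    {
                        "category": cat,
                        "omega": round(tr.omega, 4),
                        "lrt_statistic": round(tr.lrt.statistic, 4),
                        "p_value": round(tr.p_value, 4),
                    }
                )
            report.selection = rows
            with open(run_dir / "selection.tsv", "w") as fh:
                fh.write("category\tomega\tlrt_statistic\tp_value\n")
                for r in rows:
                    fh.write(f"{r['category']}\t{r['omega']}\t{r['lrt_statistic']}\t{r['p_value']}\n")
            report.completed_stages.append("selection")
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (run_dir / "summary.json").write_text(report.to_json())
    log = {
        "version": __version__,
        "parameters": params,
        "stages": config.stages,
        "inputs": {
            "reference": str(config.reference_fasta),
            "loci": str(config.loci_fasta),
            "tree": str(config.tree),
        },
    }
    (run_dir / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=True))
    return report


def map_reference(reference: ReferenceGene, region: GenomicLocus, params: dict) -> MappedAlignment:
    from .annotate import map_reference_cds

    return map_reference_cds(reference, region, min_coverage=params["map_min_coverage"])


def _read_sets_for(reads_dir: Path | None, taxon: str):
    if reads_dir is None or not Path(reads_dir).exists():
        return {}
    sets = {}
    for f in sorted(Path(reads_dir).glob(f"{taxon}.*.fastq")):
        sets[f.stem.split(".", 1)[1]] = read_fastq(f)
    return sets
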