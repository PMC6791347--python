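"""Shared-lesion aggregation and Dollo counting of independent losses.

Lesions with identical identity keys (kind, reference-projected
coordinate, length) are merged across taxa into a lesions-by-taxa
matrix (present / absent / unknown).  Under Dollo parsimony each lesion
arises once and is never reverted: a lesion is placed on the stem of
the smallest clade containing all its carriers after unknown-status
taxa are pruned, splitting into per-subclade origins when the carriers
are not monophyletic.  A leaf's inactivation branch is the most basal
lesion-bearing branch on its root path; the distinct inactivation
branches are the independent loss events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotate import ERODED, INCONCLUSIVE, InactivatingMutation
from .trees import LabeledTree

logger = logging.getLogger(__name__)

PRESENT, ABSENT, UNKNOWN = 1, 0, -1


class LossInferenceError(ValueError):
    pass


@dataclass
class MutationMatrix:
    """Lesions x taxa presence/absence/unknown matrix."""

    lesions: list[tuple[str, int, int]]  # (kind, ref_coord, length_nt)
    taxa: list[str]
    values: pd.DataFrame  # index: lesion key string; columns: taxa
    statuses: dict[str, str] = field(default_factory=dict)

    @staticmethod
    def key_str(key: tuple[str, int, int]) -> str:
        return f"{key[0]}@{key[1]}+{key[2]}"

    def carriers(self, key: tuple[str, int, int]) -> list[str]:
        row = self.values.loc[self.key_str(key)]
        return [t for t in self.taxa if row[t] == PRESENT]

    def unknowns(self, key: tuple[str, int, int]) -> list[str]:
        row = self.values.loc[self.key_str(key)]
        return [t for t in self.taxa if row[t] == UNKNOWN]

    def eroded_taxa(self) -> list[str]:
        return [t for t in self.taxa if self.statuses.get(t) == ERODED]

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t")


def build_mutation_matrix(
    per_taxon_mutations: dict[str, list[InactivatingMutation]],
    statuses: dict[str, str],
    covered_intervals: dict[str, list[tuple[int, int]]] | None = None,
) -> MutationMatrix:
    """Merge per-taxon lesions on identical identity keys.

    A taxon is unknown at a lesion when its coding status is
    inconclusive and the lesion coordinate falls outside its covered
    intervals (with no intervals given, an inconclusive taxon is
    unknown everywhere).
    """
    covered_intervals = covered_intervals or {}
    taxa = list(per_taxon_mutations)
    keys: list[tuple[str, int, int]] = []
    for taxon in taxa:
        for m in per_taxon_mutations[taxon]:
            k = m.key()
            if k not in keys:
                keys.append(k)
    seen_coords: dict[tuple[int, int], str] = {}
    for kind, coord, length in keys:
        prev = seen_coords.get((coord, length))
        if prev is not None and prev != kind:
            logger.warning(
                "lesions of different kinds at identical coordinate %d (%s vs %s); kept distinct",
                coord,
                prev,
                kind,
            )
        seen_coords[(coord, length)] = kind
    keys.sort(key=lambda k: (k[1], k[0], k[2]))

    def cell(taxon: str, key: tuple[str, int, int]) -> int:
        if any(m.key() == key for m in per_taxon_mutations[taxon]):
            return PRESENT
        if statuses.get(taxon) == INCONCLUSIVE:
            ivs = covered_intervals.get(taxon)
            if ivs is None:
                return UNKNOWN
            coord = key[1]
            if not any(a <= coord <= b for a, b in ivs):
                return UNKNOWN
        return ABSENT

    df = pd.DataFrame(
        {t: [cell(t, k) for k in keys] for t in taxa},
        index=[MutationMatrix.key_str(k) for k in keys],
    )
    return MutationMatrix(lesions=keys, taxa=taxa, values=df, statuses=dict(statuses))


@dataclass
class LossEventSet:
    """Branches on which independent inactivation events are inferred.

    Each branch is identified by the leaf set of the clade below it.
    """

    event_clades: list[frozenset[str]]
    lesion_origins: dict[str, list[frozenset[str]]]
    leaf_assignment: dict[str, frozenset[str]]

    @property
    def count(self) -> int:
        return len(self.event_clades)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("event\tbranch_clade\tleaves_assigned\n")
            for i, clade in enumerate(sorted(self.event_clades, key=sorted)):
                assigned = sorted(t for t, c in self.leaf_assignment.items() if c == clade)
                fh.write(f"{i + 1}\t{','.join(sorted(clade))}\t{','.join(assigned)}\n")


def _lesion_origin_clades(
    tree: LabeledTree,
    carriers: set[str],
    unknowns: set[str],
) -> list[frozenset[str]]:
    """Minimal Dollo origins: one per maximal carrier-only clade
    (unknown taxa ignored), placed at the MRCA of that group's carriers."""
    known_non_carriers = set(tree.taxa) - carriers - unknowns
    candidate: dict[int, bool] = {}
    leafset: dict[int, frozenset[str]] = {}
    for nd in tree.tree.postorder_node_iter():
        ls = tree.clade_leaves(nd)
        leafset[id(nd)] = ls
        known = ls & (carriers | known_non_carriers)
        # the root is never a candidate: an origin must sit on a branch
        candidate[id(nd)] = (
            nd.parent_node is not None and bool(known) and known <= carriers
        )
    origins: list[frozenset[str]] = []
    for nd in tree.tree.preorder_node_iter():
        if not candidate[id(nd)]:
            continue
        parent = nd.parent_node
        if parent is not None and candidate[id(parent)]:
            continue  # not maximal
        group = leafset[id(nd)] & carriers
        if not group:
            continue
        origins.append(frozenset(tree.clade_leaves(tree.mrca(group))))
    return origins


def count_independent_losses(matrix: MutationMatrix, tree: LabeledTree | str) -> LossEventSet:
    """Dollo placement of every lesion, then the distinct most-basal
    lesion-bearing branches over the eroded leaves."""
    if isinstance(tree, str):
        tree = LabeledTree.from_newick(tree)
    tree_taxa = set(tree.taxa)
    lesion_origins: dict[str, list[frozenset[str]]] = {}
    origin_clades: set[frozenset[str]] = set()
    for key in matrix.lesions:
        carriers = set(matrix.carriers(key))
        missing = carriers - tree_taxa
        if missing:
            raise LossInferenceError(f"carriers absent from tree: {sorted(missing)}")
        if not carriers:
            continue
        unknowns = set(matrix.unknowns(key)) & tree_taxa
        origins = _lesion_origin_clades(tree, carriers, unknowns)
        lesion_origins[MutationMatrix.key_str(key)] = origins
        origin_clades.update(origins)

    leaf_assignment: dict[str, frozenset[str]] = {}
    for taxon in matrix.eroded_taxa():
        if taxon not in tree_taxa:
            raise LossInferenceError(f"eroded taxon {taxon!r} absent from tree")
        # root path: clades containing the taxon, largest = most basal
        on_path = [c for c in origin_clades if taxon in c]
        if not on_path:
            logger.warning("eroded taxon %s has no lesion on its root path", taxon)
            continue
        leaf_assignment[taxon] = max(on_path, key=len)
    events = sorted(set(leaf_assignment.values()), key=sorted)
    return LossEventSet(
        event_clades=events,
        lesion_origins=lesion_origins,
        leaf_assignment=leaf_assignment,
    )


# ----------------------------------------------------------------------
# branch-category labeling
# ----------------------------------------------------------------------

def label_branch_categories(
    tree: LabeledTree | str,
    scheme: list[tuple[str, tuple]],
    background: str = "functional",
) -> LabeledTree:
    """Tag branches with category labels for the selection analysis.

    ``scheme`` is an ordered list of (category, selector); later entries
    overwrite earlier ones.  Selectors: ``("stem", taxa)`` the branch
    above the MRCA of taxa, ``("crown", taxa)`` every branch strictly
    within that clade, ``("terminal", taxon)`` one leaf branch.
    Unmatched selectors raise; untagged branches get ``background``.
    """
    out = tree.copy() if isinstance(tree, LabeledTree) else LabeledTree.from_newick(tree)
    for nd in out.branches():
        nd.edge.category = background
    for category, selector in scheme:
        kind = selector[0]
        matched = False
        if kind == "stem":
            node = out.mrca(selector[1])
            if node.parent_node is None:
                raise LossInferenceError(
                    f"selector {selector} for {category!r} matches the root, which has no branch"
                )
            node.edge.category = category
            matched = True
        elif kind == "crown":
            top = out.mrca(selector[1])
            for nd in top.preorder_iter():
                if nd is top:
                    continue
                nd.edge.category = category
                matched = True
        elif kind == "terminal":
            node = out.tree.find_node_with_taxon_label(selector[1])
            if node is None:
                raise LossInferenceError(f"no leaf named {selector[1]!r}")
            node.edge.category = category
            matched = True
        else:
            raise LossInferenceError(f"unknown selector kind {kind!r}")
        if not matched:
            raise LossInferenceError(f"selector {selector} matched no branch")
    return out


def cetacean_category_scheme(
    mysticeti: list[str],
    odontoceti_non_sperm: list[str],
    sperm_whale: str,
) -> list[tuple[str, tuple]]:
    """The seven-category layout used for an independently eroded gene
    in whales: crown Mysticeti, crown Odontoceti, both parvorder stems,
    the common cetacean stem, the sperm-whale branch, and a functional
    background covering the outgroups."""
    cetacea = list(mysticeti) + list(odontoceti_non_sperm) + [sperm_whale]
    odontoceti = list(odontoceti_non_sperm) + [sperm_whale]
    return [
        ("mysticeti", ("crown", list(mysticeti))),
        ("odontoceti", ("crown", odontoceti)),
        ("cetacean_stem", ("stem", cetacea)),
        ("mysticeti_stem", ("stem", list(mysticeti))),
        ("odontoceti_stem", ("stem", list(odontoceti_non_sperm))),
        ("sperm_whale_ancestor", ("terminal", sperm_whale)),
    ]
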