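"""Recursive accession-set partitioning on homozygous genotypes.

At every step the highest-DS *usable* marker is selected for the current
accession subset.  Usable means: at least two homozygous genotype classes are
present within the subset, and every child it would produce is strictly
smaller than the subset (het/missing accessions are duplicated into every
child for information redundancy, so an unproductive marker could otherwise
copy the whole subset downward forever).  Subsets at or below the significance
threshold, and subsets no marker can split, become leaves.

With marker reuse disabled, a marker selected anywhere in the tree is excluded
from all later selections; construction is depth-first, parent before
children, branches in ascending allele order, so outputs are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .matrix_io import GenotypeMatrix, HET_CODE, MISSING_CODE
from .scoring import HET_CLASS_ALLELE, rank_markers, tally_marker
from .tree_model import DecisionTree, MarkerNode, Node, SubsetNode

__all__ = ["PartitionConfig", "partition_subset", "build_tree", "leaf_multiplicity"]

logger = logging.getLogger(__name__)


@dataclass
class PartitionConfig:
    """Build-time knobs.

    subset_size_threshold
        a subset of this size or smaller is output as a leaf (1 forces
        per-accession resolution),
    allow_marker_reuse
        whether a marker already used at one node may be selected again in
        other branches,
    treat_het_as_class
        heterozygotes become their own branch class "2/2" instead of being
        duplicated (bi-allelic matrices only),
    ds_denominator
        convention for the homozygous fractions inside DS ("homozygous" or
        "all").
    """

    subset_size_threshold: int = 1
    allow_marker_reuse: bool = False
    treat_het_as_class: bool = False
    ds_denominator: str = "homozygous"

    def __post_init__(self) -> None:
        if self.subset_size_threshold < 1:
            raise ValueError("subset_size_threshold must be >= 1")
        if self.ds_denominator not in ("homozygous", "all"):
            raise ValueError(f"unknown ds_denominator {self.ds_denominator!r}")


def _split_children(
    matrix: GenotypeMatrix,
    subset: Sequence[str],
    marker: str,
    het_as_class: bool,
) -> dict[str, list[str]]:
    """Children of one candidate marker: per homozygous class, the accessions
    homozygous for it plus every het/missing accession of the subset."""
    row = matrix.codes[matrix.marker_row(marker)]
    codes = {a: int(row[matrix.accession_col(a)]) for a in subset}
    alleles = sorted({c for c in codes.values() if c >= 0})
    if het_as_class and any(c == HET_CODE for c in codes.values()):
        alleles = sorted(set(alleles) | {HET_CLASS_ALLELE})
    children: dict[str, list[str]] = {}
    for allele in alleles:
        members = []
        for a in subset:
            c = codes[a]
            if c == allele:
                members.append(a)
            elif c == MISSING_CODE:
                members.append(a)
            elif c == HET_CODE and not het_as_class:
                members.append(a)
            elif c == HET_CODE and het_as_class and allele == HET_CLASS_ALLELE:
                members.append(a)
        children[f"{allele}/{allele}"] = members
    return children


def partition_subset(
    matrix: GenotypeMatrix,
    subset: Sequence[str],
    excluded: Iterable[str] = (),
    het_as_class: bool = False,
    denominator: str = "homozygous",
) -> tuple[str, dict[str, list[str]]] | None:
    """One greedy partitioning step.

    Returns (chosen marker id, branch genotype -> child accession list) for
    the highest-DS usable marker, or None (NO_SPLIT) when no marker yields a
    valid split.
    """
    if len(subset) < 2:
        return None
    ranking = rank_markers(
        matrix,
        subset,
        excluded=excluded,
        het_as_class=het_as_class,
        denominator=denominator,
    )
    for marker, ds in ranking:
        if ds <= 0.0:
            break  # ranking is sorted; TG < 2 from here on
        stats = tally_marker(matrix, marker, subset, het_as_class=het_as_class)
        if stats.tg < 2:
            continue
        children = _split_children(matrix, subset, marker, het_as_class)
        if all(len(c) < len(subset) for c in children.values()):
            return marker, children
    return None


def build_tree(matrix: GenotypeMatrix, config: PartitionConfig | None = None) -> DecisionTree:
    """Recursively partition the full accession set into a decision tree.

    Depth-first with an explicit work stack; leaves receive indices in
    left-to-right order.  When reuse is disabled, selection anywhere in the
    tree excludes the marker globally (in construction order).
    """
    if config is None:
        config = PartitionConfig()
    excluded: set[str] = set()
    leaf_counter = 0

    # stack entries: (subset, path, attach) where attach(node) hooks the
    # finished node into its parent; children pushed reversed so the lowest
    # allele branch is processed first.
    result: dict[str, Node] = {}

    def attach_root(node: Node) -> None:
        result["root"] = node

    stack: list[tuple[list[str], list[tuple[str, str]], object]] = [
        (list(matrix.accession_ids), [], attach_root)
    ]
    while stack:
        subset, path, attach = stack.pop()
        split = None
        if len(subset) > config.subset_size_threshold:
            split = partition_subset(
                matrix,
                subset,
                excluded=excluded,
                het_as_class=config.treat_het_as_class,
                denominator=config.ds_denominator,
            )
            if split is None:
                logger.warning(
                    "subset of size %d exceeds threshold %d but no marker can "
                    "split it; emitting it as a leaf",
                    len(subset),
                    config.subset_size_threshold,
                )
        if split is None:
            leaf_counter += 1
            attach(SubsetNode(subset_index=leaf_counter, accessions=list(subset), path=path))
            continue
        marker, children = split
        if not config.allow_marker_reuse:
            excluded.add(marker)
        node = MarkerNode(marker_id=marker, accessions=list(subset))
        for label in sorted(children):  # reserve branch slots in allele order
            node.branches[label] = None  # type: ignore[assignment]
        attach(node)

        def make_attach(parent: MarkerNode, label: str):
            def _attach(child: Node) -> None:
                parent.branches[label] = child

            return _attach

        for label in sorted(children, reverse=True):
            stack.append((children[label], path + [(marker, label)], make_attach(node, label)))

    tree = DecisionTree(
        root=result["root"],
        marker_rows={},
        accession_ids=list(matrix.accession_ids),
    )
    for node, _, _ in tree.iter_nodes():
        if isinstance(node, MarkerNode):
            tree.marker_rows[node.marker_id] = matrix.marker_row(node.marker_id)
    return tree


def leaf_multiplicity(tree: DecisionTree) -> dict[str, int]:
    """How many leaves contain each accession (>= 2 indicates a het/missing
    call duplicated the accession somewhere along its decision paths)."""
    mult: dict[str, int] = {a: 0 for a in tree.accession_ids}
    for leaf in tree.leaves():
        for a in leaf.accessions:
            mult[a] = mult.get(a, 0) + 1
    return mult
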