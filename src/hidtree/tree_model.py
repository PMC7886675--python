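"""Hierarchical decision tree over homozygous genotypes.

The tree alternates two node kinds: marker nodes, whose outgoing branches are
labelled with homozygous genotype tokens ("0/0", "1/1", ... and "2/2" when
heterozygotes form their own class), and subset leaf nodes holding the
accessions that survived the root-to-leaf genotype path.  A root-to-leaf path
is an identification recipe: genotype the listed markers and an accession
matching every homozygous call on the path belongs to that leaf.

Three text outputs mirror the classic tool-chain:

``HiDTree.txt``
    versioned, indented pre-order rendering of the tree (machine-parseable,
    see :func:`read_hidtree`),
``MarkerList.txt``
    markers in first-use order with their original matrix row indices,
``SubsetList.txt``
    one line per leaf: index, accession list, and the path as
    ``marker:genotype`` steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Union

__all__ = [
    "MarkerNode",
    "SubsetNode",
    "DecisionTree",
    "write_outputs",
    "read_hidtree",
    "path_to_accession",
    "tree_stats",
    "export_dot",
]

HIDTREE_HEADER = "# HiDTree v1"


@dataclass
class SubsetNode:
    """Leaf: an output accession subset and its identification path."""

    subset_index: int
    accessions: list[str]
    path: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class MarkerNode:
    """Internal node: a selected marker branching on its homozygous genotypes."""

    marker_id: str
    branches: dict[str, "Node"] = field(default_factory=dict)
    #: accession subset this node was asked to partition (diagnostic, not serialised)
    accessions: list[str] = field(default_factory=list)


Node = Union[MarkerNode, SubsetNode]


@dataclass
class DecisionTree:
    root: Node
    #: original matrix row index of each used marker (0-based)
    marker_rows: dict[str, int] = field(default_factory=dict)
    #: every accession of the input matrix, in matrix column order
    accession_ids: list[str] = field(default_factory=list)

    def iter_nodes(self) -> Iterator[tuple[Node, int, str | None]]:
        """Pre-order traversal yielding (node, depth, incoming branch label)."""
        stack: list[tuple[Node, int, str | None]] = [(self.root, 0, None)]
        while stack:
            node, depth, label = stack.pop()
            yield node, depth, label
            if isinstance(node, MarkerNode):
                for lab, child in reversed(list(node.branches.items())):
                    stack.append((child, depth + 1, lab))

    def leaves(self) -> list[SubsetNode]:
        return [n for n, _, _ in self.iter_nodes() if isinstance(n, SubsetNode)]

    def rederive_paths(self) -> None:
        """Recompute every leaf's stored path from a root traversal."""
        stack: list[tuple[Node, list[tuple[str, str]]]] = [(self.root, [])]
        while stack:
            node, path = stack.pop()
            if isinstance(node, SubsetNode):
                node.path = path
            else:
                for lab, child in reversed(list(node.branches.items())):
                    stack.append((child, path + [(node.marker_id, lab)]))


def tree_stats(tree: DecisionTree) -> dict:
    """Node counts, distinct used markers, max depth and leaf sizes."""
    marker_nodes = 0
    subset_nodes = 0
    distinct: set[str] = set()
    max_depth = 0
    leaf_sizes: list[int] = []
    for node, depth, _ in tree.iter_nodes():
        max_depth = max(max_depth, depth)
        if isinstance(node, MarkerNode):
            marker_nodes += 1
            distinct.add(node.marker_id)
        else:
            subset_nodes += 1
            leaf_sizes.append(len(node.accessions))
    return {
        "marker_nodes": marker_nodes,
        "distinct_markers": len(distinct),
        "subset_nodes": subset_nodes,
        "max_depth": max_depth,
        "leaf_sizes": leaf_sizes,
    }


def path_to_accession(tree: DecisionTree, accession: str) -> list[list[tuple[str, str]]]:
    """All root-to-leaf identification paths whose leaf contains the accession.

    One path per containing leaf, ordered by leaf index.  Each step is a
    (marker id, homozygous genotype) pair — the PCR-validation recipe.
    """
    leaves = sorted(tree.leaves(), key=lambda leaf: leaf.subset_index)
    paths = [list(leaf.path) for leaf in leaves if accession in leaf.accessions]
    if not paths:
        raise KeyError(f"accession {accession!r} not found in any leaf")
    return paths


# ---------------------------------------------------------------------------
# text outputs


def _render_node(node: Node) -> str:
    if isinstance(node, MarkerNode):
        return f"MARKER {node.marker_id}"
    return f"SUBSET {node.subset_index} [{', '.join(node.accessions)}]"


def format_hidtree(tree: DecisionTree) -> str:
    lines = [HIDTREE_HEADER]
    for node, depth, label in tree.iter_nodes():
        prefix = "  " * depth
        if label is not None:
            prefix += f"{label} -> "
        lines.append(prefix + _render_node(node))
    return "\n".join(lines) + "\n"


def write_outputs(
    tree: DecisionTree,
    outdir: Union[str, Path],
    marker_index_base: int = 1,
) -> dict[str, Path]:
    """Write HiDTree.txt, MarkerList.txt and SubsetList.txt into outdir.

    Byte-deterministic for a given tree.  ``marker_index_base`` sets whether
    MarkerList row indices count from 0 or 1 (matrix row positions are
    conventionally quoted 1-based).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": outdir / "HiDTree.txt",
        "markers": outdir / "MarkerList.txt",
        "subsets": outdir / "SubsetList.txt",
    }
    paths["tree"].write_text(format_hidtree(tree))

    first_use: list[str] = []
    seen: set[str] = set()
    for node, _, _ in tree.iter_nodes():
        if isinstance(node, MarkerNode) and node.marker_id not in seen:
            seen.add(node.marker_id)
            first_use.append(node.marker_id)
    with open(paths["markers"], "wt") as fh:
        fh.write("marker_id\trow_index\n")
        for marker in first_use:
            row = tree.marker_rows.get(marker)
            idx = "NA" if row is None else str(row + marker_index_base)
            fh.write(f"{marker}\t{idx}\n")

    with open(paths["subsets"], "wt") as fh:
        fh.write("subset\taccessions\tpath\n")
        for leaf in sorted(tree.leaves(), key=lambda n: n.subset_index):
            path_str = ";".join(f"{m}:{g}" for m, g in leaf.path) or "."
            fh.write(f"{leaf.subset_index}\t{','.join(leaf.accessions)}\t{path_str}\n")
    return paths


def read_hidtree(path: Union[str, Path]) -> DecisionTree:
    """Parse a HiDTree.txt file back into a DecisionTree.

    Marker row indices are not stored in that file, so ``marker_rows`` of the
    result is empty; topology, branch labels, subsets and paths round-trip.
    """
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("# HiDTree"):
        raise ValueError(f"{path}: not a HiDTree file (missing header)")
    nodes: list[tuple[int, str | None, Node]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        stripped = line.lstrip(" ")
        indent = len(line) - len(stripped)
        if indent % 2:
            raise ValueError(f"{path}:{lineno}: odd indentation")
        depth = indent // 2
        label: str | None = None
        if " -> " in stripped:
            label, stripped = stripped.split(" -> ", 1)
        if stripped.startswith("MARKER "):
            node: Node = MarkerNode(marker_id=stripped[len("MARKER "):].strip())
        elif stripped.startswith("SUBSET "):
            body = stripped[len("SUBSET "):]
            idx_str, _, rest = body.partition(" ")
            rest = rest.strip()
            if not (rest.startswith("[") and rest.endswith("]")):
                raise ValueError(f"{path}:{lineno}: malformed SUBSET line")
            inner = rest[1:-1].strip()
            accs = [a.strip() for a in inner.split(",")] if inner else []
            node = SubsetNode(subset_index=int(idx_str), accessions=accs)
        else:
            raise ValueError(f"{path}:{lineno}: unrecognised node line {stripped!r}")
        nodes.append((depth, label, node))
    if not nodes:
        raise ValueError(f"{path}: no nodes")
    root_depth, root_label, root = nodes[0]
    if root_depth != 0 or root_label is not None:
        raise ValueError(f"{path}: first node must be an unlabelled root")
    ancestry: list[Node] = [root]
    for depth, label, node in nodes[1:]:
        if depth < 1 or depth > len(ancestry):
            raise ValueError(f"{path}: inconsistent nesting at node {node}")
        parent = ancestry[depth - 1]
        if not isinstance(parent, MarkerNode) or label is None:
            raise ValueError(f"{path}: child node without a marker parent/branch label")
        parent.branches[label] = node
        ancestry[depth:] = [node]
    accessions: list[str] = []
    seen_acc: set[str] = set()
    tree = DecisionTree(root=root)
    for leaf in tree.leaves():
        for a in leaf.accessions:
            if a not in seen_acc:
                seen_acc.add(a)
                accessions.append(a)
    tree.accession_ids = accessions
    tree.rederive_paths()
    return tree


# ---------------------------------------------------------------------------
# visualization


def export_dot(tree: DecisionTree) -> str:
    """Graphviz DOT rendering: ellipses for marker nodes, boxes for subset
    leaves, edges labelled with the branch homozygous genotype."""
    lines = ["digraph hidtree {", '  node [fontname="Helvetica"];']
    ids: dict[int, str] = {}
    counter = 0
    edges: list[str] = []
    for node, _, _ in tree.iter_nodes():
        name = f"n{counter}"
        ids[id(node)] = name
        counter += 1
        if isinstance(node, MarkerNode):
            lines.append(f'  {name} [shape=ellipse, label="{node.marker_id}"];')
        else:
            label = f"subset {node.subset_index}\\n({len(node.accessions)} acc)"
            lines.append(f'  {name} [shape=box, label="{label}"];')
    for node, _, _ in tree.iter_nodes():
        if isinstance(node, MarkerNode):
            for lab, child in node.branches.items():
                edges.append(f'  {ids[id(node)]} -> {ids[id(child)]} [label="{lab}"];')
    lines.extend(edges)
    lines.append("}")
    return "\n".join(lines) + "\n"
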