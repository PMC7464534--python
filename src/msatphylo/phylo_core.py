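"""Rooted phylogenetic trees with branch lengths, Newick I/O, and trait tables.

Branch lengths are in millions of years (My) throughout; every comparative
method in this package inherits its rate units from that convention.
Newick parsing/serialisation is delegated to dendropy; the in-memory
structure is a light node/parent-pointer tree optimised for the pruning
passes used by the Brownian-motion and Mk machinery.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Node",
    "PhyloTree",
    "read_newick",
    "write_newick",
    "prune_to",
    "is_ultrametric",
    "resolve_polytomies",
    "normalize_label",
    "read_trait_table",
    "TRAIT_COLUMNS",
]


class NewickParseError(ValueError):
    """Malformed Newick input (unbalanced parentheses, duplicate tips, ...)."""


class Node:
    """A tree node; ``length`` is the branch above the node (None at the root)."""

    __slots__ = ("label", "length", "parent", "children", "id")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.parent: "Node | None" = None
        self.children: list["Node"] = []
        self.id: int = -1  # assigned by PhyloTree._index()

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else "node"
        return f"<{kind} {self.label!r} len={self.length}>"


class PhyloTree:
    """Rooted tree with unique tip labels and non-negative branch lengths.

    Node ids are assigned in postorder (tips first encountered during the
    postorder sweep), so ``postorder()[-1]`` is always the root.  The
    pruning algorithms rely on this ordering.
    """

    def __init__(self, root: Node):
        self.root = root
        self._postorder: list[Node] | None = None
        self._validate()

    # -- structure ---------------------------------------------------------
    def _validate(self) -> None:
        seen: set[str] = set()
        for node in self.postorder():
            if node.is_tip:
                if not node.label:
                    raise NewickParseError("tip with empty label")
                if node.label in seen:
                    raise NewickParseError(f"duplicate tip label {node.label!r}")
                seen.add(node.label)
            if node is not self.root:
                if node.length is None:
                    node.length = 0.0
                if node.length < 0:
                    raise ValueError(
                        f"negative branch length {node.length} above {node.label!r}"
                    )

    def invalidate(self) -> None:
        """Drop cached traversals after a structural edit."""
        self._postorder = None

    def postorder(self) -> list[Node]:
        if self._postorder is None:
            order: list[Node] = []
            stack = [(self.root, False)]
            while stack:
                node, expanded = stack.pop()
                if expanded:
                    order.append(node)
                else:
                    stack.append((node, True))
                    for child in reversed(node.children):
                        stack.append((child, False))
            self._postorder = order
            for i, node in enumerate(order):
                node.id = i
        return self._postorder

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def depths(self) -> dict[Node, float]:
        """Root-to-node path lengths."""
        out: dict[Node, float] = {self.root: 0.0}
        for node in self.preorder():
            if node is not self.root:
                out[node] = out[node.parent] + (node.length or 0.0)
        return out

    def is_bifurcating(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.postorder())

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root))

    def vcv(self) -> tuple[np.ndarray, list[str]]:
        """Shared-path-length (Brownian covariance) matrix among tips.

        C[i, j] is the branch length shared by the root-to-tip paths of
        tips i and j; the diagonal holds tip depths.
        """
        tips = self.tips()
        n = len(tips)
        depths = self.depths()
        # tip sets per node, accumulated in postorder
        below: dict[Node, list[int]] = {}
        C = np.zeros((n, n))
        index = {t: i for i, t in enumerate(tips)}
        for node in self.postorder():
            if node.is_tip:
                below[node] = [index[node]]
                C[index[node], index[node]] = depths[node]
            else:
                kids = [below[c] for c in node.children]
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        for i in kids[a]:
                            for j in kids[b]:
                                C[i, j] = C[j, i] = depths[node]
                below[node] = [i for k in kids for i in k]
        return C, [t.label for t in tips]

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree with {self.n_tips} tips>"


# -- Newick I/O -------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = Node(label, dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return PhyloTree(convert(dtree.seed_node))


def read_newick(source: str | os.PathLike) -> list[PhyloTree]:
    """Read one or more trees from a Newick file path or literal string.

    A multi-tree file (one Newick per line) yields one PhyloTree per tree,
    which is how posterior tree samples are represented on disk.
    """
    text: str
    if isinstance(source, (str,)) and ("(" in source and ";" in source) and not os.path.exists(source):
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    try:
        tlist = dendropy.TreeList.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"Newick parse failure: {exc}") from exc
    if not tlist:
        raise NewickParseError("no trees found in input")
    return [_from_dendropy(t) for t in tlist]


def _newick_string(node: Node, fmt: str) -> str:
    if node.is_tip:
        body = node.label.replace(" ", "_")
    else:
        inner = ",".join(_newick_string(c, fmt) for c in node.children)
        body = f"({inner})"
        if node.label:
            body += node.label.replace(" ", "_")
    if node.length is not None:
        body += ":" + (fmt % node.length)
    return body


def write_newick(trees: PhyloTree | Sequence[PhyloTree], path: str | None = None,
                 precision: int = 17) -> str:
    """Serialise tree(s) to Newick; high default precision so that
    likelihoods are reproducible across a round trip."""
    if isinstance(trees, PhyloTree):
        trees = [trees]
    fmt = f"%.{precision}g"
    text = "\n".join(_newick_string(t.root, fmt) + ";" for t in trees) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# -- tree surgery -----------------------------------------------------------

def prune_to(tree: PhyloTree, taxa: Iterable[str]) -> PhyloTree:
    """Induced subtree on ``taxa``: unsampled tips removed, degree-2 nodes
    suppressed with branch lengths summed, so tip-to-tip path lengths are
    preserved."""
    keep = set(taxa)
    have = set(tree.tip_labels)
    unknown = keep - have
    if unknown:
        raise KeyError(f"taxa not in tree: {sorted(unknown)}")
    if len(keep) < 2:
        raise ValueError("need at least 2 taxa to prune to")
    work = tree.copy()

    def reduce(node: Node) -> Node | None:
        if node.is_tip:
            return node if node.label in keep else None
        new_children = []
        for child in node.children:
            sub = reduce(child)
            if sub is not None:
                new_children.append(sub)
        if not new_children:
            return None
        if len(new_children) == 1:
            only = new_children[0]
            only.length = (only.length or 0.0) + (node.length or 0.0)
            only.parent = None
            return only
        node.children = []
        for child in new_children:
            node.add_child(child)
        return node

    new_root = reduce(work.root)
    assert new_root is not None
    new_root.parent = None
    # the induced root keeps no stem branch
    new_root.length = None
    return PhyloTree(new_root)


def is_ultrametric(tree: PhyloTree, rel_tol: float = 1e-6) -> bool:
    """True iff all root-to-tip path lengths agree to relative tolerance."""
    depths = tree.depths()
    d = np.array([depths[t] for t in tree.tips()])
    span = d.max()
    if span == 0:
        return True
    return bool((d.max() - d.min()) <= rel_tol * span)


def resolve_polytomies(tree: PhyloTree) -> PhyloTree:
    """Arbitrary bifurcating resolution of multifurcations with zero-length
    internal branches.  BM likelihoods and ancestral estimates are invariant
    to the arbitrary choice (tested); contrast algorithms require a
    bifurcating tree."""
    work = tree.copy()
    for node in list(work.postorder()):
        while len(node.children) > 2:
            a = node.children.pop()
            b = node.children.pop()
            joint = Node(None, 0.0)
            joint.add_child(a)
            joint.add_child(b)
            node.add_child(joint)
    work.invalidate()
    return PhyloTree(work.root)


# -- trait tables -----------------------------------------------------------

TRAIT_COLUMNS = [
    "species",
    "content_per_mbp",
    "total_bp",
    "centromere_type",
    "chromosome_number",
    "genome_size_mbp",
    "busco_score",
    "order_label",
]


def normalize_label(label: str) -> str:
    """Unify whitespace and underscores so Newick tip labels join cleanly
    to trait-table species names."""
    return "_".join(str(label).strip().split()).replace(" ", "_")


def read_trait_table(path: str | os.PathLike | io.IOBase) -> pd.DataFrame:
    """Read the per-species trait TSV (see TRAIT_COLUMNS for the schema).

    Optional columns may be absent or empty; ``species`` is normalised and
    set as a plain column (not index).  Numeric fields are validated
    non-negative; centromere_type is checked against its two levels.
    """
    df = pd.read_csv(path, sep="\t")
    if "species" not in df.columns:
        raise ValueError("trait table must contain a 'species' column")
    df = df.copy()
    df["species"] = df["species"].map(normalize_label)
    if df["species"].duplicated().any():
        dups = df.loc[df["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicate species in trait table: {dups}")
    for col in ("content_per_mbp", "total_bp", "chromosome_number",
                "genome_size_mbp", "busco_score"):
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            if (vals.dropna() < 0).any():
                raise ValueError(f"negative values in column {col!r}")
            df[col] = vals
    if "centromere_type" in df.columns:
        bad = set(df["centromere_type"].dropna().unique()) - {
            "holocentric", "monocentric"}
        if bad:
            raise ValueError(f"unknown centromere_type values: {sorted(bad)}")
    return df
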