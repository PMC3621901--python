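"""Phylogenetic tree structure, node classification and variant dispatch.

Internal (non-root) nodes — "down nodes" — are classified ``down_0`` ..
``down_3`` by which of their two children are terminal: x = 1*(left child is a
leaf) + 2*(right child is a leaf).  Orthogonally, the per-node rescaling flags
scalersSet (S: an old stored scaler must be removed) and scalerNode (N: a new
scaler must be computed) define a shortcut index T = 2S + N, a secondary
classification that lets the evaluator pick one of 4*4 = 16 specialised
down-node variants up front instead of branching per site inside the pass.

The computational root may be binary (2 children, the rooted convention used by
the transfer-accounting scenario) or trifurcating (3 children, the usual
unrooted convention); under a reversible model the likelihood is invariant to
the choice (pulley principle).
"""

from __future__ import annotations

from typing import Callable, Iterator

__all__ = [
    "Node",
    "PhyloTree",
    "TreeStructureError",
    "classify_node",
    "shortcut",
    "variant_id",
    "variant_table",
    "postorder",
    "nni_neighbors",
    "caterpillar_tree",
    "BRLEN_FLOOR",
]

#: Floor applied to proposed branch lengths to avoid degenerate P(t).
BRLEN_FLOOR = 1e-8


class TreeStructureError(ValueError):
    """Raised for malformed tree structures (cycles, bad degrees, bad labels)."""


class Node:
    """A tree node. Leaves carry a taxon index; internals carry children."""

    __slots__ = ("children", "parent", "length", "taxon", "label",
                 "scalers_set", "scaler_node")

    def __init__(self, length: float = 0.0, taxon: int | None = None,
                 label: str | None = None):
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length
        self.taxon = taxon
        self.label = label
        self.scalers_set = False  # S flag: old scaler stored, must be removed
        self.scaler_node = False  # N flag: compute a new scaler at this node

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def replace_child(self, old: "Node", new: "Node") -> None:
        i = self.children.index(old)
        self.children[i] = new
        new.parent = self

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = f"leaf {self.label or self.taxon}" if self.is_leaf else f"internal[{len(self.children)}]"
        return f"<Node {kind} len={self.length:g}>"


class PhyloTree:
    """A rooted-for-computation phylogeny over a fixed taxon set."""

    def __init__(self, root: Node, taxon_labels: list[str]):
        self.root = root
        self.taxon_labels = list(taxon_labels)
        self.validate()

    @classmethod
    def from_root(cls, root: Node) -> "PhyloTree":
        """Build from a linked node structure whose leaves carry labels."""
        labels = [n.label for n in postorder(root) if n.is_leaf]
        if any(lbl is None for lbl in labels):
            raise TreeStructureError("unlabelled leaf")
        if len(set(labels)) != len(labels):
            raise TreeStructureError("duplicate leaf labels")
        index = {lbl: i for i, lbl in enumerate(labels)}
        for n in postorder(root):
            if n.is_leaf:
                n.taxon = index[n.label]
        return cls(root, labels)

    def validate(self) -> None:
        seen_taxa = set()
        for node in postorder(self.root):
            if node.is_leaf:
                if node.taxon is None or not (0 <= node.taxon < len(self.taxon_labels)):
                    raise TreeStructureError("leaf with invalid taxon index")
                if node.taxon in seen_taxa:
                    raise TreeStructureError("taxon appears twice")
                seen_taxa.add(node.taxon)
            elif node is not self.root and len(node.children) != 2:
                raise TreeStructureError("non-root internal node must be binary")
            elif node is self.root and len(node.children) not in (2, 3):
                raise TreeStructureError("root must have 2 or 3 children")
        if len(seen_taxa) != len(self.taxon_labels):
            raise TreeStructureError("leaf count does not match taxon set")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_labels)

    def postorder(self) -> Iterator[Node]:
        return postorder(self.root)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    def down_nodes(self) -> list[Node]:
        return [n for n in self.internal_nodes() if n is not self.root]

    def edges(self) -> list[Node]:
        """All branches, identified by their child node."""
        return [n for n in self.postorder() if n.parent is not None]

    def internal_edges(self) -> list[Node]:
        """Branches whose child end is an internal node (candidate NNI edges)."""
        return [n for n in self.down_nodes()]

    def total_length(self) -> float:
        return sum(n.length for n in self.edges())

    def copy(self) -> tuple["PhyloTree", dict[Node, Node]]:
        """Deep-copy the topology; returns the copy and an old->new node map."""
        mapping: dict[Node, Node] = {}

        def rec(node: Node) -> Node:
            new = Node(length=node.length, taxon=node.taxon, label=node.label)
            new.scalers_set = node.scalers_set
            new.scaler_node = node.scaler_node
            mapping[node] = new
            for ch in node.children:
                new.add_child(rec(ch))
            return new

        new_root = rec(self.root)
        return PhyloTree(new_root, self.taxon_labels), mapping

    def leaf_mask(self, node: Node) -> int:
        """Bitmask of taxon indices under ``node``."""
        if node.is_leaf:
            return 1 << node.taxon
        mask = 0
        for ch in node.children:
            mask |= self.leaf_mask(ch)
        return mask

    def splits(self) -> frozenset[int]:
        """Non-trivial bipartitions as canonical taxon bitmasks.

        Bit k stands for the k-th taxon label in sorted order — not the
        internal taxon index — so split sets are comparable across any trees
        over the same label set.  A split is stored as the side not containing
        the first label, making it invariant to rooting.
        """
        n = self.n_taxa
        full = (1 << n) - 1
        rank = {lbl: i for i, lbl in enumerate(sorted(self.taxon_labels))}
        out = set()
        masks: dict[Node, int] = {}
        for node in self.postorder():
            if node.is_leaf:
                masks[node] = 1 << rank[self.taxon_labels[node.taxon]]
            else:
                masks[node] = 0
                for ch in node.children:
                    masks[node] |= masks[ch]
        for node in self.postorder():
            if node.parent is None:
                continue
            m = masks[node]
            if m & 1:
                m = full & ~m
            if 2 <= bin(m).count("1") <= n - 2:
                out.add(m)
        return frozenset(out)

    def newick(self, include_lengths: bool = True) -> str:
        from .io_formats import write_newick

        return write_newick(self, include_lengths=include_lengths)


def postorder(root: Node) -> Iterator[Node]:
    """Children-first traversal; raises on cycles."""
    seen: set[int] = set()
    stack: list[tuple[Node, bool]] = [(root, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded:
            yield node
            continue
        if id(node) in seen:
            raise TreeStructureError("cycle detected in tree")
        seen.add(id(node))
        stack.append((node, True))
        for ch in reversed(node.children):
            stack.append((ch, False))


def classify_node(node: Node) -> int:
    """down_x class of an internal node: x = left-is-leaf + 2*right-is-leaf."""
    if node.is_leaf:
        raise TreeStructureError("cannot classify a terminal node")
    if len(node.children) != 2:
        raise TreeStructureError("classification requires a binary node")
    left, right = node.children
    return (1 if left.is_leaf else 0) + 2 * (1 if right.is_leaf else 0)


def shortcut(S: int, N: int) -> int:
    """Scaler shortcut index T = 2S + N for flags S (scalersSet), N (scalerNode)."""
    if S not in (0, 1) or N not in (0, 1):
        raise ValueError("S and N must be 0 or 1")
    return 2 * S + N


def variant_id(x: int, T: int) -> str:
    if x not in range(4) or T not in range(4):
        raise ValueError("variant indices must lie in 0..3")
    return f"down_{x}_{T}"


def variant_table() -> list[str]:
    """All 16 down-node variant identifiers down_x_T."""
    return [variant_id(x, T) for x in range(4) for T in range(4)]


# ---------------------------------------------------------------------------
# topology surgery
# ---------------------------------------------------------------------------

def swap_subtrees(a: Node, b: Node) -> None:
    """Exchange two subtrees (neither ancestral to the other), keeping branch
    lengths attached to their subtrees."""
    pa, pb = a.parent, b.parent
    if pa is None or pb is None:
        raise TreeStructureError("cannot swap the root")
    ia = pa.children.index(a)
    ib = pb.children.index(b)
    pa.children[ia], pb.children[ib] = b, a
    a.parent, b.parent = pb, pa


def _nni_partners(v: Node) -> tuple[list[Node], list[Node]]:
    """For internal edge (parent(v), v): v-side subtrees and the exchangeable
    subtrees on the parent side."""
    u = v.parent
    if u is None or v.is_leaf:
        raise TreeStructureError("NNI requires an internal edge")
    others = [c for c in u.children if c is not v]
    if u.parent is None and len(u.children) == 2:
        # binary root: the unrooted edge continues through the sibling
        sib = others[0]
        if sib.is_leaf:
            raise TreeStructureError("edge is terminal in the unrooted sense")
        return list(v.children), list(sib.children)
    return list(v.children), others


def nni_neighbors(tree: PhyloTree, edge_child: Node) -> list[PhyloTree]:
    """The two nearest-neighbour-interchange topologies across an internal edge.

    ``edge_child`` is the child end of the edge.  Returns two independent tree
    copies; the input tree is untouched.  Branch lengths travel with their
    subtrees.
    """
    vside, uside = _nni_partners(edge_child)  # validates
    out = []
    for u_pick, v_pick in _nni_choices(edge_child):
        new_tree, mapping = tree.copy()
        swap_subtrees(mapping[v_pick], mapping[u_pick])
        new_tree.validate()
        out.append(new_tree)
    return out


def _nni_choices(v: Node) -> list[tuple[Node, Node]]:
    """The two (parent-side, v-side) subtree pairs whose exchange yields the
    two distinct NNI rearrangements of edge (parent(v), v)."""
    vside, uside = _nni_partners(v)
    if len(uside) == 1:
        return [(uside[0], vside[0]), (uside[0], vside[1])]
    # parent side offers two subtrees (trifurcating root or binary-root sibling)
    return [(uside[0], vside[0]), (uside[1], vside[0])]


def reroot_on_edge(tree: PhyloTree, edge_child: Node, fraction: float = 0.5) -> PhyloTree:
    """Re-root the unrooted topology on the branch above ``edge_child``.

    Returns a new binary-rooted tree whose root splits the chosen branch at
    ``fraction`` of its length (child side gets ``fraction``).  A former binary
    root of degree 2 is suppressed with its two branch lengths merged, so the
    unrooted topology — and, under a reversible model, the likelihood — is
    preserved (pulley principle).
    """
    if edge_child.parent is None:
        raise TreeStructureError("cannot reroot on the root")
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    # undirected adjacency with edge lengths
    adj: dict[int, list[tuple[Node, float]]] = {}
    obj: dict[int, Node] = {}
    for node in tree.postorder():
        obj[id(node)] = node
        adj.setdefault(id(node), [])
        if node.parent is not None:
            adj[id(node)].append((node.parent, node.length))
            adj.setdefault(id(node.parent), []).append((node, node.length))

    def build(node: Node, come_from: Node | None, length: float) -> Node:
        neigh = [(n, w) for n, w in adj[id(node)] if n is not come_from]
        if not neigh and node.is_leaf:
            return Node(length=length, taxon=node.taxon,
                        label=tree.taxon_labels[node.taxon])
        if len(neigh) == 1:
            # degree-2 vertex (the former binary root): suppress it
            nxt, w = neigh[0]
            return build(nxt, node, length + w)
        out = Node(length=length)
        for nxt, w in neigh:
            out.add_child(build(nxt, node, w))
        return out

    u = edge_child.parent
    t = edge_child.length
    root = Node()
    root.add_child(build(edge_child, u, fraction * t))
    root.add_child(build(u, edge_child, (1.0 - fraction) * t))
    return PhyloTree.from_root(_relabel(root, tree))


def _relabel(root: Node, tree: PhyloTree) -> Node:
    for n in postorder(root):
        if n.is_leaf and n.label is None:
            n.label = tree.taxon_labels[n.taxon]
    return root


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def caterpillar_tree(n_taxa: int, branch_length: float = 0.1,
                     labels: list[str] | None = None) -> PhyloTree:
    """Binary-rooted caterpillar: every down node except the deepest pairs one
    leaf with one internal child; the root pairs a leaf with the chain.

    This is the tree used by the transfer-accounting scenario.
    """
    if n_taxa < 3:
        raise TreeStructureError("need at least 3 taxa")
    if labels is None:
        labels = [f"t{i}" for i in range(n_taxa)]
    leaves = [Node(length=branch_length, taxon=i, label=labels[i]) for i in range(n_taxa)]
    node = Node(length=branch_length)
    node.add_child(leaves[0])
    node.add_child(leaves[1])
    for i in range(2, n_taxa - 1):
        up = Node(length=branch_length)
        up.add_child(node)
        up.add_child(leaves[i])
        node = up
    root = Node()
    root.add_child(node)
    root.add_child(leaves[n_taxa - 1])
    return PhyloTree(root, labels)
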