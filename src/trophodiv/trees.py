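"""Rooted binary phylogenies: data model, Newick/Nexus I/O, pruning, traversal.

The in-memory representation is array-based and postorder-numbered: node ``i``'s
children always have indices ``< i`` and the root is the last node.  Tips are
the nodes without children.  This layout is what the likelihood kernel, the
simulators and the signal statistics traverse; parsing, serialization and
taxon-set extraction are delegated to :mod:`dendropy`.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np

__all__ = [
    "TreeError",
    "ParseError",
    "PolytomyError",
    "Phylogeny",
    "TipStateMap",
    "read_newick",
    "read_nexus",
    "write_newick",
    "prune_to_labels",
]


class TreeError(ValueError):
    """Invalid tree structure or content."""


class ParseError(TreeError):
    """Malformed serialized tree."""


class PolytomyError(TreeError):
    """Tree contains a node with more than two children."""


class Phylogeny:
    """A rooted binary phylogeny with branch lengths in time units.

    Parameters
    ----------
    left, right : arrays of int
        Child indices per node, ``-1`` for tips.  Children precede parents
        (postorder numbering); the root is node ``n_nodes - 1``.
    blen : array of float
        Length of the edge above each node; the root entry is 0 unless the
        source tree carried a root edge.
    labels : sequence of str
        Tip label per node ('' for internal nodes).
    tag : str, optional
        Opaque per-tree tag (e.g. which backbone or replicate a tree came
        from); carried through I/O round trips only as metadata.
    """

    def __init__(self, left, right, blen, labels, tag: Optional[str] = None):
        self.left = np.asarray(left, dtype=np.int64)
        self.right = np.asarray(right, dtype=np.int64)
        self.blen = np.asarray(blen, dtype=np.float64)
        self.labels = list(labels)
        self.tag = tag
        self._validate()

    # ------------------------------------------------------------------ basic
    @property
    def n_nodes(self) -> int:
        return len(self.blen)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def is_tip(self) -> np.ndarray:
        return self.left < 0

    @property
    def tip_indices(self) -> np.ndarray:
        return np.nonzero(self.left < 0)[0]

    @property
    def n_tips(self) -> int:
        return int(np.sum(self.left < 0))

    @property
    def tip_labels(self) -> list:
        return [self.labels[i] for i in self.tip_indices]

    @property
    def total_branch_length(self) -> float:
        """Sum of all branch lengths, excluding any root edge."""
        s = float(self.blen.sum())
        return s - float(self.blen[self.root])

    def parent_array(self) -> np.ndarray:
        par = np.full(self.n_nodes, -1, dtype=np.int64)
        for i in range(self.n_nodes):
            if self.left[i] >= 0:
                par[self.left[i]] = i
                par[self.right[i]] = i
        return par

    def node_depths(self) -> np.ndarray:
        """Distance from the root to each node (root depth 0)."""
        depth = np.zeros(self.n_nodes)
        par = self.parent_array()
        for i in range(self.n_nodes - 2, -1, -1):
            depth[i] = depth[par[i]] + self.blen[i]
        return depth

    def tree_height(self) -> float:
        return float(self.node_depths()[self.tip_indices].max())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = self.node_depths()[self.tip_indices]
        h = d.max()
        return bool(h == 0 or (d.max() - d.min()) <= rel_tol * h)

    # ------------------------------------------------------------- validation
    def _validate(self) -> None:
        n = self.n_nodes
        if n < 1 or len(self.left) != n or len(self.right) != n or len(self.labels) != n:
            raise TreeError("inconsistent array lengths")
        seen_child = np.zeros(n, dtype=bool)
        for i in range(n):
            l, r = self.left[i], self.right[i]
            if (l < 0) != (r < 0):
                raise PolytomyError(
                    f"node {i} has exactly one child; binary trees required"
                )
            if l >= 0:
                if l >= i or r >= i:
                    raise TreeError("children must precede parents (postorder numbering)")
                if seen_child[l] or seen_child[r] or l == r:
                    raise TreeError(f"node {l if seen_child[l] else r} has multiple parents")
                seen_child[l] = seen_child[r] = True
        orphans = [i for i in range(n - 1) if not seen_child[i]]
        if orphans:
            raise TreeError(f"nodes {orphans} are unreachable from the root")
        if seen_child[n - 1]:
            raise TreeError("root must not have a parent")
        if np.any(~np.isfinite(self.blen)) or np.any(self.blen < 0):
            raise TreeError("all branch lengths must be finite and non-negative")
        tips = [self.labels[i] for i in self.tip_indices]
        if any(lb is None or str(lb).strip() == "" for lb in tips):
            raise TreeError("every tip must carry a non-empty label")
        if len(set(tips)) != len(tips):
            dup = sorted({t for t in tips if tips.count(t) > 1})
            raise TreeError(f"duplicate tip labels: {dup}")

    # ------------------------------------------------------------------- I/O
    @classmethod
    def _from_dendropy(cls, dtree: "dendropy.Tree", tag: Optional[str] = None) -> "Phylogeny":
        index = {}
        left, right, blen, labels = [], [], [], []
        for nd in dtree.postorder_node_iter():
            children = nd.child_nodes()
            if len(children) == 1:
                raise PolytomyError(
                    f"node {nd.label or '<unnamed>'} has a single child (unifurcation)"
                )
            if len(children) > 2:
                name = nd.label or (nd.taxon.label if nd.taxon else "<unnamed internal>")
                raise PolytomyError(
                    f"polytomy at node {name!r}: {len(children)} children (binary trees required)"
                )
            if children:
                label = ""
            else:
                label = (nd.taxon.label if nd.taxon is not None else nd.label) or ""
                label = label.strip()
            el = nd.edge.length
            if el is None:
                if nd.parent_node is None:
                    el = 0.0
                else:
                    raise TreeError(
                        f"missing branch length above node {label or nd.label or '<internal>'!r}"
                    )
            if el < 0:
                raise TreeError(f"negative branch length {el} above node {label!r}")
            index[nd] = len(blen)
            left.append(index[children[0]] if children else -1)
            right.append(index[children[1]] if children else -1)
            blen.append(float(el))
            labels.append(label)
        return cls(left, right, blen, labels, tag=tag)

    def _to_dendropy(self) -> "dendropy.Tree":
        taxa = dendropy.TaxonNamespace()
        nodes = [None] * self.n_nodes
        for i in range(self.n_nodes):
            nd = dendropy.Node()
            nd.edge.length = float(self.blen[i])
            if self.left[i] < 0:
                nd.taxon = taxa.new_taxon(label=self.labels[i])
            else:
                nd.add_child(nodes[self.left[i]])
                nd.add_child(nodes[self.right[i]])
            nodes[i] = nd
        tree = dendropy.Tree(taxon_namespace=taxa)
        tree.seed_node = nodes[-1]
        if self.blen[self.root] == 0:
            tree.seed_node.edge.length = None
        return tree

    @classmethod
    def from_newick(cls, text: str, tag: Optional[str] = None) -> "Phylogeny":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises schema-specific errors
            raise ParseError(f"Newick parse error: {exc}") from None
        return cls._from_dendropy(dtree, tag=tag)

    @classmethod
    def from_nexus(cls, text: str, tag: Optional[str] = None) -> "Phylogeny":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="nexus",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:
            raise ParseError(f"Nexus parse error: {exc}") from None
        return cls._from_dendropy(dtree, tag=tag)

    def to_newick(self, precision: int = 6) -> str:
        dtree = self._to_dendropy()
        text = dtree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=f".{precision}f",
            unquoted_underscores=True,
        )
        return text.strip() + "\n"

    # --------------------------------------------------------------- pruning
    def prune_to(self, labels: Iterable[str]) -> "Phylogeny":
        """Subtree induced by ``labels``; suppressed degree-2 nodes have their
        branch lengths summed, so patristic distances among retained tips are
        preserved exactly."""
        want = {str(s).strip() for s in labels}
        if len(want) < 2:
            raise TreeError("pruning needs at least 2 tip labels")
        have = set(self.tip_labels)
        unknown = sorted(want - have)
        if unknown:
            raise TreeError(f"unknown tip labels: {unknown}")

        # bottom-up: each node maps to (subtree, accumulated edge length) or None
        sub = [None] * self.n_nodes  # entries: (newick-free nested rep)
        for i in range(self.n_nodes):
            if self.left[i] < 0:
                if self.labels[i] in want:
                    sub[i] = ("tip", self.labels[i], float(self.blen[i]))
            else:
                a, b = sub[self.left[i]], sub[self.right[i]]
                if a is not None and b is not None:
                    sub[i] = ("node", (a, b), float(self.blen[i]))
                elif a is not None or b is not None:
                    kind, payload, el = a if a is not None else b
                    sub[i] = (kind, payload, el + float(self.blen[i]))
        top = sub[self.root]
        assert top is not None
        # renumber to postorder arrays; the retained root keeps no root edge
        left, right, blen, labs = [], [], [], []

        def emit(entry, is_root=False):
            kind, payload, el = entry
            if kind == "tip":
                left.append(-1)
                right.append(-1)
                blen.append(0.0 if is_root else el)
                labs.append(payload)
            else:
                a = emit(payload[0])
                b = emit(payload[1])
                left.append(a)
                right.append(b)
                blen.append(0.0 if is_root else el)
                labs.append("")
            return len(blen) - 1

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 10 * self.n_nodes + 1000))
        try:
            emit(top, is_root=True)
        finally:
            sys.setrecursionlimit(old)
        return Phylogeny(left, right, blen, labs, tag=self.tag)

    # ------------------------------------------------------------- distances
    def patristic_distances(self):
        """(labels, matrix): sum of branch lengths along the path between tips."""
        depth = self.node_depths()
        desc: list = [None] * self.n_nodes
        order = []
        dist = {}
        for i in range(self.n_nodes):
            if self.left[i] < 0:
                desc[i] = [i]
                order.append(i)
            else:
                a, b = desc[self.left[i]], desc[self.right[i]]
                for x in a:
                    for y in b:
                        dist[(x, y)] = depth[x] + depth[y] - 2 * depth[i]
                desc[i] = a + b
                desc[self.left[i]] = desc[self.right[i]] = None
        labels = [self.labels[i] for i in order]
        n = len(order)
        pos = {t: j for j, t in enumerate(order)}
        mat = np.zeros((n, n))
        for (x, y), d in dist.items():
            mat[pos[x], pos[y]] = mat[pos[y], pos[x]] = d
        return labels, mat

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny {self.n_tips} tips, height {self.tree_height():.4g}>"


class TipStateMap(dict):
    """Mapping tip label -> state index in ``0..k-1`` or ``None`` (unknown)."""

    def __init__(self, mapping: Mapping[str, Optional[int]], k: Optional[int] = None):
        super().__init__({str(s).strip(): v for s, v in mapping.items()})
        known = [v for v in self.values() if v is not None]
        if k is None:
            k = (max(known) + 1) if known else 1
        if k < 1:
            raise TreeError("k must be >= 1")
        for s, v in self.items():
            if v is not None and not (0 <= int(v) < k):
                raise TreeError(f"state {v} of tip {s!r} outside 0..{k-1}")
        self.k = int(k)

    def validate_against(self, tree: Phylogeny) -> None:
        missing = sorted(set(self) - set(tree.tip_labels))
        if missing:
            raise TreeError(f"mapped labels not in tree: {missing}")

    def encode(self, tree: Phylogeny) -> np.ndarray:
        """Per-node state array: state index at tips, -1 for unknown tips.

        Internal nodes get -2.  Every tip of the tree must be present in the
        map (unknown states are allowed explicitly as ``None``)."""
        self.validate_against(tree)
        out = np.full(tree.n_nodes, -2, dtype=np.int64)
        for i in tree.tip_indices:
            lab = tree.labels[i]
            if lab not in self:
                raise TreeError(f"tip {lab!r} has no mapped state")
            v = self[lab]
            out[i] = -1 if v is None else int(v)
        return out


def read_newick(text: str, tag: Optional[str] = None) -> Phylogeny:
    return Phylogeny.from_newick(text, tag=tag)


def read_nexus(text: str, tag: Optional[str] = None) -> Phylogeny:
    return Phylogeny.from_nexus(text, tag=tag)


def write_newick(tree: Phylogeny, precision: int = 6) -> str:
    return tree.to_newick(precision=precision)


def prune_to_labels(tree: Phylogeny, labels: Iterable[str]) -> Phylogeny:
    return tree.prune_to(labels)
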