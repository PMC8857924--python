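"""Indexed reference phylogeny with clade bitsets and query insertion.

A branch is identified with its *child node*: branch ``b`` is the edge
between node ``b`` and its parent, so every non-root node carries exactly
one branch and the root carries none.  This makes "the clade below a
branch" unambiguous: it is the set of leaves descending from (and
including, for a leaf branch) node ``b``.

Clade membership is stored as a Python-int bitset over leaf indices
(input order), which makes the set algebra used throughout SNP-to-branch
assignment a handful of machine-word operations per branch.

Multifurcations are accepted as-is; branch lengths are optional and are
only ever used for insertion-point arithmetic, never for scoring.
"""

from __future__ import annotations

import re
from typing import Iterable, Iterator

import dendropy

__all__ = [
    "ReferenceTree",
    "NewickParseError",
    "TreeValidationError",
    "UnknownBranchError",
    "read_newick",
    "read_newick_file",
    "write_newick",
]


class NewickParseError(ValueError):
    """Malformed newick input."""


class TreeValidationError(ValueError):
    """Structurally invalid tree (duplicate/empty leaf labels, bad ids)."""


class UnknownBranchError(KeyError):
    """A branch id that does not exist in the tree."""


_PLAIN_LABEL = re.compile(r"^[A-Za-z0-9_.|+-]+$")


def _quote_label(label: str) -> str:
    if _PLAIN_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


class ReferenceTree:
    """Rooted phylogeny with integer node ids and per-branch clade bitsets.

    Node ids are assigned in preorder at construction (root = 0) and are
    stable under :meth:`insert_query`, which appends new nodes at the end.

    Attributes
    ----------
    parent : list[int | None]
        Parent node id per node; ``None`` for the root.
    children : list[list[int]]
        Child node ids per node, input order.
    lengths : list[float | None]
        Length of the branch above each node (``None`` when absent).
    labels : list[str | None]
        Node label: leaf name for leaves, internal label if present.
    leaf_names : list[str]
        Leaf names in input order; index into this list is the bit
        position used by ``clade_bits``.
    clade_bits : list[int]
        Bitset of leaf indices below each node (inclusive).
    """

    def __init__(
        self,
        parent: list[int | None],
        children: list[list[int]],
        lengths: list[float | None],
        labels: list[str | None],
    ) -> None:
        self.parent = parent
        self.children = children
        self.lengths = lengths
        self.labels = labels
        roots = [i for i, p in enumerate(parent) if p is None]
        if len(roots) != 1:
            raise TreeValidationError(f"expected exactly one root, found {len(roots)}")
        self.root: int = roots[0]
        self._reindex()

    # ------------------------------------------------------------------
    # construction / indexing

    def _reindex(self) -> None:
        n = len(self.parent)
        leaf_names: list[str] = []
        leaf_index_of_node: list[int | None] = [None] * n
        order: list[int] = []
        stack = [self.root]
        while stack:  # preorder; children pushed reversed to keep input order
            v = stack.pop()
            order.append(v)
            if not self.children[v]:
                name = self.labels[v]
                if not name:
                    raise TreeValidationError("leaf with empty name")
                leaf_index_of_node[v] = len(leaf_names)
                leaf_names.append(name)
            else:
                stack.extend(reversed(self.children[v]))
        seen: dict[str, int] = {}
        for name in leaf_names:
            if name in seen:
                raise TreeValidationError(f"duplicate leaf label: {name!r}")
            seen[name] = 1
        self.preorder: list[int] = order
        self.leaf_names: list[str] = leaf_names
        self.leaf_index_of_node = leaf_index_of_node
        self._leaf_node = {
            self.leaf_names[li]: v
            for v, li in enumerate(leaf_index_of_node)
            if li is not None
        }
        clade = [0] * n
        depth = [0] * n
        for v in order:
            p = self.parent[v]
            depth[v] = 0 if p is None else depth[p] + 1
        for v in reversed(order):
            li = leaf_index_of_node[v]
            if li is not None:
                clade[v] = 1 << li
            for c in self.children[v]:
                clade[v] |= clade[c]
        self.clade_bits: list[int] = clade
        self.depth: list[int] = depth
        self.branches: list[int] = [v for v in order if v != self.root]

    @classmethod
    def from_newick(cls, text: str) -> "ReferenceTree":
        """Parse a newick string into an indexed tree.

        Leaf order is deterministic (input order); internal labels and
        branch lengths are preserved.
        """
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            if "Duplicate taxon labels" in str(exc):
                label = str(exc).rsplit(":", 1)[-1].strip()
                raise TreeValidationError(
                    f"duplicate leaf label: {label!r}"
                ) from exc
            line = getattr(exc, "line_num", None)
            col = getattr(exc, "col_num", None)
            where = f" (line {line}, column {col})" if line is not None else ""
            raise NewickParseError(f"malformed newick{where}: {exc}") from exc
        parent: list[int | None] = []
        children: list[list[int]] = []
        lengths: list[float | None] = []
        labels: list[str | None] = []

        def add(node: "dendropy.Node", parent_id: int | None) -> int:
            nid = len(parent)
            parent.append(parent_id)
            children.append([])
            lengths.append(node.edge.length)
            if node.taxon is not None:
                labels.append(node.taxon.label)
            else:
                labels.append(node.label)
            if parent_id is not None:
                children[parent_id].append(nid)
            for ch in node.child_nodes():
                add(ch, nid)
            return nid

        add(dtree.seed_node, None)
        return cls(parent, children, lengths, labels)

    # ------------------------------------------------------------------
    # queries

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    def is_leaf(self, node: int) -> bool:
        return not self.children[node]

    def _check_branch(self, branch: int) -> None:
        if not (0 <= branch < len(self.parent)) or branch == self.root:
            raise UnknownBranchError(f"unknown branch id: {branch}")

    def leaf_branch(self, name: str) -> int:
        """Branch id of the pendant edge above the named leaf."""
        try:
            return self._leaf_node[name]
        except KeyError:
            raise UnknownBranchError(f"unknown leaf name: {name!r}") from None

    def clade_leaves(self, branch: int) -> set[str]:
        """Leaf names below (and including, for a leaf) the branch."""
        self._check_branch(branch)
        bits = self.clade_bits[branch]
        return {self.leaf_names[i] for i in _iter_bits(bits)}

    def strict_ancestors(self, branch: int) -> Iterator[int]:
        """Branch ids strictly above ``branch``, nearest first."""
        self._check_branch(branch)
        p = self.parent[branch]
        while p is not None and p != self.root:
            yield p
            p = self.parent[p]

    def path_to_root(self, branch: int) -> list[int]:
        """Branch ids from the root-adjacent branch down to ``branch``."""
        self._check_branch(branch)
        path = [branch] + list(self.strict_ancestors(branch))
        path.reverse()
        return path

    def is_ancestor_or_self(self, a: int, b: int) -> bool:
        """True iff branch ``a`` is ``b`` or lies on b's path to the root."""
        ca, cb = self.clade_bits[a], self.clade_bits[b]
        return cb & ca == cb and (a == b or self.depth[a] < self.depth[b])

    def mrca_branch(self, a: int, b: int) -> int | None:
        """Deepest common branch of two branches (None when only the root)."""
        anc = set([a]) | set(self.strict_ancestors(a))
        v: int | None = b
        while v is not None and v != self.root:
            if v in anc:
                return v
            v = self.parent[v]
        return None

    def subtree_sums(self, values: dict[int, float]) -> dict[int, float]:
        """Inclusive per-branch sums of ``values`` over each branch's subtree."""
        out = {b: float(values.get(b, 0.0)) for b in self.branches}
        for v in reversed(self.preorder):
            for c in self.children[v]:
                if v != self.root:
                    out[v] += out[c]
        return out

    # ------------------------------------------------------------------
    # manipulation

    def insert_query(self, branch: int, fraction: float, name: str) -> "ReferenceTree":
        """Return a new tree with leaf ``name`` attached along ``branch``.

        ``fraction`` positions the attachment measured from the parent end
        (0 = at the parent node, 1 = at the child node).  When the branch
        has no length, 1.0 is assumed for the split arithmetic only.
        Original node ids (hence branch ids) are preserved; the two new
        nodes are appended.
        """
        self._check_branch(branch)
        if not (0.0 <= fraction <= 1.0):
            raise ValueError(f"fraction must be in [0, 1], got {fraction}")
        if name in self._leaf_node:
            raise TreeValidationError(f"leaf name already present: {name!r}")
        parent = list(self.parent)
        children = [list(cs) for cs in self.children]
        lengths = list(self.lengths)
        labels = list(self.labels)
        p = parent[branch]
        assert p is not None
        length = lengths[branch]
        eff = 1.0 if length is None else length
        mid = len(parent)  # new internal node
        tip = mid + 1  # new query leaf
        parent.append(p)
        children.append([branch, tip])
        lengths.append(None if length is None else fraction * eff)
        labels.append(None)
        parent.append(mid)
        children.append([])
        pendant = None if length is None else (1.0 - fraction) * eff
        lengths.append(pendant)
        labels.append(name)
        children[p][children[p].index(branch)] = mid
        parent[branch] = mid
        lengths[branch] = None if length is None else (1.0 - fraction) * eff
        return ReferenceTree(parent, children, lengths, labels)

    # ------------------------------------------------------------------
    # output

    def to_newick(self) -> str:
        """Serialize to newick, preserving internal labels and lengths."""

        def render(v: int) -> str:
            if self.children[v]:
                inner = ",".join(render(c) for c in self.children[v])
                s = f"({inner})"
                if self.labels[v]:
                    s += _quote_label(self.labels[v])
            else:
                s = _quote_label(self.labels[v] or "")
            if self.lengths[v] is not None:
                s += f":{self.lengths[v]:.10g}"
            return s

        return render(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<ReferenceTree leaves={self.n_leaves} branches={self.n_branches}>"
        )


def _iter_bits(bits: int) -> Iterator[int]:
    i = 0
    while bits:
        if bits & 1:
            yield i
        bits >>= 1
        i += 1


def read_newick(text: str) -> ReferenceTree:
    """Parse a newick string (see :meth:`ReferenceTree.from_newick`)."""
    return ReferenceTree.from_newick(text)


def read_newick_file(path: str) -> ReferenceTree:
    with open(path) as fh:
        return read_newick(fh.read())


def write_newick(tree: ReferenceTree, path: str | None = None) -> str:
    """Serialize ``tree``; also write to ``path`` when given."""
    text = tree.to_newick()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def check_sample_overlap(
    tree: ReferenceTree, samples: Iterable[str]
) -> tuple[list[str], list[str]]:
    """Pre-flight check of tree leaves vs genotyped sample names.

    Returns ``(leaves_without_genotypes, samples_not_in_tree)``; matching
    is exact and case-sensitive.
    """
    sset = set(samples)
    leaves = set(tree.leaf_names)
    return sorted(leaves - sset), sorted(sset - leaves)
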