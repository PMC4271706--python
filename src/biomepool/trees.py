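"""Dated phylogenetic trees: parsing, ages, patristic distances, pruning, ensembles.

A :class:`DatedTree` is an array-backed rooted tree whose node ages are measured
in Myr before present, with extant tips at age 0.  It is the substrate of every
downstream stage (biogeographic likelihood, event extraction, trait
reconstruction, diversification fitting), all of which need indexed traversal,
so nodes are stored as flat arrays rather than linked objects.  Newick reading
and writing is delegated to :mod:`dendropy`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

import dendropy

__all__ = [
    "TreeError",
    "TreeParseError",
    "DatedTree",
    "TreeEnsemble",
    "parse_newick",
    "write_newick",
]


class TreeError(ValueError):
    """Structural problem with a tree or a tree query."""


class TreeParseError(TreeError):
    """Malformed Newick input; the message names the offending token."""


@dataclass
class DatedTree:
    """Rooted, dated phylogeny with node ages in Myr before present.

    Parameters
    ----------
    parent : array of int
        Parent index per node; the root has parent ``-1``.
    lengths : array of float
        Branch length (Myr) subtending each node; the root entry is 0.
    labels : list of str or None
        Tip labels (unique, required at tips); internal labels are optional
        metadata.

    Node ages are computed from cumulative root-to-node depths: the deepest
    tip sits at age 0 and ``age = max_depth - depth``.  Invariants (exactly
    one root, positive parent-child age gaps, age/length consistency) are
    checked at construction.
    """

    parent: np.ndarray
    lengths: np.ndarray
    labels: list
    ages: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=int)
        self.lengths = np.asarray(self.lengths, dtype=float)
        n = self.parent.size
        if self.lengths.size != n or len(self.labels) != n:
            raise TreeError("parent/lengths/labels size mismatch")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise TreeError(f"tree must have exactly one root, found {roots.size}")
        self.root = int(roots[0])
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            if i != self.root:
                self.children[self.parent[i]].append(i)
        self._postorder = self._compute_postorder()
        if self.ages is None:
            depth = np.zeros(n)
            for i in self.preorder():
                if i != self.root:
                    depth[i] = depth[self.parent[i]] + self.lengths[i]
            self.ages = depth.max() - depth
        else:
            self.ages = np.asarray(self.ages, dtype=float)
        self._tips = [i for i in range(n) if not self.children[i]]
        self._label_to_node = {}
        for i in self._tips:
            lab = self.labels[i]
            if lab is None or lab == "":
                raise TreeError(f"tip {i} has no label")
            if lab in self._label_to_node:
                raise TreeParseError(f"duplicate tip label {lab!r}")
            self._label_to_node[lab] = i
        self._validate()

    # -- construction ---------------------------------------------------

    def _compute_postorder(self) -> np.ndarray:
        order = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        return np.asarray(order[::-1], dtype=int)

    def _validate(self):
        if np.any(self.lengths[np.arange(self.parent.size) != self.root] < 0):
            raise TreeError("negative branch length")
        for i in range(self.parent.size):
            if i == self.root:
                continue
            gap = self.ages[self.parent[i]] - self.ages[i]
            if abs(gap - self.lengths[i]) > 1e-9:
                raise TreeError(
                    f"age(parent)-age(child) != branch length at node {i}: "
                    f"{gap} vs {self.lengths[i]}"
                )
            if self.lengths[i] > 0 and gap <= 0:
                raise TreeError(f"parent not older than child at node {i}")
        if np.any(self.ages[self._tip_mask()] < -1e-9):
            raise TreeError("tip age below zero")

    def _tip_mask(self) -> np.ndarray:
        mask = np.zeros(self.parent.size, dtype=bool)
        mask[[i for i in range(self.parent.size) if not self.children[i]]] = True
        return mask

    # -- basic queries ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    @property
    def tip_indices(self) -> list[int]:
        return list(self._tips)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self._tips]

    @property
    def root_age(self) -> float:
        return float(self.ages[self.root])

    def is_tip(self, i: int) -> bool:
        return not self.children[i]

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        return bool(np.all(np.abs(self.ages[self._tips]) <= tol))

    def node_of(self, label: str) -> int:
        try:
            return self._label_to_node[label]
        except KeyError:
            raise TreeError(f"unknown tip label {label!r}") from None

    def postorder(self) -> Iterable[int]:
        return self._postorder

    def preorder(self) -> Iterable[int]:
        return self._postorder[::-1]

    def path_to_root(self, i: int) -> list[int]:
        path = [i]
        while path[-1] != self.root:
            path.append(int(self.parent[path[-1]]))
        return path

    def mrca(self, a: int, b: int) -> int:
        seen = set(self.path_to_root(a))
        node = b
        while node not in seen:
            node = int(self.parent[node])
        return node

    def descendant_tips(self, i: int) -> list[int]:
        out, stack = [], [i]
        while stack:
            n = stack.pop()
            if self.is_tip(n):
                out.append(n)
            else:
                stack.extend(self.children[n])
        return out

    # -- distances -------------------------------------------------------

    def patristic_distance(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path ``a -> MRCA -> b`` (Myr)."""
        ia, ib = self.node_of(a), self.node_of(b)
        if ia == ib:
            return 0.0
        m = self.mrca(ia, ib)
        return float((self.ages[m] - self.ages[ia]) + (self.ages[m] - self.ages[ib]))

    def shared_depth_matrix(self, tips: Sequence[int] | None = None) -> np.ndarray:
        """Root-to-MRCA path length for every tip pair (the BM covariance shape).

        ``S[i, j] = root_age - age(mrca(tip_i, tip_j))``; diagonal entries are the
        root-to-tip depths.
        """
        tips = list(self._tips) if tips is None else list(tips)
        pos = {t: k for k, t in enumerate(tips)}
        n = len(tips)
        S = np.zeros((n, n))
        below: dict[int, list[int]] = {}
        for node in self.postorder():
            if self.is_tip(node):
                if node in pos:
                    S[pos[node], pos[node]] = self.root_age - self.ages[node]
                    below[node] = [pos[node]]
                else:
                    below[node] = []
            else:
                kids = self.children[node]
                sets = [below.pop(k) for k in kids]
                depth = self.root_age - self.ages[node]
                for x in range(len(sets)):
                    for y in range(x + 1, len(sets)):
                        if sets[x] and sets[y]:
                            ix = np.asarray(sets[x])[:, None]
                            iy = np.asarray(sets[y])[None, :]
                            S[ix, iy] = depth
                            S[iy.T, ix.T] = depth
                merged = [p for s in sets for p in s]
                below[node] = merged
        return S

    # -- editing ---------------------------------------------------------

    def prune_tips(self, drop: Iterable[str]) -> "DatedTree":
        """Drop the named tips, suppressing degree-2 nodes and merging lengths.

        Ages of retained nodes are carried over unchanged.
        """
        drop = set(drop)
        unknown = drop - set(self.tip_labels)
        if unknown:
            raise TreeError(f"cannot drop unknown tips: {sorted(unknown)}")
        keep_tips = [i for i in self._tips if self.labels[i] not in drop]
        if len(keep_tips) < 2:
            raise TreeError("pruning must leave at least 2 tips")
        if not drop:
            return DatedTree(self.parent.copy(), self.lengths.copy(),
                             list(self.labels), self.ages.copy())
        n_desc = np.zeros(self.n_nodes, dtype=int)
        keep_set = set(keep_tips)
        for node in self.postorder():
            if self.is_tip(node):
                n_desc[node] = 1 if node in keep_set else 0
            else:
                n_desc[node] = sum(n_desc[k] for k in self.children[node])
        # new root: deepest node with >= 2 kept children subtrees
        def surviving_children(node):
            return [k for k in self.children[node] if n_desc[k] > 0]

        new_root = self.root
        while not self.is_tip(new_root) and len(surviving_children(new_root)) == 1:
            new_root = surviving_children(new_root)[0]
        # collect retained nodes: kept tips + internal nodes (under new_root)
        # with >= 2 surviving children
        retained = []
        stack = [new_root]
        parent_map: dict[int, int] = {new_root: -1}
        while stack:
            node = stack.pop()
            retained.append(node)
            if self.is_tip(node):
                continue
            for k in surviving_children(node):
                # skip down through unary chains
                m = k
                while not self.is_tip(m) and len(surviving_children(m)) == 1:
                    m = surviving_children(m)[0]
                parent_map[m] = node
                stack.append(m)
        index = {node: i for i, node in enumerate(retained)}
        parent = np.array([index[parent_map[n]] if parent_map[n] != -1 else -1
                           for n in retained])
        ages = self.ages[retained]
        lengths = np.zeros(len(retained))
        for i, node in enumerate(retained):
            if parent[i] >= 0:
                lengths[i] = ages[parent[i]] - ages[i]
        labels = [self.labels[n] for n in retained]
        pruned = DatedTree(parent, lengths, labels, ages)
        # map back to this tree's node ids (used to restrict simulator truth)
        pruned.orig_index = np.asarray(retained, dtype=int)
        return pruned

    def extract_subtree(self, node: int) -> "DatedTree":
        """The clade rooted at ``node`` as a standalone tree (ages preserved)."""
        if self.is_tip(node):
            raise TreeError("subtree root must be internal")
        nodes = []
        stack = [node]
        while stack:
            n = stack.pop()
            nodes.append(n)
            stack.extend(self.children[n])
        index = {n: i for i, n in enumerate(nodes)}
        parent = np.array([-1 if n == node else index[self.parent[n]] for n in nodes])
        ages = self.ages[nodes]
        lengths = np.array([0.0 if n == node else self.lengths[n] for n in nodes])
        labels = [self.labels[n] for n in nodes]
        return DatedTree(parent, lengths, labels, ages)

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "DatedTree":
        return parse_newick(text)

    def to_newick(self) -> str:
        """Newick string with 12-significant-digit branch lengths."""
        parts: dict[int, str] = {}
        for node in self.postorder():
            if self.is_tip(node):
                s = _escape_label(self.labels[node])
            else:
                inner = ",".join(parts.pop(k) for k in self.children[node])
                lab = self.labels[node]
                s = f"({inner}){_escape_label(lab) if lab else ''}"
            if node != self.root:
                s += f":{self.lengths[node]:.12g}"
            parts[node] = s
        return parts[self.root] + ";"


def _escape_label(label) -> str:
    if label is None:
        return ""
    if any(c in label for c in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def parse_newick(text: str) -> DatedTree:
    """Parse a single Newick tree with branch lengths into a :class:`DatedTree`.

    Node labels after ``)`` are retained as metadata; square-bracket comments
    are ignored.  Unbalanced parentheses, duplicate tip labels, or missing
    branch lengths raise :class:`TreeParseError`.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeParseError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(dtree)


def _from_dendropy(dtree: "dendropy.Tree") -> DatedTree:
    nodes = list(dtree.preorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=int)
    lengths = np.zeros(n)
    labels: list = [None] * n
    for i, node in enumerate(nodes):
        if node.parent_node is not None:
            parent[i] = index[id(node.parent_node)]
            if node.edge.length is None:
                name = node.taxon.label if node.taxon else (node.label or f"#{i}")
                raise TreeParseError(f"missing branch length at node {name!r}")
            lengths[i] = float(node.edge.length)
        if node.taxon is not None:
            labels[i] = node.taxon.label
        elif node.label:
            labels[i] = node.label
    return DatedTree(parent, lengths, labels)


def write_newick(tree: DatedTree) -> str:
    return tree.to_newick()


class TreeEnsemble:
    """An ordered collection of dated trees sharing a tip-label universe.

    The unit of phylogenetic uncertainty: summaries downstream are means and
    95% quantiles across members (e.g. bootstrap trees).
    """

    def __init__(self, trees: Sequence[DatedTree]):
        trees = list(trees)
        if not trees:
            raise TreeError("ensemble must contain at least one tree")
        self.trees = trees

    def __len__(self):
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i):
        return self.trees[i]

    @property
    def tip_label_universe(self) -> set:
        out: set = set()
        for t in self.trees:
            out.update(t.tip_labels)
        return out

    @classmethod
    def from_newick_file(cls, path) -> "TreeEnsemble":
        """Read a multi-tree Newick file (one tree per line / per ';')."""
        with open(path) as fh:
            text = fh.read()
        chunks = [c.strip() for c in text.split(";") if c.strip()]
        return cls([parse_newick(c + ";") for c in chunks])

    def to_newick_file(self, path):
        with open(path, "w") as fh:
            for t in self.trees:
                fh.write(t.to_newick() + "\n")
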