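"""Rooted phylogenies: generic branch-length trees and ultrametric time trees.

Trees are stored as flat arrays (parent pointers, child lists, branch lengths)
for fast likelihood computation; Newick reading/writing is delegated to
dendropy.  Two flavours share one structure:

* :class:`TimeTree` — a chronogram; branch lengths are durations in million
  years (MY) and every root-to-tip path has the same total duration.
* :class:`PhyloTree` — the same topology with branch lengths in expected
  amino-acid substitutions per site, typically produced by the maximum
  likelihood optimizer, carrying the final log-likelihood.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = ["Phylogeny", "TimeTree", "PhyloTree", "TopologyMismatchError"]

ULTRAMETRIC_RTOL = 1e-9


class TopologyMismatchError(ValueError):
    """Raised when two trees expected to share a topology do not."""


class Phylogeny:
    """A rooted tree with branch lengths, indexed by integer node ids.

    Node 0..n_nodes-1; ``parent[i]`` is -1 for the root.  ``labels[i]`` is the
    taxon name for tips and ``None`` (or an internal label) otherwise.
    """

    def __init__(
        self,
        parent: Sequence[int],
        lengths: Sequence[float],
        labels: Sequence[str | None],
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=float)
        self.labels = list(labels)
        n = len(self.parent)
        if not (len(self.lengths) == n and len(self.labels) == n):
            raise ValueError("parent, lengths and labels must have equal length")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[int(p)].append(i)
        if np.any(np.isnan(self.lengths)) or np.any(self.lengths < 0):
            raise ValueError("branch lengths must be non-negative and finite")
        self._postorder: np.ndarray | None = None

    # ------------------------------------------------------------------ basic
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tip_ids(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_ids]  # type: ignore[misc]

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    def postorder(self) -> np.ndarray:
        """Node ids in postorder (children before parents)."""
        if self._postorder is None:
            order: list[int] = []
            stack = [self.root]
            while stack:
                v = stack.pop()
                order.append(v)
                stack.extend(self.children[v])
            self._postorder = np.array(order[::-1], dtype=np.int64)
        return self._postorder

    def preorder(self) -> np.ndarray:
        return self.postorder()[::-1]

    def tip_index(self) -> dict[str, int]:
        idx = {}
        for i in self.tip_ids:
            lab = self.labels[i]
            if lab in idx:
                raise ValueError(f"duplicate tip label {lab!r}")
            idx[lab] = i
        return idx

    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node."""
        d = np.zeros(self.n_nodes)
        for v in self.preorder():
            p = self.parent[v]
            if p >= 0:
                d[v] = d[p] + self.lengths[v]
        return d

    def total_length(self) -> float:
        return float(self.lengths.sum())

    def path_to_root(self, node: int) -> list[int]:
        path = []
        v = node
        while v != self.root:
            path.append(v)
            v = int(self.parent[v])
        return path

    def clade_tips(self, node: int) -> list[int]:
        """Tip ids in the subtree rooted at ``node``."""
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if not self.children[v]:
                out.append(v)
            else:
                stack.extend(self.children[v])
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Tip-label set of every clade (topology fingerprint for rooted trees)."""
        out = set()
        for v in range(self.n_nodes):
            if self.children[v]:
                out.add(frozenset(self.labels[t] for t in self.clade_tips(v)))
        return out

    def same_topology(self, other: "Phylogeny") -> bool:
        if set(self.tip_labels) != set(other.tip_labels):
            return False
        return self.bipartitions() == other.bipartitions()

    def with_lengths(self, lengths: Sequence[float], cls: type | None = None):
        """Copy of this tree (same node indexing) with new branch lengths."""
        cls = cls or type(self)
        return cls(self.parent.copy(), np.asarray(lengths, float), list(self.labels))

    # ------------------------------------------------------------------- I/O
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, **kw):
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = [-1] * len(nodes)
        lengths = [0.0] * len(nodes)
        labels: list[str | None] = [None] * len(nodes)
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                lengths[i] = float(nd.edge.length or 0.0)
            if nd.taxon is not None:
                labels[i] = nd.taxon.label
            elif nd.label:
                labels[i] = nd.label
        return cls(parent, lengths, labels, **kw)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)
        dnodes = {self.root: tree.seed_node}
        for v in self.preorder():
            if v == self.root:
                continue
            nd = dendropy.Node()
            nd.edge.length = float(self.lengths[v])
            dnodes[int(self.parent[v])].add_child(nd)
            dnodes[v] = nd
        for i in range(self.n_nodes):
            if not self.children[i]:
                dnodes[i].taxon = taxa.new_taxon(self.labels[i])
            elif self.labels[i]:
                dnodes[i].label = self.labels[i]
        return tree

    @classmethod
    def from_newick(cls, newick: str, **kw):
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls.from_dendropy(tree, **kw)

    @classmethod
    def read_newick(cls, path, **kw):
        with open(path) as fh:
            return cls.from_newick(fh.read(), **kw)

    def to_newick(self) -> str:
        s = self.to_dendropy().as_string(
            schema="newick", unquoted_underscores=True, suppress_rooting=True
        )
        return s.strip() + ("\n" if not s.strip().endswith("\n") else "")

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick())

    def __repr__(self):  # pragma: no cover
        return f"<{type(self).__name__} {self.n_tips} tips, {self.n_nodes} nodes>"


class TimeTree(Phylogeny):
    """Rooted ultrametric chronogram; branch lengths are durations in MY."""

    def __init__(self, parent, lengths, labels, check_ultrametric: bool = True):
        super().__init__(parent, lengths, labels)
        if check_ultrametric and not self.is_ultrametric():
            raise ValueError("TimeTree must be ultrametric (equal root-to-tip depths)")

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        d = self.depths()[self.tip_ids]
        span = d.max() - d.min()
        scale = max(d.max(), 1.0)
        return bool(span <= rtol * scale)

    @property
    def root_age(self) -> float:
        """Age of the root = depth of the tips (MY)."""
        return float(np.max(self.depths()[self.tip_ids]))

    def node_ages(self) -> np.ndarray:
        """Age (time before present, MY) of every node."""
        return self.root_age - self.depths()

    def terminal_duration(self, species: str) -> float:
        """Duration (MY) of the terminal branch of ``species`` = parent-node age."""
        return float(self.lengths[self.tip_index()[species]])

    def prune_to(self, taxa: Iterable[str]) -> "TimeTree":
        """Subtree induced by ``taxa`` with in-line degree-2 nodes collapsed."""
        keep = set(taxa)
        missing = keep - set(self.tip_labels)
        if missing:
            raise ValueError(f"taxa not in tree: {sorted(missing)}")
        tree = self.to_dendropy()
        tree.retain_taxa_with_labels(sorted(keep))
        # suppress unifurcations introduced by pruning, but keep the root even
        # if it becomes degree-2 (rooted trees stay rooted)
        tree.suppress_unifurcations()
        return TimeTree.from_dendropy(tree)


class PhyloTree(Phylogeny):
    """Tree with branch lengths in expected substitutions/site.

    Carries the log-likelihood under which the lengths were estimated.
    """

    def __init__(self, parent, lengths, labels, log_likelihood: float | None = None):
        super().__init__(parent, lengths, labels)
        self.log_likelihood = log_likelihood
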