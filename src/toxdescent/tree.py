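"""Rooted species trees with labeled internal nodes.

All downstream stages (Dollo parsimony, subsampling nulls, the pure-loss
likelihood model) run dynamic programs over the same rooted phylogeny, so the
tree is stored in flat preorder arrays: ``parent[i]`` indexing, a leaf mask,
and a precomputed node-by-leaf incidence matrix.  Newick text is parsed with
dendropy and converted once.
"""

from __future__ import annotations

import io
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = ["SpeciesTree", "TreeError", "suite1_tree", "suite2_tree"]


class TreeError(ValueError):
    """Malformed newick input or an invalid tree query."""


class SpeciesTree:
    """A rooted phylogeny with unique string labels on every node.

    Nodes are held in preorder; node 0 is the root.  Polytomies are permitted.
    Unlabeled internal nodes are auto-named ``N<preorder-index>`` so that event
    tables are comparable across runs.

    Parameters
    ----------
    parent
        ``parent[i]`` is the preorder index of node *i*'s parent (-1 for the
        root, which must be node 0).
    labels
        Unique label per node, aligned with ``parent``.
    branch_lengths
        Optional non-negative length of the branch above each node
        (``nan`` for the root).
    """

    def __init__(
        self,
        parent: Sequence[int],
        labels: Sequence[str],
        branch_lengths: Sequence[float] | None = None,
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.labels = list(labels)
        if len(self.labels) != len(self.parent):
            raise TreeError("labels and parent arrays differ in length")
        if self.parent[0] != -1 or np.any(self.parent[1:] < 0):
            raise TreeError("node 0 must be the unique root (parent -1)")
        if np.any(self.parent[1:] >= np.arange(1, len(self.parent))):
            raise TreeError("parent indices must precede children (preorder)")
        if len(set(self.labels)) != len(self.labels):
            dup = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise TreeError(f"duplicate node labels: {dup}")
        if branch_lengths is None:
            self.branch_lengths = None
        else:
            bl = np.asarray(branch_lengths, dtype=float)
            if np.any(bl[1:] < 0):
                raise TreeError("branch lengths must be non-negative")
            self.branch_lengths = bl

        n = len(self.labels)
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            self.children[self.parent[i]].append(i)
        self.is_leaf = np.array([len(c) == 0 for c in self.children])
        self.depth = np.zeros(n, dtype=np.int64)
        for i in range(1, n):
            self.depth[i] = self.depth[self.parent[i]] + 1
        self._index = {lab: i for i, lab in enumerate(self.labels)}
        # leaf_matrix[v, j]: leaf j (in leaf_labels order) lies under node v
        leaves = np.flatnonzero(self.is_leaf)
        self.leaf_labels = [self.labels[i] for i in leaves]
        self._leaf_nodes = leaves
        lm = np.zeros((n, len(leaves)), dtype=bool)
        for j, lf in enumerate(leaves):
            v = lf
            while v != -1:
                lm[v, j] = True
                v = self.parent[v]
        self.leaf_matrix = lm
        # descendant_or_self[u, v]: v lies in the subtree rooted at u
        dos = np.zeros((n, n), dtype=bool)
        for v in range(n):
            u = v
            while u != -1:
                dos[u, v] = True
                u = self.parent[u]
        self.descendant_or_self = dos

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise TreeError(f"unknown node label: {label!r}") from None

    def leaves_under(self, label: str) -> list[str]:
        """Leaf labels inside the clade rooted at ``label``."""
        v = self.index(label)
        return [self.leaf_labels[j] for j in np.flatnonzero(self.leaf_matrix[v])]

    def mrca(self, leaf_labels: Iterable[str]) -> str:
        """Most recent common ancestor of a non-empty set of leaves."""
        want = set(leaf_labels)
        if not want:
            raise TreeError("mrca of an empty leaf set is undefined")
        mask = np.array([lab in want for lab in self.leaf_labels])
        if mask.sum() != len(want):
            missing = want - set(self.leaf_labels)
            raise TreeError(f"unknown leaves: {sorted(missing)}")
        covers = np.flatnonzero((self.leaf_matrix & mask).sum(axis=1) == mask.sum())
        return self.labels[covers[np.argmax(self.depth[covers])]]

    def postorder(self) -> list[int]:
        return list(range(self.n_nodes))[::-1]

    # ------------------------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTree":
        """Parse a newick string; internal labels optional.

        Unlabeled internal nodes are named ``N<preorder-index>``
        deterministically.  Raises :class:`TreeError` on malformed input,
        including the parser's position information.
        """
        try:
            dt = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several DataError types
            raise TreeError(f"newick parse error: {exc}") from exc
        parent: list[int] = []
        labels: list[str] = []
        lengths: list[float] = []
        idx_of: dict[int, int] = {}
        have_lengths = False
        for node in dt.preorder_node_iter():
            i = len(parent)
            idx_of[id(node)] = i
            parent.append(-1 if node.parent_node is None else idx_of[id(node.parent_node)])
            if node.is_leaf():
                lab = node.taxon.label if node.taxon else node.label
            else:
                lab = node.label
            labels.append(lab if lab else f"N{i}")
            if node.edge.length is not None:
                have_lengths = True
            lengths.append(np.nan if node.edge.length is None else float(node.edge.length))
        return cls(parent, labels, lengths if have_lengths else None)

    def to_newick(self, branch_lengths: Sequence[float] | None = None) -> str:
        """Serialize with internal labels; optional per-node branch lengths."""
        bl = branch_lengths if branch_lengths is not None else self.branch_lengths

        def render(v: int) -> str:
            s = ""
            if self.children[v]:
                s = "(" + ",".join(render(c) for c in self.children[v]) + ")"
            s += self.labels[v]
            if bl is not None and self.parent[v] != -1 and not np.isnan(bl[v]):
                s += f":{bl[v]:.6g}"
            return s

        return render(0) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"SpeciesTree({self.n_leaves} leaves, {self.n_nodes} nodes, root={self.labels[0]!r})"


# ----------------------------------------------------------------------
# Reference topologies for the two study suites.
#
# Suite 1: the 12-species human/eco-toxicology panel (mammals, tetrapods,
# fish, insects, crustaceans, a nematode) used for the gene-family analyses.
# Suite 2: the 8-species panel with pathway-level annotations.

_SUITE1_NEWICK = (
    "((((Homo_sapiens,Mus_musculus)Mammalia,Xenopus_tropicalis)Tetrapoda,"
    "(Danio_rerio,Fundulus_heteroclitus)Fish)Vertebrata,"
    "((((Drosophila_melanogaster,Anopheles_gambiae)Diptera,Nasonia_vitripennis)Hexapoda,"
    "((Daphnia_magna,Daphnia_pulex)Cladocera,Hyalella_azteca)Crustacea)Arthropoda,"
    "Caenorhabditis_elegans)Ecdysozoa)Bilateria;"
)

_SUITE2_NEWICK = (
    "(((((Homo_sapiens,(Mus_musculus,Rattus_norvegicus)Rodentia)Euarchontoglires,"
    "Gallus_gallus)Amniota,Xenopus_tropicalis)Tetrapoda,Danio_rerio)Vertebrata,"
    "(Drosophila_melanogaster,Caenorhabditis_elegans)Ecdysozoa)Bilateria;"
)


def suite1_tree() -> SpeciesTree:
    """The 12-species gene-family suite (root Bilateria, vertebrates vs ecdysozoans)."""
    return SpeciesTree.from_newick(_SUITE1_NEWICK)


def suite2_tree() -> SpeciesTree:
    """The 8-species pathway suite (5 vertebrates + Homo, 2 invertebrates)."""
    return SpeciesTree.from_newick(_SUITE2_NEWICK)
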