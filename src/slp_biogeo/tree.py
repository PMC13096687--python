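"""Rooted phylogenies as flat arrays, with Newick I/O through dendropy.

The array layout keeps the numerics (patristic distances, Brownian
simulation, postorder trait sweeps) vectorisable: tips occupy indices
``0 .. n_tips-1``, internal nodes follow, and ``parent[root] == -1``.
dendropy is used only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["Phylogeny", "read_newick", "write_newick"]


class NewickError(ValueError):
    """Raised for malformed or out-of-contract Newick input."""


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths and unique tip labels.

    Parameters
    ----------
    parent
        ``parent[i]`` is the index of node *i*'s parent; the root has -1.
    edge_length
        Length of the edge above each node (root entry ignored, kept 0).
    tip_labels
        Labels for nodes ``0 .. n_tips-1``.
    """

    parent: np.ndarray
    edge_length: np.ndarray
    tip_labels: list[str]
    _children: list[list[int]] = field(default=None, repr=False, compare=False)
    _postorder: np.ndarray = field(default=None, repr=False, compare=False)
    _depths: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.edge_length = np.asarray(self.edge_length, dtype=np.float64)
        if len(self.tip_labels) != len(set(self.tip_labels)):
            raise NewickError("duplicate tip labels")
        if np.any(self.edge_length < -1e-12):
            raise ValueError("negative branch length")
        if self.n_tips < 2:
            raise ValueError("a phylogeny needs at least 2 tips")

    # -- basic structure -------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.where(self.parent == -1)[0][0])

    @property
    def children(self) -> list[list[int]]:
        if self._children is None:
            ch = [[] for _ in range(self.n_nodes)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(i)
            self._children = ch
        return self._children

    @property
    def postorder(self) -> np.ndarray:
        """Node indices, every child before its parent."""
        if self._postorder is None:
            order, stack = [], [self.root]
            while stack:
                node = stack.pop()
                order.append(node)
                stack.extend(self.children[node])
            self._postorder = np.array(order[::-1], dtype=np.int64)
        return self._postorder

    @property
    def depths(self) -> np.ndarray:
        """Root-to-node path lengths."""
        if self._depths is None:
            d = np.zeros(self.n_nodes)
            for node in self.postorder[::-1]:  # preorder
                p = self.parent[node]
                if p >= 0:
                    d[node] = d[p] + self.edge_length[node]
            self._depths = d
        return self._depths

    @property
    def height(self) -> float:
        return float(self.depths[: self.n_tips].max())

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        tips = self.depths[: self.n_tips]
        return bool(tips.max() - tips.min() <= tol * max(tips.max(), 1.0))

    def tip_index(self, labels) -> np.ndarray:
        lookup = {lab: i for i, lab in enumerate(self.tip_labels)}
        try:
            return np.array([lookup[x] for x in labels], dtype=np.int64)
        except KeyError as e:
            raise KeyError(f"label {e.args[0]!r} not a tip of this tree") from None

    # -- pairwise matrices -----------------------------------------------

    def _tipsets(self):
        """Per-node array of descendant tip indices (postorder fill)."""
        sets = [None] * self.n_nodes
        for node in self.postorder:
            kids = self.children[node]
            if not kids:
                sets[node] = np.array([node], dtype=np.int64)
            else:
                sets[node] = np.concatenate([sets[k] for k in kids])
        return sets

    def patristic_matrix(self) -> np.ndarray:
        """Sum of branch lengths between every pair of tips."""
        n = self.n_tips
        depth = self.depths
        D = np.zeros((n, n))
        sets = self._tipsets()
        for node in self.postorder:
            kids = self.children[node]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    ta, tb = sets[kids[a]], sets[kids[b]]
                    block = depth[ta][:, None] + depth[tb][None, :] - 2.0 * depth[node]
                    D[np.ix_(ta, tb)] = block
                    D[np.ix_(tb, ta)] = block.T
        return D

    def vcv_matrix(self) -> np.ndarray:
        """Brownian covariance structure: depth of the MRCA of each tip pair."""
        n = self.n_tips
        depth = self.depths
        C = np.zeros((n, n))
        C[np.diag_indices(n)] = depth[:n]
        sets = self._tipsets()
        for node in self.postorder:
            kids = self.children[node]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    ta, tb = sets[kids[a]], sets[kids[b]]
                    C[np.ix_(ta, tb)] = depth[node]
                    C[np.ix_(tb, ta)] = depth[node]
        return C

    # -- pruning ----------------------------------------------------------

    def prune_to(self, labels) -> "Phylogeny":
        """Restrict to the given tips, collapsing unary nodes so patristic
        distances among retained tips are unchanged."""
        keep_labels = list(labels)
        keep = set(self.tip_index(keep_labels).tolist())
        if len(keep) < 2:
            raise ValueError("pruning would leave fewer than 2 tips")
        # count retained tips below each node
        count = np.zeros(self.n_nodes, dtype=np.int64)
        for node in self.postorder:
            kids = self.children[node]
            if not kids:
                count[node] = 1 if node in keep else 0
            else:
                count[node] = sum(count[k] for k in kids)
        # new parent/length by walking from each retained node up through
        # kept ancestors, skipping those with a single retained child
        root = self.root
        is_junction = np.zeros(self.n_nodes, dtype=bool)
        for node in range(self.n_nodes):
            kids = [k for k in self.children[node] if count[k] > 0]
            if len(kids) >= 2:
                is_junction[node] = True
        # new root: deepest junction on the path from old root (others above
        # it have one retained child)
        new_nodes = sorted(keep) + [i for i in range(self.n_nodes)
                                    if is_junction[i] and count[i] > 0]
        # keep only junctions that have >=2 retained-descendant children
        remap = {old: new for new, old in enumerate(new_nodes)}
        m = len(new_nodes)
        parent = np.full(m, -1, dtype=np.int64)
        length = np.zeros(m)
        for old in new_nodes:
            # climb to nearest retained junction ancestor
            p = self.parent[old]
            acc = self.edge_length[old]
            while p >= 0 and not is_junction[p]:
                acc += self.edge_length[p]
                p = self.parent[p]
            if p >= 0:
                parent[remap[old]] = remap[p]
                length[remap[old]] = acc
        tip_labels = [self.tip_labels[i] for i in sorted(keep)]
        return Phylogeny(parent, length, tip_labels)

    # -- dendropy bridge ---------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        leaves = [lf for lf in tree.leaf_node_iter()]
        labels = []
        for lf in leaves:
            lab = lf.taxon.label if lf.taxon is not None else lf.label
            if lab is None:
                raise NewickError("unlabelled tip")
            labels.append(lab)
        if len(labels) != len(set(labels)):
            raise NewickError("duplicate tip labels")
        internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
        index = {}
        for i, lf in enumerate(leaves):
            index[id(lf)] = i
        for j, nd in enumerate(internals):
            index[id(nd)] = len(leaves) + j
        m = len(leaves) + len(internals)
        parent = np.full(m, -1, dtype=np.int64)
        length = np.zeros(m)
        for nd in tree.preorder_node_iter():
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                length[i] = nd.edge.length if nd.edge.length is not None else 0.0
        return cls(parent, length, labels)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace(self.tip_labels)
        tree = dendropy.Tree(taxon_namespace=taxa)
        nodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for i in range(self.n_tips):
            nodes[i].taxon = taxa.get_taxon(self.tip_labels[i])
        for i, p in enumerate(self.parent):
            nodes[i].edge.length = float(self.edge_length[i])
            if p >= 0:
                nodes[p].add_child(nodes[i])
        tree.seed_node = nodes[self.root]
        tree.seed_node.edge.length = None
        return tree

    def to_newick(self) -> str:
        return self.to_dendropy().as_string(schema="newick",
                                            suppress_rooting=True).strip()


def read_newick(path_or_string, *, from_string: bool = False) -> Phylogeny:
    """Read a single rooted tree from a Newick file (or literal string).

    Raises ``NewickError`` on parse failure, on multiple trees in one file,
    or on duplicate tip labels.
    """
    if from_string:
        src = {"data": path_or_string}
    else:
        src = {"path": str(path_or_string)}
    try:
        trees = dendropy.TreeList.get(schema="newick",
                                      suppress_internal_node_taxa=True, **src)
    except Exception as e:  # dendropy raises various error classes
        raise NewickError(f"could not parse Newick input: {e}") from e
    if len(trees) != 1:
        raise NewickError(f"expected exactly one tree, found {len(trees)}")
    return Phylogeny.from_dendropy(trees[0])


def write_newick(tree: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def read_newick_string(s: str) -> Phylogeny:
    return read_newick(s, from_string=True)
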