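"""Rooted-phylogeny container, Newick I/O, pruning, and patristic geometry.

A :class:`Phylogeny` wraps a :class:`dendropy.Tree` and caches the quantities
every downstream diversity metric needs: tip depths (root-to-tip path
lengths), the patristic distance matrix, and the shared-branch-length
covariance / correlation matrices.  All tip labels are normalised on
construction (whitespace trimmed, internal spaces replaced by underscores) so
that community tables and trees from different sources match by exact string
comparison.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import dendropy
import numpy as np

__all__ = [
    "NewickFormatError",
    "Phylogeny",
    "normalize_label",
    "read_newick",
    "prune_to_taxa",
]


class NewickFormatError(ValueError):
    """Raised when a Newick source cannot be parsed or violates tree invariants."""


def normalize_label(label: str) -> str:
    """Trim surrounding whitespace and replace internal spaces with underscores."""
    return label.strip().replace(" ", "_")


class Phylogeny:
    """A rooted tree with branch lengths, the substrate for all metrics.

    Invariants enforced at construction: unique tip labels, a branch length on
    every non-root edge, and no negative branch lengths.

    Parameters
    ----------
    tree:
        A rooted :class:`dendropy.Tree`; it is used as-is (not copied), so do
        not mutate it afterwards.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate_and_index()
        self._D: np.ndarray | None = None
        self._V: np.ndarray | None = None

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        """Parse a Newick string (branch lengths required)."""
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickFormatError(f"invalid Newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def read(cls, path) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                path=str(path), schema="newick", preserve_underscores=True
            )
        except FileNotFoundError:
            raise
        except Exception as exc:
            raise NewickFormatError(f"invalid Newick in {path}: {exc}") from exc
        return cls(tree)

    def _validate_and_index(self) -> None:
        tree = self._tree
        labels: list[str] = []
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or leaf.taxon.label is None:
                raise NewickFormatError("tree contains an unlabelled tip")
            leaf.taxon.label = normalize_label(leaf.taxon.label)
            labels.append(leaf.taxon.label)
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise NewickFormatError(f"duplicate tip labels: {dupes}")
        if not labels:
            raise NewickFormatError("tree has no tips")

        root = tree.seed_node
        for edge in tree.preorder_edge_iter():
            if edge.head_node is root:
                continue
            if edge.length is None:
                raise NewickFormatError(
                    "branch length missing on an edge; all metrics require "
                    "branch lengths"
                )
            if edge.length < 0:
                raise NewickFormatError(f"negative branch length {edge.length}")

        # Stable tip order: order of appearance in the Newick source.
        self._labels: tuple[str, ...] = tuple(labels)
        self._index: dict[str, int] = {l: i for i, l in enumerate(labels)}

        # Node depths and, per tip, the list of edges on the root path.
        n = len(labels)
        depth = {root: 0.0}
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            depth[node] = depth[node.parent_node] + node.edge.length
        self._tip_depths = np.array(
            [depth[leaf] for leaf in tree.leaf_node_iter()], dtype=float
        )

        # Edge indexing for Faith's PD: edge id -> length; per tip the ids on
        # its path to the root (root edge, if any, excluded).
        edge_len: list[float] = []
        edge_id: dict[int, int] = {}
        for edge in tree.preorder_edge_iter():
            if edge.head_node is root or edge.length is None:
                continue
            edge_id[id(edge)] = len(edge_len)
            edge_len.append(edge.length)
        self._edge_lengths = np.asarray(edge_len, dtype=float)
        paths: list[np.ndarray] = []
        for leaf in tree.leaf_node_iter():
            ids = []
            node = leaf
            while node is not root:
                ids.append(edge_id[id(node.edge)])
                node = node.parent_node
            paths.append(np.asarray(ids, dtype=np.intp))
        self._tip_edge_paths = paths
        self._node_depth = depth

    # -- basic accessors ---------------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        """The underlying dendropy tree (treat as read-only)."""
        return self._tree

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return self._labels

    @property
    def n_tips(self) -> int:
        return len(self._labels)

    @property
    def tip_depths(self) -> np.ndarray:
        """Root-to-tip path length per tip, in tip order."""
        return self._tip_depths

    @property
    def total_branch_length(self) -> float:
        return float(self._edge_lengths.sum())

    def indices_of(self, taxa: Iterable[str]) -> np.ndarray:
        """Map tip labels to matrix row indices; unknown labels raise KeyError."""
        taxa = [normalize_label(t) for t in taxa]
        missing = sorted(t for t in taxa if t not in self._index)
        if missing:
            raise KeyError(f"taxa not in tree: {missing}")
        return np.asarray([self._index[t] for t in taxa], dtype=np.intp)

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        d = self._tip_depths
        return bool(np.allclose(d, d[0], rtol=rtol, atol=rtol * max(d.max(), 1.0)))

    # -- geometry ----------------------------------------------------------

    def _compute_matrices(self) -> None:
        """Fill shared-depth (V) and patristic (D) matrices in one postorder pass.

        For tips i, j with root-to-tip depths t_i, t_j and most recent common
        ancestor at depth s_ij, the patristic distance is
        d_ij = t_i + t_j - 2 s_ij, and the Brownian covariance is V_ij = s_ij.
        """
        n = self.n_tips
        V = np.zeros((n, n), dtype=float)
        tipsets: dict[int, np.ndarray] = {}
        leaf_counter = iter(range(n))
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                tipsets[id(node)] = np.array([next(leaf_counter)], dtype=np.intp)
                continue
            child_sets = [tipsets.pop(id(c)) for c in node.child_nodes()]
            d = self._node_depth[node]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    V[np.ix_(child_sets[a], child_sets[b])] = d
                    V[np.ix_(child_sets[b], child_sets[a])] = d
            tipsets[id(node)] = np.concatenate(child_sets)
        np.fill_diagonal(V, self._tip_depths)
        t = self._tip_depths
        D = t[:, None] + t[None, :] - 2.0 * V
        np.fill_diagonal(D, 0.0)
        self._V, self._D = V, D

    @property
    def patristic_matrix(self) -> np.ndarray:
        """Symmetric tip-to-tip path-length matrix, rows/cols in tip order."""
        if self._D is None:
            self._compute_matrices()
        return self._D

    @property
    def covariance_matrix(self) -> np.ndarray:
        """Shared root-to-MRCA branch length per tip pair (Brownian covariance)."""
        if self._V is None:
            self._compute_matrices()
        return self._V

    @property
    def correlation_matrix(self) -> np.ndarray:
        """Covariance scaled to unit diagonal: C_ij = V_ij / sqrt(V_ii V_jj)."""
        V = self.covariance_matrix
        s = np.sqrt(np.diag(V))
        if np.any(s <= 0):
            raise ValueError(
                "a tip sits at zero depth; the phylogenetic correlation "
                "matrix is undefined"
            )
        C = V / np.outer(s, s)
        np.fill_diagonal(C, 1.0)
        return C

    def pd_edges(self, taxa: Iterable[str], include_root: bool = True) -> float:
        """Total branch length of the subtree spanning ``taxa``.

        With ``include_root`` the spanning subtree is anchored at the root
        (the classic definition); otherwise branches above the MRCA of the
        set are excluded.
        """
        idx = self.indices_of(taxa)
        if idx.size == 0:
            raise ValueError("empty taxon set has no phylogenetic diversity")
        paths = [self._tip_edge_paths[i] for i in idx]
        union = np.unique(np.concatenate(paths))
        total = float(self._edge_lengths[union].sum())
        if include_root:
            return total
        shared = paths[0]
        for p in paths[1:]:
            shared = np.intersect1d(shared, p, assume_unique=True)
        return total - float(self._edge_lengths[shared].sum())

    def prune(self, taxa: Iterable[str]) -> "Phylogeny":
        """Return the tree restricted to ``taxa``.

        Unary nodes created by pruning are collapsed with their branch lengths
        summed, so patristic distances between retained tips are unchanged.
        """
        taxa = [normalize_label(t) for t in taxa]
        self.indices_of(taxa)  # raises on missing labels
        sub = self._tree.extract_tree_with_taxa_labels(
            labels=taxa, suppress_unifurcations=True
        )
        return Phylogeny(sub)

    def write(self, path) -> None:
        self._tree.write(path=str(path), schema="newick", unquoted_underscores=True)

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", unquoted_underscores=True)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny with {self.n_tips} tips, total length {self.total_branch_length:.4g}>"


def read_newick(path) -> Phylogeny:
    """Read a rooted Newick tree with branch lengths from ``path``."""
    return Phylogeny.read(path)


def prune_to_taxa(tree: Phylogeny, taxa: Iterable[str]) -> Phylogeny:
    """Prune ``tree`` down to exactly ``taxa`` (patristic distances preserved)."""
    return tree.prune(taxa)
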