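"""Phylogenetic tree container and the covariance kernels used downstream.

A :class:`PhyloTree` is a rooted tree with branch lengths in absolute time
units (Ma here).  It may be *non-ultrametric*: tips representing extinct taxa
end before the present, so root-to-tip depths differ.  Two kernels are
derived from it:

* the Brownian-motion (BM) covariance, ``C[i, j] = depth(MRCA(i, j))`` — the
  shared root-to-MRCA path length of two tips; and
* the Ornstein–Uhlenbeck correlation ``exp(-alpha * d_ij)`` with ``d_ij`` the
  patristic (path-length) distance, i.e. the "corMartins" structure used to
  weight generalized least squares.

Branch lengths are kept in their own time units by default (no rescaling to
unit height), so OU pull rates are expressed per Ma; pass
``normalize_height=True`` where supported to work on a unit-height tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PhyloTree",
    "TipCovariance",
    "NewickError",
    "shared_path_matrix",
    "ou_correlation_matrix",
    "patristic_distances",
]

#: tips whose depth falls short of the maximum by more than this are extinct
EXTINCT_DEPTH_TOL = 1e-6


class NewickError(ValueError):
    """Raised when a newick string cannot be parsed into a valid tree."""


@dataclass
class TipCovariance:
    """A tip-by-tip (co)variance or correlation matrix in a fixed tip order.

    ``kind`` is ``"BM"`` (shared-path covariance, parameter ``sigma2``) or
    ``"OU-correlation"`` (``exp(-alpha d)``, parameter ``alpha``).
    """

    taxa: list[str]
    matrix: np.ndarray
    kind: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match number of taxa")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("covariance matrix must be symmetric")


class PhyloTree:
    """Rooted tree stored as parent-pointer arrays in preorder.

    Node 0 is the root.  ``parent[i]`` is the preorder index of node ``i``'s
    parent (−1 for the root) and ``lengths[i]`` the branch length above node
    ``i`` (0 for the root).  Tip labels are unique non-empty strings; internal
    labels are optional.  Polytomies are accepted as-is.
    """

    def __init__(
        self,
        parent: Sequence[int],
        lengths: Sequence[float],
        labels: Sequence[str | None],
    ) -> None:
        self.parent = np.asarray(parent, dtype=int)
        self.lengths = np.asarray(lengths, dtype=float)
        self.labels = list(labels)
        n = self.parent.size
        if n == 0:
            raise ValueError("empty tree")
        if self.parent[0] != -1 or np.any(self.parent[1:] < 0):
            raise ValueError("nodes must be in preorder with root first")
        if np.any(self.parent[1:] >= np.arange(1, n)):
            raise ValueError("parent indices must precede children (preorder)")
        if np.any(self.lengths[1:] < 0):
            raise ValueError("negative branch length")

        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            self.children[self.parent[i]].append(i)
        self._tip_idx = np.array(
            [i for i in range(n) if not self.children[i]], dtype=int
        )
        tip_labels = [self.labels[i] for i in self._tip_idx]
        if any(lbl is None or not str(lbl).strip() for lbl in tip_labels):
            raise ValueError("every tip must carry a label")
        tip_labels = [str(lbl).strip() for lbl in tip_labels]
        if len(set(tip_labels)) != len(tip_labels):
            dupes = sorted({t for t in tip_labels if tip_labels.count(t) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        self._tip_labels = tip_labels

        zero_term = [
            tip_labels[k]
            for k, i in enumerate(self._tip_idx)
            if self.lengths[i] == 0.0
        ]
        if zero_term:
            warnings.warn(
                "zero-length terminal branch(es) at "
                f"{zero_term}: such tips are perfectly correlated with their "
                "parent under BM",
                stacklevel=2,
            )

        # depths by preorder accumulation
        self._depths = np.zeros(n)
        for i in range(1, n):
            self._depths[i] = self._depths[self.parent[i]] + self.lengths[i]

        # preorder intervals for O(1) ancestor queries
        self._in = np.arange(n)
        self._out = np.arange(n)
        for i in range(n - 1, 0, -1):
            p = self.parent[i]
            self._out[p] = max(self._out[p], self._out[i])

    # ------------------------------------------------------------------ basic

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_tips(self) -> int:
        return self._tip_idx.size

    @property
    def tip_labels(self) -> list[str]:
        return list(self._tip_labels)

    @property
    def tip_indices(self) -> np.ndarray:
        return self._tip_idx.copy()

    @property
    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node (preorder)."""
        return self._depths.copy()

    @property
    def tip_depths(self) -> np.ndarray:
        return self._depths[self._tip_idx].copy()

    @property
    def height(self) -> float:
        """Maximum root-to-tip depth."""
        return float(self._depths[self._tip_idx].max())

    def is_ancestor(self, a: int, b: int) -> bool:
        """True when node ``a`` is an ancestor of (or equal to) node ``b``."""
        return bool(self._in[a] <= self._in[b] <= self._out[a])

    def is_ultrametric(self, tol: float = EXTINCT_DEPTH_TOL) -> bool:
        d = self._depths[self._tip_idx]
        return bool(d.max() - d.min() <= tol)

    def extinct_tips(self, tol: float = EXTINCT_DEPTH_TOL) -> list[str]:
        """Labels of tips whose depth falls short of the deepest tip."""
        d = self._depths[self._tip_idx]
        cutoff = d.max() - tol
        return [self._tip_labels[k] for k in range(self.n_tips) if d[k] < cutoff]

    def tip_index(self, label: str) -> int:
        try:
            return self._tip_idx[self._tip_labels.index(label.strip())]
        except ValueError:
            raise KeyError(f"tip {label!r} not in tree") from None

    # ------------------------------------------------------------------- I/O

    @classmethod
    def from_newick(cls, newick_text: str) -> "PhyloTree":
        """Parse a newick string (branch lengths required on non-root edges)."""
        import dendropy

        try:
            dtree = dendropy.Tree.get(
                data=newick_text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy errors carry line/column info
            raise NewickError(f"malformed newick: {exc}") from exc

        parent: list[int] = []
        lengths: list[float] = []
        labels: list[str | None] = []
        index: dict[int, int] = {}
        for node in dtree.preorder_node_iter():
            i = len(parent)
            index[id(node)] = i
            if node.parent_node is None:
                parent.append(-1)
                lengths.append(0.0)
            else:
                parent.append(index[id(node.parent_node)])
                if node.edge.length is None:
                    where = (
                        node.taxon.label
                        if node.taxon is not None
                        else f"internal node #{i}"
                    )
                    raise NewickError(f"missing branch length above {where}")
                lengths.append(float(node.edge.length))
            if node.taxon is not None:
                labels.append(str(node.taxon.label).strip())
            elif node.label is not None:
                labels.append(str(node.label).strip())
            else:
                labels.append(None)
        return cls(parent, lengths, labels)

    def to_newick(self, node_labels: dict[int, str] | None = None) -> str:
        """Serialize to newick.  ``node_labels`` overrides internal labels."""

        def fmt(i: int) -> str:
            lbl = (node_labels or {}).get(i, self.labels[i]) or ""
            if self.children[i]:
                inner = ",".join(fmt(c) for c in self.children[i])
                core = f"({inner}){lbl}"
            else:
                core = str(lbl)
            if self.parent[i] == -1:
                return core
            return f"{core}:{self.lengths[i]:.10g}"

        return fmt(0) + ";"

    # ------------------------------------------------------------- kernels

    def mrca(self, a: int, b: int) -> int:
        """Preorder index of the most recent common ancestor of two nodes."""
        u = a
        while not self.is_ancestor(u, b):
            u = self.parent[u]
        return u

    def shared_times(self, nodes: Sequence[int] | None = None) -> np.ndarray:
        """Matrix of MRCA depths for a node set (default: tips, tip order).

        Entry (i, j) is the root-to-MRCA path length — the time during which
        lineages i and j evolved together.  The diagonal is the node depth.
        """
        if nodes is None:
            if not hasattr(self, "_tip_shared"):
                self._tip_shared = self.shared_times(self._tip_idx)
            return self._tip_shared.copy()
        idx = np.asarray(nodes, dtype=int)
        m = idx.size
        S = np.empty((m, m))
        for a in range(m):
            S[a, a] = self._depths[idx[a]]
            for b in range(a + 1, m):
                S[a, b] = S[b, a] = self._depths[self.mrca(idx[a], idx[b])]
        return S

    def patristic(self, nodes: Sequence[int] | None = None) -> np.ndarray:
        """Path-length distances between nodes (default: tips, tip order)."""
        idx = self._tip_idx if nodes is None else np.asarray(nodes, dtype=int)
        S = self.shared_times(None if nodes is None else idx)
        d = self._depths[idx]
        return d[:, None] + d[None, :] - 2.0 * S

    def normalized(self) -> "PhyloTree":
        """Copy with branch lengths divided by tree height (unit height)."""
        return PhyloTree(self.parent, self.lengths / self.height, self.labels)


# ---------------------------------------------------------------- functions


def read_tree(newick_text: str) -> PhyloTree:
    """Parse newick text into a :class:`PhyloTree` (see ``from_newick``)."""
    return PhyloTree.from_newick(newick_text)


def shared_path_matrix(tree: PhyloTree) -> TipCovariance:
    """BM tip covariance: entry (i, j) = root-to-MRCA path length."""
    return TipCovariance(
        taxa=tree.tip_labels,
        matrix=tree.shared_times(),
        kind="BM",
        parameters={"sigma2": 1.0},
    )


def patristic_distances(tree: PhyloTree) -> np.ndarray:
    """Tip-tip patristic distance matrix in tip-label order."""
    return tree.patristic()


def ou_correlation_matrix(
    tree: PhyloTree, alpha: float, normalize_height: bool = False
) -> TipCovariance:
    """OU ("corMartins") tip correlation ``exp(-alpha * d_ij)``, unit diagonal.

    ``alpha`` is the mean-reversion rate per unit branch length (per Ma when
    the tree is in Ma).  With ``normalize_height=True`` distances are divided
    by tree height first, so alpha is per unit tree height.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    D = tree.patristic()
    if normalize_height:
        D = D / tree.height
    M = np.exp(-alpha * D)
    np.fill_diagonal(M, 1.0)
    return TipCovariance(
        taxa=tree.tip_labels,
        matrix=M,
        kind="OU-correlation",
        parameters={"alpha": float(alpha), "normalize_height": normalize_height},
    )
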