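"""Time-scaled phylogenies (chronograms) and the Brownian-motion covariance.

A :class:`Chronogram` is a rooted tree whose branch lengths are in Myr.
Because many tips are fossils, trees are generally *non-ultrametric*: tips
terminate at different distances from the root. Under Brownian motion a
trait evolved on such a tree has covariance matrix ``C`` with
``C[i, j]`` equal to the shared root-to-MRCA path length of tips *i* and
*j* — the amount of evolutionary history the two lineages have in common.
Pagel's lambda rescales the off-diagonal of ``C``, interpolating between
the full phylogenetic covariance (lambda = 1) and independent tips
(lambda = 0).

Trees are wrapped around :mod:`dendropy`; Newick and NEXUS input is
accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

#: Default age (Myr) of the hypothetical common ancestor inserted between
#: conspecific plates, per the splitting rule used to place multiple
#: sections of one species on the tree.
CONSPECIFIC_SPLIT_MYR = 1.0

#: Perturbation applied to zero-length terminal branches only when they
#: make the phylogenetic covariance singular.
ZERO_BRANCH_EPSILON = 1e-8

__all__ = [
    "Chronogram",
    "PhyloCovariance",
    "parse_chronogram",
    "phylo_covariance",
    "lambda_transform",
    "split_conspecific_tips",
    "CONSPECIFIC_SPLIT_MYR",
]


class ChronogramError(ValueError):
    """Raised for structurally invalid chronograms."""


@dataclass
class Chronogram:
    """A rooted tree with branch lengths in Myr and specimen-labelled tips."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ChronogramError(f"duplicate tip labels: {dupes}")
        for nd in self.tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            if nd.edge.length is None:
                name = nd.taxon.label if nd.taxon else (nd.label or "<internal>")
                raise ChronogramError(f"missing branch length on edge to {name!r}")
            if nd.edge.length < 0:
                name = nd.taxon.label if nd.taxon else (nd.label or "<internal>")
                raise ChronogramError(f"negative branch length on edge to {name!r}")

    # -- constructors -------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "Chronogram":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except dendropy.utility.error.DataParseError as exc:
            raise ChronogramError(str(exc)) from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path, schema: str = "newick") -> "Chronogram":
        try:
            tree = dendropy.Tree.get(
                path=str(path), schema=schema, preserve_underscores=True
            )
        except dendropy.utility.error.DataParseError as exc:
            raise ChronogramError(str(exc)) from exc
        return cls(tree)

    # -- basic structure ----------------------------------------------
    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def to_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length (Myr) per tip label."""
        depths: dict[str, float] = {}
        for nd, d in _node_depths(self.tree).items():
            if nd.is_leaf():
                depths[nd.taxon.label] = d
        return depths

    def clone(self) -> "Chronogram":
        return Chronogram(self.tree.clone(depth=1))

    def covariance(self) -> "PhyloCovariance":
        return phylo_covariance(self)


@dataclass
class PhyloCovariance:
    """Brownian-motion covariance: shared root-to-MRCA path lengths (Myr)."""

    matrix: np.ndarray
    tip_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("covariance matrix must be square")
        if self.tip_order and len(self.tip_order) != self.matrix.shape[0]:
            raise ValueError("tip_order length does not match matrix size")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def reorder(self, tip_order: Sequence[str]) -> "PhyloCovariance":
        idx = [self.tip_order.index(t) for t in tip_order]
        return PhyloCovariance(self.matrix[np.ix_(idx, idx)], list(tip_order))

    def lambda_transform(self, lam: float) -> "PhyloCovariance":
        return lambda_transform(self, lam)


def parse_chronogram(newick: str) -> Chronogram:
    """Parse a Newick string (branch lengths required) into a chronogram."""
    return Chronogram.from_newick(newick)


def _node_depths(tree: dendropy.Tree) -> dict:
    depths = {tree.seed_node: 0.0}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            depths[nd] = depths[nd.parent_node] + (nd.edge.length or 0.0)
    return depths


def phylo_covariance(tree: Chronogram) -> PhyloCovariance:
    """Compute ``C[i, j]`` = root-to-MRCA(i, j) path length for all tip pairs.

    The diagonal holds the root-to-tip depths, so ultrametric trees give a
    constant diagonal and fossil tips a shorter one. Computed by a single
    postorder sweep: an internal node at depth *d* is the MRCA of every tip
    pair drawn from two different child subtrees.
    """
    t = tree.tree
    tips = list(t.leaf_node_iter())
    index = {nd: i for i, nd in enumerate(tips)}
    depths = _node_depths(t)
    n = len(tips)
    C = np.zeros((n, n))

    leafsets: dict = {}
    for nd in t.postorder_node_iter():
        if nd.is_leaf():
            leafsets[nd] = [index[nd]]
            C[index[nd], index[nd]] = depths[nd]
        else:
            children = [leafsets.pop(ch) for ch in nd.child_nodes()]
            d = depths[nd]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    ia = np.asarray(children[a])
                    ib = np.asarray(children[b])
                    C[np.ix_(ia, ib)] = d
                    C[np.ix_(ib, ia)] = d
            leafsets[nd] = [i for ch in children for i in ch]

    # zero-length terminal branches can duplicate rows of C; perturb the
    # affected diagonal entries only when that actually makes C singular
    try:
        np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        zero_tips = [
            i for i, lf in enumerate(tips) if (lf.edge.length or 0.0) == 0.0
        ]
        if zero_tips:
            logger.warning(
                "singular covariance: perturbing %d zero-length terminal "
                "branch(es) by %g Myr", len(zero_tips), ZERO_BRANCH_EPSILON
            )
            C[zero_tips, zero_tips] += ZERO_BRANCH_EPSILON
    return PhyloCovariance(C, [lf.taxon.label for lf in tips])


def lambda_transform(C: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Multiply the off-diagonal of ``C`` by ``lam``; diagonal unchanged.

    Raises if the result is not positive definite, which signals a ``lam``
    too large for this tree (possible above 1 on non-ultrametric trees).
    """
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    M = C.matrix * lam
    np.fill_diagonal(M, np.diag(C.matrix))
    try:
        np.linalg.cholesky(M)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"lambda={lam} makes the covariance non positive definite"
        ) from exc
    return PhyloCovariance(M, list(C.tip_order))


def split_conspecific_tips(
    tree: Chronogram,
    groups: Mapping[str, Sequence[str]],
    delta: float = CONSPECIFIC_SPLIT_MYR,
) -> Chronogram:
    """Replace placeholder tips by cherries of conspecific specimen tips.

    Plates belonging to the same species (or the same specimen) cannot be
    resolved by the phylogeny, so each such group is hung from a
    hypothetical common ancestor ``delta`` Myr older than the placeholder
    tip: the placeholder's pendant branch is shortened by ``delta`` and *k*
    child branches of length ``delta`` are attached, one per specimen.
    With ``delta`` = 1 Myr on trees spanning hundreds of Myr the induced
    distortion of path lengths is below 1%. Groups of size 1 simply rename
    the placeholder. Pairwise MRCA ages between specimens of different
    groups are preserved exactly.
    """
    if delta <= 0:
        raise ValueError(f"delta must be > 0, got {delta}")
    out = tree.clone()
    t = out.tree
    by_label = {lf.taxon.label: lf for lf in t.leaf_node_iter()}
    all_new = [m for members in groups.values() for m in members]
    if len(set(all_new)) != len(all_new):
        raise ValueError("specimen ids repeated across groups")

    for placeholder, members in groups.items():
        if placeholder not in by_label:
            raise KeyError(f"placeholder tip {placeholder!r} not in tree")
        if len(members) == 0:
            raise ValueError(f"group {placeholder!r} is empty")
        node = by_label[placeholder]
        if len(members) == 1:
            node.taxon = t.taxon_namespace.new_taxon(label=members[0])
            continue
        if node.edge.length is None or node.edge.length <= delta:
            raise ValueError(
                f"pendant branch of {placeholder!r} ({node.edge.length}) "
                f"too short to insert a {delta}-Myr-old ancestor"
            )
        node.edge.length -= delta
        node.taxon = None
        for member in members:
            child = node.new_child(edge_length=delta)
            child.taxon = t.taxon_namespace.new_taxon(label=member)
    return Chronogram(t)
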