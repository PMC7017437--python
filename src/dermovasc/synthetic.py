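"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: time-scaled
trees, continuous traits evolved on them, and two-valued cross-section
rasters of known porosity with optional apical ornamentation. The
generators emulate the *statistical and geometric structure* the analysis
assumes — Brownian motion with a controllable lambda and rate, lifestyle
mean shifts, enclosed vascular cavities, crest/pit ornament — not the
texture of real histological sections.

Default simulation conditions mirror the shape of the real datasets:
trees of ~64 tips spanning 200 Myr (the two empirical chronograms span
180 and 250 Myr), a Brownian rate sized so that tip standard deviations
land near 0.1 porosity units, and a root state of 0.15 in the middle of
the observed porosity range.

Everything is deterministic under its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
from skimage.draw import disk as draw_disk
from scipy import ndimage

from .porosity import BinarySection
from .signal import TraitVector
from .trees import Chronogram, lambda_transform, phylo_covariance

logger = logging.getLogger(__name__)

TREE_SHAPES = ("balanced", "yule-like", "star", "fixed-newick")

__all__ = [
    "SimulationSpec",
    "SectionSpec",
    "SectionGroundTruth",
    "simulate_tree",
    "simulate_traits",
    "assign_groups",
    "generate_section",
    "TREE_SHAPES",
]


@dataclass
class SimulationSpec:
    """Conditions for tree + trait simulation."""

    n_tips: int = 64
    tree_shape: str = "yule-like"
    depth: float = 200.0  # root-to-tip span, Myr
    sigma2: float = 5e-5  # BM rate, trait variance per Myr
    lam: float = 1.0  # Pagel's lambda of the generating process
    root_state: float = 0.15
    group_assignment: str = "random"  # or "clade-based"
    n_groups: int = 2
    effect_sizes: dict | None = None  # group label -> mean shift
    newick: str | None = None  # for tree_shape == "fixed-newick"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 3:
            raise ValueError("n_tips must be >= 3")
        if self.sigma2 <= 0 or self.depth <= 0:
            raise ValueError("sigma2 and depth must be positive")
        if not 0 <= self.lam <= 1:
            raise ValueError("lam must lie in [0, 1]")
        if self.tree_shape not in TREE_SHAPES:
            raise ValueError(f"tree_shape must be one of {TREE_SHAPES}")


@dataclass
class SectionSpec:
    """Conditions for synthetic cross-section rasters."""

    width: int = 400
    height: int = 300
    target_porosity: float = 0.18
    pore_radius_mean: float = 6.0
    pore_radius_sd: float = 2.0
    ornamented: bool = False
    n_crests: int = 5
    crest_height: int = 20  # pixels above the inter-crest baseline
    pit_depth: int = 10  # pixels carved below the baseline between crests
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_porosity < 0.6:
            raise ValueError("target_porosity must lie in [0, 0.6)")
        if self.width < 40 or self.height < 40:
            raise ValueError("raster too small")
        if self.ornamented:
            if self.n_crests < 2:
                raise ValueError("ornamented sections need at least 2 crests")
            if self.crest_height + self.pit_depth + 20 > self.height:
                raise ValueError("ornament does not fit the raster height")


@dataclass
class SectionGroundTruth:
    pore_mask: np.ndarray  # enclosed cavities carved into the bone
    pit_mask: np.ndarray  # pit space enclosed once crests are bridged
    apex_coords: list  # (row, col) of each crest apex
    bone_area: int
    pore_area: int
    pit_area: int
    porosity: float  # pore_area / (pore_area + bone_area)


# -- trees -----------------------------------------------------------------

def _new_tree() -> dendropy.Tree:
    return dendropy.Tree(taxon_namespace=dendropy.TaxonNamespace())


def _label_leaves(tree: dendropy.Tree) -> None:
    for i, lf in enumerate(tree.leaf_node_iter(), start=1):
        lf.taxon = tree.taxon_namespace.new_taxon(label=f"t{i}")


def _balanced(n: int, depth: float) -> dendropy.Tree:
    """Near-balanced ultrametric topology: node ages halve at each split."""
    tree = _new_tree()

    def grow(node, k: int, age: float) -> None:
        child_age = age / 2.0
        for size in (k - k // 2, k // 2):
            if size == 1:
                node.new_child(edge_length=age)  # leaf spans down to 0
            else:
                ch = node.new_child(edge_length=age - child_age)
                grow(ch, size, child_age)

    grow(tree.seed_node, n, depth)
    _label_leaves(tree)
    return tree


def _star(n: int, depth: float) -> dendropy.Tree:
    tree = _new_tree()
    for _ in range(n):
        tree.seed_node.new_child(edge_length=depth)
    _label_leaves(tree)
    return tree


def _yule(n: int, depth: float, rng: np.random.Generator) -> dendropy.Tree:
    tree = _new_tree()
    tree.seed_node.time_ = 0.0
    leaves = [tree.seed_node.new_child(), tree.seed_node.new_child()]
    t = 0.0
    while len(leaves) < n:
        t += rng.exponential(1.0 / len(leaves))
        nd = leaves.pop(int(rng.integers(len(leaves))))
        nd.time_ = t
        leaves.extend([nd.new_child(), nd.new_child()])
    total = t + rng.exponential(1.0 / n)
    scale = depth / total
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        child_t = getattr(nd, "time_", total)
        nd.edge.length = (child_t - nd.parent_node.time_) * scale
    _label_leaves(tree)
    return tree


def simulate_tree(spec: SimulationSpec, seed: int | None = None) -> Chronogram:
    """Generate a chronogram of the requested shape; ultrametric by design."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if spec.tree_shape == "star":
        tree = _star(spec.n_tips, spec.depth)
    elif spec.tree_shape == "balanced":
        tree = _balanced(spec.n_tips, spec.depth)
    elif spec.tree_shape == "yule-like":
        tree = _yule(spec.n_tips, spec.depth, rng)
    else:  # fixed-newick
        if not spec.newick:
            raise ValueError("tree_shape 'fixed-newick' requires spec.newick")
        return Chronogram.from_newick(spec.newick)
    return Chronogram(tree)


def assign_groups(
    tree: Chronogram, spec: SimulationSpec, seed: int | None = None
) -> np.ndarray:
    """Group labels per tip: balanced random, or by subtree under the root."""
    n = tree.n_tips
    labels = np.array([f"g{i % spec.n_groups}" for i in range(n)])
    if spec.group_assignment == "random":
        rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
        return labels[rng.permutation(n)]
    if spec.group_assignment == "clade-based":
        tips = list(tree.tree.leaf_node_iter())
        index = {lf.taxon.label: i for i, lf in enumerate(tips)}
        out = np.empty(n, dtype=object)
        children = tree.tree.seed_node.child_nodes()
        for ci, ch in enumerate(children):
            for lf in ch.leaf_iter():
                out[index[lf.taxon.label]] = f"g{ci % spec.n_groups}"
        return out.astype(str)
    raise ValueError(f"unknown group_assignment {spec.group_assignment!r}")


def simulate_traits(
    tree: Chronogram,
    spec: SimulationSpec,
    groups: np.ndarray | None = None,
    seed: int | None = None,
) -> TraitVector:
    """Evolve a trait on the tree: BM increments, lambda blending, shifts.

    With ``lam`` = 1 the trait is built by exact root-to-tip Gaussian
    branch increments (cheap on large trees); for ``lam`` < 1 tips are
    drawn jointly from ``N(root_state, sigma2 * C(lam))`` through a
    Cholesky factor. Group mean shifts from ``spec.effect_sizes`` are
    added afterwards.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    tip_order = tree.tip_labels
    if spec.lam == 1.0:
        values_by_node: dict = {tree.tree.seed_node: spec.root_state}
        out = {}
        for nd in tree.tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            step = rng.normal(0.0, np.sqrt(spec.sigma2 * nd.edge.length)) if nd.edge.length > 0 else 0.0
            values_by_node[nd] = values_by_node[nd.parent_node] + step
            if nd.is_leaf():
                out[nd.taxon.label] = values_by_node[nd]
        x = np.array([out[t] for t in tip_order])
    else:
        C = lambda_transform(phylo_covariance(tree), spec.lam)
        L = np.linalg.cholesky(spec.sigma2 * C.matrix)
        x = spec.root_state + L @ rng.standard_normal(len(tip_order))

    if groups is not None and spec.effect_sizes:
        shifts = np.array([spec.effect_sizes.get(g, 0.0) for g in np.asarray(groups)])
        x = x + shifts
    return TraitVector(x, tip_order, trait_name="porosity")


# -- binary sections -------------------------------------------------------

_MARGIN = 3  # exterior void frame around the section


def generate_section(
    spec: SectionSpec, seed: int | None = None
) -> tuple[BinarySection, SectionGroundTruth]:
    """Draw a bone silhouette with enclosed pores at the target porosity.

    Pores are rejection-sampled non-overlapping discs (radius ~ Normal,
    clipped at 1 px) carved at least two pixels inside the bone, topped up
    with isolated single-pixel pores so the carved area hits
    ``round(target * silhouette_area)`` exactly — the achieved porosity
    differs from the target only by that rounding. Ornamented sections
    carry ``n_crests`` equal-height triangular crests whose apices are
    recorded, with pits of ``pit_depth`` carved between the crest bases;
    the pit ground truth is exactly the void that apex-chaining encloses.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    H, W = spec.height, spec.width
    bone = np.zeros((H, W), dtype=bool)

    baseline = _MARGIN + (spec.crest_height if spec.ornamented else 0)
    bottom, left, right = H - _MARGIN - 1, _MARGIN, W - _MARGIN - 1
    bone[baseline : bottom + 1, left : right + 1] = True

    apex_coords: list[tuple[int, int]] = []
    if spec.ornamented:
        h = spec.crest_height
        bw = h  # 45-degree flanks: base half-width == height
        span = right - left - 2 * bw - 2
        if spec.n_crests * (2 * bw + 2) > span + 2 * bw:
            raise ValueError("crests do not fit the raster width")
        cols = np.linspace(left + bw + 1, right - bw - 1, spec.n_crests)
        cols = np.round(cols).astype(int)
        apex_row = baseline - h
        for c in cols:
            for d in range(h + 1):
                hw = int(round(d * bw / h))
                bone[apex_row + d, c - hw : c + hw + 1] = True
            apex_coords.append((apex_row, int(c)))
        # carve pits between consecutive crest bases
        for c0, c1 in zip(cols[:-1], cols[1:]):
            lo, hi = c0 + bw + 1, c1 - bw - 1
            if lo <= hi:
                bone[baseline : baseline + spec.pit_depth, lo : hi + 1] = False

    bone_area0 = int(bone.sum())
    target_pore = int(round(spec.target_porosity * bone_area0))

    # pore placement region: >= 2 px inside the solid body
    row_lo = baseline + (spec.pit_depth if spec.ornamented else 0) + 2
    row_hi, col_lo, col_hi = bottom - 2, left + 2, right - 2
    if row_hi <= row_lo or col_hi <= col_lo:
        raise ValueError("no interior room for pores")

    pore_mask = np.zeros_like(bone)
    placed = 0
    attempts = 0
    while placed < target_pore and attempts < 20000:
        attempts += 1
        remaining = target_pore - placed
        r = int(np.clip(round(rng.normal(spec.pore_radius_mean, spec.pore_radius_sd)), 1, 50))
        # shrink the disc rather than overshooting the target area
        while r > 1 and np.pi * r * r > remaining:
            r -= 1
        if np.pi * r * r > remaining:
            break  # finish with single pixels
        cr = int(rng.integers(row_lo + r, row_hi - r + 1)) if row_hi - r + 1 > row_lo + r else None
        cc = int(rng.integers(col_lo + r, col_hi - r + 1)) if col_hi - r + 1 > col_lo + r else None
        if cr is None or cc is None:
            break
        rr, cc_idx = draw_disk((cr, cc), r, shape=bone.shape)
        if rr.size > remaining:  # never overshoot the exact pixel target
            continue
        # keep a 1-px bone gap around every pore: reject near-contact
        r0, r1 = rr.min() - 1, rr.max() + 2
        c0, c1 = cc_idx.min() - 1, cc_idx.max() + 2
        if pore_mask[r0:r1, c0:c1].any():
            continue
        pore_mask[rr, cc_idx] = True
        placed += rr.size

    if placed < target_pore:  # exact top-up with isolated single pixels
        struct = np.ones((3, 3), dtype=bool)
        for _ in range(target_pore - placed):
            blocked = ndimage.binary_dilation(pore_mask | ~bone, structure=struct)
            cand_r, cand_c = np.nonzero(~blocked)
            ok = (cand_r >= row_lo) & (cand_r <= row_hi) & (cand_c >= col_lo) & (cand_c <= col_hi)
            cand_r, cand_c = cand_r[ok], cand_c[ok]
            if cand_r.size == 0:
                raise ValueError("target porosity unreachable for this geometry")
            j = int(rng.integers(cand_r.size))
            pore_mask[cand_r[j], cand_c[j]] = True
            placed += 1

    bone &= ~pore_mask
    bone_area = int(bone.sum())
    pore_area = int(pore_mask.sum())

    pit_mask = np.zeros_like(bone)
    if spec.ornamented and len(apex_coords) >= 2:
        apex_row = apex_coords[0][0]
        c_first, c_last = apex_coords[0][1], apex_coords[-1][1]
        top_bone = np.where(bone.any(axis=0), np.argmax(bone, axis=0), H)
        rows = np.arange(H)[:, None]
        cols_g = np.arange(W)[None, :]
        pit_mask = (
            (rows > apex_row)
            & (rows < top_bone[None, :])
            & (cols_g >= c_first)
            & (cols_g <= c_last)
        )

    gt = SectionGroundTruth(
        pore_mask=pore_mask,
        pit_mask=pit_mask,
        apex_coords=apex_coords,
        bone_area=bone_area,
        pore_area=pore_area,
        pit_area=int(pit_mask.sum()),
        porosity=pore_area / (pore_area + bone_area),
    )
    return BinarySection(bone), gt
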