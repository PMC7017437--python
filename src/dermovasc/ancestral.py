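"""Squared-change parsimony ancestral reconstruction of a continuous trait.

Internal-node states are chosen to minimise the (optionally branch-length
weighted) sum of squared changes along branches::

    sum over branches (x_child - x_parent)^2 / w_b

with ``w_b`` the branch length in the weighted form and 1 otherwise.
This is a strictly convex quadratic with a unique minimiser, found by
solving the normal equations — a graph-Laplacian linear system over the
internal nodes with tip values fixed. The weighted solution coincides
with the maximum-likelihood ancestral states under Brownian motion, which
is why the weighted form is the default alongside the K/lambda analyses;
the unweighted variant is kept because historical implementations differ.

By the maximum principle every reconstructed state lies inside the range
of the tip values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import Chronogram, _node_depths
from .signal import TraitVector

__all__ = ["AncestralReconstruction", "squared_change_parsimony"]


@dataclass
class AncestralReconstruction:
    node_states: dict[str, float]  # internal node id -> state
    tip_states: TraitVector
    objective: float
    node_depths: dict[str, float] = field(default_factory=dict)
    weighted: bool = True

    def to_dataframe(self, root_age: float | None = None) -> pd.DataFrame:
        """Table of node_id, depth-from-root (Myr), reconstructed state.

        With ``root_age`` an absolute age column (root_age - depth) is
        added, useful for fossil chronograms whose root age is known.
        """
        rows = []
        for nid, state in self.node_states.items():
            row = {
                "node_id": nid,
                "depth_from_root": self.node_depths.get(nid, np.nan),
                "reconstructed_state": state,
            }
            if root_age is not None:
                row["age"] = root_age - row["depth_from_root"]
            rows.append(row)
        return pd.DataFrame(rows)


def squared_change_parsimony(
    tree: Chronogram, traits: TraitVector, weighted: bool = True
) -> AncestralReconstruction:
    """Minimise the weighted sum of squared changes over internal states.

    Tip states are the data; each internal node (including the root)
    satisfies the stationarity condition that the conductance-weighted
    mean of its neighbours equals its own state (conductance = 1/branch
    length when ``weighted``). Solved as a dense symmetric linear system;
    the trees involved have tens of nodes.
    """
    t = tree.tree
    tip_map = {lf.taxon.label: lf for lf in t.leaf_node_iter()}
    if traits.tip_order:
        if set(traits.tip_order) != set(tip_map):
            raise ValueError("trait tip order does not match tree tips")
        values = {lbl: v for lbl, v in zip(traits.tip_order, traits.values)}
    else:
        if traits.n != len(tip_map):
            raise ValueError("trait length does not match number of tips")
        values = {lbl: v for lbl, v in zip(tree.tip_labels, traits.values)}

    internal = [nd for nd in t.preorder_node_iter() if not nd.is_leaf()]
    if not internal:
        raise ValueError("tree has no internal nodes")
    index = {nd: i for i, nd in enumerate(internal)}
    m = len(internal)
    A = np.zeros((m, m))
    b = np.zeros(m)

    def conductance(edge_length: float | None) -> float:
        if not weighted:
            return 1.0
        if edge_length is None or edge_length <= 0:
            raise ValueError(
                "weighted squared-change parsimony needs strictly positive "
                "branch lengths"
            )
        return 1.0 / edge_length

    for nd in internal:
        i = index[nd]
        for child in nd.child_nodes():
            c = conductance(child.edge.length)
            A[i, i] += c
            if child.is_leaf():
                b[i] += c * values[child.taxon.label]
            else:
                A[i, index[child]] -= c
        if nd.parent_node is not None:
            c = conductance(nd.edge.length)
            A[i, i] += c
            A[i, index[nd.parent_node]] -= c

    try:
        states = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular system: tree is degenerate or disconnected") from exc

    # stable internal node ids: existing labels, else preorder numbering
    ids = {}
    for k, nd in enumerate(internal):
        ids[nd] = nd.label if nd.label else f"node{k}"

    objective = 0.0
    for nd in t.preorder_node_iter():
        if nd.parent_node is None:
            continue
        xc = values[nd.taxon.label] if nd.is_leaf() else states[index[nd]]
        xp = states[index[nd.parent_node]]
        objective += conductance(nd.edge.length) * (xc - xp) ** 2

    depths = _node_depths(t)
    return AncestralReconstruction(
        node_states={ids[nd]: float(states[index[nd]]) for nd in internal},
        tip_states=traits,
        objective=float(objective),
        node_depths={ids[nd]: float(depths[nd]) for nd in internal},
        weighted=weighted,
    )
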