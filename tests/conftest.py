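"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive quantities by a different route
than the library (breadth-first flood fill, explicit dense inverses,
pairwise MRCA scans, generic numeric minimisation) so that agreement is
meaningful.
"""

from collections import deque

import numpy as np
import pytest

from dermovasc import Chronogram, PhyloCovariance, parse_chronogram


@pytest.fixture
def tree3() -> Chronogram:
    return parse_chronogram("((A:1,B:1):1,C:2);")


@pytest.fixture
def tree6() -> Chronogram:
    # non-ultrametric, mixed depths; used for worked K / lambda instances
    return parse_chronogram(
        "(((A:2.0,B:1.5):1.0,(C:0.8,D:2.2):2.0):1.0,(E:3.0,F:2.5):0.5);"
    )


# ---------------------------------------------------------------- oracles

def flood_fill_porosity(bone: np.ndarray) -> float:
    """Brute-force: BFS from the border over void (4-neighbour) pixels;
    porosity = unreachable void / (unreachable void + bone)."""
    H, W = bone.shape
    seen = np.zeros_like(bone, dtype=bool)
    dq = deque()
    for r in range(H):
        for c in (0, W - 1):
            if not bone[r, c] and not seen[r, c]:
                seen[r, c] = True
                dq.append((r, c))
    for c in range(W):
        for r in (0, H - 1):
            if not bone[r, c] and not seen[r, c]:
                seen[r, c] = True
                dq.append((r, c))
    while dq:
        r, c = dq.popleft()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < H and 0 <= cc < W and not bone[rr, cc] and not seen[rr, cc]:
                seen[rr, cc] = True
                dq.append((rr, cc))
    enclosed = int((~bone & ~seen).sum())
    return enclosed / (enclosed + int(bone.sum()))


def brute_covariance(tree: Chronogram) -> PhyloCovariance:
    """Pairwise MRCA path sums by explicit ancestor-set intersection."""
    t = tree.tree
    tips = list(t.leaf_node_iter())

    def ancestors(nd):
        out = []
        while nd is not None:
            out.append(nd)
            nd = nd.parent_node
        return out

    def depth(nd):
        d = 0.0
        while nd.parent_node is not None:
            d += nd.edge.length
            nd = nd.parent_node
        return d

    n = len(tips)
    C = np.zeros((n, n))
    for i in range(n):
        anc_i = ancestors(tips[i])
        for j in range(n):
            if i == j:
                C[i, i] = depth(tips[i])
                continue
            anc_j = set(id(a) for a in ancestors(tips[j]))
            mrca = next(a for a in anc_i if id(a) in anc_j)
            C[i, j] = depth(mrca)
    return PhyloCovariance(C, [lf.taxon.label for lf in tips])


def dense_K(x: np.ndarray, C: np.ndarray) -> float:
    """Blomberg's K from scratch with explicit dense inverses."""
    n = x.size
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    a = (ones @ Cinv @ x) / (ones @ Cinv @ ones)
    r = x - a
    mse = r @ Cinv @ r / (n - 1)
    mse0 = r @ r / (n - 1)
    expected = (np.trace(C) - n / (ones @ Cinv @ ones)) / (n - 1)
    return (mse0 / mse) / expected


def dense_lambda_loglik(x: np.ndarray, C: np.ndarray, lam: float) -> float:
    """Profile log-likelihood of lambda via explicit dense algebra."""
    n = x.size
    M = C * lam
    np.fill_diagonal(M, np.diag(C))
    Minv = np.linalg.inv(M)
    ones = np.ones(n)
    a = (ones @ Minv @ x) / (ones @ Minv @ ones)
    r = x - a
    s2 = r @ Minv @ r / n
    sign, logdet = np.linalg.slogdet(M)
    return -0.5 * (n * np.log(2 * np.pi) + n * np.log(s2) + logdet + n)
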