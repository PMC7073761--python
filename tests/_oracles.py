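"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles (brute
force, enumeration, direct likelihood maximization) and shares no code
path with the package implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import minimize, minimize_scalar, nnls

# ---------------------------------------------------------------------------
# Maximum-likelihood distance oracles
# ---------------------------------------------------------------------------

def jc_ml_distance(p: float, n: int) -> float:
    """MLE of the JC distance by direct 1-D likelihood maximization.

    Under JC the probability that a site differs after distance d is
    q(d) = (3/4)(1 - exp(-4d/3)); the likelihood is binomial in the
    number of differing sites.
    """
    nd = p * n

    def negloglik(d: float) -> float:
        q = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
        if q <= 0.0 or q >= 1.0:
            return np.inf
        return -(nd * math.log(q) + (n - nd) * math.log(1.0 - q))

    res = minimize_scalar(
        negloglik, bounds=(1e-9, 10.0), method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


def _k2p_pq(d: float, kappa: float) -> tuple[float, float]:
    """Expected transition/transversion proportions after distance d
    under K2P with ts/tv rate ratio kappa (rates normalized so the
    total substitution rate is 1 per unit d)."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = math.exp(-4.0 * beta * d)
    e2 = math.exp(-2.0 * (alpha + beta) * d)
    return 0.25 + 0.25 * e1 - 0.5 * e2, 0.5 * (1.0 - e1)


def k2p_ml_distance(P: float, Q: float, n: int) -> float:
    """MLE of the K2P distance by 2-D likelihood maximization over
    (d, kappa), multinomial in (transitions, transversions, identities).
    """
    nts, ntv = P * n, Q * n
    nsame = n - nts - ntv

    def negloglik(x: np.ndarray) -> float:
        d, kappa = x
        if d <= 0.0 or kappa <= 0.0:
            return np.inf
        p, q = _k2p_pq(d, kappa)
        same = 1.0 - p - q
        if min(p, q, same) <= 0.0:
            return np.inf
        return -(
            nts * math.log(p) + ntv * math.log(q / 2.0) + nsame * math.log(same)
        )

    best = None
    for d0, k0 in [(0.1, 2.0), (0.5, 2.0), (1.0, 5.0), (0.05, 0.5)]:
        res = minimize(
            negloglik, x0=[d0, k0], method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000},
        )
        if best is None or res.fun < best.fun:
            best = res
    return float(best.x[0])


# ---------------------------------------------------------------------------
# Exhaustive least-squares tree oracle
# ---------------------------------------------------------------------------

def _enumerate_topologies(labels: list[str]):
    """All unrooted binary topologies by sequential taxon insertion.

    A topology is a list of edges; each edge is (node_a, node_b) over
    string leaf labels and integer internal ids.  3 taxa -> 1 topology,
    4 -> 3, 5 -> 15.
    """
    assert len(labels) >= 3
    base = [("#0", labels[0]), ("#0", labels[1]), ("#0", labels[2])]
    tops = [base]
    for idx, label in enumerate(labels[3:], start=1):
        new_tops = []
        for top in tops:
            for k in range(len(top)):
                node = f"#{idx}x{k}"
                a, b = top[k]
                rest = top[:k] + top[k + 1 :]
                new_tops.append(
                    rest + [(a, node), (node, b), (node, label)]
                )
        tops = new_tops
    return tops


def _edge_paths(top, labels):
    """Boolean incidence matrix: row per leaf pair, column per edge,
    True where the edge lies on the path between the pair."""
    adj: dict[str, list[tuple[str, int]]] = {}
    for e, (a, b) in enumerate(top):
        adj.setdefault(a, []).append((b, e))
        adj.setdefault(b, []).append((a, e))

    def path_edges(src: str, dst: str) -> set[int]:
        stack = [(src, None, [])]
        seen = {src}
        while stack:
            node, _, edges = stack.pop()
            if node == dst:
                return set(edges)
            for nxt, e in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, node, edges + [e]))
        raise AssertionError("disconnected topology")

    pairs = list(itertools.combinations(labels, 2))
    X = np.zeros((len(pairs), len(top)))
    for row, (a, b) in enumerate(pairs):
        for e in path_edges(a, b):
            X[row, e] = 1.0
    return X, pairs


def topology_bipartitions(top, labels) -> set[frozenset[str]]:
    """Non-trivial bipartitions (as the smaller-or-lexicographic
    frozenset of leaf labels) induced by a topology's internal edges."""
    adj: dict[str, list[str]] = {}
    for a, b in top:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    out = set()
    for a, b in top:
        if a.startswith("#") and b.startswith("#"):
            # leaves on b's side of the edge
            stack, seen = [b], {a, b}
            side = set()
            while stack:
                node = stack.pop()
                if not node.startswith("#"):
                    side.add(node)
                for nxt in adj[node]:
                    if nxt not in seen:
                        seen.add(nxt)
                        stack.append(nxt)
            comp = frozenset(labels) - side
            out.add(min(frozenset(side), comp, key=lambda s: (len(s), sorted(s))))
    return out


def ls_tree_oracle(labels, D: np.ndarray):
    """Exhaustive least-squares tree fit: for every unrooted topology,
    solve nonnegative least squares for branch lengths against the
    pairwise distances; return (bipartitions, rss, fitted distances) of
    the best topology."""
    best = None
    for top in _enumerate_topologies(list(labels)):
        X, pairs = _edge_paths(top, list(labels))
        y = np.array([D[labels.index(a), labels.index(b)] for a, b in pairs])
        lengths, _ = nnls(X, y)
        rss = float(np.sum((X @ lengths - y) ** 2))
        if best is None or rss < best[1] - 1e-15:
            best = (topology_bipartitions(top, list(labels)), rss, top, lengths)
    return best


def random_additive_matrix(labels, rng: np.random.Generator):
    """A random unrooted binary tree with positive branch lengths and
    its exact path-length distance matrix."""
    tops = _enumerate_topologies(list(labels))
    top = tops[rng.integers(0, len(tops))]
    lengths = rng.uniform(0.05, 1.0, size=len(top))
    X, pairs = _edge_paths(top, list(labels))
    d = X @ lengths
    n = len(labels)
    D = np.zeros((n, n))
    for (a, b), val in zip(pairs, d):
        i, j = labels.index(a), labels.index(b)
        D[i, j] = D[j, i] = val
    return D, topology_bipartitions(top, list(labels)), top, lengths


# ---------------------------------------------------------------------------
# Quadratic inverted-repeat oracle
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def sw_inverted_repeat_oracle(seq: str):
    """Plain quadratic Smith–Waterman of *seq* vs its reverse
    complement (match +1, mismatch -1, gap -2; cells i + j <= n),
    written as the textbook row-by-row loop.  Best cell is the first
    maximum in row-major order; traceback prefers diagonal, then up,
    then left.  Returns (score, arm1, arm2) with 0-based half-open
    coordinates in *seq*.
    """
    s = seq.upper()
    n = len(s)
    r = s.translate(_COMP)[::-1]
    H = [[0] * (n + 1) for _ in range(n + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        row, prev = H[i], H[i - 1]
        for j in range(1, n - i + 1):  # i + j <= n
            sub = 1 if s[i - 1] == r[j - 1] else -1
            val = max(0, prev[j - 1] + sub, prev[j] - 2, row[j - 1] - 2)
            row[j] = val
            if val > best:
                best, bi, bj = val, i, j
    if best == 0:
        return 0, None, None
    i, j = bi, bj
    while i > 0 and j > 0 and H[i][j] > 0:
        sub = 1 if s[i - 1] == r[j - 1] else -1
        if H[i][j] == H[i - 1][j - 1] + sub:
            i, j = i - 1, j - 1
        elif H[i][j] == H[i - 1][j] - 2:
            i -= 1
        else:
            j -= 1
    return best, (i, bi), (n - bj, n - j)


def best_inverted_arms(seq: str):
    """Brute-force O(n^2) scan for the best *ungapped* pair of
    reverse-complementary arms (match +1, mismatch -1), constrained to
    non-overlapping arms.  Returns (score, set of optimal
    ((a1s, a1e), (a2s, a2e)) coordinate pairs, 0-based half-open).
    """
    n = len(seq)
    s = seq.upper()
    r = s.translate(_COMP)[::-1]
    best, coords = 0, set()
    # an ungapped arm pair is a run of cells along a diagonal
    # c = i - j (1-based cell coordinates); cell (i, j) pairs s[i-1]
    # with s[n-i+c], symmetric about the stem's center; the max run per
    # diagonal is Kadane's max-subarray, restricted to the same cell
    # constraint (i + j <= n) as the detector
    for c in range(-(n - 1), n):
        i_lo = max(1, c + 1)
        i_hi = (n + c) // 2
        run, run_start = 0, i_lo
        for i in range(i_lo, i_hi + 1):
            j = i - c
            sc = 1 if s[i - 1] == r[j - 1] else -1
            if run <= 0:
                run, run_start = sc, i
            else:
                run += sc
            if run > best:
                best = run
                coords = set()
            if run == best and best > 0:
                arm1 = (run_start - 1, i)            # 0-based half-open in s
                arm2 = (n - i + c, n - run_start + c + 1)
                coords.add((arm1, arm2))
    return best, coords
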