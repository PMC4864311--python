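"""Independent brute-force references used to check the library.

Everything here is deliberately written from first principles — exhaustive
topology enumeration with linear least squares, subset-search event
minimisation, random additive matrices built from explicit path sums — and
never calls the library code paths it is used to verify.
"""

from __future__ import annotations

import itertools

import numpy as np

# ---------------------------------------------------------------------------
# unrooted binary topologies as edge lists
# ---------------------------------------------------------------------------
# A topology over taxa 0..n-1 is a list of edges (u, v); taxa are nodes
# 0..n-1, internal nodes are numbered from n upward.


def enumerate_topologies(n: int) -> list[list[tuple[int, int]]]:
    """All (2n−5)!! unrooted binary topologies over taxa 0..n−1."""
    if n < 3:
        raise ValueError("need >= 3 taxa")
    base = [[(0, n), (1, n), (2, n)]]
    next_internal = n + 1
    for taxon in range(3, n):
        grown = []
        for edges in base:
            for i, (u, v) in enumerate(edges):
                new = edges[:i] + edges[i + 1:]
                mid = next_internal
                new += [(u, mid), (mid, v), (taxon, mid)]
                grown.append(new)
        base = grown
        next_internal += 1
    return base


def _adjacency(edges):
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    return adj


def path_edges(edges, a: int, b: int) -> list[int]:
    """Indices of the edges on the unique a→b path."""
    adj = _adjacency(edges)
    index = {}
    for i, (u, v) in enumerate(edges):
        index[(u, v)] = index[(v, u)] = i
    # DFS from a to b
    stack = [(a, None, [])]
    while stack:
        node, parent, trail = stack.pop()
        if node == b:
            return trail
        for nb in adj[node]:
            if nb != parent:
                stack.append((nb, node, trail + [index[(node, nb)]]))
    raise RuntimeError("disconnected topology")


def design_matrix(edges, n: int) -> np.ndarray:
    """(n·(n−1)/2, n_edges) incidence of edges on leaf-pair paths."""
    pairs = list(itertools.combinations(range(n), 2))
    A = np.zeros((len(pairs), len(edges)))
    for r, (a, b) in enumerate(pairs):
        for e in path_edges(edges, a, b):
            A[r, e] = 1.0
    return A


def ls_sse(edges, n: int, D: np.ndarray) -> float:
    """Least-squares lack of fit of a topology to a distance matrix."""
    A = design_matrix(edges, n)
    d = np.array([D[a, b] for a, b in itertools.combinations(range(n), 2)])
    _, res, _, _ = np.linalg.lstsq(A, d, rcond=None)
    if res.size:
        return float(res[0])
    fit = A @ np.linalg.lstsq(A, d, rcond=None)[0]
    return float(np.sum((fit - d) ** 2))


def topology_bipartitions(edges, n: int) -> set[frozenset]:
    """Nontrivial taxon bipartitions (as index frozensets, side without 0)."""
    adj = _adjacency(edges)
    out = set()
    for u, v in edges:
        # leaves on v's side of edge (u, v)
        stack, seen, leaves = [v], {u, v}, []
        while stack:
            node = stack.pop()
            if node < n:
                leaves.append(node)
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        side = frozenset(leaves)
        if 0 in side:
            side = frozenset(range(n)) - side
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def best_ls_topology(D: np.ndarray) -> tuple[set[frozenset], float]:
    """Exhaustive search: bipartition set of the least-squares-best topology."""
    n = D.shape[0]
    best_edges, best = None, np.inf
    for edges in enumerate_topologies(n):
        sse = ls_sse(edges, n, D)
        if sse < best:
            best, best_edges = sse, edges
    return topology_bipartitions(best_edges, n), best


def _ls_projectors(n: int):
    """Per-topology residual projectors I − A·A⁺, cached per taxon count."""
    if n not in _PROJECTOR_CACHE:
        topos = enumerate_topologies(n)
        n_pairs = n * (n - 1) // 2
        P = np.empty((len(topos), n_pairs, n_pairs))
        for t, edges in enumerate(topos):
            A = design_matrix(edges, n)
            P[t] = np.eye(n_pairs) - A @ np.linalg.pinv(A)
        _PROJECTOR_CACHE[n] = (topos, P)
    return _PROJECTOR_CACHE[n]


_PROJECTOR_CACHE: dict = {}


def best_ls_topology_fast(D: np.ndarray) -> tuple[set[frozenset], float]:
    """Same optimum as :func:`best_ls_topology`, via precomputed projectors."""
    n = D.shape[0]
    topos, P = _ls_projectors(n)
    d = np.array([D[a, b] for a, b in itertools.combinations(range(n), 2)])
    sse = np.einsum("tij,j->ti", P, d)
    sse = np.sum(sse * sse, axis=1)
    best = int(np.argmin(sse))
    return topology_bipartitions(topos[best], n), float(sse[best])


def random_additive_matrix(
    rng: np.random.Generator, n: int, blen_range=(0.05, 1.0)
) -> tuple[np.ndarray, set[frozenset]]:
    """Additive distance matrix from a random topology with random branch
    lengths, plus the generating topology's bipartitions."""
    topos = enumerate_topologies(n)
    edges = topos[rng.integers(0, len(topos))]
    lengths = rng.uniform(*blen_range, size=len(edges))
    A = design_matrix(edges, n)
    dvec = A @ lengths
    D = np.zeros((n, n))
    for (a, b), d in zip(itertools.combinations(range(n), 2), dvec):
        D[a, b] = D[b, a] = d
    return D, topology_bipartitions(edges, n)


# ---------------------------------------------------------------------------
# rooted random trees + gain/loss event minimisation
# ---------------------------------------------------------------------------


def random_rooted_newick(rng: np.random.Generator, tips: list[str]) -> str:
    """Uniform random rooted binary tree over the given tip labels."""
    nodes = [t for t in tips]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0] + ";"


def _parse_rooted(newick: str):
    """Minimal rooted-newick parser: returns (children, tips_below, root)."""
    s = newick.strip().rstrip(";")
    counter = itertools.count()
    children: dict[int, list] = {}
    labels: dict[int, str] = {}

    def parse(text: str) -> int:
        node = next(counter)
        if text.startswith("("):
            depth, start, parts = 0, 1, []
            for i, ch in enumerate(text):
                if ch == "(":
                    depth += 1
                elif ch == ")":
                    depth -= 1
                    if depth == 0:
                        parts.append(text[start:i])
                        break
                elif ch == "," and depth == 1:
                    parts.append(text[start:i])
                    start = i + 1
            children[node] = [parse(p) for p in parts]
        else:
            children[node] = []
            labels[node] = text
        return node

    root = parse(s)
    tips_below: dict[int, frozenset] = {}

    def fill(node: int) -> frozenset:
        if not children[node]:
            tips_below[node] = frozenset([labels[node]])
        else:
            tips_below[node] = frozenset().union(
                *(fill(c) for c in children[node])
            )
        return tips_below[node]

    fill(root)
    return children, tips_below, root


def min_dollo_events(newick: str, presence: dict[str, int]) -> int:
    """Minimum of (1 gain + losses) over all gain nodes and loss-edge
    subsets consistent with the tip states, by exhaustive subset search
    of increasing cardinality."""
    children, tips_below, root = _parse_rooted(newick)
    nodes = sorted(tips_below)
    carriers = frozenset(t for t, v in presence.items() if v)
    if not carriers:
        raise ValueError("no carriers")

    def consistent(gain: int, losses: frozenset) -> bool:
        state: dict[int, int] = {}

        def down(node: int, s: int):
            if node == gain:
                s = 1
            if node in losses:
                s = 0
            state[node] = s
            for c in children[node]:
                down(c, s)

        down(root, 0)
        for node in nodes:
            if not children[node]:
                (tip,) = tips_below[node]
                if state[node] != presence[tip]:
                    return False
        return True

    for k in range(len(nodes) + 1):
        for gain in nodes:
            if not carriers <= tips_below[gain]:
                continue
            below = [m for m in nodes if tips_below[m] < tips_below[gain]]
            for losses in itertools.combinations(below, k):
                if consistent(gain, frozenset(losses)):
                    return 1 + k
    raise RuntimeError("no consistent scenario found")
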