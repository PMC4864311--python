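"""Protein-alignment statistics and distance-based tree inference.

The pipeline mirrors the classical protein phylogenetics recipe: columns
containing gaps or missing data are excluded completely (a column with '-'
or 'X' in *any* row is dropped), pairwise identities and p-distances are
computed on the remaining columns, p-distances are Poisson-corrected
(d = −ln(1−p), the expected substitutions per site under an equal-rates
model), and a Neighbor-Joining tree is built with bootstrap support from
column resampling.

Trees are returned as :class:`dendropy.Tree` objects (unrooted, branch
lengths in substitutions/site, bootstrap percentages as internal node
labels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import DomainError, InputError, SaturationError

__all__ = [
    "AMINO_ACIDS",
    "GAP_CHARS",
    "ProteinAlignment",
    "DistanceMatrix",
    "strip_gap_columns",
    "pairwise_identity",
    "group_identity_stats",
    "poisson_distance",
    "poisson_distance_matrix",
    "nj_tree",
    "tree_distance_matrix",
    "leaf_bipartitions",
    "bootstrap_support",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Characters treated as "gap or missing data" for complete deletion.
GAP_CHARS = frozenset("-X")


@dataclass(frozen=True)
class ProteinAlignment:
    """Aligned amino-acid sequences.

    ``column_mask`` records the original column indices removed by
    :func:`strip_gap_columns` (empty for an alignment as read from file).
    """

    names: tuple[str, ...]
    rows: tuple[str, ...]
    column_mask: tuple[int, ...] = ()

    def __post_init__(self):
        names = tuple(self.names)
        rows = tuple(r.upper() for r in self.rows)
        if len(names) != len(rows):
            raise InputError("names and rows differ in count")
        if len(names) == 0:
            raise InputError("alignment has no sequences")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise InputError(f"duplicate sequence names: {dupes}")
        length = len(rows[0])
        bad = [names[i] for i, r in enumerate(rows) if len(r) != length]
        if bad:
            raise InputError(f"rows of unequal length: {bad}")
        alphabet = set(AMINO_ACIDS) | GAP_CHARS
        for n, r in zip(names, rows):
            extra = set(r) - alphabet
            if extra:
                raise InputError(
                    f"sequence {n!r} contains invalid characters {sorted(extra)}"
                )
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "column_mask", tuple(self.column_mask))

    @property
    def n_sequences(self) -> int:
        return len(self.names)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise InputError(f"no sequence named {name!r}") from None

    def to_array(self) -> np.ndarray:
        """(n_sequences, n_columns) array of single characters."""
        return np.array([list(r) for r in self.rows], dtype="U1")

    def has_gaps(self) -> bool:
        return any(set(r) & GAP_CHARS for r in self.rows)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of evolutionary distances (substitutions/site)."""

    names: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        names = tuple(self.names)
        m = np.asarray(self.matrix, dtype=float)
        n = len(names)
        if m.shape != (n, n):
            raise InputError(f"matrix shape {m.shape} does not match {n} names")
        if not np.all(np.isfinite(m)):
            raise InputError("distance matrix contains non-finite entries")
        if np.any(m < 0):
            raise InputError("distances must be >= 0")
        if not np.allclose(m, m.T, atol=1e-12):
            raise InputError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise InputError("distance matrix diagonal must be zero")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "matrix", m)

    def __len__(self):
        return len(self.names)


# ---------------------------------------------------------------------------
# alignment statistics
# ---------------------------------------------------------------------------


def strip_gap_columns(aln: ProteinAlignment) -> ProteinAlignment:
    """Complete deletion: drop every column holding '-' or 'X' in any row."""
    arr = aln.to_array()
    bad = np.zeros(aln.n_columns, dtype=bool)
    for ch in GAP_CHARS:
        bad |= (arr == ch).any(axis=0)
    keep = ~bad
    removed = tuple(int(i) for i in np.nonzero(bad)[0])
    rows = tuple("".join(r) for r in arr[:, keep])
    return ProteinAlignment(aln.names, rows, column_mask=removed)


def _stripped(aln: ProteinAlignment) -> ProteinAlignment:
    return strip_gap_columns(aln) if aln.has_gaps() else aln


def pairwise_identity(
    aln: ProteinAlignment,
    i: int | str,
    j: int | str,
    *,
    exclusion: str = "global",
) -> float:
    """Fraction of identical residues between two aligned sequences.

    ``exclusion="global"`` (default) first applies complete deletion across
    the whole alignment — the convention of computing identities on the
    gap-stripped multiple alignment.  ``exclusion="pair"`` instead drops
    only columns gapped in either of the two sequences compared.
    """
    if exclusion not in ("global", "pair"):
        raise InputError(f"unknown exclusion mode {exclusion!r}")
    ii = aln.index(i) if isinstance(i, str) else int(i)
    jj = aln.index(j) if isinstance(j, str) else int(j)
    if exclusion == "global":
        work = _stripped(aln)
        a = np.frombuffer(work.rows[ii].encode(), dtype="S1")
        b = np.frombuffer(work.rows[jj].encode(), dtype="S1")
    else:
        a = np.frombuffer(aln.rows[ii].encode(), dtype="S1")
        b = np.frombuffer(aln.rows[jj].encode(), dtype="S1")
        gap = np.isin(a, [b"-", b"X"]) | np.isin(b, [b"-", b"X"])
        a, b = a[~gap], b[~gap]
    if a.size == 0:
        raise InputError("no comparable columns after gap exclusion")
    return float(np.mean(a == b))


def group_identity_stats(
    aln: ProteinAlignment,
    target: str,
    group: set[str] | list[str],
    *,
    exclusion: str = "global",
) -> tuple[float, float, int]:
    """Mean ± sample SD of identities between ``target`` and each group member.

    Returns ``(mean, sd, n)`` with ``sd`` the n−1-denominator standard
    deviation (0.0 for a single member, by convention).
    """
    members = sorted(set(group))
    if not members:
        raise InputError("group must be nonempty")
    if target in members:
        raise InputError("group must not contain the target sequence")
    idents = [
        pairwise_identity(aln, target, m, exclusion=exclusion) for m in members
    ]
    n = len(idents)
    mean = float(np.mean(idents))
    sd = float(np.std(idents, ddof=1)) if n > 1 else 0.0
    return mean, sd, n


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def poisson_distance(p: float) -> float:
    """Poisson-corrected distance d = −ln(1−p), substitutions per site."""
    if p < 0:
        raise DomainError(f"p-distance must be >= 0, got {p}")
    if p >= 1:
        raise SaturationError(
            f"p-distance {p} >= 1: Poisson correction is undefined (saturated)"
        )
    return -math.log1p(-p)


def poisson_distance_matrix(aln: ProteinAlignment) -> DistanceMatrix:
    """Pairwise Poisson-corrected distances on the gap-stripped alignment."""
    work = _stripped(aln)
    if work.n_columns == 0:
        raise InputError("alignment has no gap-free columns")
    arr = work.to_array()
    n = work.n_sequences
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = float(np.mean(arr[i] != arr[j]))
            if p >= 1:
                raise SaturationError(
                    f"pair ({work.names[i]!r}, {work.names[j]!r}) differs at "
                    "every site; Poisson distance saturated"
                )
            d[i, j] = d[j, i] = -math.log1p(-p)
    return DistanceMatrix(work.names, d)


# ---------------------------------------------------------------------------
# Neighbor-Joining
# ---------------------------------------------------------------------------


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei Neighbor-Joining tree from a distance matrix.

    Iteratively joins the pair minimising
    ``Q(i,j) = (n−2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k)`` (ties broken on the
    lowest index pair, deterministically), with the standard branch-length
    and distance-update formulas.  Negative branch-length estimates are
    clamped to 0 and the deficit moved to the sister branch; the tree's
    ``clamped_branches`` annotation counts such events.  On an additive
    matrix the tree's path lengths reproduce the input exactly.
    """
    n = len(dm)
    if n < 3:
        raise InputError(f"NJ requires >= 3 taxa, got {n}")
    if not np.all(np.isfinite(dm.matrix)):
        raise InputError("distance matrix contains NaN/inf")

    taxa = dendropy.TaxonNamespace(list(dm.names))
    nodes: dict[int, dendropy.Node] = {}
    for idx, name in enumerate(dm.names):
        leaf = dendropy.Node(taxon=taxa.get_taxon(name))
        nodes[idx] = leaf

    D = {
        (i, j): float(dm.matrix[i, j])
        for i in range(n)
        for j in range(n)
        if i != j
    }
    active = list(range(n))
    next_id = n
    clamped = 0

    def d(i, j):
        return 0.0 if i == j else D[(i, j)]

    while len(active) > 2:
        m = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d(i, j) - r[i] - r[j]
                if best is None or q < best[0] - 1e-15:
                    best = (q, i, j)
        _, i, j = best
        dij = d(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negative estimates, moving the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
            clamped += 1
        if lj < 0:
            li += lj
            lj = 0.0
            clamped += 1
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        nodes[next_id] = parent
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (d(i, k) + d(j, k) - dij)
            D[(next_id, k)] = D[(k, next_id)] = duk
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    a, b = active
    # seed the tree at an internal node; attach the other remaining node
    if nodes[a].is_leaf():
        a, b = b, a
    root = nodes[a]
    root.add_child(nodes[b])
    final_len = d(a, b)
    if final_len < 0:
        final_len = 0.0
        clamped += 1
    nodes[b].edge.length = final_len

    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    tree.clamped_branches = clamped
    return tree


def tree_distance_matrix(tree: dendropy.Tree, names=None) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree."""
    pdm = tree.phylogenetic_distance_matrix()
    if names is None:
        names = [t.label for t in tree.taxon_namespace]
    n = len(names)
    taxa = {t.label: t for t in tree.taxon_namespace}
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pdm.patristic_distance(taxa[names[i]], taxa[names[j]])
    return DistanceMatrix(tuple(names), m)


def leaf_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Nontrivial leaf bipartitions induced by internal edges.

    Each bipartition is canonicalised as the frozenset of leaf names on the
    side *not* containing the lexicographically first taxon, so trees over
    the same leaf set are directly comparable regardless of rooting.
    """
    all_leaves = frozenset(
        lf.taxon.label for lf in tree.leaf_node_iter()
    )
    anchor = min(all_leaves)
    out: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(
            lf.taxon.label for lf in node.leaf_iter()
        )
        if anchor in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(side)
    return out


def bootstrap_support(
    aln: ProteinAlignment, B: int = 1000, seed: int = 0
) -> dendropy.Tree:
    """NJ tree with bootstrap support from column resampling.

    Resamples alignment columns with replacement ``B`` times, rebuilds the
    Poisson-distance NJ tree for each replicate, and annotates every internal
    edge of the full-data tree with the percentage of replicates containing
    its bipartition (as the internal node label).  Deterministic given
    ``seed``.
    """
    if B < 1:
        raise InputError(f"bootstrap replicate count must be >= 1, got {B}")
    work = _stripped(aln)
    if work.n_columns < 2:
        raise InputError("alignment too short to bootstrap (< 2 columns)")
    full_tree = nj_tree(poisson_distance_matrix(work))
    target = leaf_bipartitions(full_tree)
    counts = {bp: 0 for bp in target}

    arr = work.to_array()
    L = work.n_columns
    rng = np.random.default_rng(seed)
    for _ in range(B):
        cols = rng.integers(0, L, size=L)
        rep_rows = tuple("".join(r) for r in arr[:, cols])
        rep = ProteinAlignment(work.names, rep_rows)
        rep_tree = nj_tree(poisson_distance_matrix(rep))
        for bp in leaf_bipartitions(rep_tree):
            if bp in counts:
                counts[bp] += 1

    support = {bp: 100.0 * c / B for bp, c in counts.items()}
    all_leaves = frozenset(t.label for t in full_tree.taxon_namespace)
    anchor = min(all_leaves)
    for node in full_tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = all_leaves - side
        if side in support:
            node.label = str(int(round(support[side])))
    full_tree.bootstrap_replicates = B
    full_tree.bipartition_support = support
    return full_tree
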