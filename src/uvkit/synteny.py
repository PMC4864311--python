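"""Microsynteny block detection and gene gain/loss scenarios.

The target gene (here the fish-specific UV opsin paralog) sits in a
conserved neighbourhood flanked by two anchor genes (gapdh and iffo1b in
the original arrangement, with nppcl immediately upstream).  Per-genome
gene-order tables are scanned for the anchor pair; a species either carries
the target inside the block (``present_in_block``), preserves the anchors
side by side without the target (``absent_block_conserved`` — the signature
of a gene loss), or lacks a recognisable block (``block_not_found``).

Given the resulting presence/absence pattern on a rooted species tree,
:func:`dollo_scenarios` enumerates single-gain (Dollo) scenarios: one gene
gain on some ancestor of all carriers, plus the unique minimal set of loss
branches below it, ranked by total event count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import pandas as pd

from .errors import AmbiguityError, DomainError, InputError

__all__ = [
    "GENE_TABLE_COLUMNS",
    "GeneTable",
    "SyntenyBlockReport",
    "DolloScenario",
    "locate_block",
    "synteny_matrix",
    "dollo_scenarios",
]

GENE_TABLE_COLUMNS = ["gene_id", "orthogroup", "scaffold", "start", "strand"]


@dataclass(frozen=True)
class GeneTable:
    """Ordered gene records of one genome.

    ``records`` holds columns gene_id, orthogroup, scaffold, start (0-based
    bp), strand (+/−); rows are kept sorted by (scaffold, start).
    """

    species: str
    records: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.records)
        missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise InputError(f"gene table missing columns {missing}")
        df = df[GENE_TABLE_COLUMNS].copy()
        df["start"] = df["start"].astype(int)
        if (df["start"] < 0).any():
            raise InputError("gene starts must be >= 0")
        if df["orthogroup"].isna().any() or (df["orthogroup"] == "").any():
            raise InputError("every record needs a nonempty orthogroup")
        bad_strand = ~df["strand"].isin(["+", "-"])
        if bad_strand.any():
            raise InputError(
                f"invalid strand values: {sorted(df.loc[bad_strand, 'strand'].unique())}"
            )
        df = df.sort_values(["scaffold", "start"], kind="mergesort").reset_index(
            drop=True
        )
        object.__setattr__(self, "records", df)

    def rows_for(self, orthogroup: str) -> pd.DataFrame:
        return self.records[self.records["orthogroup"] == orthogroup]


@dataclass(frozen=True)
class SyntenyBlockReport:
    """Outcome of the anchor-flanked block search in one genome."""

    species: str
    status: str  # present_in_block | absent_block_conserved | block_not_found
    anchor_gap_gene_count: int = 0
    orientation: str | None = None
    scaffold: str | None = None
    note: str = ""

    def __post_init__(self):
        allowed = {"present_in_block", "absent_block_conserved", "block_not_found",
                   "error"}
        if self.status not in allowed:
            raise InputError(f"unknown status {self.status!r}")
        if self.status == "present_in_block" and self.orientation is None:
            raise InputError("present_in_block requires an orientation")


def _anchor_pair(table: GeneTable, left: str, right: str):
    """Pick the same-scaffold (left, right) copy pair of minimal genomic span.

    Post-duplication genomes can carry several copies of an anchor; the pair
    spanning the fewest bases is taken as the orthologous block.  A tie in
    span is ambiguous and raises; anchors never co-occurring on a scaffold
    yield ``None``.
    """
    lrows = table.rows_for(left)
    rrows = table.rows_for(right)
    if lrows.empty or rrows.empty:
        return None
    candidates = []
    for _, lr in lrows.iterrows():
        for _, rr in rrows.iterrows():
            if lr["scaffold"] != rr["scaffold"]:
                continue
            span = abs(int(rr["start"]) - int(lr["start"]))
            candidates.append((span, lr, rr))
    if not candidates:
        return None
    candidates.sort(key=lambda c: c[0])
    if len(candidates) > 1 and candidates[0][0] == candidates[1][0]:
        tied = [
            f"{c[1]['gene_id']}..{c[2]['gene_id']}@{c[1]['scaffold']}"
            for c in candidates
            if c[0] == candidates[0][0]
        ]
        raise AmbiguityError(
            f"{table.species}: anchor pair ({left}, {right}) ties on genomic "
            f"span across copies",
            candidates=tied,
        )
    return candidates[0][1], candidates[0][2]


def locate_block(
    table: GeneTable,
    target: str,
    anchors: tuple[str, str],
    window: int = 5,
) -> SyntenyBlockReport:
    """Search one genome for the anchor-flanked target block.

    Betweenness is decided by start coordinates, not record order, and is
    agnostic to which anchor is left or right.  ``anchor_gap_gene_count``
    is the number of genes strictly between the two anchors (the target
    included when present).  Anchors co-occurring with at most ``window``
    intervening genes but no target give ``absent_block_conserved``.
    """
    left, right = anchors
    if left == right:
        raise InputError("anchors must be distinct orthogroups")
    pair = _anchor_pair(table, left, right)
    if pair is None:
        return SyntenyBlockReport(
            species=table.species,
            status="block_not_found",
            note="anchors absent or never on one scaffold",
        )
    lr, rr = pair
    scaffold = lr["scaffold"]
    lo, hi = sorted((int(lr["start"]), int(rr["start"])))
    df = table.records
    between = df[
        (df["scaffold"] == scaffold) & (df["start"] > lo) & (df["start"] < hi)
    ]
    gap_count = len(between)
    hits = between[between["orthogroup"] == target]
    if not hits.empty:
        return SyntenyBlockReport(
            species=table.species,
            status="present_in_block",
            anchor_gap_gene_count=gap_count,
            orientation=str(hits.iloc[0]["strand"]),
            scaffold=str(scaffold),
        )
    if gap_count <= window:
        return SyntenyBlockReport(
            species=table.species,
            status="absent_block_conserved",
            anchor_gap_gene_count=gap_count,
            scaffold=str(scaffold),
        )
    return SyntenyBlockReport(
        species=table.species,
        status="block_not_found",
        anchor_gap_gene_count=gap_count,
        scaffold=str(scaffold),
        note=f"anchors {gap_count} genes apart (> window {window})",
    )


def synteny_matrix(
    tables: list[GeneTable],
    target: str,
    anchors: tuple[str, str],
    window: int = 5,
    species_order: list[str] | None = None,
) -> pd.DataFrame:
    """Per-species block status table (one row per genome).

    Errors from individual genomes are captured in their row (status
    ``error``) rather than aborting the whole matrix.  ``species_order``
    (e.g. the tip order of a species tree) controls row order when given.
    """
    if not tables:
        raise InputError("need at least one gene table")
    reports = []
    for t in tables:
        try:
            reports.append(locate_block(t, target, anchors, window))
        except (AmbiguityError, InputError) as exc:
            reports.append(
                SyntenyBlockReport(species=t.species, status="error",
                                   note=str(exc))
            )
    rows = pd.DataFrame(
        {
            "species": [r.species for r in reports],
            "status": [r.status for r in reports],
            "anchor_gap_gene_count": [r.anchor_gap_gene_count for r in reports],
            "orientation": [r.orientation for r in reports],
            "scaffold": [r.scaffold for r in reports],
            "note": [r.note for r in reports],
        }
    )
    if species_order is not None:
        order = {s: i for i, s in enumerate(species_order)}
        rows = rows.sort_values(
            "species", key=lambda s: s.map(lambda x: order.get(x, len(order))),
            kind="mergesort",
        ).reset_index(drop=True)
    return rows


# ---------------------------------------------------------------------------
# Dollo gain/loss scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DolloScenario:
    """One single-gain scenario: the gain clade and its loss clades.

    ``gain_clade`` is the tip set descending from the branch on which the
    gene was gained; each member of ``losses`` is the tip set under one
    loss branch.  ``events`` = 1 gain + number of losses.
    """

    gain_clade: frozenset
    losses: tuple[frozenset, ...]

    @property
    def events(self) -> int:
        return 1 + len(self.losses)


def _tipset(node) -> frozenset:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def dollo_scenarios(
    tree: dendropy.Tree, presence: dict[str, int]
) -> list[DolloScenario]:
    """All single-gain gain/loss scenarios, ranked by event count.

    Under the Dollo assumption the gene is gained exactly once, on a branch
    ancestral to every carrier, and subsequently lost on zero or more
    branches.  For each candidate gain node (the carriers' MRCA and each of
    its ancestors up to the root) the minimal loss set is unique: the
    maximal subtrees below the gain containing no carrier.  Scenarios are
    returned best-first; ties in event count are all reported.
    """
    if not tree.is_rooted:
        raise InputError("dollo_scenarios requires a rooted species tree")
    tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
    unknown = set(presence) - tips
    if unknown:
        raise InputError(f"presence map names unknown tips: {sorted(unknown)}")
    missing = tips - set(presence)
    if missing:
        raise InputError(f"presence state missing for tips: {sorted(missing)}")
    carriers = {t for t, v in presence.items() if v}
    if not carriers:
        raise InputError("at least one tip must carry the gene")

    mrca = tree.mrca(taxon_labels=sorted(carriers))
    # candidate gain nodes: MRCA of carriers and every ancestor up to the root
    candidates = []
    node = mrca
    while node is not None:
        candidates.append(node)
        node = node.parent_node

    scenarios = []
    for gain in candidates:
        losses = []

        def collect(n):
            sub = _tipset(n)
            if sub & carriers:
                for ch in n.child_nodes():
                    collect(ch)
            else:
                losses.append(sub)  # maximal carrier-free subtree => one loss

        collect(gain)
        scenarios.append(
            DolloScenario(gain_clade=_tipset(gain), losses=tuple(sorted(
                losses, key=lambda s: (len(s), sorted(s))
            )))
        )
    scenarios.sort(key=lambda s: (s.events, len(s.gain_clade)))
    return scenarios
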