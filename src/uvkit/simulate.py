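"""Synthetic-data generators for every stage of the pipeline.

Three generators, all bit-reproducible given (config, seed):

* irradiation series of a bistable two-form pigment — each state is an
  affine mixture of a UV Gaussian band and a visible template band plus a
  constant baseline and additive Gaussian noise;
* protein families evolved on a tree under the 20-state equal-rates
  ("Poisson") substitution model, the model under which the Poisson
  distance correction is consistent;
* per-genome gene-order tables carrying the anchor-flanked target block,
  with the target engineered out in chosen lineages.

Each generator draws from its own child RNG stream (a fixed offset mixed
into the root seed), so adding a generator never perturbs the output of an
existing one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .decomposition import IrradiationSeries
from .errors import DomainError, InputError
from .molevol import AMINO_ACIDS, ProteinAlignment
from .spectra import AbsorbanceSpectrum, gaussian_band, pigment_template
from .synteny import GeneTable

__all__ = [
    "STREAM_OFFSETS",
    "SpectraSimConfig",
    "SeqSimConfig",
    "BlockSpec",
    "expected_p_distance",
    "simulate_irradiation_series",
    "simulate_protein_family",
    "simulate_gene_tables",
]

#: Fixed per-generator offsets mixed into the root seed.
STREAM_OFFSETS = {"spectra": 0, "sequences": 1, "genomes": 2}


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng([STREAM_OFFSETS[component], int(seed)])


# ---------------------------------------------------------------------------
# irradiation spectra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpectraSimConfig:
    """Conditions of a simulated irradiation experiment.

    ``fractions`` maps each state label, in irradiation order, to the
    fraction of pigment in the UV-absorbing form; the remainder sits in the
    visible-absorbing photoproduct.  Defaults emulate a dark sample fully in
    the UV form driven near-completely to the visible form by UV light and
    back by yellow light, with photosteady states short of total conversion.
    """

    uv_center: float = 360.0
    uv_sigma: float = 35.0
    uv_amplitude: float = 1.0
    visible_lambda_max: float = 462.0
    visible_amplitude: float = 0.8
    fractions: tuple[tuple[str, float], ...] = (
        ("dark", 1.0),
        ("uv_1", 0.1),
        ("yellow_1", 0.9),
        ("uv_2", 0.1),
        ("yellow_2", 0.9),
    )
    noise_sd: float = 0.005
    baseline_offset: float = 0.01
    grid_start: float = 250.0
    grid_stop: float = 700.0
    grid_step: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for label, f in self.fractions:
            if not (0.0 <= f <= 1.0):
                raise DomainError(f"fraction for state {label!r} outside [0, 1]")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")
        if len(self.fractions) < 2:
            raise DomainError("need >= 2 irradiation states")

    @property
    def grid(self) -> np.ndarray:
        return np.arange(self.grid_start, self.grid_stop + self.grid_step / 2,
                         self.grid_step)


def simulate_irradiation_series(
    cfg: SpectraSimConfig,
) -> tuple[IrradiationSeries, dict]:
    """Generate one irradiation series plus its ground truth.

    Each state is ``f·UV_band + (1−f)·visible_band + baseline + noise`` on
    the configured grid.  The ground-truth record holds both component
    curves (noiseless, unit mixture) and the per-state fractions.
    """
    grid = cfg.grid
    rng = _rng(cfg.seed, "spectra")
    uv = gaussian_band(cfg.uv_center, cfg.uv_sigma, cfg.uv_amplitude, grid)
    vis = pigment_template(cfg.visible_lambda_max, grid)
    vis_curve = cfg.visible_amplitude * vis.absorbance

    states = []
    for label, f in cfg.fractions:
        clean = f * uv.absorbance + (1.0 - f) * vis_curve + cfg.baseline_offset
        noisy = clean + rng.normal(0.0, cfg.noise_sd, size=grid.size) \
            if cfg.noise_sd > 0 else clean
        states.append(AbsorbanceSpectrum(grid, noisy, label=label))

    truth = {
        "uv_band": {"center": cfg.uv_center, "sigma": cfg.uv_sigma,
                    "amplitude": cfg.uv_amplitude},
        "visible_band": {"lambda_max": cfg.visible_lambda_max,
                         "amplitude": cfg.visible_amplitude},
        "fractions": dict(cfg.fractions),
        "baseline_offset": cfg.baseline_offset,
        "noise_sd": cfg.noise_sd,
        "uv_component": uv.absorbance.tolist(),
        "visible_component": vis_curve.tolist(),
    }
    return IrradiationSeries(tuple(states)), truth


# ---------------------------------------------------------------------------
# protein families
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeqSimConfig:
    """A protein family simulated on a tree.

    ``tree`` is a rooted Newick string with branch lengths in expected
    substitutions per site; ``length`` is the root sequence length.
    """

    tree: str
    length: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.length < 1:
            raise DomainError("sequence length must be >= 1")


def expected_p_distance(d: float) -> float:
    """Expected fraction of differing sites at divergence ``d`` under the
    20-state equal-rates model: p = (19/20)·(1 − e^(−20d/19))."""
    return (19.0 / 20.0) * (1.0 - math.exp(-20.0 * d / 19.0))


def simulate_protein_family(
    cfg: SeqSimConfig,
) -> tuple[ProteinAlignment, dendropy.Tree, dict]:
    """Evolve a protein family along a tree under the equal-rates model.

    The root sequence is i.i.d. uniform over the 20 amino acids.  Along a
    branch of length ``d`` each site receives ``N ~ Poisson(d·20/19)``
    substitution events, each drawing a letter uniformly from all 20 (so
    some events are silent); this uniformised chain reproduces the exact
    equal-rates transition probabilities, hence the closed-form expected
    p-distance of :func:`expected_p_distance`.  Gap-free by construction.

    Returns the leaf alignment, the true tree, and a ground-truth record
    with per-branch event counts.
    """
    tree = dendropy.Tree.get(data=cfg.tree, schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise DomainError("branch lengths must be >= 0")
    rng = _rng(cfg.seed, "sequences")
    L = cfg.length
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")

    root_seq = rng.integers(0, 20, size=L)
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    site_event_counts: dict[str, list[int]] = {}

    branch_i = 0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = seqs[id(node.parent_node)]
        d = node.edge.length or 0.0
        seq = parent_seq.copy()
        if d > 0:
            n_events = rng.poisson(d * 20.0 / 19.0, size=L)
            for site in np.nonzero(n_events)[0]:
                k = int(n_events[site])
                draws = rng.integers(0, 20, size=k)
                seq[site] = draws[-1]
        else:
            n_events = np.zeros(L, dtype=int)
        label = node.taxon.label if node.is_leaf() else f"internal_{branch_i}"
        branch_i += 1
        site_event_counts[label] = [int(x) for x in n_events]
        seqs[id(node)] = seq

    names, rows = [], []
    for leaf in tree.leaf_node_iter():
        names.append(leaf.taxon.label)
        rows.append(alphabet[seqs[id(leaf)]].tobytes().decode())
    aln = ProteinAlignment(tuple(names), tuple(rows))
    truth = {
        "site_event_counts": site_event_counts,
        "event_counts": {k: int(sum(v)) for k, v in site_event_counts.items()},
        "length": L,
    }
    return aln, tree, truth


# ---------------------------------------------------------------------------
# gene-order tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlockSpec:
    """Layout of the conserved target neighbourhood.

    ``upstream``/``downstream`` are ordered orthogroups before and after the
    target (default nppcl, gapdh | iffo1b, matching the conserved fish
    arrangement); ``flank_decoys`` random unrelated genes pad each side and
    ``max_intervening`` decoys may fall between the anchors.
    """

    target: str = "opn5m2"
    upstream: tuple[str, ...] = ("nppcl", "gapdh")
    downstream: tuple[str, ...] = ("iffo1b",)
    flank_decoys: int = 4
    max_intervening: int = 2

    @property
    def anchors(self) -> tuple[str, str]:
        return self.upstream[-1], self.downstream[0]


def simulate_gene_tables(
    species_tree: str | dendropy.Tree,
    loss_tips: set[str] | list[str] = (),
    seed: int = 0,
    block: BlockSpec = BlockSpec(),
) -> tuple[list[GeneTable], dict[str, int], dendropy.Tree]:
    """Generate one gene table per species tip, with engineered losses.

    Every genome carries the anchor neighbourhood on one scaffold; species
    in ``loss_tips`` have the target gene deleted (anchors preserved side by
    side — the loss signature).  Decoy genes with species-private
    orthogroups pad the flanks and may intervene between anchors.  Returns
    the tables, the presence map {tip: 0/1}, and the parsed species tree.
    """
    tree = (
        species_tree
        if isinstance(species_tree, dendropy.Tree)
        else dendropy.Tree.get(data=species_tree, schema="newick")
    )
    tree.is_rooted = True
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    unknown = set(loss_tips) - set(tips)
    if unknown:
        raise InputError(f"loss_tips not in species tree: {sorted(unknown)}")
    rng = _rng(seed, "genomes")

    tables = []
    presence = {}
    for sp in tips:
        lost = sp in set(loss_tips)
        presence[sp] = 0 if lost else 1
        order: list[str] = []
        decoy_i = 0

        def decoys(k):
            nonlocal decoy_i
            out = [f"decoy_{sp}_{decoy_i + j}" for j in range(k)]
            decoy_i += k
            return out

        order += decoys(int(rng.integers(0, block.flank_decoys + 1)))
        order += list(block.upstream)
        mid = decoys(int(rng.integers(0, block.max_intervening + 1)))
        if not lost:
            mid.insert(int(rng.integers(0, len(mid) + 1)), block.target)
        order += mid
        order += list(block.downstream)
        order += decoys(int(rng.integers(0, block.flank_decoys + 1)))

        start = int(rng.integers(10_000, 50_000))
        recs = []
        for og in order:
            strand = "+" if rng.random() < 0.5 else "-"
            recs.append(
                {
                    "gene_id": f"{sp}.{og}",
                    "orthogroup": og,
                    "scaffold": f"chr_{sp}",
                    "start": start,
                    "strand": strand,
                }
            )
            start += int(rng.integers(5_000, 40_000))
        tables.append(GeneTable(species=sp, records=pd.DataFrame(recs)))
    return tables, presence, tree
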