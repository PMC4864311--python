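"""Readers and writers for the toolkit's on-disk formats.

Formats are deliberately plain text:

* spectra — CSV with columns ``wavelength_nm,absorbance`` (header required),
  one file per irradiation state, listed in irradiation order by a YAML
  manifest;
* alignments — (aligned) FASTA via Biopython;
* trees — Newick via dendropy, bootstrap percentages as internal node
  labels, branch lengths printed with 6 significant digits;
* gene tables — TSV with columns gene_id, orthogroup, scaffold, start
  (0-based), strand;
* distance matrices — square CSV with a leading name column.
"""

from __future__ import annotations

import json
import platform
import sys
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .decomposition import IrradiationSeries
from .errors import InputError
from .molevol import DistanceMatrix, ProteinAlignment
from .spectra import AbsorbanceSpectrum, resample
from .synteny import GENE_TABLE_COLUMNS, GeneTable

__all__ = [
    "read_alignment",
    "write_alignment",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_spectra_series",
    "write_spectra_series",
    "read_gene_table",
    "write_gene_table",
    "read_tree",
    "write_tree",
    "read_distance_matrix",
    "write_distance_matrix",
    "provenance_record",
]


# -- alignments -------------------------------------------------------------


def read_alignment(path) -> ProteinAlignment:
    """Read an aligned FASTA file into a validated :class:`ProteinAlignment`."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"{path}: no FASTA records found")
    names = tuple(r.id for r in records)
    rows = tuple(str(r.seq).upper() for r in records)
    return ProteinAlignment(names, rows)


def write_alignment(aln: ProteinAlignment, path) -> None:
    records = [
        SeqRecord(Seq(row), id=name, description="")
        for name, row in zip(aln.names, aln.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


# -- spectra ----------------------------------------------------------------


def read_spectrum_csv(path, label: str = "") -> AbsorbanceSpectrum:
    path = Path(path)
    df = pd.read_csv(path)
    need = {"wavelength_nm", "absorbance"}
    if not need.issubset(df.columns):
        raise InputError(
            f"{path}: expected columns {sorted(need)}, got {list(df.columns)}"
        )
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    if not np.all(np.diff(wl) > 0):
        raise InputError(f"{path}: wavelengths must be strictly increasing")
    return AbsorbanceSpectrum(wl, df["absorbance"].to_numpy(dtype=float),
                              label=label or path.stem)


def write_spectrum_csv(spectrum: AbsorbanceSpectrum, path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "absorbance": spectrum.absorbance}
    ).to_csv(path, index=False)


def read_spectra_series(manifest_path) -> IrradiationSeries:
    """Load an irradiation series from a YAML manifest.

    Manifest schema::

        grid: {start: 250, stop: 700, step: 1}   # optional common grid
        states:
          - {label: dark, file: dark.csv}
          - {label: uv_1, file: uv_1.csv}

    State files are resolved relative to the manifest.  States are resampled
    onto the declared grid (or the first state's grid when none is given);
    a grid extending beyond any state's recorded range is an error.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    if not manifest or "states" not in manifest or len(manifest["states"]) < 2:
        raise InputError(f"{manifest_path}: manifest must list >= 2 states")
    specs = []
    for entry in manifest["states"]:
        fpath = manifest_path.parent / entry["file"]
        if not fpath.exists():
            raise InputError(f"{manifest_path}: missing state file {fpath}")
        specs.append(read_spectrum_csv(fpath, label=entry.get("label", fpath.stem)))
    if "grid" in manifest and manifest["grid"]:
        g = manifest["grid"]
        grid = np.arange(float(g["start"]), float(g["stop"]) + float(g["step"]) / 2,
                         float(g["step"]))
    else:
        grid = specs[0].wavelengths
    states = tuple(resample(s, grid) for s in specs)
    return IrradiationSeries(states)


def write_spectra_series(series: IrradiationSeries, outdir,
                         manifest_name: str = "series.yaml") -> Path:
    """Write one CSV per state plus the manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, state in enumerate(series.states):
        label = state.label or f"state_{i}"
        fname = f"{label}.csv"
        write_spectrum_csv(state, outdir / fname)
        entries.append({"label": label, "file": fname})
    grid = series.grid
    step = float(grid[1] - grid[0])
    manifest = {"states": entries}
    if np.allclose(np.diff(grid), step):
        manifest["grid"] = {"start": float(grid[0]), "stop": float(grid[-1]),
                            "step": step}
    mpath = outdir / manifest_name
    with open(mpath, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return mpath


# -- gene tables ------------------------------------------------------------


def read_gene_table(path, species: str | None = None) -> GeneTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"scaffold": str})
    return GeneTable(species=species or path.stem, records=df)


def write_gene_table(table: GeneTable, path) -> None:
    table.records[GENE_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


# -- trees ------------------------------------------------------------------


def read_tree(path, rooted: bool | None = None) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    if rooted is not None:
        tree.is_rooted = rooted
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    """Write Newick with internal-node labels (supports) and 6-significant-
    digit branch lengths."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6g",
    )
    Path(path).write_text(s)


# -- distance matrices ------------------------------------------------------


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(tuple(df.index), df.to_numpy(dtype=float))


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.matrix, index=list(dm.names), columns=list(dm.names)).to_csv(
        path
    )


# -- provenance -------------------------------------------------------------


def provenance_record(command: str, config: dict, inputs: list[str],
                      seed: int | None = None) -> dict:
    """Machine-readable record sufficient to re-run a deterministic stage."""
    import uvkit

    return {
        "tool": "uvkit",
        "version": uvkit.__version__,
        "command": command,
        "config": config,
        "inputs": [str(p) for p in inputs],
        "seed": seed,
        "python": sys.version.split()[0],
        "platform": platform.platform(),
    }
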