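#!/usr/bin/env python
"""Generate the synthetic datasets every later stage consumes.

Writes to results/data/: an irradiation series of a bistable UV pigment
(dark / UV / yellow / UV / yellow states), a protein family evolved on a
six-taxon tree, and per-genome gene tables carrying the anchored target
block with losses engineered in the four species that lack the gene.
"""

import json
from pathlib import Path

from uvkit import io as uio
from uvkit.simulate import (
    SeqSimConfig,
    SpectraSimConfig,
    simulate_gene_tables,
    simulate_irradiation_series,
    simulate_protein_family,
)

SEED = 2016
OUT = Path(__file__).resolve().parent.parent / "results" / "data"

FISH_TREE = "((((medaka,(platyfish,molly)),tilapia),zebrafish),gar);"
LOSS_SET = ["medaka", "platyfish", "molly", "tilapia"]
FAMILY_TREE = (
    "(((a:0.1,b:0.1):0.08,c:0.2):0.08,((d:0.1,e:0.1):0.08,f:0.2):0.08);"
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    series, truth = simulate_irradiation_series(SpectraSimConfig(seed=SEED))
    manifest = uio.write_spectra_series(series, OUT / "spectra")
    with open(OUT / "spectra" / "ground_truth.json", "w") as fh:
        json.dump(truth, fh)
    print(f"spectra: {len(series)} states -> {manifest}")

    aln, tree, _ = simulate_protein_family(
        SeqSimConfig(tree=FAMILY_TREE, length=500, seed=SEED)
    )
    uio.write_alignment(aln, OUT / "family.fasta")
    uio.write_tree(tree, OUT / "family_true_tree.nwk")
    print(f"sequences: {aln.n_sequences} taxa x {aln.n_columns} sites -> "
          f"{OUT / 'family.fasta'}")

    tables, presence, sp_tree = simulate_gene_tables(
        FISH_TREE, loss_tips=LOSS_SET, seed=SEED
    )
    for t in tables:
        uio.write_gene_table(t, OUT / f"genome_{t.species}.tsv")
    uio.write_tree(sp_tree, OUT / "species_tree.nwk")
    with open(OUT / "presence.json", "w") as fh:
        json.dump(presence, fh)
    print(f"genomes: {len(tables)} gene tables, target deleted in "
          f"{sorted(LOSS_SET)}")


if __name__ == "__main__":
    main()
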