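# uvkit

Analysis toolkit for characterizing a bistable UV-sensitive opsin paralog
found only in ray-finned fishes: its photochemistry (UV- and visible-
absorbing spectral forms interconverted by light), its placement in the
opsin family tree, and the genomic footprint of its gain and loss across
fish lineages.

The package is aimed at photobiologists and molecular evolutionists who
need the complete chain from raw absorbance series and protein alignments
to fitted pigment spectra, bootstrapped trees and gene gain/loss scenarios,
with every stage testable on synthetic data of known ground truth.

## What it computes

**Spectral decomposition.** A bistable pigment's irradiation series
(dark → UV light → yellow light → …) is reduced to consecutive difference
spectra ΔA(λ), earlier minus later. Each ΔA is modelled as a signed sum of
two bands: the visible-absorbing photoproduct, described by the standard A1
visual-pigment absorbance template S(λ; λmax) fit in a visible window
(420–560 nm by default), and the UV-absorbing dark form, described by a
Gaussian a·exp(−(λ−c)²/2σ²) fit to the residual in 300–420 nm. Because the
broad UV band reaches into the visible window, the two fits are alternated
to convergence (coordinate descent on the joint least-squares objective).
The fitted λmax pair, band amplitudes and residual RMS are reported, with
components normalized to the visible band's peak. Detection of
photoconversion (max |ΔA| > k·σ_noise, default k = 5) and a
photoreversibility index (RMS shape difference of peak-normalized spectra)
complete the photochemical characterization.

**Molecular evolution.** Alignment columns containing gaps or missing
residues in any sequence are excluded (complete deletion); pairwise
identities and p-distances are computed on the remaining columns;
distances are Poisson-corrected, d = −ln(1−p) substitutions/site; trees
are built by Saitou–Nei Neighbor-Joining with column-resampling bootstrap
support (the conventional 1000 replicates by default).

**Synteny and gene loss.** Per-genome gene tables are scanned for the
conserved neighbourhood nppcl–gapdh–[target]–iffo1b. A genome is scored
`present_in_block`, `absent_block_conserved` (anchors adjacent, target
gone — the loss signature), or `block_not_found`. Given the resulting
presence/absence pattern on a rooted species tree, single-gain (Dollo)
scenarios are enumerated: one gain on an ancestor of all carriers plus the
unique minimal loss set below it, ranked by event count.

**Synthetic data.** Generators for irradiation series (affine mixtures of
the two bands plus baseline and noise), protein families under the
20-state equal-rates substitution model (the model that makes the Poisson
correction consistent), and gene tables with engineered losses. All are
bit-reproducible given a seed.

## Worked example

The `analysis/` scripts run the whole pipeline on synthetic data:

```sh
python analysis/01_simulate_data.py
python analysis/02_decompose_spectra.py
python analysis/03_phylogeny_identity.py
python analysis/04_synteny_dollo.py
```

Stage 02 decomposes the four difference spectra of a simulated series
whose true bands sit at 462 nm (visible, template) and 360 nm (UV,
Gaussian σ = 35 nm):

```
dark-uv_1: visible 461.8 nm, UV 360.0 nm, residual RMS 7.37e-03
uv_1-yellow_1: visible 461.9 nm, UV 360.0 nm, residual RMS 7.11e-03
yellow_1-uv_2: visible 462.0 nm, UV 360.0 nm, residual RMS 7.51e-03
uv_2-yellow_2: visible 462.0 nm, UV 360.1 nm, residual RMS 7.24e-03
photoreversibility index (yellow_1 vs yellow_2): 0.0078 (reversible)
dark -> UV photoconversion detected: True (max |dA| = 0.796)
```

Both λmax are recovered to a fraction of a nanometre; the residual RMS
matches the injected noise level (0.005 OD per state, √2 larger in a
difference); the two yellow-light states have the same shape (index below
the 0.02 reversibility threshold), and the dark→UV absorbance change is
far above the 5σ detection threshold. Stage 03 then recovers the true
6-taxon topology with 100% bootstrap support on every internal edge, and
stage 04 reproduces the engineered loss pattern and ranks the
two-event scenario (one gain at the root of the fishes, one loss on the
stem of the four-species clade) first.

Equivalent shell entry points exist for each stage
(`uvkit simulate|decompose|identity|tree|synteny|dollo`).

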