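# Methods

## Spectral model

A bistable UV pigment has two stable, photo-interconvertible forms: a
UV-absorbing dark state (11-cis retinal) and a visible-absorbing
photoproduct (all-trans retinal). An irradiation experiment records the
absolute absorbance A(λ) of one sample through a protocol of light steps;
subtracting consecutive states (earlier minus later, so a dark→UV step has
a positive UV lobe and a negative visible lobe) cancels the light-inert
background and isolates the photoconverted fraction:

ΔA(λ) = Δf · [ A_UV(λ) − A_vis(λ) ]

with Δf the change in the fraction of pigment in the UV form.

The visible form is modelled with the standard A1 visual-pigment
absorbance template: an α-band

S_α(x) = 1 / (exp[A(a−x)] + exp[B(b−x)] + exp[C(c−x)] + D),  x = λmax/λ,

with A = 69.7, B = 28, C = −14.9, D = 0.674, b = 0.922, c = 1.104 and
a = 0.8795 + 0.0459·exp[−(λmax−300)²/11940], plus a β-band Gaussian of
amplitude 0.26 centred at 189 + 0.315·λmax with bandwidth
−40.5 + 0.195·center. The sum is normalized numerically to unit peak on a
fine internal grid, and the constants live in a configuration dict
(`TEMPLATE_A1`) so an alternative template (e.g. an A2 porphyropsin
nomogram) can be substituted. Validity is restricted to λmax ∈ [330, 650]
nm. The UV form's shape is not template-like and is modelled as a plain
Gaussian parameterized by its standard deviation σ (FWHM = 2.3548σ is
reported alongside), optionally with a constant baseline term (off by
default).

### Fitting procedure

`fit_visible_component` fits the template to ΔA inside a visible window
(default 420–560 nm; the window is configuration and is echoed into all
outputs). For fixed λmax the optimal signed amplitude is a linear
least-squares coefficient, so the amplitude is profiled out and a bounded
1-D problem in λmax is solved with `scipy.optimize.least_squares` from
three starts (window endpoints and midpoint), tolerance 1e−10 on the
residual sum of squares, at most 500 iterations. The UV Gaussian is fit
the same way in 300–420 nm with bounded centre and σ; a fit whose σ
approaches the window span is flagged degenerate.

A single sequential pass (template first, Gaussian on the residual) is
biased when the UV band is broad: a σ = 35 nm Gaussian at 360 nm still
contributes ~0.23 of its peak at 420 nm, inside the visible window, and
pulls the template fit by several nm. `decompose_difference` therefore
alternates the two fits — each band refit on ΔA minus the other's current
estimate — until both λmax move by < 1e−4 nm (at most 50 rounds). This is
coordinate descent on the joint two-band least-squares objective; on
simulated series it converges in a handful of rounds and removes the bias
(recovery to ≤ 0.2 nm at the default noise). Reported quantities: both
bands (λmax, magnitude amplitude, sign, σ for the Gaussian), the full-grid
residual RMS after removing both components, and the component curves
normalized so the visible band peaks at 1.

### Detection and reversibility

`detect_photoconversion` declares a spectral change when
max|ΔA| over 300–600 nm exceeds k·σ_noise, default k = 5. σ_noise is the
per-point noise of the *difference*; callers comparing two spectra that
each carry noise σ should pass √2·σ. With that convention the familywise
false-positive rate over a ~300-point grid is far below 1% (per-point
exceedance probability ≈ 6e−7); defining σ_noise per spectrum instead
would put the effective threshold at 3.5σ of the difference and produce
~10% false positives, which is why the difference-level convention is
used. `photoreversibility_index` is the RMS difference of the two
peak-normalized spectra over 300–600 nm; it is invariant to positive
scaling, zero for identical shapes, and compared against a configurable
threshold (default 0.02) to call a photocycle reversible.

## Sequence statistics and trees

Columns containing '-' or 'X' in any row are removed before identity or
distance computation (complete deletion; 'X' is treated as missing data).
Identities are fractions of identical residues over the retained columns
of the *multiple* alignment; a per-pair exclusion mode (`exclusion="pair"`)
exists because two-sequence comparisons are sometimes quoted from pairwise
alignments instead. Group statistics report the mean and n−1-denominator
standard deviation of the target-versus-member identities.

Distances use the Poisson correction d = −ln(1−p) (substitutions/site),
which is the exact inverse of the expected p-distance under an equal-rates
substitution model with many states; p = 1 raises a saturation error
naming the offending pair. Trees are built by Saitou–Nei Neighbor-Joining:
join the pair minimizing Q(i,j) = (n−2)d(i,j) − Σ_k d(i,k) − Σ_k d(j,k),
ties broken deterministically on the lowest index pair; branch lengths
from the standard formulas, with negative estimates clamped to zero and
the deficit moved to the sister branch (count recorded on the tree).
On additive matrices the result reproduces the input path lengths exactly
(tested to 1e−9) and coincides with the exhaustive least-squares-best
topology.

Bootstrap support resamples alignment columns with replacement, rebuilds
the distance+NJ tree per replicate, and annotates each internal edge of
the full-data tree with the percentage of replicates containing its leaf
bipartition (bipartitions canonicalized to the side not containing the
lexicographically first taxon). The replicate stream is a seeded
`numpy.random.Generator`; the library default seed is 0 and the CLI
requires an explicit seed. Support is attached to the full-data tree, not
a consensus tree.

## Synteny and Dollo scenarios

Gene tables carry (gene_id, orthogroup, scaffold, start, strand) with
0-based starts; orthology is taken as given by the orthogroup column.
Block detection finds the two anchors on one scaffold — when a genome has
several anchor copies (post-duplication paralogs) the same-scaffold pair
of minimal genomic span is chosen, and a tie raises an ambiguity error —
and tests whether the target's start lies strictly between the anchor
starts (coordinates decide, not record order; strand is reported for
display only). Anchors with at most `window` (default 5) intervening genes
and no target give `absent_block_conserved`, the expected signature of a
gene loss in an otherwise conserved neighbourhood.

`dollo_scenarios` assumes the gene is gained once (a gene is a complex
character; independent re-invention is excluded) and lost freely. For a
gain on node g, the minimal loss set is unique: the maximal subtrees below
g containing no carrier, one loss each. Candidate gains are the carriers'
MRCA and each of its ancestors; all candidates are reported ranked by
1 + losses, because near-minimal scenarios (gain deeper than the MRCA)
remain biologically relevant when outgroup data are incomplete, and the
data alone often cannot choose between them. Event counts are verified in
the tests against an exhaustive search over gain nodes and loss-edge
subsets of increasing cardinality.

## Synthetic data

The generators define the conditions under which the pipeline is
validated; their defaults are fixed and are not tuning knobs.

*Spectra.* Each state is f·UV_band + (1−f)·vis_band + baseline + noise,
with UV Gaussian (360 nm, σ 35 nm, amplitude 1.0), visible template
(462 nm, amplitude 0.8 — the photoproduct of this pigment class absorbs
somewhat less strongly than the UV form), baseline 0.01 OD, per-point
Gaussian noise 0.005 OD, grid 250–700 nm at 1 nm. The default protocol is
dark (f = 1.0), UV (f = 0.1), yellow (f = 0.9), UV (0.1), yellow (0.9):
photosteady states fall short of complete conversion, as in real
photoequilibria. The headline recovery check runs at a harder noise level
chosen so the difference-spectrum peak signal-to-noise ratio is 20. What
the simulator does not emulate: wavelength-dependent baseline drift,
scattering, photobleaching, or more than two spectral forms — so passing
tests demonstrate correct two-component decomposition under additive
white noise, not robustness to those artefacts.

*Sequences.* Root sequence i.i.d. uniform over the 20 amino acids; along a
branch of length d each site receives N ~ Poisson(d·20/19) events, each
drawing a letter uniformly from all 20. This is the uniformized equal-
rates chain: allowing silent events makes the per-site event count exactly
Poisson(d·20/19) while reproducing the exact transition probabilities,
hence the closed-form expected p-distance
p(d) = (19/20)(1 − e^(−20d/19)) — p(0.5) = 0.38876 — under which the
Poisson distance correction is consistent. Richer exchangeability matrices
(JTT and kin), rate heterogeneity and indels are deliberately out of
scope; gap handling is exercised with hand-built fixtures instead.

*Genomes.* One scaffold per species carrying flank decoys, the upstream
anchors (nppcl, gapdh), up to two intervening decoys, the target (unless
the species is in the engineered loss set), and the downstream anchor
(iffo1b), with random strands and intergenic spacings of 5–40 kb. Decoy
orthogroups are species-private so they never create spurious anchors.

All generators draw from child RNG streams (fixed per-generator offsets
mixed into the root seed), so adding a generator never changes another's
output, and everything is bit-reproducible given (config, seed).

## Problem sizes and numerical choices

The validation suite uses 100 simulated irradiation series for λmax
recovery, 200 random additive matrices of 4–8 taxa for the NJ-vs-
exhaustive-search check (the oracle scores all topologies — up to 10,395
at 8 taxa — by projecting the distance vector onto each topology's
path-incidence column space), 10,000 sites for the simulator consistency
check, 100 bootstrap replicates on a conflict-free quartet, 100 random
trees of up to 10 tips for the Dollo oracle, and 1,000/100 noise/signal
pairs for the detector's error rates. These sizes give the checks sharp
expected outcomes (binomial or closed-form) while keeping the whole suite
fast on a single CPU.

Known limitations: the two-band decomposition assumes exactly two
spectral forms and a constant baseline; the NJ implementation targets the
small (tens of taxa) alignments of this analysis, not genome-scale
matrices; Dollo enumeration reports scenarios, it does not weigh them by
branch lengths or gene-specific loss rates; and the published identity
percentages for the real opsin set can only be checked after the
accession sequences are retrieved and aligned, since raw spectra and
curated alignments are not redistributable here.
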