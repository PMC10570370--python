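# Methods

## Scope and data model

The package analyzes direct-infusion negative-mode FT-ICR-MS peak lists of an
evolving CHOS reaction system. The atomic unit of annotation is the
`ElementalComposition` (integer C/H/O/S/Na counts plus a ¹³C substitution
count). All ions carry charge −1: deprotonated `[M−H]⁻` at m/z = M − m(p⁺),
and sodiated-deprotonated `[M−2H+Na]⁻` at m/z = M − 2·m(p⁺) + m(Na⁺).
Subtracting the *proton* (not hydrogen-atom) mass keeps the electron with the
anion, which is the standard negative-ESI convention. Atomic masses are the
AME2020/CODATA monoisotopic values hard-coded to ≥9 decimals; the six
reaction-edge masses printed to 5 d.p. in the analysis (+H₂O, +H₂S, +C₂H₂,
+CH₂O₂, +CH₂OS, +H₂) are reproduced from this table.

## Preprocessing

Per replicate: peaks with s/n < 4 or outside the closed window [122, 1000] u
are dropped; both boundaries are inclusive. Replicate consensus pools the
(usually three) technical replicates, groups peaks by single linkage on the
sorted m/z axis (gap > tol_ppm starts a new group; default 1 ppm), and keeps
groups supported by **more than 66%** of replicates — so 2-of-3 passes
(66.7% > 66%) and 1-of-3 does not. A group reports the median m/z and the
mean intensity over contributing replicates; the median reduces the effective
mass error of a triplicate by roughly √3.

Affine recalibration (`mz' = a·mz + b`, least squares on ≥2 calibrant pairs)
is available for instrument data; synthetic data are already on scale.

Two cleanup filters are heuristic reconstructions of unpublished in-house
filters and are individually switchable, with every removal logged:

* **³⁴S isotopologues**: a peak +1.99580 u above a more intense peak is
  removed when its intensity ratio falls within [0.3, 3] of the natural
  expectation 0.0421·s·I(parent) for some s ≤ 3. The cap of 3 keeps
  implausibly intense satellites (ratio ≳ 0.4) untouched while still catching
  genuine satellites of up to S₆ compounds, whose expectation (≤ 0.25) lies
  inside the s = 3 band.
* **Wiggle sidebands**: a peak within ±0.01 u of a ≥50× more intense peak is
  removed when below 1% of it.

## Formula assignment

Two independent routes:

**Brute force (oracle).** For a target m/z and ion type, iterate C, O, S, Na
counts (defaults C ≤ 40, H ≤ 80, O ≤ 10, S ≤ 5, Na ≤ 1) and solve the
hydrogen count from the mass residual, keeping candidates within tolerance
(default 0.5 ppm, FT-ICR-typical) sorted by |error|, then fewer heteroatoms,
then formula string. Used directly as the assignment oracle in tests and to
seed the network method.

**Mass-difference network.** Seed formulas are propagated across the six
reaction deltas in both directions, best-first in cumulative |ppm error|
(Dijkstra on the peak graph), so each peak receives the assignment reachable
with the smallest total error; ties break deterministically (heteroatoms,
then formula). Propagation targets are computed from the *theoretical* m/z of
the assigned composition, so errors do not accumulate along chains. Element
counts must remain valid and the elemental-ratio window (0.5 ≤ H/C ≤ 2.5,
O/C < 1.5; the H/C bounds inclusive, the O/C bound strict) is enforced at
every step. Each annotation records its path.

**Seeding.** The default pipeline brute-forces every consensus peak below
200 u (ratio filters on) and uses the top candidates as seeds: low-mass CHOS
formulas are unambiguous at sub-ppm accuracy, and 200 u safely covers all
lineage "entry points" — observed molecules whose precursors fall below the
122 u acquisition limit, which are at most one reaction delta (≤ 62 u) above
it. Ground-truth seeding is available as an option for controlled
experiments.

**Satellite exclusion.** Natural M+1 peaks (+1.003355 u) and Na-adduct peaks
(+21.981945 u = m(Na⁺) − m(p⁺)) each replicate the entire reaction network
shifted by a constant, so a single accidental match would let propagation
annotate a whole shadow family. Peaks lying at either offset above a
sufficiently stronger peak are therefore excluded from assignment. Two exact
identities matter here: the Na-adduct of M is *exactly* isobaric with the
deprotonated ion of composition (M − H + Na) — because m(H) = m(p⁺) + m(e⁻)
— so pipeline assignment enumerates CHOS formulas only (Na = 0) and treats
sodium strictly as adduct evidence, attached to the neutral composition by
pairing each annotation with a peak at its sodiated m/z.

## ¹³C labelling degree

Feeding ¹³CO (or ¹³C₂H₂) shifts a product's monoisotopic ion by
k·Δ(¹³C−¹²C), k the number of incorporated labelled carbons. For each
annotated composition and k ∈ 0..min(c, k_max), the classifier compares the
labelled channel's intensity at the shifted m/z — relative to the unlabelled
channel's monoisotopic intensity, after per-channel total-intensity
normalization — against the natural expectation, and calls degree k when the
observed ratio is at least **twice** the expectation ("surpasses it by
100%"), inclusive at the boundary. The expectation is

* k = 1: the linear 1%-per-carbon rule, p·c with p = 0.01;
* k ≥ 2: the binomial C(c,k)·p^k·(1−p)^(c−k);
* plus the natural-satellite stack of lower called degrees: a species called
  at degree k′ contributes its own natural (k−k′)-fold satellite at shift k,
  expectation rel(k′)·natural(c−k′, k−k′). Without this term the M+1
  satellite of any labelled species (≈1.1% per remaining carbon) would always
  exceed the tiny binomial threshold and falsely call degree k+1.

Degree 0 is called when the unshifted peak survives in the labelled channel
above twice a residual-unlabelled expectation (default 0.05, covering
labelled-gas purities down to ~90%). The classifier's p stays at the nominal
0.01 even though natural abundance is ≈0.011; the ×2 headroom absorbs the
difference. k_max defaults to 6 for the CO channel (observed label counts
stay in the single digits) and to c for the acetylene channel, where the
complementary degree c − n_CO can be large. A composition called at ≥2
degrees is a *mixed* annotation (co-eluting isomers with different synthesis
histories); pipeline degree sets are unions over timepoints, so isomers with
different peak times are both seen. Cross-channel closure (k_CO + k_C₂H₂ = c)
flags compositions whose carbon budget is fully explained by the two feeds.

## Compound classes

Annotations partition exhaustively by (O-count, S-count) of the neutral
composition. Per subspace the mean H/C is reported per called degree, mixed
compositions contributing to each of their degrees (the averaging convention
is a documented choice). In carboxylic-acid subspaces the (degree, Na-adduct)
pair maps to candidate classes — degree 2 with adduct → dicarboxylic
candidate, degree 2 without → hydroxy-keto candidate, degree 1 →
dihydroxy-acid, degree 3 → diketo-acid; degree-1-with-adduct is logged as a
rule violation. Labels are *candidates*: exact-mass data cannot fix
functional-group positions. C2-homologous series are maximal chains under
repeated +C₂H₂ within one labelling degree, each composition in at most one
chain per degree; members therefore step by exactly (C2, H2).

## Molecular network

Nodes are neutral annotated compositions (label-degree variants collapse,
degree sets merge); an undirected edge joins two nodes whose composition
difference equals a reaction delta *exactly* — since nodes are already
formula-assigned, no m/z tolerance is involved and isobars cannot create
false edges. Edge direction (lower → higher mass) is kept as an attribute.
Connectivity is the percentage of nodes with degree ≥ 1. Per timepoint the
package reports class shares: among S-containing annotations the percentage
per sulfur count, among CHO annotations per oxygen count.

## SOM temporal clustering

Per-composition intensity vectors over the timepoint grid are min-max scaled
to [0,1] (constant vectors map to zeros). The clusterer is a classic online
Kohonen map on a 2×4 rectangular grid: per iteration one random sample is
drawn, its best-matching unit found by Euclidean distance, and all units
updated toward it with a Gaussian neighborhood of the BMU's grid position.
Learning rate starts at 0.1 and decays linearly to 0.01 over the 50,000
iterations; the neighborhood radius starts at 1.0 (in grid units — the data
live in the unit cube, and the initial radius must couple adjacent units)
and decays linearly to 0.1, by which point updates are effectively
winner-only. Weights initialize uniformly in [0,1] from the run seed; given
the seed, training is deterministic. Each occupied grid node is one temporal
cluster; its peak time is the timepoint maximizing the mean member profile,
ties to the earliest. The implementation follows the scikit-learn estimator
contract and composes with sklearn tooling.

A note on cluster cardinality: an online SOM trained on a few *isolated*
tight clusters routinely strands one interpolating unit between them, leaving
it empty. Real direct-infusion profile populations are not isolated islands —
peak times and shapes vary continuously. The synthetic benchmark population
(`archetype_profiles`) mirrors this: eight named shape families (four
transients whose peak positions tile the time axis, two sigmoidal risers, a
decayer and a broad plateau) with within-family variation, which reliably
occupies all eight nodes.

## Synthetic ground truth

The generator grows molecules from three seeds — acetaldehyde-equivalent
C₂H₄O (acetylene hydration), acrylic acid C₃H₄O₂ (Reppe carbonylation, one
CO-carbon), thioacetic acid C₂H₄OS — by applying each of the six reactions
independently per molecule per generation (defaults: C₂H₂ 0.70, H₂O 0.30,
H₂S 0.30, CO+H₂O 0.40, CO+H₂S 0.25, H₂ 0.25; 7 generations, ≈250–400
molecules). Products must satisfy the elemental-ratio window and h ≤ 2c + 2,
so every synthesis chain is valid end to end (this underlies the network
closure property). Carbonylation increments the CO-carbon count; two
water-carbonylations mark a molecule dicarboxylic; a configurable fraction of
compositions is duplicated at a different CO-carbon count to create true
mixed isomers.

Peak times are sulfur-determined — s = 0 → 168 h, 1 → 72 h, 2 → 24 h,
s ≥ 3 → 2 h, optionally jittered by one grid position (probability 0.25) —
encoding the early-sulfur-rich, late-sulfur-poor temporal trend. Abundance
follows a Gaussian kernel in ln(time) around the peak time (σ = 1.0 ln-hours)
times a log-normal amplitude (median 10⁶, σ = 1 ln-units). Rendering adds,
per species: the deprotonated monoisotopic peak, a natural M+1 at
0.011·(light carbons), a natural ³⁴S satellite at 0.0421·s, an Na adduct at
30% for dicarboxylics; labelled channels place the molecule at its channel
degree with 99% isotopic purity (residual unlabelled at 1%). Every m/z gets
Gaussian ppm error (default 0.2 ppm s.d.); s/n is intensity over a fixed
noise floor (10⁴), and peaks below s/n 1 are not recorded. Contaminant noise
peaks (150 per channel/timepoint, log-normal intensities mostly below the
s/n-4 cut) share positions across technical replicates — per-replicate random
noise would never survive the consensus rule and would make false-annotation
accounting vacuous. Replicates drop true peaks independently with probability
0.02. All randomness fans out from one seed via CRC32-keyed streams, so
outputs are byte-reproducible across processes.

What the generator does *not* emulate: chemical kinetics (abundances are
phenomenological kernels, not rate equations), peak shape and resolution
(peaks are sticks; isobaric interference appears only as exact coincidence),
space-charge or calibration drift, isotope fine structure, and positive-mode
chemistry. Passing tests therefore demonstrate the correctness of the
analysis logic under realistic mass error, noise and replicate statistics —
not robustness to instrument-level artifacts outside this model.

## Numerical conventions and degenerate inputs

Mass tolerances are relative (ppm); peak lookup takes the nearest candidate
within tolerance. Consensus m/z is the median, master-list intensity the
per-timepoint maximum. Empty spectra, empty subspaces, all-zero profiles and
an empty simulation all produce empty-but-valid outputs; an empty network has
undefined connectivity (error). Artifact CSVs use fixed float formatting so a
rerun with the same seed reproduces files byte for byte. Problem sizes
throughout (generator defaults, archetype-benchmark size 400) are chosen so a
complete default run takes a few seconds on one CPU.

## Known limitations

* The two in-house cleanup filters and the original seed list are not public;
  the reconstructions here are labelled as such and switchable.
* The satellite-exclusion step can in principle suppress a genuine compound
  that sits exactly one satellite offset above a stronger compound; with
  sub-ppm windows such coincidences are rare, and all exclusions are
  recoverable from the master peak table.
* Mixed-isomer statistics count degree multiplicity only; relative isomer
  abundances are not deconvolved.
* The assignment tolerance (0.5 ppm) and the labelled-gas purity (0.99) are
  stated assumptions of the study conditions, both configurable.
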