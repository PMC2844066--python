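# Methods

This note documents the models and procedures implemented in
`mtepitope`, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the package's known limitations.

## Sequence layer

Sequences are 1-based strings over the 20 amino acids plus `X`
(unknown); all intervals (`SequenceRegion`) are closed, matching the
epitope notation used in the tubulin literature (β81–95 includes both
endpoints).

**Global alignment** uses BLOSUM62 with affine gaps, open 10 and extend
0.5 (a gap of length k costs 10 + 0.5·(k − 1)), the common
needle-style default. Percent identity counts identical non-gap
columns over all columns except terminal-gap columns; internal gaps
are mismatches and `X` never matches. This convention is stated
explicitly because reported tubulin identities ("approximately 85%"
between vertebrate and plant β-tubulin) are only reproducible once the
denominator is fixed. Among co-optimal alignments the aligner's first
(diagonal-preferring) traceback is reported; the optimal *score* is
unique and is what the test suite pins against an independent
affine-gap dynamic-programming oracle.

**Consensus** is per-column majority over non-gap symbols, `X` excluded
from voting, ties broken toward the alphabetically lowest residue for
determinism, and columns with agreement < 0.5 flagged low-confidence.

**Bundled references.** `data/btub_pig_synthetic.fasta` and
`data/tbb1_arath_synthetic.fasta` are synthetic stand-ins — clearly
labelled as such in filename and header — constructed to carry the
documented properties of the porcine β-tubulin and *A. thaliana* TBB1
database entries: 445 residues with Asp-Pro bonds at 31–32 and 304–305
and nowhere else; 447 residues carrying the published epitope regions
1–10 `MREILHVQGG`, 81–95 `PYGQIFRPDNFVFGQ`, 426–435 `YQDATADEED`,
436–447 `EYDEEEEQVYES` verbatim; and ≈85% mutual global identity under
the scoring above. Conclusions that depend on the *exact* database
residues outside these pinned properties should be re-derived with the
real records.

## Chemical cleavage

A `CleavageSite` at position p cuts the peptide bond between residues
p and p+1; for Asp-Pro chemistry residue p is D and p+1 is P, so the
two β-tubulin bonds "31–32" and "304–305" are sites 31 and 304. A
digest with up to m missed cleavages enumerates every interval whose
ends are cleavage boundaries or chain termini with at most m uncut
internal sites; the intact chain is subject to the same filter rather
than special-cased, which yields exactly the five-fragment pattern at
m = 1 with two sites. Complete-digest fragments are labelled β1, β2, …
by descending length (gel-band convention, heaviest first); composite
fragments join their constituents' labels ("β1+β2").

Masses are **average** residue masses (pyteomics) plus one water,
because the downstream context is SDS-PAGE band interpretation;
monoisotopic masses are available via the `average=False` switch. `X`
residues require an explicit placeholder mass.

**Localization** intersects the regions of all fragments an antibody
stains. The result is flagged inconsistent when the intersection is
empty or lies entirely inside a fragment reported negative. Blot
reactivity is treated as presence/absence; band intensities are out of
scope. Note that containment logic predicts *every* fragment carrying
the epitope as reactive, whereas real blots may show only the abundant
bands; the package does not model band abundance.

## Peptide scans

`design_scan` tiles a region with `length`-mers (default 15) every
`step` residues (default 5). Two points deserve emphasis:

* **Step = 5, i.e. adjacent 15-mers overlap by 10.** Scan membranes of
  this design are sometimes described as having "5 amino acid
  overlaps", but the published spot counts (34 peptides for a
  180-residue region) are only achievable with a step of 5; the counts
  win, and this package always means *step* 5.
* **C-anchoring** (default on) appends one final peptide ending exactly
  at the region end when the last regular tile stops short — standard
  SPOT practice, and what turns 53 regular tiles of region 171–447
  into the 54-spot membrane. `anchor_c=False` reproduces the 53-spot
  variant.

`call_epitope` computes the core (intersection of all positive spans,
optionally intersected with a prior such as the immunogen peptide) and,
for each negative peptide overlapping the core, records the parts of
the core outside that peptide as must-include constraints; a negative
peptide covering the whole core marks the call inconsistent, and no
positive spot at all is a distinct no-signal outcome. The brute-force
oracle in the test suite enumerates every sub-interval of the scan
region and keeps those contained in all positive and no negative
peptide; the core always contains that consistent set.

**Exactness caveat.** For an epitope of length 2·step whose start lies
on the tiling grid, the core equals the epitope exactly; off-grid
epitopes (or lengths between 2·step and the peptide length) yield a
core that strictly contains the epitope, and lengths above ~11 at
unfavourable offsets can produce no containing spot at all. The
recovery properties are therefore stated as: containment for arbitrary
detectable plants (length ≤ 11 anywhere), exact equality for on-grid
length-10 plants.

**Intensity threshold.** When no threshold is supplied, spots are split
at mean + 2·SD of the lowest intensity quartile (assumed background).
The simulated membranes place positives in (1.5, 3.0) and negatives in
(0, 0.5) around a fixed threshold of 1.0.

## Lattice geometry

All transforms are proper rigid motions recorded per placed copy, so
any copy superposes back onto the input dimer exactly (inverse
transform, RMSD at machine precision; coordinates are stored in
float32 by the structure container, so file-level comparisons use
~1e-3 Å tolerances).

* **Orientation**: dimer centroid at the origin, α→β monomer-centroid
  axis along +z (β toward the plus end), using the minimal rotation
  (axis = v × z) — deterministic, never a reflection.
* **Protofilament**: copies at z = 0, rise, 2·rise, … with
  rise = 79.4 Å per dimer and no inter-copy rotation.
* **Wall**: protofilament k at radius R = s/(2·sin(π/n)) (chord
  formula from the lateral spacing s = 53 Å; n = 13 gives
  R ≈ 110.7 Å, outer diameter with a tubulin-dimensioned monomer
  ≈ 26 nm), azimuth k·360/n, axial offset k·3·rise/(2n) ≈ k·9.16 Å
  (3-start helix). The seam arises naturally from the stagger; no
  special-casing, no energy refinement.

The transform series sometimes quoted for protofilament arrangement —
per-protofilament axial rotation 14° with an angular shift of 10° at
53 Å — cannot close a 13-fold ring (13 × 10° ≠ 360°). The default
lattice is therefore the closed 13-protofilament B-lattice above, which
satisfies testable invariants (53.0 Å adjacent-axis distance, 13-fold
rotational closure off-seam). The literal series is preserved as
`paper_literal=True`: an open 120° arc with radius 53/(2·sin 5°) and a
k·14° spin of each protofilament about its own axis. The per-
protofilament spin is applied *only* in that mode because a
k-dependent spin is incompatible with rotational closure. Whether the
14° was meant as a per-dimer twist, a protofilament spin or a
supertwist is not decidable from the available description; both
angles remain plain parameters. Dimers per protofilament defaults
to 3 — enough axial context for an interior dimer at desk scale.

PDB output cycles chain labels A–Z, a–z, 0–9 per copy-chain (62 labels)
and splits larger assemblies across MODEL records; the
(protofilament, dimer, chain) → label mapping is returned to the
caller and recorded by the pipeline manifest.

## Solvent accessibility and exposure classes

SASA is a from-scratch Shrake–Rupley implementation: a deterministic
golden-spiral point set (default 960 points) on each atom's
solvent-expanded sphere (van der Waals radius + 1.4 Å probe), with
points inside any neighbor's expanded sphere inaccessible. It is exact
for an isolated atom, within 2% of the analytic two-sphere formula at
default sampling, and cross-checked against an independent library
implementation in the tests. Coarse-grained pseudo-atoms (element `X`)
carry a 3 Å radius.

Relative SASA divides by the residue's free-state reference: the
extended Gly-X-Gly tripeptide table (theoretical values) for all-atom
residues, and the closed form 4π(r + probe)² for single-pseudo-atom
residues, where the tripeptide convention is meaningless.

Classification is deliberately simple and fully documented, replacing
by an explicit rule what was historically done by eye in a molecular
viewer: buried if relative SASA < 0.10; otherwise outer / lumen if the
residue centroid's distance from the microtubule axis is more than
δ = 6 Å above / below the mean wall radius; lateral otherwise. The
thresholds are this package's own calibration: they recover 100% of
synthetic ground truth planted ≥ 10 Å from the boundaries, and both
are configurable. No quantitative exposure criterion exists in the
source material ("completely exposed" is a visual call), so these
defaults are labelled as the package's own.

Exposure is evaluated on an interior copy (middle protofilament index,
middle dimer) so the residue sees both lateral neighbors and axial
context, mimicking an infinite lattice. The epitope verdict is the
majority class among non-buried residues, `mixed` on ties. Residues
beyond the last resolved residue (flexible C-terminal tails) inherit
the class of their last resolved anchor and are flagged
`tail-inferred` — mirroring the standard argument that tail residues
anchored on the outer surface are themselves outside.

Expected outcomes on a *real* tubulin dimer structure (TU-06 lumen;
TU-12/TUB 2.1/TU-14 outer; C-terminal tyrosines such as 426 and 437
outer) are documented here as what a user supplying such a structure
should see; they are not unit tests, because building that homology
model is outside this package's scope.

## Synthetic data: what it does and does not show

The generators are pure functions of their seed (byte-identical
outputs) and plant recoverable ground truth: isotype families with
i.i.d. substitutions (no indels by default; consensus recovers the
base), sequences with DP planted exactly at chosen bonds and excluded
elsewhere, spot membranes with containment-driven positives and
configurable false-positive/negative rates, and coarse dimers — one
3 Å pseudo-atom per residue on two stacked spheroids with tubulin-like
half-dimensions (23 × 20 × 32.5 Å) — whose planted residues sit on the
±x cap so that assembly forces their radial class (planted margins
exceed 10 Å beyond the ±δ band).

Passing the planted-recovery suites shows the *logic* of each stage is
correct; it does not show that real tubulin epitopes are correctly
classified, because the coarse dimer has no fold, no side chains, no
atomic packing, and its lateral interfaces are only geometrically,
not chemically, apposed. Real-structure exposure additionally depends
on the homology model quality, fixation state and antibody footprint,
none of which are modelled.

## Problem sizes and numerical choices

The default verification runs use: 200 noise-free simulated scans
(lengths 6–11, plus 51 on-grid length-10 plants) for epitope recovery;
960 sphere points for SASA (two-sphere oracle error ~0.03%, well
under the 2% bound); 13 protofilaments × 3 dimers × 200 pseudo-atoms
for lattice invariants; and 50 seeded plantings × 12 residues for
exposure recovery — sizes at which the full suite runs in seconds
while every invariant is exercised at its stated tolerance. Rigid-
transform and closure residuals are at machine precision (< 1e-12 Å)
against the 1e-6 Å requirement; tolerances on file round-trips
(1.5e-3 Å) reflect fixed-width PDB precision, and orientation checks
use float32-storage-appropriate bounds (1e-6 rad on axis recovery).

## Known limitations

* Homology modeling, energy refinement and contact-interface
  optimization of the dimer are out of scope; the dimer is an input.
* Multiple-sequence alignment construction is out of scope; consensus
  operates on provided or generated alignments (the generator emits
  gapless families).
* Blot band abundance, image quantification, antibody steric
  footprints (a ~150 kDa IgG), electrostatics and fixation-induced
  conformational changes are not modelled.
* The immunogen-prior intersect narrows a scan core but cannot, by
  interval logic alone, reproduce every historically reported final
  epitope assignment (some used binding knowledge beyond the scan).
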