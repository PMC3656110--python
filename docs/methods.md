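# Methods

## The model

`prefint` quantifies how a small cosolvent (the motivating case is glycerol
in water) partitions around rigid protein structures, and how changes of
that partitioning upon protein-protein association translate into shifts of
the association constant.

The central quantity is the preferential interaction coefficient of the
two-domain model.  Solvent molecules are split into a *local* domain — any
heavy atom within a cutoff (default 5 Å) of the solute van der Waals
surface — and the *bulk* remainder.  With local counts `n_w`, `n_x` and
totals `N_w`, `N_x`, the instantaneous coefficient of a frame is

    Γ(t) = n_x(t) − n_w(t) · (N_x − n_x(t)) / (N_w − n_w(t))

and the reported Γ is its trajectory mean.  Γ < 0 means preferential
exclusion of the cosolvent (preferential hydration), Γ > 0 preferential
binding.  The surface distance of a molecule is the minimum over its heavy
atoms and all solute atoms of (center distance − solute-atom vdW radius);
a molecule is local if that minimum is at most the cutoff.

Each local molecule is assigned to exactly one residue — the residue whose
surface it is nearest, ties broken toward the lowest (chain, residue number)
pair.  Because the assignment is a partition, per-residue coefficients

    Γ_res(t) = n_x,res(t) − n_w,res(t) · B(t),   B(t) the global bulk ratio,

sum to the global Γ(t) *exactly*, frame by frame.  This additivity is what
makes regional decompositions well-defined and is asserted in the tests at
1e-10 absolute tolerance.

### Interface decomposition

For a complex with a chain split A|B, the interface region inte(D) contains
every residue (of either side) with at least one atom within an atom-center
distance D of the partner.  Regional coefficients are frame-wise sums of
member-residue series, so Γ = Γ^inte(D) + Γ^non-inte(D) identically for all
D.  The interface distance D* is the smallest scanned D (default grid
3–12 Å, step 1 Å) at which the non-interface coefficient no longer differs
significantly between the associated and free states:

    |ΔΓ^non-inte(D)| ≤ k · SE,  SE in quadrature over the three systems,

with k = 1 by default.  Beyond D*, the entire association-induced solvation
change ΔΓ is carried by the interface region, where it can be measured with
much smaller statistical error than the global difference.  The default
k = 1 and the minimal-D rule (the criterion need not hold at every D > D*;
the scan report exposes all rows) are pinned choices: published analyses of
the antibody–lysozyme systems report non-interface differences at D* that
are small compared to their standard errors, which is the regime k = 1
captures.  The free↔complex residue correspondence is by (chain, residue
number, residue name) equality, with an explicit override table for
renumbered structures.

### Wyman linkage

Linkage theory gives d ln K_A / d ln a_x = ΔΓ.  Treating the cosolvent
activity as proportional to molality (flagged as an assumption in the
output) and using the empirically common exponential response of K_A to
molality, this integrates to ln(K_A/K_A0) = s·m with s the per-molal
solvation change, so ΔΓ_exp(m) = s·m.  The slope is fit by (weighted) least
squares through the origin — K_A0 is the measured reference, not a free
parameter.  K_A values come from Scatchard analysis of steady-state binding
responses (R/C vs R; slope −K_A), with a direct nonlinear 1:1 isotherm fit
as a cross-check that must agree within 10% on clean data.

### Volumetric maps

Per-species occupancy grids (default spacing 0.5 Å, padding 10 Å around the
solute bounding box, half-open voxels) support three products: local
concentration fields (written as OpenDX text, z-fastest data order as
molecular viewers expect), a voxel classification into cosolvent-preferred /
water-preferred / neutral / undersampled by comparing the voxel occupancy
ratio against the bulk ratio with a fold threshold (default 2, minimum
occupancy 20 counts — the published figures use a high-concentration
threshold whose numeric value is not stated, so these defaults are pinned
here), and high-occupancy hydration sites: greedy non-overlapping occupancy
maxima whose occupancy is the fraction of frames with at least one water
heavy atom within the site radius.  The bulk reference composition is
measured beyond 8 Å from the vdW surface, safely outside the 5 Å local
domain; with a periodic box only voxels lying entirely inside the cell
enter the bulk estimate.

## The synthetic generator

Real inputs for this analysis are long constrained-backbone MD trajectories;
the package instead ships a generator that emulates the *mechanisms* those
trajectories exhibit, with known ground truth:

* solutes are rigid pseudo-atom blobs (single sphere, or a two-blob complex
  with a contact axis), one residue per atom;
* solvent molecules are placed by rejection sampling: uniform proposals in
  the box, rejected inside the solute hard core, accepted with probability
  proportional to the enrichment factor of the region they fall in
  (normalized so the largest factor maps to 1) — regions are the solvation
  shell, an optional contact cylinder (dewetting), and an optional spherical
  patch at a residue;
* frames are i.i.d. by default; an AR(1) mode re-samples each molecule with
  probability 1−ρ per frame, giving occupancy statistics a lag-1
  autocorrelation of ρ (used only to validate the block-error estimator);
* identical spec + seed regenerates bit-identical trajectories.

Default composition is the 6 molal glycerol/water mole ratio
(N_x/N_w ≈ 0.108, e.g. 43/400).  The absolute number density is far below
liquid water: shell-counting statistics depend on composition and geometry,
not on absolute density, and the reduced density keeps every scenario
desk-scale.  What the generator does *not* emulate: solvent structure
(radial distribution shells, hydrogen bonding), orientational correlations,
and force-field-level energetics — so passing tests validate the estimators
and the decomposition logic, not any force field's solvation numbers.

Ground truth is computed by Monte-Carlo integration of the same sampling
density with an independent seed: sampled points are classified exactly like
trajectory molecules, giving expected per-residue occupancies and a plug-in
expected Γ (accurate to O(1/N)).  For the dewetted-contact scenario the
generator-truth interface distance applies the same minimal-D rule to the
expected regional differences at the measured noise level.

The canonical scenarios used by the tests and the acceptance script:

* `demo_null_sphere` — uniform solvent around a 12-atom blob; E[Γ] = 0 by
  symmetry (null calibration).
* `demo_dewetted_complex` — two 26-atom blobs (radius 5.5 Å, surface gap
  1.5 Å) in a 58 Å box with 2400/260 solvent molecules, cosolvent shell
  enrichment 2, and total cosolvent exclusion from a 7 Å × ±4 Å contact
  cylinder.  Association therefore expels shell-enriched cosolvent from the
  contact: ΔΓ and ΔΓ^inte are negative, and the change is confined to the
  interface.

## Numerical choices

* Neighbor search uses a k-d tree on solute atoms; exactness of surface
  distances is guaranteed by bounding the candidate set with the
  nearest-center distance plus the largest vdW radius, and is verified
  against an all-pairs brute-force oracle on every test fixture.
* Residue-assignment ties (equal surface distance within 1e-9 Å) go to the
  lowest (chain, residue number) pair.
* Block-error estimation halves the block count per level (block length
  n/2^k), requires at least 4 blocks per level, reads the plateau as the
  maximum SE over the two coarsest admissible levels, and floors the result
  at half the naive i.i.d. SE.  The estimate is noisy at 4–8 blocks — the
  max-rule deliberately errs on the conservative side.
* The per-frame ("instantaneous") bulk ratio is the default Γ estimator; a
  ratio-of-trajectory-means variant is available and must agree within one
  SE on test fixtures.  Only the instantaneous form is exactly additive
  across residues.
* Degenerate inputs raise: empty solvent frames, frames with no bulk water,
  series shorter than 8 frames, chain splits that leave a side empty, grids
  with no bulk voxels.
* vdW radii default to the Bondi set (H from Rowland & Taylor).  The radii
  used by any given force field differ slightly; at a fixed 5 Å cutoff Γ is
  weakly sensitive to the choice, but the table is pinned and overridable
  for reproducibility.

## Problem sizes

Test fixtures use 5–26 solute atoms, 60–2400 solvent molecules and 8–2000
frames; the dewetted-contact demonstration uses three 200-frame systems and
400k-point truth integration.  These sizes give standard errors a few times
smaller than the constructed effects, which is the regime the estimators are
designed for; all suites complete in a few minutes on one CPU.

## Known limitations

* Frames are assumed pre-aligned to the rigid solute; no superposition or
  fitting is performed, and conformational flexibility is out of scope.
* The interface criterion compares means to quadrature SEs; it is a
  significance heuristic, not a formal hypothesis test, and D* inherits the
  statistical resolution of the regional SEs.
* The activity-proportional-to-molality assumption in the linkage module is
  adequate for the dilute-to-moderate molality range; no activity-coefficient
  model is applied.
* The finite simulation box couples local and bulk compositions: expelling
  cosolvent from the local domain slightly enriches the bulk, producing a
  small far-field offset in regional differences that vanishes only as the
  solvent reservoir grows.  The canonical scenarios are sized so this offset
  is below the statistical resolution.
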