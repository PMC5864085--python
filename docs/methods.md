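# Methods

This note documents the models and conventions implemented in
`dimerscope`, the defaults and why they were chosen, and what the bundled
synthetic generators do and do not emulate.

## Dimerization criterion and event detection

Two receptors are dimeric when the interaction energy between their
transmembrane segments — the sum of Lennard-Jones and Coulomb terms,
supplied as a two-column time series per replica — is below
`e_on = −50 kJ/mol`; an existing dimer ends only when the energy rises
above `e_off = −1 kJ/mol`. Energies inside (−50, −1] are treated as a
hysteresis band (a Schmitt trigger): they neither create nor destroy a
dimer. This two-threshold reading is the only internally consistent one
when entry and exit thresholds differ; it makes dimerization and
dissociation events strictly alternate, which downstream counting relies
on. Both thresholds are strict inequalities (an energy of exactly
−50 kJ/mol does not form a dimer), and a replica whose very first frame
is already below `e_on` is dimeric from t = 0 with no recorded event —
it is left-censored and excluded from rate fitting. Tighter criteria
(−100, −150, −200 kJ/mol) re-run the same machinery to probe
increasingly compact dimers.

## Association rate

The ensemble of per-replica first-dimerization times defines the
surviving-monomer fraction f(t). The reported rate is a through-origin
weighted least-squares fit of ln f(t) = −kt over the event times with
f > 0, weighted by the number of monomeric replicas still at risk
(the variance of ln f shrinks with that count). Because the exact fitting
procedure behind such survivor curves is rarely stated, the
censored-exponential maximum-likelihood estimate
k̂ = d / (Σ event times + Σ censored horizons) is always computed
alongside as an independent cross-check; the two agree within a few
percent at ensemble sizes of ~500. If every replica dimerizes in the
first output frame the rate is at the resolution limit of the output
interval and is flagged as such.

## Binding free-energy lower bound

P₁ is the total time the ensemble spends dimeric; P₀ is monomeric time
occurring *after* a replica's first dissociation (time before the first
dimerization never counts, and a re-dimerization closes a P₀ interval).
Then

    K_D = (P₀/P₁) / (N_Av · V)        [mol/L]
    ΔG  = R·T · ln(K_D / c°),  c° = 1 mol/L.

The relation is sometimes printed with the volume factor multiplying
rather than dividing; only the dividing form is dimensionally consistent
and reproduces the published ΔG ↔ K_D pairs (e.g. −24.95 kJ/mol at 310 K
corresponds to K_D ≈ 6.3·10⁻⁵ M), so that is what is implemented, and no
further sign fixing is applied. V defaults to the simulation box xy-area
times a 4 nm slab enclosing the protein–lipid bilayer; the slab thickness
is configurable because no canonical value exists. P₀/P₁ = 0 (no
dissociation ever observed) yields the sentinel K_D = 0, ΔG = −∞ rather
than a number. Because dissociation is rare, ΔG is a lower bound: longer
ensembles can only raise P₀/P₁. Dissociation propensities and P₀/P₁ can
be restricted to the replicas of the most populated interfaces (three for
homodimers, five for heterodimers) to exclude implausible dimer
configurations.

## Molecular frames and relative orientation

Each receptor's frame has its origin at the centre of mass of its TM
backbone beads (TM backbone rather than all beads, so flexible loops
cannot tilt the frame), z along the membrane normal (+z extracellular),
and x along the first principal component of the xy-projected TM backbone
beads. A principal axis is defined only up to sign, which would leave the
orientation angles ambiguous modulo 180°; the sign is fixed by requiring
the TM1 backbone centroid to sit at an azimuth in [−90°, 90°). This makes
the frame deterministic, translation invariant and exactly equivariant
under rotations about z. An isotropic in-plane bead distribution (equal
principal moments) has no defined axes and raises an error.

Angles (degrees, counterclockwise seen from the extracellular side,
wrapped to [0, 360)):

* β — azimuth of B's origin in A's frame (where B binds on A),
* φ — rotation of B's x axis relative to A's about z,
* χ = (180° + β − φ) mod 360 — where A binds on B; identically equal to
  the azimuth of A's origin measured in B's frame, which the tests verify
  to < 10⁻⁶ degrees on 1000 random rigid placements.

Frames whose membrane normals disagree by more than 15° violate the
quasi-planar assumption and are rejected. Orientation statistics use the
final 50 ns of each dimer-containing replica (configurable): late windows
sample the relaxed interface rather than the collision geometry.

## Height-fields, watershed basins and labels

(β, χ) samples are binned to the nearest node of a 1° × 1° grid and
smoothed with a periodic Gaussian (default bandwidth 10°, matching the 1D
binding-position KDE). This binned KDE is exact for grid-resolution data
and keeps the 360×360 field cheap. Local maxima are plateau-collapsed
cells that survive a periodic maximum filter; maxima below 5 % of the
global maximum are pruned as noise (their mass drains into the surviving
basins). Watershed runs on the negated field with the retained maxima as
markers; periodicity is handled by tiling the field 3×3 with identically
labelled marker copies and extracting the central tile, so basins wrap
seamlessly across 0°/360°. Every cell belongs to exactly one basin and
the basin count equals the retained-maximum count; a uniform field
collapses to a single basin flagged degenerate.

Replicas are assigned by the circular mean of their last-window (β, χ) —
population counts are per simulation, not per frame (per-frame assignment
exists as an option). Replicas whose dimer lived shorter than the
analysis window are excluded with a warning. Basin labels list the
helices whose angular footprints lie within a 15° contact half-width of
the maximum on either protomer, with consecutive TM numbers compressed
(`TM5,TM6,TM7` → `TM5-7`); the half-width reproduces conventional
composite labels such as `TM1,H8`. The helix footprint map attributes
each 1° azimuth bin to the helix with the largest mean radial distance
there, so inner helices occluded by an outer helix are marked unexposed —
a geometric reading of surface exposure that needs no SASA computation.
Representative structures are chosen among the basin members whose
distance to the maximum is in the lowest decile (ties at the decile
boundary all compete), taking the one with the most negative final
interaction energy.

## Cholesterol contacts

A residue is cholesterol-bound in a frame if any of the 8 beads of any
cholesterol molecule is within 0.62 nm (inclusive, with a 10⁻⁹ nm
rounding guard) of any bead of the residue — all residue beads, not just
the backbone, since side-chain beads mediate most lipid contacts.
Occupancy is the bound-frame fraction after discarding the first 200 ns
as equilibration. Spatial densities rank molecules per frame by their
minimum bead distance to the receptor (minimum-image over the box), take
the 5 nearest, superpose the frame onto the receptor reference pose by a
least-squares fit of the TM backbone beads, and accumulate all beads —
and separately the ROH headgroup beads — of those molecules on a 0.1 nm
grid. Minimum-distance ranking (rather than centre-of-mass distance)
matches the contact semantics of the occupancy rule. Before per-frame
normalisation the all-bead grid total is frames × 5 × 8 by construction,
which the tests assert as a bookkeeping identity.

## Lateral diffusion

MSD is lateral (xy), averaged over the beads of the protein and over all
time origins, with lags capped at 25 % of the analysis window (longer
lags average too few origins). The centre-of-mass motion of the
protein–membrane system is removed per frame before displacements are
accumulated. D = slope/4 by least squares on the 5–20 ns lag window of
the first 200 ns of each trajectory; dimerization runs contribute only if
no protein–protein interaction occurred before 250 ns. D is reported in
nm²/ns and 10⁻⁷ cm²/s (factor 1000).

## Structure metrics

*Rubber bands*: harmonic bonds between all backbone bead pairs within
0.9 nm, k_ij = f·exp(−a·d_ij^(2p)) with f = 500 kJ/mol/nm², a = 3, p = 6;
pairs at sequence separation 1 or 2 are excluded (already bonded in the
coarse-grained topology). The printed form of the kernel exponent is
typographically ambiguous; the grouping d^(2p) is adopted because it
yields a smooth decay from ~500 at contact to ~214 kJ/mol/nm² at the
cutoff, and the exponent expression is configurable.

*RMSD*: least-squares (Kabsch) superposition, reported in nm and Å, with
a partial-fit mode that superposes on a subset (e.g. one protomer) while
measuring the deviation over all beads.

*Buried surface area*: BSA = SASA(A) + SASA(B) − SASA(A∪B) with
Shrake–Rupley sampling implemented in-package (Fibonacci sphere points,
default 960 per bead; boundary contact counts as buried). Defaults for
coarse-grained beads are radius 0.264 nm and probe 0.191 nm; no canonical
coarse-grained SASA parameters exist, so absolute BSA values can shift by
several percent with other choices — all three are configurable. The
implementation is validated against the analytic two-sphere cap formula
and against its own high-density refinement.

*Percent identity*: identities divided by aligned columns (both
sequences carry a residue), the convention of common percent-identity
matrices; the full-alignment-length denominator and restriction to a
residue range (per-helix identities) are options. Alignments are inputs
(any Clustal-compatible tool); the package does not align.

## Synthetic generators

The generators emulate the *statistical* structure of the target
ensembles, not their physics: exponential first-passage dimerization at
0.05–0.3 µs⁻¹ over ~500 replicas of 3–8 µs; monomeric energy jitter in
[−1, 0] kJ/mol and Ornstein–Uhlenbeck-like dimer energies around
−150 kJ/mol (clipped at −60 so the generating state sequence is exactly
recoverable by the detection thresholds — the OU model makes no claim of
matching real force-field fluctuation spectra); wrapped-normal (β, χ)
interface modes; idealised 7-TM bundles with helices on an ellipse
(the anisotropy keeps the principal axes defined; helix azimuths are
exact ground truth); 8-bead cholesterol with an ROH headgroup planted in
the contact shell of hotspot residues along a deterministic outward
direction, background molecules kept a clearance away so planted
occupancies are exact; rigid 2D Brownian walks with known D. Every
generator is driven by `numpy.random.default_rng(seed)` and is
byte-reproducible; each returns machine-readable ground truth and can
materialise the same file formats the readers consume (GRO/XTC/XVG/
manifest), so tests exercise I/O paths as well as in-memory ones.

Consequently, a passing suite shows that the *analysis* recovers what
the generators planted under realistic ensemble sizes and noise; it says
nothing about force-field accuracy, sampling convergence of real MD, or
membrane physics.

## Problem sizes and numerical choices

Recovery tests and the acceptance script run at the study's ensemble
scale where that is cheap (500 replicas × 3 µs at 1 ns output for
kinetics; 400-sample orientation ensembles; 20 000-step walks) and at
reduced frame counts (≤ 200 frames) for the brute-force contact oracles,
which are quadratic by design. Wrapped angular arithmetic uses half-open
[0, 360) everywhere; torus distances are wrapped-Euclidean; circular
means use the resultant-vector definition. Watershed tie-breaking is
deterministic (stable ordering of maxima by height, plateau collapse to
the lexicographically first cell), so identical inputs give identical
basin maps.

## Known limitations

* Interaction energies are inputs; the package never recomputes them
  from coordinates (that would require a force-field rerun).
* The three-angle orientation system assumes quasi-planar membranes;
  large tilts (> 15°) are rejected, not modelled.
* No second-order (concentration-dependent) kinetics, no rotational
  diffusion, no finite-size hydrodynamic corrections, no
  cholesterol residence-time kinetics.
* The manifest's `dt_out_ns` is bookkeeping supplied by the user; the
  package does not attempt to infer output intervals from files.
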