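# Methods

This note records the models and estimators implemented in `channelmd`,
the defaults and why they were chosen, what the synthetic generators do
and do not emulate, and the numerical conventions that matter when
interpreting results.

## Coordinates, units and numbering

Everything is in Ångström and nanoseconds; axes are right-handed; no
unit conversion happens anywhere downstream of I/O. Residue numbers are
the 1-based author numbers read verbatim from the PDB file, because
channel residues are referred to by author numbering (V625, S620,
G626). Insertion codes are rejected; for alternate locations the first
altloc is kept with a warning (trajectories have no altlocs, only a
seed structure might). Hydrogens are retained if present: the pore
profiler and distance operations use exactly the atoms a selection
names, never an implicit heavy-atom filter.

## van der Waals radii

Pore radii are radius-set-relative, so the set in use is always an
explicit, overridable input. The built-in element table is C 1.70,
N 1.55, O 1.52, S 1.80, H 1.20, P 1.80 Å (Bondi-style values); unknown
elements take a declared default with a warning, or raise if no default
is given. The pipeline manifest records the table used for a run.

## Pore-radius profile

At axial position z the pore radius is the largest sphere centered in
the plane through z perpendicular to the axis that clears all vdW
spheres: R(z) = max_c min_i(|c − x_i| − r_i). The center is constrained
exactly to the plane (2-D search); center drift along the axis is not
modeled. The maximization uses 32 seeded random starts in a search disc
(default radius 15 Å) refined by Nelder–Mead, because the clearance
objective is piecewise-smooth with possibly several basins. A
brute-force in-plane grid oracle at 0.01 Å spacing is shipped alongside
and is deliberately independent of the optimizer path; the test suite
and the acceptance script require agreement within 0.05 Å. Profiles use
a 0.125 Å z grid by default, sampled every 20 ns of trajectory time
(stride derived from `frame_dt`, overridable).

The axis is fitted as the principal component of a user-selected atom
set (origin at its centroid), oriented toward positive z or toward a
supplied reference selection pair. The fit refuses selections whose top
two covariance eigenvalues are degenerate — a single planar ring has no
unique principal axis, so axis selections should span the pore axially.

Band classification: radii strictly below the K+ ionic radius (1.33 Å)
are `sub_ionic`, strictly above the hydrodynamic radius (3.6 Å) `bulk`,
and the closed interval between them `intermediate`; both boundaries
belong to the middle band since the outer bands are defined by strict
inequalities. Selectivity-filter state from the mean opposing-Cα
distance: ≥ 7.5 Å conductive, 5–7 Å inactive, the 7–7.5 Å gap is
reported as `intermediate` rather than silently forced into either
state, and < 5 Å is flagged `undefined`.

## Backbone torsions

Dihedrals are signed on (−180°, 180°] with the convention that rotating
the fourth point by +θ about the p2→p3 axis (right-hand rule) increases
the angle by +θ. Note the signed dihedral is invariant under full
point-order reversal (reversal flips both the viewing direction and the
order); it is mirror reflection that flips the sign — the tests assert
both properties. φ = C(i−1)–N–Cα–C and ψ = N–Cα–C–N(i+1) with neighbors
defined by consecutive author numbering; at chain termini the undefined
angle is simply absent, while a missing backbone atom next to an
existing neighbor is an error naming the residue.

Ramachandran summaries use 10° circular bins over (−180°, 180°]² and
circular mean/sd; the circular mean is flagged unreliable when the mean
resultant length falls below 0.1 (near-uniform angles). Carbonyl
orientation is the cosine between the C→O bond and the outward radial
direction from the pore axis; negative means `in` (toward the pore) and
an exact zero is `out` by a documented tie-break.

The S4–S5 interhelical torsion is defined as the dihedral of four
centroids — S4 distal half, S4 proximal half, S5 proximal half, S5
distal half, where proximal means adjacent to the linker — so the
middle two points span the linker axis. This four-centroid construction
was chosen because it is noise-robust and exactly testable: rotating a
distal helix half by θ about the linker axis changes the torsion by
exactly θ. Helix halves split at the midpoint with the odd middle
residue joining the linker-adjacent half; torsions are computed per
subunit. Exact helix/linker residue ranges are configuration inputs.

## Contact probabilities

The interaction probability of a pair is the portion of its distance
density below the class threshold. Computed from trajectory samples
this is exactly the empirical CDF at the threshold, which is the
default estimator; a Gaussian-KDE integral (Silverman bandwidth) exists
for density curves and converges to the empirical value with n. Values
exactly at the threshold do not count as contact (strict inequality).
Class defaults: H-bond and salt bridge 3.5 Å (donor/acceptor or
charged-moiety heavy atoms, minimum over the atom cross product; no
angle term, since the statistic is defined on distance alone),
hydrophobic 5 Å, cation-π 6 Å between charged-group nitrogen centroid
and aromatic ring-carbon centroid. The cation-π criterion is a declared
convention, configurable per contact, as no standard geometric
criterion is universal; anion-π uses the same geometry with the
carboxylate-oxygen centroid. Per-subunit probabilities are reported
separately or pooled by concatenation, making the pooled value exactly
the frame-count-weighted mean of the per-subunit fractions.

## Coupling networks

Traces sampled at different cadences are aligned either by intersecting
their time grids or by linear interpolation onto the coarsest grid;
angles are unwrapped before interpolation and entered in unwrapped
degrees, and any angular trace with circular sd above 60° is flagged as
unreliable under linearization rather than silently linearized.

Pearson r is tested with the two-sided t statistic r√((n−2)/(1−r²)).
Because MD frames are serially correlated, the default replaces n per
pair with the lag-1 effective sample size n(1−ρ₁ρ₂)/(1+ρ₁ρ₂) (floored
at 3); this keeps the empirical type-I error near the nominal 5% on
strongly autocorrelated AR(1) inputs where the uncorrected test is
badly anticonservative (measured in the acceptance script). The
uncorrected mode remains available for reproducing analyses that used
raw frame counts, and the choice is recorded in the report. The mask is
raw p < α (default 0.05) per pair; a Benjamini–Hochberg mode exists but
is off by default since per-pair masking is the convention being
reproduced.

Replicates are pooled by within-replicate standardization followed by
concatenation (default) — standardization prevents between-replicate
mean shifts from manufacturing correlation, a failure mode the tests
demonstrate explicitly — or by Fisher-z averaging of per-replicate
coefficients. Contrasting a variant against a reference flags pairs as
`lost` (significant only in the reference, |Δr| above a minimum, default
0.3), `gained` (converse), `sign_flipped` (significant in both with
opposite signs) or `preserved`.

## Mobility

Kabsch superposition via SVD with determinant correction so reflections
are never returned. RMSD is computed per frame after superposing onto
the reference over the selection (default Cα). RMSF uses the iterated
mean structure: frames are superposed onto frame 0, the mean computed,
frames re-superposed onto the mean, and the pass repeated until the
mean is a fixed point — which makes the result independent of the
seeding frame. Note that rigid-body fitting absorbs six degrees of
freedom, shrinking apparent fluctuations by a factor ≈ √(1 − 2/N) for
N fitted atoms; the analytic √3·σ check for isotropic jitter is
therefore run with all-atom fits where N is large. Region means default
to the four Kv11.1-like domains (PAS 1–131, TM 398–687, C-linker
688–741, CNBD 742–863), inclusive bounds, author numbering.

## Synthetic generators

`make_toy_channel` builds n-fold symmetric rings of spheres about z;
the exact on-axis maximal-sphere radius per ring is axial_distance −
atom_radius (for zero jitter), recorded as the oracle profile. It
emulates pore geometry only — no side chains, no membrane, no ions.

`make_correlated_traces` is a stationary first-order vector
autoregression x_t = φx_{t−1} + ε_t with φ = exp(−1/relaxation_frames)
and innovation covariance (1−φ²)C, so the stationary covariance is
exactly the target correlation C and the lag-1 autocorrelation is φ,
mimicking the serial correlation of MD distance traces. Sampling error
of the sample correlation decays like 1/√n (checked at n = 500, 5000,
50000).

`make_occupancy_trace` is deliberately two-valued so the below-threshold
fraction is exact by construction, isolating the probability statistic
from density-estimation choices. `make_helix` places an ideal
poly-alanine backbone by internal coordinates (N–Cα 1.458, Cα–C 1.525,
C–N 1.329, C=O 1.231 Å; angles 111.2°, 116.6°, 121.9°, 120.5°) so that
recomputed φ/ψ equal the inputs to floating-point precision.

What passing these tests shows: the geometry, statistics and contrast
machinery are correct against analytic and brute-force oracles. What it
does not show: anything about force fields, sampling convergence, or
real conformational ensembles — the generators have Gaussian, gap-free,
stationary statistics that real trajectories need not have.

## Validation problem sizes

The shipped validation uses sizes chosen to exercise every code path at
desk scale: 25 random ring channels of 36–80 atoms with 3 slices each
against the 0.01 Å grid oracle; correlation recovery at n = 5000
frames; type-I error over 500 independent AR(1) pairs at n = 1000,
φ ≈ 0.90; RMSF over 2000 jittered frames; and the end-to-end contrast
scenario over six observables at n = 4000 frames with couplings of
ρ = 0.7 injected or removed, contrasted at |Δr| ≥ 0.3.

## Known limitations

- The per-slice sphere is not allowed to drift off-plane, so radii in
  strongly kinked pores can differ from solvent-excluded-surface
  methods; Connolly-surface rendering is out of scope.
- H-bond detection has no angular term; probabilities are upper bounds
  relative to angle-aware criteria.
- Linearized angles in correlation matrices are only meaningful for
  angles fluctuating well within a branch; widely wandering torsions
  are flagged, not fixed.
- The effective-sample-size correction uses lag-1 autocorrelation only;
  long-memory processes will still inflate significance somewhat.
- Binary trajectory formats are out of scope at the parser level;
  convert to multi-model PDB / XYZ tables, or adapt an established
  reader to the `Trajectory` contract.
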