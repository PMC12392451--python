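# Methods

## Model

A ring of N identical unit-mass beads, bonded cyclically by stiff
harmonic springs U_bond = (K/2)(r − r0)² with K = 1035.8 and r0 = 1,
interacts through a full Lennard-Jones potential
U_LJ = 4ε[(σ/r)¹² − (σ/r)⁶] with ε = 1 and σ = 1.888 over **all pairs
except the N directly bonded ones** — pairs separated by two bonds do
interact.  No cutoff or shift is applied; all-pairs summation is cheap
at N ≤ a few hundred.  ε sets the energy unit: scaling ε by s scales
every nonbonded term exactly by s (asserted in tests), and scaling ε
and T together leaves all occupation probabilities unchanged.  Energies
are in ε, lengths in r0, temperatures in ε with k_B = 1.

Gradient and Hessian are analytic.  For a pair potential u(r) the
(i,j) Hessian block is (u″ − u′/r) r̂r̂ᵀ + (u′/r)·I, accumulated with
opposite sign on the diagonal (translational invariance, asserted as
H·t ≈ 0).

### Zero modes

Every isolated ring has exactly six rigid-body modes.  They are *not*
identified by an eigenvalue-magnitude cut: the stiff bonds put the top
of the spectrum near 4·10³ while genuine soft bending modes of open
rings fall to ~10⁻⁵ (and keep falling as N grows), so no fixed relative
threshold separates the two reliably.  Instead the exactly known
rigid-body subspace (3 translations + 3 centroid rotations) is
projected out and shifted to the top of the spectrum; the remaining
3N − 6 eigenvalues are the vibrational spectrum used everywhere
(minimum records, saddle acceptance, log-products).  A residual
magnitude cut of 10⁻⁹·max|λ| only guards against numerical noise.

## Local minimisation and basin-hopping

Minimisation is L-BFGS to RMS gradient < 10⁻⁶ (per-coordinate uniform
convention).  Two pragmatic safeguards proved necessary on this stiff
landscape: (i) if the line search stalls just above tolerance, a few
eigenvector-following Newton steps with the analytic Hessian finish
convergence quadratically; (ii) symmetric starting geometries (perfect
circles, parametric torus curves) can descend onto genuine saddles
with vanishing gradient — these are escaped by a 0.05 kick along the
negative-curvature eigenvector followed by re-descent.

Basin-hopping perturbs every Cartesian coordinate uniformly in
[−max_step, +max_step], re-minimises, and applies Metropolis acceptance
on the *minimised* energies at an acceptance temperature whose default
is 1 ε (a conventional choice; the effective landscape of minimised
energies is far smoother than the raw potential).  Move sets:

- `unrestricted` (default max_step ~1): explores the topologically
  unconstrained landscape; chains may cross during minimisation.
- `small_step` (max_step 0.69): small enough that the chain cannot
  pass through itself, conserving the knot class.
- `compress_release`: minimise model + compressive radial bias
  (harmonic, k ≈ 5) until the combined RMS gradient < 0.01, then
  finish on the bare model.  Compression deforms the ring into
  neighbouring basins without threading the chain through itself.

Minima are deduplicated by an energy window of 10⁻⁶ plus permutational
alignment distance < 10⁻³, keeping the first-found representative.

### What the scaled-down searches show

The published global minima of the N=100 landscapes (−738.99 unknot,
−738.24 trefoil, −760.59 for 7_1) require hours of sampling; the test
suite runs the same two protocols for tens of steps and checks the
protocol invariants instead (monotone running minimum, Metropolis
acceptance, topology preservation, and that no energy below the known
global minimum ever appears).  At N = 30 the trefoil landscape turns
out to be dominated by a single basin: 200 compress-release moves at
step 0.69 never leave it, while at N ≥ 40 the same move set hops
between many distinct trefoil minima with zero topology changes — the
ring needs slack before compression can restructure it.

## Radial bias and expansion

V_radial = (k/2) Σ_α |r_α − r_c|^p about the instantaneous centroid;
the gradient carries the centroid's dependence on every coordinate,
and a bead exactly at the centroid contributes a zero subgradient for
p = 1.  Expansion ramps k from 0 to −15 (p = 1 by default) in 10 equal
stages, minimising the combined potential at each stage.  Expansion is
strictly radius-of-gyration-increasing and never changes the Jones
polynomial on any fixture.  One quantitative caveat: under strict
local minimisation our compact minima remain metastable at k = −15
(the swelling is modest rather than dramatic), but classification
succeeds regardless because even moderately expanded — at N ≤ 60, even
compact — structures project below the crossing cap.

The pulling alternative V = −f·|r_a − r_b| (constant-magnitude
separating force between two chosen beads) is provided; the constant-
force form is this package's choice of functional form.

## Knot identification

A configuration is rotated by a uniform random rotation (uniform unit
quaternion), projected onto xy, and all non-adjacent segment pairs are
tested for proper 2D intersection; over/under comes from interpolated
z and the sign convention is positive when the overpass runs
left-to-right while the underpass runs bottom-to-top (equivalently,
sign of (d_over × d_under)·ẑ).  Degenerate projections — grazing or
endpoint intersections, |Δz| < 10⁻⁹, collinear overlaps, a projected
bead at the origin for winding numbers — are discarded and redrawn,
and do not count toward the rotation budget.

The Jones polynomial is computed from the fewest-crossing diagram by a
Kauffman-bracket state sum over all 2^C smoothings (loops counted by
union-find over the 2C along-curve arcs), normalised by (−A)^(−3w) and
converted to t = A⁻⁴.  Any non-degenerate diagram below the crossing
cap (20 by default; 2^20 states is the practical limit) yields the
exact polynomial, so classification needs only a moderate rotation
budget; compact structures above the cap are expanded first.  The
reference table for knots through seven crossings is *generated* from
standard minimal planar-diagram codes by this same bracket evaluator
and cross-checked in the test suite against an independent recursive
evaluation, the closed-form (2,q) torus-knot polynomial, and the
classical span/determinant invariants.  Chirality convention: the
variant of a chiral knot whose Jones polynomial lives on positive
powers of t is tagged right-handed, matching positive-crossing torus
knots.

Writhe and crossing counts are reported as mean ± sd over the random
projections; the projection-averaged writhe is checked against the
deterministic Gauss-integral writhe (pairwise solid-angle formula) —
an equality theorem for uniform direction averaging, asserted at three
standard errors.  The winding number sums signed successive angles of
the projected centroid-relative bead vectors, *including the closing
step* from bead N back to bead 1 (a closed curve must close its angle
sum).  Each statistic draws its own seeded rotation set.

## Transition networks

Saddle candidates come from a doubly nudged elastic band: interior
images feel the true gradient perpendicular to the tangent, the spring
gradient along it, plus the portion of the perpendicular spring
gradient orthogonal to the perpendicular true gradient.  The band (15
images, spring 10 by default) is relaxed by FIRE with per-image force
clipping, which survives the hard-core overlaps of naive linear
interpolation.  Interior energy maxima are refined by hybrid
eigenvector-following; at desk-scale N the analytic Hessian plus dense
eigendecomposition per iteration (uphill Newton step along the lowest
non-zero mode, Newton descent in the orthogonal complement, overall
trust radius) is both cheaper and far more robust than gradient-only
tangent minimisation, which stalls orders of magnitude above the
tolerance on this stiff landscape.  A saddle is accepted only with
exactly one negative vibrational eigenvalue, and its two minima are
found by descent from ±0.01 displacements along that eigenvector.
Degenerate rearrangements (both descents reach the same minimum) are
kept as self-loops but excluded from rate matrices.

Networks lump permutational copies (energy window + alignment over all
2N ring relabelings; inversions excluded to preserve chirality).  The
missing-connection selector runs Dijkstra on the complete graph with
weight 0 on connected pairs and squared alignment distance on
unconnected ones; pairs that already failed a search are up-weighted
×100 so alternative routes are proposed.  Connection targets are the
*input* minima — incidental minima discovered by endpoint assignment
are kept but not chased, which keeps the effort bounded.  Minima of
different knot classes effectively cannot be connected: the
chain-crossing saddle is out of reach at desk effort, so demo networks
cover one topology at a time.  For hard same-class pairs,
expansion-guided connection expands both minima saving frames,
reverses one trajectory, and returns evenly spaced anchors for
successive double-ended searches.

## Thermodynamics and kinetics

Occupation probabilities use classical harmonic weights
w_γ e^(−V_γ/T) e^(−L_γ/2) with L_γ = Σ ln λ over the κ = 3N − 6
positive eigenvalues; the common (2πT)^(κ/2) and all mass/Planck
factors cancel.  The degeneracy weight defaults to 2N (trivial point
group; point-group detection is out of scope) and cancels when equal.
Gradients g_γ = ∂p_γ/∂T = p_γ(V_γ − ⟨V⟩)/T² are analytic.

Heat capacity is computed in the moment form
C_V/k_B = κ + (⟨V²⟩ − ⟨V⟩²)/T² and cross-asserted to 10⁻⁸ against the
per-minimum decomposition κ + Σ_γ V_γ g_γ(T), which also provides the
red/blue sign partition and the smallest subset reproducing a target
fraction of the configurational C_V.

TST rates are k_{δ←γ} = (1/2π) e^{(L_γ − L_ts)/2} e^{−(E_ts−V_γ)/T}
with multi-edges summed; detailed balance with the harmonic
occupations holds by construction and is asserted to 10⁻¹⁰.  Mean
first passage times use graph transformation with the elimination
denominator evaluated as the *explicit sum* of outgoing branching
probabilities — the textbook 1 − P_xx form cancels catastrophically
for deep traps — and the final MFPT read off as τ_s/P(s→target).
Underflow of the rate constants themselves (barriers beyond ~700 T)
still limits the accessible temperature range, as expected.  FPT
distributions eigendecompose the absorbing-target generator; if the
slowest mode's amplitude is numerically lost the normalisation
condition plus the graph-transformation MFPT pin its amplitude and
rate.  The default log-time grid spans [min(1/ν)/10³, max(1/ν)·10³]
with 400 points.

## Disconnectivity graphs

A union-find sweep over descending energy levels (default
ΔE = (E_max − V_global)/100) builds superbasin trees restricted to the
n_lowest minima connected to the global minimum; each node records its
*split energy*, the lowest level at which its members still
interconvert, which converges to the exact minimax (max-min path) merge
energy as ΔE → 0 (asserted against brute-force path enumeration).
Leaves can be coloured by scalars (linear red→blue) or sign labels;
layout allocates horizontal slots proportional to subtree leaf counts
with the lowest-energy child centred, and the SVG output is
byte-deterministic.

## Fixtures

Torus-knot rings sample the (p,q) curve on a torus with tube ratio
0.4, resampled to equal arc length and scaled to unit mean bond
length; the base curve is right-handed (positive writhe) and
`handedness="left"` mirrors it.  These fixtures stand in for the
unspecified starting structures of the original landscape study.  They
are ideal smooth curves: passing tests on them demonstrates the
machinery's correctness, not sampling convergence on rugged real
landscapes.

## Problem sizes

The test suite and acceptance script run the full workflow at N = 8–100
with short searches (hundreds of basin-hopping steps, thousands of
random projections), sizes chosen so the complete analysis runs on one
CPU in minutes while still exercising every stage at the production
code paths.
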