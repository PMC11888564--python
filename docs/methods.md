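# Methods

## Model class and assumptions

The package analyzes admissible ODEs on regular networks: `n` cells, each
with state `x_v ∈ ℝ^s` (s = 1 or 2 for the classification theory; the
block-Jacobian oracle accepts any s), identical smooth kinetics
`ẋ_v = f(x_v, w_v, λ)` where `w_v` is the *average* state of the ν input
neighbours and λ is a slowly varied bifurcation parameter.  The underlying
biological assumptions: cells are well-mixed compartments, start nearly
identical, receive identical external signals, sit in a uniform lattice, and
average their neighbours' signals.  Networks must be strongly connected,
self-arrow-free and regular (equal input counts); these conditions make the
Perron structure available (largest adjacency eigenvalue = valence, simple,
with the all-ones eigenvector) and force a traceless adjacency with at least
one eigenvalue of negative real part.

Adjacency convention: `A[i, j]` counts arrows `j → i` (row = target), so row
sums equal the valence.  Many graph libraries use the transpose; every
spectrum in this package is of this orientation.  Arrow multiplicities are
nonnegative integers; graded coupling strengths are expressed as repeated
arrows.  Indices are 0-based in memory and 1-based in all files and reports.

## Linearization convention

Because cells average their inputs, the per-arrow coupled block is
`R = (1/ν) ∂f/∂w`.  With this normalization the *raw arrow-count* adjacency
spectrum is used unmodified in the blocks `Q + μ_j R`; the convention is
pinned by a test comparing `I ⊗ Q + A ⊗ R` eigenvalues against the block
union on random networks.

## Classifiers

Both 2-D classifiers require an all-real adjacency spectrum and refuse
otherwise; complex spectra leave the case analysis undefined.  Sign
tolerance: a quantity is treated as zero when `|q| ≤ 1e-9 · scale(Q, R)`
(scale² for determinant-type quantities); values within 10× of the tolerance
add a degeneracy warning.  A "bifurcation is occurring" is the caller's
assertion — the classifiers describe the criticality type, they do not locate
it (locating is done by the simulator's λ sweep or by the constructed-
bifurcation generators).

Case selection with `det R = 0`: the block trace and determinant are both
linear in μ, so each can vanish at the smallest eigenvalue, the largest, or
everywhere.  If the trace nondegeneracy `tr Q < −|ν tr R|` holds, onset is a
real (steady-state) eigenvalue and the sign of `B = tr(Q)tr(R) − tr(QR)`
picks the block (`B > 0` → μ₁, `B < 0` → μ_k, `B = 0` → all blocks).  If the
determinant nondegeneracy `det Q > |ν B|` holds, onset is a Hopf pair and
the sign of `tr R` picks the block.  If both hold no block can be critical
(the classifier reports "no row" with a warning); if neither holds the
matching degenerate row (coincident trace and determinant roots) is returned
with `degenerate=True` — the nondegeneracy inequalities are sufficient, not
exhaustive, so no sharper claim is made.  Sign-pattern inputs are propagated
through sympy symbols with positivity assumptions; the trace nondegeneracy is
provable from signs exactly when `tr R = 0` structurally and `tr Q < 0`,
which is the lateral-inhibition situation.

Defective eigenvalues: pattern-space bases include generalized eigenvectors
but are flagged, and table dimensions are reported with geometric
multiplicities; when β₁ < α₁ the existence theory for the bifurcating branch
may fail, and downstream consumers see the `defective` flag.

## The designer

`design_local_dynamics` builds planar dynamics whose unique critical block is
any chosen μ_target = m:

```
Q = [[-t, u], [v, -t]],  R = [[0, 1], [-1, 0]],
u = 1 + 2|m|,  v = u + 2m,  t = sqrt(m² + u v)
```

Then `det(Q + μR) = (μ − m)²` and `tr(Q + μR) = −2t < 0` identically, so the
single critical eigenvalue is real and comes from the target block, with
`det R = 1 > 0` as interior targets require.  This closed form was preferred
over a scaled diagonal-Q family because it satisfies every inequality exactly
with no iteration.

## Delta–Notch kinetics and defaults

The reference model (state `(D, N)` per cell):

```
dD/dt = λ · g(N) − γ_D · D        g(N) = 1 / (1 + (N/K_D)^h_D)
dN/dt = F(w_D)  − γ_N · N         F(w) = w^h_N / (K_N + w^h_N)
```

Defaults `h_D = h_N = 2`, `K_D = K_N = 0.1`, `γ_D = γ_N = 1` (concentration
scale of order one, decay time = 1 time unit).  At any synchronous
equilibrium with positive coupling the linearization has the lateral-
inhibition sign structure `Q = ((−,−),(0,−))`, `R = ((0,0),(+,0))`, hence
`det R = 0`, `tr R = 0`, `B > 0`: the predicted pattern space is `P_μ1`
regardless of the parameter values.  Any smooth kinetics with the same signs
is accepted; the defaults are one representative of the qualitative class.

## Simulation protocol

Integration: `scipy.integrate.solve_ivp` (RK45, rtol 1e-9, atol 1e-12),
states recorded on a fixed grid; a single seeded uniform perturbation of
amplitude `1e-3 ×` the equilibrium scale is applied at t = 0 (cells start
nearly, not exactly, identical).  With a fixed seed trajectories are
bit-for-bit reproducible.

The canonical onset experiment (`quasistatic_pattern_run`) first locates the
threshold λ\* by root-finding on the binding linearized stability margin,
then prepares the tissue at the synchronous equilibrium at `0.9 λ*`, ramps
to `1.3 λ*` over 150 time units (≥ 100× the slowest linear relaxation time,
so the ramp is quasistatic) and holds for 550 time units.  Stopping modestly
above threshold is essential: the onset theory describes the *first*
bifurcating branch, which is the unique stable pattern only in a parameter
region near λ\*; ramping far beyond it destabilizes further blocks and
probes secondary branches outside the scope of the analysis (empirically, an
8×8 torus ramped to many times threshold settles into a mixture of
near-critical modes rather than the pure checkerboard).

Behavior detection examines the last 20% of the final-λ plateau: oscillation
when the peak-to-peak amplitude exceeds `1e-4` of the state scale, synchrony
when the cross-cell standard deviation is below `1e-3` of scale.  For
patterned outcomes the time-averaged deviation from the cross-cell mean is
projected (component-wise, variance-weighted) onto every pattern space.

Flow-invariance checks run on the stable side of the bifurcation (or, for
the patterned subspace, at a plateau where the pattern is attracting).  The
subspace invariance is exact in the model; on the unstable side float
round-off (~1e-16) is amplified exponentially, so a long unstable run would
measure the instability of the synchronous state, not the invariance
property.

## Synthetic study conditions

All networks are generated, not measured: the 6-cell reflective row (the
vulval-precursor architecture), tori with the nearest = 3 / diagonal = 1
stencil (valence 16; its smallest eigenvalue is simple with the checkerboard
eigenvector — verified by direct eigencomputation and by the closed-form
torus symbol `6(cos a + cos b) + 4 cos a cos b`, minimized at a = b = π),
and random regular digraphs built as weighted sums of derangement
permutation matrices (automatically regular and self-arrow-free; symmetrized
when a real spectrum is needed).  Randomized classifier validation uses
constructed bifurcations that are exact by closed form: rank-1 trace-free
couplings for steady onsets, rank-1 `B = 0` couplings for Hopf onsets, and
bisection on the binding margin for the `det R ≤ 0` sweeps.  The 8×8 torus
is the default lattice size for speed; the 16×16 run is exercised in the
test suite with identical outcome.

What the synthetic conditions do not emulate: heterogeneous cells, spatial
morphogen gradients, stochastic kinetics, cell division or rearrangement,
and boundary effects beyond the reflective row (tori are periodic).  Passing
tests therefore demonstrate the internal consistency of the theory and its
realization by one representative kinetic class, not quantitative agreement
with any measured tissue.

## Tolerances and degenerate inputs

Eigenvalue grouping: computed eigenvalues within `1e-8 · max(1, ρ(A))` are
one distinct eigenvalue (integer matrices at fixture sizes have well-
separated spectra); geometric multiplicity is the SVD rank deficiency at the
same tolerance.  Pattern membership: an observed pattern "lies in" a space
when ≥ 0.95 of its deviation variance projects there (a "weak" qualifier is
attached between 0.95 and 0.99) — simulated patterns carry integration
noise.  Single-node networks are vacuously strongly connected but rejected
by the classifiers (no synchrony to break).  The `det R ≤ 0` conclusion for
interior patterns is generic: the all-blocks-critical case is possible but
extremely degenerate, and the inference report says so rather than assigning
a probability.

## Known limitations

Normal-form coefficients, branch direction (super/subcritical) and secondary
bifurcations are out of scope — the classification is linear criticality
only.  Node dimensions above 2 are rejected by the classifiers.  Complex
adjacency spectra (strongly non-normal networks) are refused by the 2-D
classifiers and by observed-pattern inference.  Long-range coupling stencils
are fully supported by the lattice builder, but no specific long-range
fixture beyond the nearest/diagonal torus is shipped.
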