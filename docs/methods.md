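# Methods

## Model and assumptions

The engine simulates isotopically instationary, metabolically stationary
¹³C labeling: fluxes v and pool sizes C are constant in time, the tracer
is switched on as a step at t = 0, and every intracellular (balanced)
metabolite obeys Σ S·v = 0. Substrates are held at a fixed positional
isotopomer distribution; growth-related dilution is not modeled. Natural
¹³C abundance correction of measurements is out of scope — states are
fractions of molecules carrying w heavy atoms introduced by the tracer.

Reversible exchange must be written as two irreversible reactions.
Symmetric molecules are expressed as multiple atom-transition alternatives
per reaction, each weighted 1/n of the flux; this is the minimal general
mechanism and is how succinate-like symmetry should be encoded.

The balanced set is inferred structurally: a metabolite is balanced iff it
is produced and consumed by the network and is not a labeled substrate.
Substrates and terminal sinks (`*_OUT`) are unbalanced.

## Mass isotopomer reorganization

EMU decomposition follows the standard backward trace; the departure is
that each mass isotopomer is its own node rather than one EMU-MID vector
per node. This permits (a) pruning at mass-isotopomer resolution — only
ancestors of the measured mass isotopomers are kept, computed by reverse
BFS on the transposed graph, which retains exactly the same set as an
all-pairs (Floyd–Warshall) transitive closure at far lower cost (the
all-pairs variant is kept in the test suite as a reference); and (b) SCC
decomposition in which every component is weight-homogeneous, because a
heavier mass isotopomer can never feed a lighter one.

Substrate mass isotopomers are not graph nodes: their values are constants
and enter the ODEs as source terms. This convention is what makes the toy
network count 14 mass isotopomers / 14 SCCs (B, C, E at weights 0–2 and F
at weights 0–4).

Topological sorting is weight-major with a deterministic within-weight
Kahn order (ties broken by smallest member key), so identical inputs give
identical orderings. λ-aggregation greedily merges consecutive same-weight
SCCs head-to-tail until each unit holds ≥ λ nodes; the trailing unit of a
weight class may stay smaller. Merging only consecutive units of one
weight class provably preserves the topological validity of the order, and
the SCC count is non-increasing in λ.

## ODE assembly

For each retained mass isotopomer x of an EMU of metabolite P:

    C_P dx/dt = Σ_prod v·(weight-composition production) − (Σ_cons v)·x

Production enumerates the weight compositions of each producing EMU
reaction; with several dynamic reactants this is the MID convolution,
restricted to the index set actually retained (pruned reactant nodes can
only affect pruned product weights, so missing entries are exactly zero).
The consumption coefficient counts every reactant instance of P in every
consuming reaction.

Two backends are assembled from one structural term list:

* **vector** (default): a global sparse CSR matrix for all single-molecule
  transitions plus per-reaction convolution terms (gather EMU vectors →
  `numpy.convolve` → scatter). Self-convolution (one EMU in both slots)
  needs no special case — the gather simply reads the same rows twice.
* **tensor**: every term expanded into explicit 0/1 transition-tensor
  entries, evaluated entry by entry.

Both divide by the pool size row-wise (the diagonal C is inverted once at
assembly). They are mathematically identical and are cross-checked to
1e-12 at random states; the vector form is the faster and is the default.

The per-block internal matrix M_i (single-molecule transitions within the
block plus all consumption, C⁻¹-scaled) is exposed for spectral
diagnostics: for flux-balanced models whose every node drains to an
outflow, its eigenvalues have strictly negative real parts.

## Sensitivities

Fluxes are parameterized as v = v₀ + N·u with N an orthonormal SVD null
space basis of S over the balanced set (deterministic for fixed input);
pool parameters are the pool sizes of metabolites present in the pruned
network. Forward (tangent) sensitivities are used — parameter counts are
at most a few hundred, and the cascade structure is preserved: block i of
each sensitivity depends only on block i and its ancestors. The flux
forcing ∂f/∂u_j is obtained for free by re-binding the flux-linear
structural terms to the basis column N[:, j]; the pool forcing is
−f(x)/C_m on the rows of metabolite m. All sensitivity blocks start at
zero. Because production sums telescope, per-EMU weight sums of every
sensitivity block are exactly conserved at zero (to roundoff), which the
conservation report verifies along trajectories.

## Integration

Constant-step mode is the classical RK4 tableau (weights (1,2,2,1)/6,
stages at t, t+h/2, t+h/2, t+h). Every stage is evaluated on the full
cascade with same-stage parent values, so the blockwise integrator equals
RK4 on the monolithic system exactly.

Adaptive mode is the embedded Cash–Karp 4(5) pair; the error estimate is
|4th − 5th| per component and the accepted state is the 5th-order one.
The per-component tolerance is `tol_scaling·|y| + tol_addition`
(defaults 1e-9 and 1e-7) — the two packaged factors are mapped onto the
standard relative + absolute form. Step acceptance is decided on the
*pilot* set only: the weight-0 mass isotopomers of the smallest
topological prefix of SCCs covering at least one EMU of every pruned
metabolite (lightest-node fallback if a metabolite has no weight-0 node).
The rationale is that mass isotopomers of one EMU sum to one and their
curves share steepness, so the pilot's step suits all blocks. Acceptance
is settled on the pilot before the step is considered delivered, so no
downstream rollback can occur. Growth uses the standard safety·ratio^(−1/5)
rule capped at 5×; rejection shrinks by safety·ratio^(−1/4), floored at
0.2×, with an underflow abort below h_min.

### Parallel contract

Parallelism is specified as a scheduling contract, not a threading
primitive: per-(block, stage) tasks become ready only once the block's and
its parents' previous-stage values are delivered; a deadlock watchdog
aborts naming the blocked block if no task is ready. The shipped scheduler
is a deterministic list-scheduling simulation over `worker_count` virtual
workers. Because every task writes its own slice with the same elementwise
arithmetic as the serial sweep and the reduction order is fixed, any
schedule — hence any worker count — reproduces the serial trajectory bit
for bit, and the pilot-chosen step sequence is worker-count independent.
Wall-clock speed-up is hardware-dependent and is deliberately not a
property of this package.

## Numerical choices

* Dense output at arbitrary times uses cubic Hermite interpolation with
  derivatives re-evaluated from the system (4th-order accurate).
* Stationary MIDs are solved algebraically size-by-size (one linear solve
  per EMU size; multi-reactant terms only involve smaller sizes); a
  singular block raises naming the EMUs involved.
* The brute-force reference integrates all positional isotopomers
  (2ⁿ per metabolite) with DOP853 at rtol 1e-11 / atol 1e-13, guarded to
  ≤ 10⁴ isotopomers, and marginalizes to MIDs. It shares nothing with the
  EMU/SCC code path and anchors the oracle-equivalence tests at 1e-8.
* Stiffness is reported per block as max|Re λ|/min|Re λ| of M_i via a
  dense eigensolver (blocks are small after decomposition); a zero minimal
  real part is flagged "undefined" rather than silently inf. Imaginary
  parts are reported, not assumed zero.

## Default study conditions

Packaged defaults: end time 10 s, constant step 0.005 s, λ = 10,
tolerance factors 1e-9 / 1e-7, substrate uptake 10 (flux units:
mmol gDW⁻¹ h⁻¹ before scaling). The toy network ships with a balanced
flux set (v = 100, 50, 30, 10, 10, 20, 30, 10 for V_1…V_8) and pool sizes
(B 100, C 80, D 60, E 40, F 50, concentration units consistent with the
fluxes), chosen so turnover times C/v span roughly 1–10 s — labeling
dynamics that neither saturate instantly nor stall within the 10 s window.
The toy's substrate is fully ¹³C-labeled by default.

## Synthetic generator

`random_network` grows a connected atom-mapped network from one labeled
substrate: each new metabolite is formed from already-producible ones
(bimolecular with configurable probability, with splitting when carbon
counts overflow), unconsumed terminals get sinks, atom maps are random
permutations (so carbon conservation holds by construction), fluxes are
drawn by hit-and-run sampling in the positive null-space polytope (scaled
to the substrate uptake), and pool sizes are log-uniform over a
configurable range defaulting to the physiological micromolar–millimolar
span. Draws that admit no strictly positive balanced flux are rejected up
to a retry limit. What the generator does *not* emulate: realistic pathway
topology (cycles and cofactor coupling), reversible exchange fluxes, or
measurement noise — so passing generated-fixture tests demonstrates
algorithmic correctness on this model class, not biological realism. Tests
that integrate generated networks with the constant-step method use pool
ranges giving tame turnover times; the physiological default combined with
uptake-scale fluxes yields rates far above 1/h, which is exactly the stiff
regime the adaptive method exists for.

## Problem sizes used in the shipped checks

All shipped tests and the acceptance script run at desk scale: the
8-reaction toy network (14 mass isotopomers, 3 free fluxes, 4 free pools)
and generated fixtures of ~6–10 metabolites. Genome-scale and
organism-specific reconstructions are treated as optional external inputs
through `load_supplementary_model` (same TSV dialect); checks that depend
on them run opportunistically when such files are supplied under
`data/external/`.

## Known limitations

* Explicit integrators only; severely stiff systems (fast pools at
  physiological concentrations under high flux) need small steps — there
  is no BDF fallback by design.
* One compartment; no metabolite compartmentalization or FTBL/SBML
  atom-map import.
* The inverse problem (fitting fluxes to measured labeling data) is out of
  scope; this package is the forward engine such a fitter would call.
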