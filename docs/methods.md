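# Methods

## Discrete operators of a complex

Simplices are stored as strictly increasing tuples of vertex ids, sorted
lexicographically within each dimension; this canonical order fixes every
matrix column, so rebuilding a complex from a shuffled edge list yields
byte-identical operators. Orientation is induced by the vertex order: the
entry of the boundary matrix `B_m` for the face obtained by deleting the
vertex at position `p` of an `m`-simplex is `(-1)^p`, the sign of the
permutation that re-sorts the face together with the deleted vertex. This
reproduces the gradient convention `(B_1)_{i,[i,j]} = -1`,
`(B_1)_{j,[i,j]} = +1` and guarantees `B_m B_{m+1} = 0`.

The Hodge Laplacians are `L_m = B_mᵀ B_m + B_{m+1} B_{m+1}ᵀ` with `B_0` and
`B_{M+1}` empty, so `L_0 = B_1 B_1ᵀ = K - A` is the ordinary graph Laplacian
of the 1-skeleton. Betti numbers are computed from numerical ranks of the
boundary matrices (`β_m = n_m - rank B_m - rank B_{m+1}`), with an SVD
cutoff of 1e-8 times the largest singular value; exact integer homology is
out of scope. The kernel multiplicity of `L_m` is used as an independent
cross-check in the tests.

Clique complexes fill every `(m+1)`-clique up to `max_dim ≤ 3`: tetrahedra
are representable combinatorially, but only dimensions 0–2 are discretized
as continuous domains.

## Block-Laplacian dynamics and their diagnostics

`ẋ = -γ L x` is solved by dense eigendecomposition (the systems of interest
are small — a few hundred simplices; a sparse ODE path is unnecessary at
this scale, and correctness of the spectral route is checked against a dense
matrix-exponential oracle). γ defaults to 1 and is exposed as a scalar.
Eigenvalues are clipped at zero before exponentiation so that -1e-16
round-off does not grow at large times.

Diagnostics report the global minimum and its location, total mass per time,
per-dimension steady states (kernel projections of the initial block), and a
global-consensus flag (all steady values equal within 1e-6). Negativity of
positive initial data is a real feature of this model, but it requires a
positive off-diagonal somewhere in some `L_m`: a lower-adjacent simplex pair
whose orientation signs agree and which does not sit inside a common
higher simplex (inside one, the up- and down-contributions cancel exactly).
On the five-vertex two-triangle fixture every such pair is capped by a
filled triangle, so all blocks are Metzler and the trajectory from
nonnegative data provably stays nonnegative there; the negativity
diagnostics are therefore exercised on random clique complexes, where
uncapped positive couplings are generic. Early-time scans use a geometric
grid from 1e-3 to 10 (the transient time scale of unit-strength Laplacians).

The deflation patch `L - λ₁ v₁ v₁ᵀ` (moving the slowest non-trivial mode
into the kernel to force a non-trivial steady state) is provided as a
standalone operator transform.

## Reference domains

- dim 0: one node, zero stiffness, mass 1.
- dim 1: `n` equispaced nodes on the unit segment; P1 stiffness is the
  classic `1/h` tridiagonal with zero row sums; lumped mass `h` (ends `h/2`)
  sums to 1 exactly.
- dim 2: structured triangulation of the unit equilateral triangle with `n`
  nodes per side — `n(n+1)/2` nodes, `(n-1)²` congruent equilateral
  elements. P1 element stiffness is assembled from the gradient formula;
  because all angles are 60°, off-diagonals are non-positive (Metzler
  structure, hence positivity of the coupled flow). The lumped mass
  (area/3 per element vertex) is rescaled from the raw area √3/4 to total
  1, so every simplex carries unit measure and the diffusive steady state
  is a single shared density; stiffness is left unscaled, which only
  rescales the internal diffusion speed of triangles relative to segments.

`n = 20` is the reference resolution (210 mesh nodes); `n` is a single
shared parameter for segments and triangle sides, so matched boundaries
always have equal node counts. A 1-D refinement test checks consistency of
the discrete Laplacian at order h².

## Coupling and assembly

One bidirectional sink–source per (face, coface) incidence: triangle sides
pair node-by-node with the full segment of the shared edge — both ordered
from the lower- to the higher-labelled vertex, so shared corners coincide —
and segment endpoints pair with their vertex nodes. Corner nodes of a
triangle belong to two sides and hence to two couplings; the alternative
(excluding corners from one side) would merely reduce two conductances by
one unit and is not exposed.

Each matched pair has conductance κ (default 1): pairs act as unit-weight
graph edges, making the inter-domain hops literally graph-Laplacian moves on
the mesh. This makes the domain-level exchange rate grow with resolution;
`kappa_mode="normalized"` (κ split across a coupling's pairs) gives a
resolution-independent total instead. No empirical value for κ is asserted
anywhere; it is a model parameter with units mass·time⁻¹ per unit density
difference.

The assembled flow matrix `S = blockdiag(stiffness) + C`, with `C` the
graph Laplacian of the matched pairs, is symmetric with zero column sums and
non-positive off-diagonals. Consequences used throughout: constants span its
kernel on a connected complex, `Σ D u` is exactly invariant, and
`(D + dt S)` is an M-matrix.

The domain-level transition matrix (off-diagonal: total conductance
exchanged; diagonal: minus total outflow) is a lossy summary: the two-segment
fixture realizes the same `[[-1, 1], [1, -1]]` with the exchange at one
coincident point or split across opposite endpoints (two half-conductance
pairs), and the transients differ while the steady state does not. The
"separated" geometry is one concrete choice of placing sink and source apart;
any explicit pair list can be supplied to build other geometries.

## Time integration

Implicit Euler `(D + dt S) u_{k+1} = D u_k` with a single sparse LU
factorization; conservation holds to round-off (zero column sums) and
nonnegativity exactly (M-matrix inverse is nonnegative). Crank–Nicolson is
available when second-order accuracy matters more than a positivity
guarantee; a Richardson test confirms the expected orders (1 and 2). Default
dt = 0.01 and 10⁴ steps; convergence-sensitive assertions instead terminate
on a relative per-step change below `steady_tol` (1e-12 in the tests) rather
than a fixed horizon, since the relaxation rate depends on the complex.
Mass and the running minimum are tracked at every step even when stored
states are thinned with `store_every`.

Initial conditions spread per-simplex masses uniformly inside each domain
(with unit measures, density = mass). Built-ins: a delta on one simplex;
degree-weighted vertex masses (each vertex starts with its 1-skeleton
degree, so the density pushed into each incident edge is initially equal);
a `degree_normalized` variant with unit vertex masses; seeded per-simplex
uniform random masses; and explicit tables (CSV with `dim:v0-v1-…` labels).

## Diagnostics on metaplex runs

Per-simplex totals `Σ_a D_a u_a` aggregate the trajectory to one number per
simplex; at consensus all totals equal total mass / number of simplices.
Return probability from a delta seed is the seed's total renormalized by its
initial mass; it converges to a strictly positive limit (1/#simplices for
unit mass), in contrast to the vanishing analogue on kernel-free
block-Laplacian blocks.

Hole detection flags triangles whose total at a snapshot stays below
θ × consensus (default θ = 0.1, undefined "almost empty" made concrete), and
reports each triangle's mean interior / mean boundary density ratio. The
default snapshot is the earliest stored time whose per-step relative change
drops below 1e-4 — a pre-consensus state, since at consensus nothing is
distinguishable. Disconnected complexes relax per component; consensus-based
quantities assume a connected complex (the kernel-dimension check in the
steady-state oracle guards this).

The model comparison runs both dynamics from the same per-simplex mass table
on one shared time grid and reports minimum value, mass drift, sup-distance
of the final state from the global consensus, and a convergence time (first
time the trajectory stays within 1e-6 of its own final state). The metaplex
converges more slowly — it resolves continuous transport inside every
simplex on top of the inter-simplex hops.

## Synthetic data

Fixtures are generated, never bundled. The two-triangle complex (vertices
1–5, triangles (1,2,3) and (3,4,5) hinged at vertex 3) is the minimal
face-closed worked example. Seeded Erdős–Rényi clique complexes provide
richer topology; `synthetic_connectome` uses 30 vertices with edge
probability 190/435, matching the density of the macaque visual-cortex
network (30 areas, 190 connections) that motivates the connectome pipeline —
it reproduces that network's scale and density but not its anatomical wiring,
so tests on it validate pipeline mechanics and qualitative behaviour
(conservation, positivity, interiors lagging boundaries pre-consensus), not
area-specific observations. Users with the real connectome can feed it in as
a plain edge list (`smx build-complex --edges …`).

## Problem sizes

Default test and example runs use the two-triangle complex at 5–20 nodes per
edge (135–545 DOFs, 10⁴ implicit-Euler steps) and the 30-node synthetic
connectome at 5 nodes per edge (~6000 DOFs, several hundred steps) — sizes
chosen so the whole suite runs in seconds while exercising every code path;
the assembly and solver are sparse throughout and scale to finer meshes.

## Known limitations

- Tetrahedral (and higher) domains are not meshed; complexes may contain
  them, but metaplex construction refuses.
- Couplings only join dimension-adjacent simplices; arbitrary-gap
  transitions and weighted/directed complexes are out of scope.
- Betti numbers are floating-point rank computations; pathological spectra
  near the 1e-8 cutoff could miscount.
- The block-Laplacian solver is dense (eigendecomposition); it is meant for
  complexes up to a few thousand simplices.
- Reaction–diffusion, synchronization and persistent homology are not
  implemented.
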