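# smx — diffusion on simplicial complexes via metaplexes

Many networked systems — cortical areas exchanging neurotransmitters through
the extracellular fluid, landscape patches leaking organisms across the space
between them, residues generating fields inside a protein — are better
described by *geometric* simplicial complexes than by graphs: edges and
triangles are pieces of continuous space, not abstract relations. `smx` is a
toolkit for studying diffusion on such complexes, aimed at researchers in
higher-order network science and computational neuroscience.

It implements and contrasts two models.

**Block Hodge-Laplacian diffusion.** From the signed incidence matrices
`B_m` of a complex (entries are permutation signs of the vertex orderings,
with `(B_1)_{i,[i,j]} = -1`, `(B_1)_{j,[i,j]} = +1`) one builds the
higher-order Laplacians

```
L_m = B_mᵀ B_m + B_{m+1} B_{m+1}ᵀ,      L = blockdiag(L_0, …, L_M),
```

and runs `ẋ = -L x`. The kernel dimension of `L_m` is the Betti number
`β_m`, so blocks without topology decay to zero; the process is not
conservative, can drive positive initial data negative, and each dimension
reaches its own steady state instead of a global consensus. `smx` computes
all of these operators and diagnostics.

**Simplicial-metaplex diffusion.** Each simplex becomes a continuous domain
(point, unit segment, unit equilateral triangle meshed with P1 finite
elements and lumped mass normalized to measure 1), and dimension-adjacent
simplices exchange density through matched boundary nodes (sinks/sources):
each triangle side pairs node-by-node with its edge's segment, each segment
endpoint with its vertex. The semi-discrete system

```
D u̇ = -S u,      S = blockdiag(stiffness) + coupling Laplacian,
```

is symmetric with zero column sums and Metzler `-S`, so implicit-Euler
integration conserves total mass to round-off and preserves positivity, and
the whole complex relaxes to the average of the initial condition — ordinary
diffusion behaviour, now with a traceable density *inside* every simplex.
Triangles that stay almost empty flag candidate topological holes.

## Worked example

```python
import smx

K = smx.two_triangle_complex()          # 5 vertices, 6 edges, 2 triangles
print(smx.simplex_counts(K))            # {0: 5, 1: 6, 2: 2}
print(smx.betti_numbers(K))             # [1, 0, 0]

M = smx.build_metaplex(K, nodes_per_edge=20)
print(M.n_dofs)                         # 545  (5 + 6*20 + 2*210)

ic = {"0:0": 1.0, "1:0-1": 1.0, "2:0-1-2": 1.0}   # unit mass on a vertex,
u0 = smx.initial_condition(M, ("table", ic))       # an edge and a triangle
print(smx.consensus_value(u0, M))       # 0.2307692307692308  (= 3/13)

traj = smx.integrate(M, u0, smx.DiffusionConfig(dt=0.01, n_steps=10_000))
print(traj.mass_drift, traj.global_min) # 2.25e-12  0.0
```

Three mass units spread over thirteen unit-measure simplices, so every
per-simplex total converges to 3/13 ≈ 0.2308 (the run above ends within
4.2e-10 of it), with zero mass drift and no negative densities. The same
initial condition under the block Hodge Laplacian loses two of its three
mass units (3 → 1) and never reaches a global consensus —
`smx.hodge_diagnostics` reports both.

The same workflow is scriptable from the shell:

```
smx fixture two-triangle --out complex.json
smx build-metaplex --complex complex.json --nodes-per-edge 20 --out system.h5
smx diffuse --system system.h5 --ic degree --steps 10000 --out run.h5
smx detect-holes --run run.h5 --system system.h5 --theta 0.1
smx compare --complex complex.json
```

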