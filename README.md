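# rimpore

Tools for studying **rim pores in hemifusion diaphragms (HDs)** — the
transient openings at the edge of the single-bilayer patch that forms when
two apposing membranes (for example a synaptic vesicle and the presynaptic
membrane) merge their contacting leaflets.  Whether such a pore grows into
a full fusion pore or shrinks away controls content release, so its
stability is a central question in membrane biophysics.

The package has two coupled layers:

1. **A phenomenological line-tension model of the rim pore.**  The pore
   boundary is a composite of three circular arcs through two shared
   vertices: the remaining HD rim (three-bilayer junction, tension λh),
   the membrane edge inside the HD (λe) and the fusion-pore-like outer
   segment (λp).  The free energy is

       F = λh·L_h + λe·L_e + λp·L_p

   minimized/stationarized at fixed total membrane area.  Critical rim
   pores are index-1 saddle points of F over (Rh, Re, Rp) with the pore
   half-width `a` slaved to the area constraint; at a saddle the Laplace
   force balances hold: `Re = λe/Σ`, `Rh = λh/Σ`, `Rp = λp/2Σ`, with Σ the
   membrane tension (the constraint's Lagrange multiplier).  The module
   classifies line-tension space (unzipping, edge-unbalanced, detachment,
   recessed/protruding critical pores) and builds phase diagrams, at zero
   and finite membrane separation 2d.

2. **A self-consistent field theory (SCFT) engine for lipid bilayers.**
   Lipids are Gaussian AB diblocks (tail fraction f, head-tail and
   water-tail repulsion χN) plus a short solvent (relative length 0.1),
   solved in 1D planar, 1D cylindrical and 2D Cartesian geometries with
   pseudo-spectral / Crank–Nicolson propagators.  From it the package
   computes the membrane thickness D, the bending modulus κ, the monolayer
   spontaneous curvature c0 and — from 2D cross-sections of the edge,
   junction and pore-wall configurations — the three line tensions that
   parametrize the phenomenological model.

## Worked example

```python
from rimpore import LineTensions, SystemSpec, find_saddle, laplace_check

lt = LineTensions(lambda_e=0.9, lambda_p=0.5)   # ratios to lambda_h = 1
res = find_saddle(lt, SystemSpec())             # Ah0 = pi, d = 0
print(f"area fraction Ap/Ah0 = {res.pore_area_fraction:.4f}")
print(f"Sigma = {res.Sigma:.4f}, eigenvalues = {res.hessian_eigenvalues}")
Sigma, residuals = laplace_check(res)
print(f"Laplace residuals = {residuals}")
```

prints

```
area fraction Ap/Ah0 = 0.0254
Sigma = 1.0230, eigenvalues = [-49.07487761   0.01463638  10.48484228]
Laplace residuals = [0. 0. 0.]
```

i.e. the critical pore at these tensions occupies 2.5 % of the reference
HD area; the one negative Hessian eigenvalue is the unstable breathing of
the HD radius (pinning Rh stabilizes the pore), and the Laplace relations
hold to machine precision.

The SCFT side follows the same pattern (heavier to run):

```python
from rimpore.scft import ChainModel
from rimpore.membrane import tensionless_bilayer, bending_modulus

chain = ChainModel()                  # f = 0.8, chiN = 30
flat = tensionless_bilayer(chain)     # ~10 s
print(f"D = {flat.D:.3f} R0")         # -> D = 1.102 R0
print(f"kappa = {bending_modulus(chain, flat):.3f}")   # ~3 min -> 0.190
```

A command-line interface mirrors the library
(`rimpore saddle --lambda-e 0.9 --lambda-p 0.5`, `rimpore phase-diagram`,
`rimpore bilayer`, `rimpore kappa`, `rimpore line-tensions`,
`rimpore full-pipeline`, `rimpore fixtures`); outputs are deterministic
CSV/JSON (plus HDF5 field snapshots) stamped with a config hash.

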