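# knotscape

Energy-landscape analysis for coarse-grained **knotted ring polymers**.

A closed homopolymer of N beads is modelled with stiff harmonic bonds
between cyclic neighbours,

    U_bond(r) = (K/2) (r - r0)^2,        K = 1035.8, r0 = 1,

and Lennard-Jones interactions between every non-bonded pair,

    U_LJ(r) = 4 eps [ (sigma/r)^12 - (sigma/r)^6 ],   eps = 1, sigma = 1.888.

Because the model potential lets chains pass through each other only
over very high barriers, each knot type (unknot 0_1, trefoil 3_1, the
7_1 torus knot, ...) effectively owns its own potential-energy
landscape.  `knotscape` provides the full workflow for exploring and
analysing those landscapes:

- **Basin-hopping global optimisation** with unrestricted moves,
  topology-safe small steps (max perturbation 0.69), and
  *compress-release* moves: a compressive radial potential
  V = (k/2) Σ_α |r_α − r_c|^p applied at the start of each
  minimisation and released once the combined RMS gradient falls below
  ~0.01, which hops between basins without changing the knot type.
- **Radial expansion** (k = −15, p = 1 ramped in stages) to swell
  compact structures so their crossings can be counted.
- **Knot classification**: random projections → crossing diagrams →
  Kauffman-bracket state sum → Jones polynomial V(t), matched against a
  reference table of knots through seven crossings (with chirality).
- **Order parameters**: projection-averaged crossing number, writhe
  (with an independent Gauss-integral oracle), and winding number
  WN = |Σ_i χ_i| / 2π with χ_i = atan2([v'_i × v'_{i+1}]·ẑ, v'_i · v'_{i+1}).
- **Kinetic transition networks**: doubly nudged elastic band searches,
  hybrid eigenvector-following saddle refinement, permutational
  lumping over the 2N ring symmetries, missing-connection selection and
  Dijkstra fastest paths.
- **Observables**: harmonic-superposition occupation probabilities and
  heat capacity C_V/k_B = κ + (⟨V²⟩−⟨V⟩²)/T² with its per-minimum
  decomposition κ + Σ_γ V_γ ∂p_γ/∂T, harmonic TST rates,
  graph-transformation mean first passage times, and first-passage-time
  distributions P(ln θ) from the master-equation eigenspectrum.
- **Disconnectivity graphs** with branch colouring by any per-minimum
  scalar (C_V sign sets, MFPT, winding number, writhe), written as SVG.

## Worked example

```python
import numpy as np
from knotscape import sampling, knot_analysis as ka
from knotscape.io_cli import make_torus_knot
from knotscape.polymer_model import PotentialParams, RingConfiguration

params = PotentialParams()                      # eps=1, sigma=1.888, K=1035.8
ring = make_torus_knot(2, 3, 100)               # N=100 trefoil fixture
rec = sampling.minimize(ring, params)
print(f"relaxed energy: {rec.energy:.3f}")

kc = ka.classify_knot(RingConfiguration(rec.coords), params,
                      np.random.default_rng(1), n_rotations=400)
print(kc.full_label, ka.format_jones(kc.jones))

print(f"gauss writhe: {ka.gauss_writhe(ring):+.3f}")
```

prints

```
relaxed energy: -621.152
3_1+ +1t^1 +1t^3 -1t^4
gauss writhe: +3.332
```

The relaxed N=100 trefoil fixture sits at −621.2 ε (reaching the
global minimum of this landscape, −738.24 ε, needs hours of
basin-hopping); its Jones polynomial t + t³ − t⁴ identifies the
right-handed trefoil, and the writhe ≈ +3.3 reflects its three
positive crossings plus geometric coiling.

The same stages are scriptable from the shell:

```bash
knotscape generate --p 2 --q 3 --n-beads 100 --out ring.xyz
knotscape bh --start ring.xyz --moves compress_release --steps 1000 --seed 1
knotscape classify --in ring.xyz --rotations 10000 --seed 7
knotscape expand --in min.xyz --k -15 --p 1 --stages 10 --out expanded.xyz
knotscape pipeline --config run.toml
```

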