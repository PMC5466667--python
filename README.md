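# protocell

Semi-empirical protocell simulator: two minimal proto-metabolic reaction
networks (PM1, a "heterotrophic" two-cycle scheme; PM2, an "autotrophic"
three-cycle scheme) coupled to a dynamic, osmotically regulated lipid
vesicle whose solute permeability depends on the membrane lipid
composition, plus the dye-leakage assay pipeline that parameterizes the
composition-to-permeability curve.

## What is modelled

- **Reaction networks** (`protocell.networks`): declarative mass-action
  networks with catalysts that enter the rate law only.  PM1's catalysts
  (AB, ACD) mutually promote each other's condensation from energy-rich
  nutrients; PM2 interposes an extra reinforcing cycle through AC.  An
  optional extension adds endogenous lipid synthesis (P → L, catalysed by
  AB) and a displacement constant `k_d` that tunes how efficiently the
  synthesized lipid replaces the primitive one in the bilayer.
- **Compartment physics** (`protocell.physics`): bilayer surface area from
  the lipid head-area census, internal volume as an exact isotonic
  projection after every update, the reduced surface Φ = S/(36πV²)^(1/3)
  as the shape/stability parameter (divide at Φ ≥ 2^(1/3), burst at
  Φ ≤ 1 − ε), and exact-matching polynomial permeability curves.
- **Deterministic engine** (`protocell.deterministic`): stiff ODE
  integration with division executed as deterministic halving on a
  Φ-crossing event; fixed-compartment steady states (long relaxation +
  root polishing) and two-parameter bistability scans (catalyst decay ×
  nutrient permeability).  PM1 is monostable on the default grid, PM2
  bistable.
- **Stochastic engine** (`protocell.stochastic`): exact direct-method SSA
  over reaction, transport and membrane-exchange channels, volume/surface
  recomputed after every firing, binomial partition at division with one
  daughter followed.  A numba-jitted kernel (~4M events/s) with a pure
  Python fallback.
- **Assay pipeline** (`protocell.assay`): release-trace fitting
  (exponential sink kinetics, or early-linear), conversion to permeability
  P = k·r/3 and trans-membrane diffusion D = P·λ, molar-to-surface
  fraction mapping via head areas, and the exact interpolating polynomial
  through the per-composition points — the semi-empirical bridge back into
  the simulator.
- **Synthetic data** (`protocell.synthetic`): seeded generators for noisy
  release traces and composition series, plus packaged default parameter
  sets for every scenario.

## CLI

```bash
protocell steady-map --model pm2 --out out/map        # Φ-free steady-state scan
protocell reproduce --model pm2 --engine ode --out out/rep
protocell selection --model both --out out/sel        # k_d sweep, division times
protocell assay --out out/assay                       # leakage pipeline → curve
protocell gen-fixtures --out data                     # regenerate fixtures
```

All experiments emit tidy CSVs (plus JSON summaries) and are reproducible
from `(config, seed)`.  `protocell assay` emits a permeability-curve block
that loads directly into the simulator's physics config.

## Units

Time in hours internally (CLI reports days where natural), concentrations
in mol/m³ (≡ mM), permeabilities in m/s in configs (converted once at
compile time), lengths in nm in configs, SI internally.
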