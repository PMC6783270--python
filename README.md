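# oligopath

Quantitative modelling of oligomer-mediated amyloid assembly, built around
the self-association and seeded fibril-elongation behaviour of ΔN6 — the
N-terminally truncated variant of human β2-microglobulin that forms amyloid
in dialysis-related amyloidosis.  At mildly acidic pH, ΔN6 monomers
assemble through head-to-head dimers into hexamers, and it is the hexamer —
not the monomer — that adds to fibril ends.  `oligopath` implements the
machinery needed to reach that conclusion from kinetic and NMR data, and a
synthetic-data module so every stage can be exercised without any
experimental download.

## What it computes

**Self-association equilibria.**  The pre-polymerization scheme

```
X1 + X1 ⇌ X2              Kd,dim = [X1]²/[X2]          (μM)
X2 + X2 + X2 ⇌ X6         Kd,hex = [X2]³/[X6]          (M²)
```

is solved by a bracketed scalar root search on the monomer conservation
equation, yielding species concentrations and population fractions
p_n = n[X_n]/[M_tot].  An optional tetramer branch covers the high-pH
regime where hexamers do not form.  The closed-form overall assembly rate
kon_over = k1app·k2app/(k₋₁ + k2app), with k1app = 2k1[M_eq] and
k2app = 3k2[D_eq]², is provided alongside.

**Seeded elongation kinetics.**  Five mass-action models couple a
pre-polymerization module to an explicit fibril ladder F0..FN
(Fi-1 + X ⇌ Fi), differing in the elongation unit X: monomer addition,
monomer conformational exchange, dimer addition, hexamer addition, and a
monomer-dimer-tetramer-hexamer scheme.  ThT fluorescence is modelled as
K_tht · Σᵢ (i·u)[Fi] plus a baseline.  Global fits share all rate constants
across concentrations (bounded least squares in log space, seeded
multi-start, K_tht and baselines profiled out exactly), enabling model
selection by residual comparison.

**NMR observables.**  Combined shifts Δδ = √((5δH)² + δN²), shift-titration
fits with a (Kd,dim, Kd,hex) grid search and Monte-Carlo errors,
single-exponential decay fitting (relaxation and PFG diffusion),
TRACT correlation times from TROSY/anti-TROSY rate differences,
PRE rates Γ2 = R2,para − R2,dia with significance bins, CPMG
R2,eff = −ln(I_x/I_0)/τ_CPMG, and the population-weighted apparent
correlation time τc,app = p_mon·τc,mon + p_dim·τc,dim + p_hex·τc,hex.

## Worked example

```python
from oligopath import (solve_equilibrium, population_fractions, tauc_mixture)
from oligopath.equilibrium import DEFAULT_PARAMS, KINETIC_FIT_PARAMS

for total in (120, 180, 480):
    f = population_fractions(solve_equilibrium(total, DEFAULT_PARAMS))
    print(f"{total:3d} uM: {100*f.p_mon:.0f}% monomer, "
          f"{100*f.p_dim:.0f}% dimer, {100*f.p_hex:.0f}% hexamer")
print(f"tau_c at 600 uM: "
      f"{tauc_mixture(population_fractions(solve_equilibrium(600, KINETIC_FIT_PARAMS))):.1f} ns")
```

prints

```
120 uM: 33% monomer, 52% dimer, 15% hexamer
180 uM: 26% monomer, 48% dimer, 26% hexamer
480 uM: 13% monomer, 32% dimer, 55% hexamer
tau_c at 600 uM: 48.8 ns
```

With a dimer Kd of 50 μM and a hexamer Kd of 10×10⁻⁹ M², roughly a third of
the protein is monomeric at 120 μM but over half sits in hexamers by
480 μM; weighting the species correlation times (9.8/18.5/60.3 ns) by these
populations predicts the sharp rise of the apparent tumbling time with
concentration.

The same machinery runs from the shell:

```bash
oligopath equilibrium --total 120 --total 480 --out speciation.csv
oligopath make-fixtures --out-dir fixtures/          # synthetic corpus
oligopath fit-tht --input fixtures/tht_hexamer_addition.csv \
    --variant hexamer_addition --params-out fit.csv
oligopath reproduce                                  # benchmark table
```

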