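# Methods

## The model

ΔN6, the truncation variant of human β2-microglobulin, self-associates at
pH 6.2 into a rapidly exchanging mixture of monomers (X1), head-to-head
dimers (X2) and hexamers (X6) before any fibril material forms.  The
package models this as two coupled mass-action equilibria,

    X1 + X1 ⇌ X2          Kd,dim = [X1]²/[X2]     (μM)
    3 X2 ⇌ X6             Kd,hex = [X2]³/[X6]     (μM²; M² at the API)

plus an optional dimer-of-dimers tetramer (X4, Kd,tet = [X2]²/[X4]) for the
pH 8.2 regime, where tetramers but no hexamers are observed.  Tetramer
support is off by default because no dissociation constant has been
measured for it.

Given a total monomer concentration M_tot, the free monomer M solves

    f(M) = M + 2M²/Kd,dim + 4[X4](M) + 6(M²/Kd,dim)³/Kd,hex − M_tot = 0.

f is strictly increasing on [0, M_tot] with f(0) < 0 ≤ f(M_tot), so Brent's
method on that bracket finds the unique root; oligomer concentrations
follow from detailed balance.  An alternative route — integrating the
kinetic equations to their long-time limit — is retained as an independent
test oracle; the two agree to a relative 1e-6 across a log-spaced
concentration grid.  Populations are reported per monomer unit,
p_n = n[X_n]/M_tot.

The closed-form overall assembly rate treats the dimer as a steady-state
intermediate between the equilibrated monomer pool and the hexamer:

    kon_over = k1app k2app / (k₋₁ + k2app),
    k1app = 2 k1 [M_eq],  k2app = 3 k2 [D_eq]².

The test suite checks this against the slow relaxation eigenvalue of the
full three-state kinetics.  The identification is only exact where the
dimer quasi-steady-state holds and the hexamer dominates the equilibrium;
the reference test point (Kd,dim 50 μM, Kd,hex 100 μM², M_eq 62.5 μM) was
chosen inside that regime, where the closed form and the eigenvalue agree
to better than 1%.

### Default dissociation constants

* `kd_dimer = 50 μM` — shift titrations and concentration-dependent RDCs
  bound homodimerization at ≤50 μM; the bound is used as the working value.
* `kd_hexamer = 10e-9 M²` — the centre of the grid-search distribution from
  the shift titration.
* `KINETIC_FIT_PARAMS` carries `kd_hexamer = 1.9e-9 M²`, the value returned
  by globally fitting the seeded ThT kinetics; correlation-time predictions
  use it (both are exposed, since which Kd generated a given published
  prediction is not always stated).

The hexamer Kd appears in the literature once with units M² and once with
M; M² is adopted as the only dimensionally consistent reading of
[X2]³/[X6].  Concentrations are μM internally; the hexamer Kd is converted
by 1e12 at the API boundary.

## Seeded elongation kinetics

Each kinetic model couples a pre-polymerization scheme to an explicit
fibril ladder.  F0 is the preformed seed (number concentration
seed_monomer_equiv / L0, with L0 = 200 monomers per seed particle ≈ a
500 nm fibril); Fi has gained i elongation units X of u monomers each:

    Fi−1 + X  →(ke)  Fi,    Fi  →(ke′)  Fi−1 + X,   1 ≤ i ≤ N,

with N = 200 by default and FN absorbing (no forward outflow).  Runs warn
when more than 1% of fibril number reaches FN — except where completing the
ladder is the intended end state, as in the high-concentration corpus.
The five variants and their elongation units:

| variant            | pre-polymerization                          | X   | u |
|--------------------|---------------------------------------------|-----|---|
| monomer_addition   | none                                        | X1  | 1 |
| monomer_exchange   | X1 ⇌ X1′                                    | X1′ | 1 |
| dimer_addition     | 2 X1 ⇌ X2                                   | X2  | 2 |
| hexamer_addition   | 2 X1 ⇌ X2, 3 X2 ⇌ X6                        | X6  | 6 |
| mdth               | 2 X1 ⇌ X2, 2 X2 ⇌ X4, X2 + X4 ⇌ X6          | X6  | 6 |

Monomer mass (soluble + fibril-borne) and fibril number are conserved by
construction and asserted to a relative 1e-6 on every integration.  The
source equations carry a few typographical slips (a duplicated rate symbol
in the hexamer scheme, a factor-of-two in the dimer scheme's elongation
coupling); the implementation uses the mass-consistent forms, which is also
what conservation testing requires.

ThT fluorescence is modelled as signal(t) = K_tht Σᵢ (i·u)[Fi] + baseline:
rung i is weighted by the monomer mass added (i·u), so K_tht has the same
meaning (a.u. per μM of elongated monomer) in every variant.  A literal
unit-count weighting (i) is available behind `weighting="unit"`.  The seed
baseline is a fitted constant per curve, since measured seeded traces start
above zero.

### Integration and fitting

The ladders are stiff when ke·X ≫ ke′; `solve_ivp` with LSODA at
rtol 1e-8 / atol 1e-12 μM integrates them (fits use 1e-7/1e-10).  Global
fits share all rate constants across concentrations.  The free subset
(by default the elongation rate plus the reverse constant that carries the
fitted Kd; forward exchange rates are held fixed because the data constrain
equilibrium ratios, not absolute exchange rates) is optimized in log10
space by bounded trust-region least squares with seeded multi-start
(default 10 starts; the scaled-down test fits use 1-3).  K_tht and the
per-curve baselines enter the model linearly and are profiled out exactly
at every iteration (variable projection), which removes two axes of
nonlinear search.

Residuals are normalized per curve by its dynamic range.  Plate-reader
amplitudes span more than an order of magnitude across the concentration
panel; unweighted residuals let the large-amplitude curves dominate and
make near-flat low-concentration curves — exactly the ones that carry the
threshold signature — statistically invisible.  Model comparison is run on
replicate-averaged curves, the form in which multi-replicate seeded assays
are reported and fitted; averaging five replicates suppresses the noise
floor fivefold in variance, so structural misfit stands out.

### Identifiability

Seeded growth data cannot pin every constant.  The depolymerization rate
of the monomer-addition generator (1e-3 /h, critical concentration
0.01 μM) sits far below the concentration panel and is invisible;
recovery tests therefore assert on the identifiable constants: the
elongation rate always, plus the free reverse constant (equivalently the
fitted Kd ratio) for the oligomer variants, and the shared K_tht.

## NMR observables

* Combined shift: Δδ = √((5δH)² + δN²).  The 5× weight on ¹H follows the
  stated convention; note it differs from the more common 1/5 on ¹⁵N.
* Titration: the observable saturates with the fraction of monomer units in
  hexamers, Δδ(c) = Bmax·6[X6]/M_tot.  Because monomer-dimer exchange
  dominates the shifts at low concentration, an alternative reading
  (fraction in any oligomer) is available via `mode="oligomer"`.
* Grid search: for each (Kd,dim, Kd,hex) node the saturation curve is
  computed once and the per-residue Bmax follows in closed form
  (Bmax = Σ s·y / Σ s², clipped at zero); the full residual surface is
  returned.  The saturation table is cached so Monte-Carlo refits cost
  only linear algebra.
* Monte-Carlo errors: residual resampling with replacement, refit on the
  same grids, 100 iterations by default, seeded and bit-reproducible.  The
  resampling scheme is this package's choice; the published analysis states
  only "Monte Carlo with 100 steps".
* Exponential decays: I = A·exp(−r·x) by nonlinear least squares with a
  log-linear start; x is the relaxation delay, or g² for PFG diffusion
  (S/S0 = exp(−d·g²)).  Non-decaying data are flagged, not rejected.
* TRACT: ΔR = Rβ − Rα = 2ηxy with
  ηxy = (d·c/8)·P2(cosθ)·[4J(0) + 3J(ωN)],
  d = μ0ħγHγN/(4πr³), c = ωN·|Δσ|, J(ω) = (2/5)τc/(1+(ωτc)²).
  The ¹⁵N CSA (−160 ppm), N–H bond length (1.02 Å) and CSA/bond angle
  (17°) are keyword parameters, not constants.  τc is recovered by
  inverting this monotone forward model with Brent's method on
  [1e-4, 1e4] ns.
* PRE: Γ2 = R2,para − R2,dia, binned gray (<20 s⁻¹, including negative
  noise-level values), yellow (>20 s⁻¹), red (>50 s⁻¹).
* CPMG: R2,eff = −ln(I_x/I_0)/τ_CPMG, the standard definition (the printed
  form of this expression is typographically garbled in the source).
* Mixture correlation time: τc,app = Σ p_s·τc,s over monomer/dimer/hexamer
  with hydrodynamic values 9.8/18.5/60.3 ns.  Tetramer-containing mixtures
  are rejected rather than silently extrapolated.

## Synthetic data

The generators define the study conditions: five ThT concentrations
(50/125/240/410/500 μM), five replicates, 20 μM monomer-equivalent seeds,
50 h time courses; titrations over 10-410 μM for ten reporter residues with
Bmax amplitudes on the 0.1-0.35 ppm scale of real amide perturbations;
TRACT delays 0.002-0.064 s, PRE delays 0.0016-0.016 s, a 12-point gradient
ramp.  Noise is homoscedastic Gaussian per observable with σ = 5% of each
curve's dynamic range (2% for the titration recovery checks, matching the
precision of peak-position measurements).  All randomness flows through
one seeded generator; a fixed seed reproduces a dataset bit for bit, and
every generator returns its ground truth alongside the data.

The hexamer-addition generating constants (k1 100 μM⁻¹h⁻¹ / k1′ 5000 h⁻¹,
k2 1 μM⁻²h⁻¹ / k2′ 1900 h⁻¹, ke 0.2 μM⁻¹h⁻¹ / ke′ 1e-3 h⁻¹) encode the
working Kds (dimer 50 μM, hexamer 1.9e-9 M²), oligomer exchange much
faster than elongation, and an elongation rate that makes seeded growth
negligible at 50 μM but fast above ~200 μM — the concentration threshold
that motivates the hexamer mechanism.  The monomer-addition set uses an
elongation rate fast enough that high-concentration curves saturate inside
the initial-rate window, producing the hyperbolic (linear-then-saturating)
rate curve characteristic of that mechanism.

What the generators do not emulate: systematic plate effects (drift,
evaporation, well-to-well gradients), signal-dependent noise, exchange
broadening of NMR peaks, baseline artefacts in decays, or de novo
nucleation (no unseeded lag phase).  Passing tests therefore demonstrate
correctness of the inference machinery under the stated statistical
assumptions, not robustness to the full pathology of real plate-reader or
spectrometer data.

## Problem sizes used in the checks

The standard model-discrimination benchmark uses the full N = 200 ladder
on replicate-averaged curves with 2-3 optimizer starts; parameter-recovery
checks use N = 60 ladders (capacity 36 μM of elongated mass, ample for the
growth window) and single starts from 3×-perturbed truth, which keeps each
fit to a few seconds without changing the estimates.  The matrix-exponential
ladder oracle runs at N = 5 with the soluble pool clamped, where the chain
is exactly linear.

## Known limitations

* The elongation ladder has no nucleation, fragmentation or
  length-dependent rates; it describes seeded growth only.
* The critical-concentration behaviour of a reversible monomer-addition
  ladder can approximate a concentration threshold at matched plateaus;
  discrimination from hexamer addition rests on the quantitative curve
  shapes, which is why fits are replicate-averaged and range-normalized.
* The TRACT inversion assumes a rigid isotropic rotor (S² = 1, no fast
  internal motion, no exchange contribution).
* Grid-search Kd uncertainties are bounded below by the grid spacing;
  Monte-Carlo spreads on a coarse grid are node-quantized.
* kon_over is a steady-state approximation; outside the dimer-QSS regime
  it is not the relaxation rate of the full scheme.
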