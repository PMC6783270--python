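"""Pre-polymerization self-association equilibria of an amyloidogenic protein.

ΔN6, the N-terminally truncated variant of human β2-microglobulin, populates
a rapidly exchanging mixture of monomers (X1), dimers (X2) and hexamers (X6)
at pH 6.2 before any fibril material is formed.  The scheme is

    X1 + X1  ⇌  X2            Kd_dim = [X1]^2 / [X2]      (μM)
    X2 + X2 + X2  ⇌  X6       Kd_hex = [X2]^3 / [X6]      (μM^2)

with an optional tetramer branch (X2 + X2 ⇌ X4, observed for ΔN6 at pH 8.2
where hexamers do not form).  Given a total monomer concentration the module
solves for the equilibrium speciation, converts it to per-monomer population
fractions p_n = n[X_n]/[M_tot], and evaluates the closed-form overall
assembly rate

    kon_over = k1app * k2app / (k-1 + k2app),
    k1app = 2 k1 [M_eq],   k2app = 3 k2 [D_eq]^2,

the steady-state rate at which monomers are funnelled into hexamers.

All internal concentrations are in μM.  The hexamer dissociation constant is
accepted in M^2 at the API boundary (the units in which it is usually
quoted) and converted by 1e12 to μM^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "M2_TO_UM2",
    "DEFAULT_KD_DIMER_UM",
    "DEFAULT_KD_HEXAMER_M2",
    "KINETIC_FIT_KD_HEXAMER_M2",
    "EquilibriumParams",
    "SpeciesState",
    "PopulationFractions",
    "AssemblyRateParams",
    "EquilibriumSolverError",
    "UndefinedFractionError",
    "DegenerateRateError",
    "solve_equilibrium",
    "population_fractions",
    "overall_assembly_rate",
    "equilibrium_table",
]

M2_TO_UM2 = 1.0e12  # (1 M)^2 = 1e12 (μM)^2

#: Dimer dissociation constant, μM.  Chemical-shift titrations place an upper
#: bound of ~50 μM on homodimer formation; the bound itself is used as the
#: working value.
DEFAULT_KD_DIMER_UM = 50.0

#: Hexamer dissociation constant from the shift-titration grid search, M^2.
DEFAULT_KD_HEXAMER_M2 = 10.0e-9

#: Hexamer dissociation constant recovered by globally fitting seeded
#: fibril-growth kinetics to the hexamer-addition model, M^2.
KINETIC_FIT_KD_HEXAMER_M2 = 1.9e-9


class EquilibriumSolverError(RuntimeError):
    """The scalar root search for the free-monomer concentration failed."""


class UndefinedFractionError(ValueError):
    """Population fractions are undefined (zero total monomer)."""


class DegenerateRateError(ValueError):
    """The overall assembly rate is 0/0 (all rate constants zero)."""


@dataclass(frozen=True)
class EquilibriumParams:
    """Dissociation constants of the pre-polymerization equilibria.

    Parameters
    ----------
    kd_dimer:
        Monomer-dimer dissociation constant [X1]^2/[X2], μM.
    kd_hexamer:
        Dimer-hexamer dissociation constant [X2]^3/[X6], in M^2
        (converted internally to μM^2).
    kd_tetramer:
        Optional dimer-tetramer dissociation constant [X2]^2/[X4], μM.
        Must be given exactly when ``"tetramer"`` is enabled.
    enabled_species:
        Which oligomers participate; subset of {"dimer", "tetramer",
        "hexamer"}.  Tetramer and hexamer both require the dimer.
    """

    kd_dimer: float
    kd_hexamer: float
    kd_tetramer: float | None = None
    enabled_species: frozenset = field(
        default=frozenset({"dimer", "hexamer"})
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "enabled_species", frozenset(self.enabled_species))
        unknown = self.enabled_species - {"dimer", "tetramer", "hexamer"}
        if unknown:
            raise ValueError(f"unknown species: {sorted(unknown)}")
        if ("tetramer" in self.enabled_species or "hexamer" in self.enabled_species) \
                and "dimer" not in self.enabled_species:
            raise ValueError("tetramer/hexamer formation requires the dimer")
        if self.kd_dimer <= 0:
            raise ValueError("kd_dimer must be positive")
        if "hexamer" in self.enabled_species and self.kd_hexamer <= 0:
            raise ValueError("kd_hexamer must be positive")
        has_tet = "tetramer" in self.enabled_species
        if has_tet != (self.kd_tetramer is not None):
            raise ValueError("kd_tetramer must be given iff the tetramer is enabled")
        if has_tet and self.kd_tetramer <= 0:
            raise ValueError("kd_tetramer must be positive")

    @property
    def kd_hexamer_uM2(self) -> float:
        """Hexamer Kd converted to μM^2."""
        return self.kd_hexamer * M2_TO_UM2


#: Working parameter set from the shift titration (Kd_dim 50 μM, Kd_hex 10e-9 M^2).
DEFAULT_PARAMS = EquilibriumParams(DEFAULT_KD_DIMER_UM, DEFAULT_KD_HEXAMER_M2)

#: Parameter set with the hexamer Kd from the kinetic global fit (1.9e-9 M^2).
KINETIC_FIT_PARAMS = EquilibriumParams(DEFAULT_KD_DIMER_UM, KINETIC_FIT_KD_HEXAMER_M2)


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium concentrations (μM) of each soluble species."""

    conc_X1: float
    conc_X2: float
    conc_X6: float
    total_monomer: float
    conc_X4: float = 0.0

    @property
    def monomer_mass(self) -> float:
        """Monomer units held in all soluble species, μM."""
        return (self.conc_X1 + 2.0 * self.conc_X2
                + 4.0 * self.conc_X4 + 6.0 * self.conc_X6)


@dataclass(frozen=True)
class PopulationFractions:
    """Fraction of monomer units residing in each species (p_n = n[X_n]/[M_tot])."""

    p_mon: float
    p_dim: float
    p_hex: float
    p_tet: float = 0.0

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_mon, self.p_dim, self.p_hex)


@dataclass(frozen=True)
class AssemblyRateParams:
    """Rate constants for the three-state monomer-dimer-hexamer kinetics.

    k1 (μM^-1 s^-1) / k1_rev (s^-1) govern dimerization, k2 (μM^-2 s^-1) /
    k2_rev (s^-1) the termolecular dimer-to-hexamer step.
    """

    k1: float
    k1_rev: float
    k2: float
    k2_rev: float

    def __post_init__(self) -> None:
        for name in ("k1", "k1_rev", "k2", "k2_rev"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _oligomer_concs(monomer: float, params: EquilibriumParams) -> tuple[float, float, float]:
    """Detailed-balance concentrations (X2, X4, X6) at a given free monomer, μM."""
    x2 = x4 = x6 = 0.0
    if "dimer" in params.enabled_species:
        x2 = monomer * monomer / params.kd_dimer
    if "tetramer" in params.enabled_species:
        x4 = x2 * x2 / params.kd_tetramer
    if "hexamer" in params.enabled_species:
        x6 = x2 ** 3 / params.kd_hexamer_uM2
    return x2, x4, x6


def solve_equilibrium(total_monomer: float, params: EquilibriumParams) -> SpeciesState:
    """Solve the self-association equilibria by a bracketed scalar root search.

    The free-monomer conservation function

        f(M) = M + 2 M^2/Kd_dim + 4 [X4](M) + 6 (M^2/Kd_dim)^3/Kd_hex - M_tot

    is strictly increasing on [0, M_tot] with f(0) < 0 <= f(M_tot), so the
    bracketed root is unique; oligomer concentrations follow from detailed
    balance.  Deterministic; raises :class:`EquilibriumSolverError` if the
    bracket fails.
    """
    if not np.isfinite(total_monomer) or total_monomer < 0:
        raise ValueError("total_monomer must be finite and non-negative")
    if total_monomer == 0.0:
        return SpeciesState(0.0, 0.0, 0.0, 0.0, 0.0)

    def residual(m: float) -> float:
        x2, x4, x6 = _oligomer_concs(m, params)
        return m + 2.0 * x2 + 4.0 * x4 + 6.0 * x6 - total_monomer

    try:
        monomer = brentq(residual, 0.0, total_monomer,
                         xtol=1e-14 * max(total_monomer, 1.0), rtol=1e-14,
                         maxiter=200)
    except (ValueError, RuntimeError) as exc:  # pragma: no cover - defensive
        raise EquilibriumSolverError(
            f"root search failed for total={total_monomer} μM: {exc}"
        ) from exc
    x2, x4, x6 = _oligomer_concs(monomer, params)
    state = SpeciesState(conc_X1=monomer, conc_X2=x2, conc_X6=x6,
                         total_monomer=total_monomer, conc_X4=x4)
    if abs(state.monomer_mass - total_monomer) > 1e-8 * total_monomer:
        raise EquilibriumSolverError(
            f"mass conservation violated at total={total_monomer} μM"
        )
    return state


def population_fractions(state: SpeciesState) -> PopulationFractions:
    """Convert equilibrium concentrations to monomer-unit population fractions."""
    if state.total_monomer <= 0.0:
        raise UndefinedFractionError("population fractions undefined for zero total monomer")
    t = state.total_monomer
    return PopulationFractions(
        p_mon=state.conc_X1 / t,
        p_dim=2.0 * state.conc_X2 / t,
        p_tet=4.0 * state.conc_X4 / t,
        p_hex=6.0 * state.conc_X6 / t,
    )


def overall_assembly_rate(state: SpeciesState, rates: AssemblyRateParams) -> float:
    """Closed-form overall rate kon_over (s^-1) of monomer flux into hexamers.

    Treating the dimer as a steady-state intermediate between the equilibrium
    monomer pool [M_eq] and the hexamer gives

        kon_over = k1app k2app / (k-1 + k2app)

    with k1app = 2 k1 [M_eq] and k2app = 3 k2 [D_eq]^2.  When the
    dimer-to-hexamer step is fast (k2app >> k-1) this reduces to the
    dimerization-limited rate k1app.
    """
    k1app = 2.0 * rates.k1 * state.conc_X1
    k2app = 3.0 * rates.k2 * state.conc_X2 ** 2
    denom = rates.k1_rev + k2app
    if denom == 0.0:
        raise DegenerateRateError("k1_rev + k2app is zero; rate undefined")
    return k1app * k2app / denom


def equilibrium_table(totals, params: EquilibriumParams) -> pd.DataFrame:
    """Speciation and populations over a panel of total concentrations.

    Returns a DataFrame with columns total_uM, X1_uM, X2_uM, X6_uM, p_mon,
    p_dim, p_hex (plus X4_uM / p_tet when the tetramer is enabled).
    """
    rows = []
    tetramer = "tetramer" in params.enabled_species
    for total in np.atleast_1d(np.asarray(totals, dtype=float)):
        state = solve_equilibrium(float(total), params)
        if total > 0:
            frac = population_fractions(state)
        else:
            frac = PopulationFractions(0.0, 0.0, 0.0, 0.0)
        row = {
            "total_uM": float(total),
            "X1_uM": state.conc_X1,
            "X2_uM": state.conc_X2,
            "X6_uM": state.conc_X6,
            "p_mon": frac.p_mon,
            "p_dim": frac.p_dim,
            "p_hex": frac.p_hex,
        }
        if tetramer:
            row["X4_uM"] = state.conc_X4
            row["p_tet"] = frac.p_tet
        rows.append(row)
    return pd.DataFrame(rows)
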