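"""Seeded fibril-elongation kinetics: five mass-action models and their fits.

Seeded ThT assays follow the growth of preformed fibril seeds incubated with
soluble protein.  Each kinetic model couples a *pre-polymerization* module
(the soluble self-association scheme) to a *polymerization* module: an
explicit fibril ladder F0..FN in which Fi is the number concentration of
fibrils that have gained i elongation units X beyond the seed,

    Fi-1 + X  -ke->  Fi ,      Fi  -ke'->  Fi-1 + X        (1 <= i <= N)

with FN absorbing (no further growth).  The identity of the elongation unit
X distinguishes the models:

    variant             pre-polymerization scheme             X      u
    ------------------  ------------------------------------  ----   ---
    monomer_addition    none                                  X1     1
    monomer_exchange    X1 ⇌ X1' (k1 / k1_rev)                X1'    1
    dimer_addition      2 X1 ⇌ X2 (k1 / k1_rev)               X2     2
    hexamer_addition    2 X1 ⇌ X2, 3 X2 ⇌ X6 (k2 / k2_rev)    X6     6
    mdth                2 X1 ⇌ X2, 2 X2 ⇌ X4 (k2 / k2_rev),
                        X2 + X4 ⇌ X6 (k3 / k3_rev)            X6     6

u is the number of monomers per elongation unit.  ThT fluorescence is taken
to be proportional to the monomer mass added to seeds,
signal(t) = K_tht * sum_i (i*u) [Fi](t) + baseline.

Rate-constant units: bimolecular steps μM^-1 h^-1 (termolecular μM^-2 h^-1),
unimolecular steps h^-1; concentrations μM; time hours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .equilibrium import EquilibriumParams

__all__ = [
    "VARIANTS",
    "KineticModel",
    "FibrilDistribution",
    "Trajectory",
    "ThTCurve",
    "FitResult",
    "IntegrationError",
    "integrate_model",
    "tht_signal",
    "initial_rate",
    "fibril_yield",
    "average_replicates",
    "global_fit_tht",
    "compare_models",
]


class IntegrationError(RuntimeError):
    """The stiff ODE integration failed; the message carries solver diagnostics."""


@dataclass(frozen=True)
class _VariantInfo:
    species: tuple[str, ...]          # soluble species, X1 first
    x_species: str                    # the elongation unit
    unit_size: int                    # monomers per elongation unit
    constants: tuple[str, ...]        # required rate constants
    monomer_units: tuple[int, ...]    # monomers per soluble species


VARIANTS: dict[str, _VariantInfo] = {
    "monomer_addition": _VariantInfo(
        species=("X1",), x_species="X1", unit_size=1,
        constants=("ke", "ke_rev"), monomer_units=(1,)),
    "monomer_exchange": _VariantInfo(
        species=("X1", "X1p"), x_species="X1p", unit_size=1,
        constants=("k1", "k1_rev", "ke", "ke_rev"), monomer_units=(1, 1)),
    "dimer_addition": _VariantInfo(
        species=("X1", "X2"), x_species="X2", unit_size=2,
        constants=("k1", "k1_rev", "ke", "ke_rev"), monomer_units=(1, 2)),
    "hexamer_addition": _VariantInfo(
        species=("X1", "X2", "X6"), x_species="X6", unit_size=6,
        constants=("k1", "k1_rev", "k2", "k2_rev", "ke", "ke_rev"),
        monomer_units=(1, 2, 6)),
    "mdth": _VariantInfo(
        species=("X1", "X2", "X4", "X6"), x_species="X6", unit_size=6,
        constants=("k1", "k1_rev", "k2", "k2_rev", "k3", "k3_rev", "ke", "ke_rev"),
        monomer_units=(1, 2, 4, 6)),
}


@dataclass(frozen=True)
class KineticModel:
    """A fibril-elongation model variant and its rate constants."""

    variant: str
    rate_constants: dict

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; "
                             f"choose from {sorted(VARIANTS)}")
        info = VARIANTS[self.variant]
        missing = [k for k in info.constants if k not in self.rate_constants]
        if missing:
            raise ValueError(f"{self.variant} requires rate constants {missing}")
        for name in info.constants:
            if self.rate_constants[name] < 0:
                raise ValueError(f"rate constant {name} must be non-negative")

    @property
    def info(self) -> _VariantInfo:
        return VARIANTS[self.variant]

    @property
    def unit_size(self) -> int:
        return self.info.unit_size

    def equilibrium_params(self) -> EquilibriumParams:
        """Kd set implied by the pre-polymerization rate constants.

        Only defined for the dimer/hexamer variants (ratio of reverse to
        forward constants).
        """
        rc = self.rate_constants
        if self.variant == "dimer_addition":
            return EquilibriumParams(rc["k1_rev"] / rc["k1"], 1.0,
                                     enabled_species=frozenset({"dimer"}))
        if self.variant == "hexamer_addition":
            kd_hex_uM2 = rc["k2_rev"] / rc["k2"]
            return EquilibriumParams(rc["k1_rev"] / rc["k1"], kd_hex_uM2 / 1e12)
        if self.variant == "mdth":
            kd_tet = rc["k2_rev"] / rc["k2"]
            kd_hex_uM2 = kd_tet * rc["k3_rev"] / rc["k3"]
            return EquilibriumParams(rc["k1_rev"] / rc["k1"], kd_hex_uM2 / 1e12,
                                     kd_tetramer=kd_tet,
                                     enabled_species=frozenset({"dimer", "tetramer",
                                                                "hexamer"}))
        raise ValueError(f"no equilibrium scheme for variant {self.variant!r}")


@dataclass(frozen=True)
class FibrilDistribution:
    """Explicit fibril ladder F0..FN (number concentrations, μM).

    F0 is the preformed seed; Fi has gained i elongation units.  The seed
    number concentration is seed_monomer_equiv / seed_length: a 20 μM
    monomer-equivalent seed stock of ~200-mer fibrils (≈500 nm) is 0.1 μM
    fibril ends.
    """

    f: np.ndarray
    seed_monomer_equiv: float
    seed_length: int = 200

    def __post_init__(self) -> None:
        f = np.asarray(self.f, dtype=float)
        object.__setattr__(self, "f", f)
        if f.ndim != 1 or f.size < 3:
            raise ValueError("ladder must be one-dimensional with N >= 2")
        if np.any(f < 0):
            raise ValueError("fibril concentrations must be non-negative")
        if self.seed_length <= 0:
            raise ValueError("seed_length must be positive")

    @classmethod
    def from_seeds(cls, seed_monomer_equiv: float, seed_length: int = 200,
                   n_ladder: int = 200) -> "FibrilDistribution":
        f = np.zeros(n_ladder + 1)
        f[0] = seed_monomer_equiv / seed_length
        return cls(f=f, seed_monomer_equiv=seed_monomer_equiv,
                   seed_length=seed_length)

    @property
    def n_ladder(self) -> int:
        return self.f.size - 1


@dataclass
class Trajectory:
    """Time courses of all species from one integration."""

    times: np.ndarray                  # hours
    species: dict                      # name -> array over times (μM)
    fibrils: np.ndarray                # (n_times, N+1) number concentrations
    model: KineticModel
    total_monomer: float               # soluble monomer added at t=0, μM
    seed_monomer_equiv: float
    seed_length: int

    @property
    def unit_size(self) -> int:
        return self.model.unit_size

    def elongated_monomer_mass(self) -> np.ndarray:
        """Monomer mass added to seeds, u * sum_i i [Fi], per time point (μM)."""
        i = np.arange(self.fibrils.shape[1])
        return self.unit_size * self.fibrils @ i.astype(float)

    def fibril_number(self) -> np.ndarray:
        """Total fibril number concentration (conserved: no nucleation/fragmentation)."""
        return self.fibrils.sum(axis=1)

    def monomer_mass(self) -> np.ndarray:
        """Total monomer mass in solution + fibrils, per time point (μM)."""
        units = np.array(self.model.info.monomer_units, dtype=float)
        soluble = sum(u * self.species[name]
                      for u, name in zip(units, self.model.info.species))
        i = np.arange(self.fibrils.shape[1])
        per_fibril = self.seed_length + i * self.unit_size
        return soluble + self.fibrils @ per_fibril.astype(float)


@dataclass
class ThTCurve:
    """A ThT fluorescence time course at one total protein concentration."""

    times: np.ndarray        # hours
    signal: np.ndarray       # a.u.
    total_monomer: float     # μM
    replicate: int = 0
    k_tht: float | None = None   # fluorescence per μM elongated monomer, if known

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape:
            raise ValueError("times and signal must have the same shape")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite")


@dataclass
class FitResult:
    """Result of a global least-squares fit across ThT curves."""

    model: str
    params: dict                 # fitted + fixed rate constants, k_tht, baselines
    rss: float
    converged: bool
    n_starts: int
    free: tuple
    uncertainties: dict | None = None
    message: str = ""


def _rhs_factory(model: KineticModel, n_ladder: int, clamp_elongation_unit: bool):
    info = model.info
    rc = model.rate_constants
    ns = len(info.species)
    ix = info.species.index(info.x_species)
    ke = rc["ke"]
    ke_rev = rc["ke_rev"]
    variant = model.variant

    def rhs(t, y):
        s = y[:ns]
        f = y[ns:]
        ds = np.zeros(ns)
        if variant == "monomer_exchange":
            flux = rc["k1"] * s[0] - rc["k1_rev"] * s[1]
            ds[0] -= flux
            ds[1] += flux
        elif variant == "dimer_addition":
            flux = rc["k1"] * s[0] * s[0] - rc["k1_rev"] * s[1]
            ds[0] -= 2.0 * flux
            ds[1] += flux
        elif variant == "hexamer_addition":
            f1 = rc["k1"] * s[0] * s[0] - rc["k1_rev"] * s[1]
            f2 = rc["k2"] * s[1] ** 3 - rc["k2_rev"] * s[2]
            ds[0] -= 2.0 * f1
            ds[1] += f1 - 3.0 * f2
            ds[2] += f2
        elif variant == "mdth":
            f1 = rc["k1"] * s[0] * s[0] - rc["k1_rev"] * s[1]
            f2 = rc["k2"] * s[1] * s[1] - rc["k2_rev"] * s[2]
            f3 = rc["k3"] * s[1] * s[2] - rc["k3_rev"] * s[3]
            ds[0] -= 2.0 * f1
            ds[1] += f1 - 2.0 * f2 - f3
            ds[2] += f2 - f3
            ds[3] += f3
        # ladder: transition j -> j+1 at rate ke*X*Fj, reverse ke_rev*F[j+1]
        x = s[ix]
        flux = ke * x * f[:-1] - ke_rev * f[1:]
        df = np.empty_like(f)
        df[0] = -flux[0]
        df[1:-1] = flux[:-1] - flux[1:]
        df[-1] = flux[-1]
        if not clamp_elongation_unit:
            ds[ix] -= flux.sum()
        return np.concatenate((ds, df))

    return rhs


def integrate_model(model: KineticModel, total_monomer: float,
                    fibrils: FibrilDistribution, times,
                    initial_species: dict | None = None,
                    clamp_elongation_unit: bool = False,
                    rtol: float = 1e-8, atol: float = 1e-12,
                    method: str = "LSODA") -> Trajectory:
    """Integrate a model from an all-monomer (or user-supplied) initial state.

    By default the soluble pool starts entirely as free monomer (the seeded
    assay adds fresh monomer to seeds) and relaxes under the model's own rate
    constants.  ``clamp_elongation_unit=True`` holds the soluble pool fixed
    (reservoir condition), which makes the ladder a linear birth-death chain.

    Mass (free + oligomeric + fibril-borne monomer) and fibril number are
    conserved to the solver tolerance; failure raises
    :class:`IntegrationError`.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing 1-D grid")
    if total_monomer < 0:
        raise ValueError("total_monomer must be non-negative")
    info = model.info
    ns = len(info.species)
    y0 = np.zeros(ns + fibrils.f.size)
    if initial_species is None:
        y0[0] = total_monomer
    else:
        for name, value in initial_species.items():
            y0[info.species.index(name)] = value
    y0[ns:] = fibrils.f

    rhs = _rhs_factory(model, fibrils.n_ladder, clamp_elongation_unit)
    t0, t1 = float(times[0]), float(times[-1])
    sol = solve_ivp(rhs, (t0, t1), y0, t_eval=times, method=method,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(
            f"{model.variant} integration failed: {sol.message} "
            f"(total={total_monomer} μM, N={fibrils.n_ladder})")
    species = {name: sol.y[j] for j, name in enumerate(info.species)}
    fmat = sol.y[ns:].T
    traj = Trajectory(times=times, species=species, fibrils=fmat, model=model,
                      total_monomer=total_monomer,
                      seed_monomer_equiv=fibrils.seed_monomer_equiv,
                      seed_length=fibrils.seed_length)
    top = fmat[:, -1].max()
    number = max(traj.fibril_number().max(), 1e-300)
    if top > 0.01 * number:
        warnings.warn(
            f"more than 1% of fibril number reached the top of the ladder "
            f"(N={fibrils.n_ladder}); the ladder is too short", stacklevel=2)
    return traj


def tht_signal(traj: Trajectory, k_tht: float, baseline: float = 0.0,
               replicate: int = 0, weighting: str = "monomer") -> ThTCurve:
    """Convert a trajectory to a ThT fluorescence curve.

    ``weighting="monomer"`` (default) weights ladder rung i by the monomer
    mass added, i*u, so K_tht (a.u. per μM of elongated monomer) is
    comparable across model variants; ``weighting="unit"`` counts elongation
    units literally (weight i).
    """
    if weighting == "monomer":
        mass = traj.elongated_monomer_mass()
    elif weighting == "unit":
        i = np.arange(traj.fibrils.shape[1], dtype=float)
        mass = traj.fibrils @ i
    else:
        raise ValueError("weighting must be 'monomer' or 'unit'")
    return ThTCurve(times=traj.times, signal=k_tht * mass + baseline,
                    total_monomer=traj.total_monomer, replicate=replicate,
                    k_tht=k_tht)


def initial_rate(curve: ThTCurve, window: float | None = None) -> float:
    """Initial elongation rate: slope (a.u./h) of a line fit to the early curve.

    ``window`` is the upper time bound (hours); by default the first fifth of
    the time base (at least 3 points) is used.
    """
    if window is None:
        n = max(3, curve.times.size // 5)
        mask = np.zeros(curve.times.size, dtype=bool)
        mask[:n] = True
    else:
        mask = curve.times <= window
    t = curve.times[mask]
    y = curve.signal[mask]
    if t.size < 3:
        raise ValueError("initial-rate window must contain at least 3 points")
    if np.ptp(t) == 0:
        raise ValueError("degenerate window: times are constant")
    slope, _ = np.polyfit(t, y, 1)
    return float(slope)


def fibril_yield(traj: Trajectory, t_end: float | None = None) -> float:
    """Fraction of the added soluble monomer converted to elongated fibril mass.

    Evaluates u * sum_i i [Fi] / total_monomer at the last time point <= t_end
    (default: the final point).  The preformed seed mass is excluded.
    """
    mass = traj.elongated_monomer_mass()
    if t_end is None:
        idx = -1
    else:
        idx = int(np.searchsorted(traj.times, t_end, side="right") - 1)
        if idx < 0:
            raise ValueError("t_end precedes the trajectory")
    if traj.total_monomer == 0:
        return 0.0
    return float(mass[idx] / traj.total_monomer)


def average_replicates(curves) -> list[ThTCurve]:
    """Average replicate curves at each total concentration.

    Replicates must share a time base.  Plate-reader fits are usually run on
    the replicate mean, which suppresses the noise floor by 1/sqrt(n) and is
    the form in which multi-replicate seeded assays are reported.
    """
    by_conc: dict[float, list[ThTCurve]] = {}
    for c in curves:
        by_conc.setdefault(float(c.total_monomer), []).append(c)
    out = []
    for conc in sorted(by_conc):
        group = by_conc[conc]
        times = group[0].times
        for c in group[1:]:
            if not np.array_equal(c.times, times):
                raise ValueError("replicates must share a time base to average")
        mean = np.mean([c.signal for c in group], axis=0)
        out.append(ThTCurve(times=times.copy(), signal=mean,
                            total_monomer=conc, replicate=0,
                            k_tht=group[0].k_tht))
    return out


#: Rate constants varied by default in a global fit, per variant.  Forward
#: oligomerization constants are held fixed (the data constrain equilibrium
#: ratios and the elongation rate, not the absolute exchange rates) so the
#: free reverse constants carry the fitted Kd.
DEFAULT_FREE: dict[str, tuple[str, ...]] = {
    "monomer_addition": ("ke", "ke_rev"),
    "monomer_exchange": ("ke", "k1_rev"),
    "dimer_addition": ("ke", "k1_rev"),
    "hexamer_addition": ("ke", "k2_rev"),
    "mdth": ("ke", "k3_rev"),
}


def _simulate_mass(model, total, times, n_ladder, seed_length, seed_monomer_equiv,
                   weighting, rtol, atol):
    fib = FibrilDistribution.from_seeds(seed_monomer_equiv, seed_length, n_ladder)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        traj = integrate_model(model, total, fib, times, rtol=rtol, atol=atol)
    if weighting == "monomer":
        return traj.elongated_monomer_mass()
    i = np.arange(traj.fibrils.shape[1], dtype=float)
    return traj.fibrils @ i


def global_fit_tht(curves, variant: str, constants: dict,
                   free: tuple[str, ...] | None = None,
                   *, n_ladder: int = 200, seed_length: int = 200,
                   seed_monomer_equiv: float = 20.0,
                   fit_baseline: bool = True, weighting: str = "monomer",
                   bounds_decades: float = 3.0, n_starts: int = 10,
                   seed: int = 0, rtol: float = 1e-7, atol: float = 1e-10,
                   normalize_curves: bool = True) -> FitResult:
    """Globally fit one model variant to ThT curves at several concentrations.

    All rate constants are shared across curves; the subset named in ``free``
    (default :data:`DEFAULT_FREE`) is optimized in log10 space by bounded
    nonlinear least squares with seeded multi-start, the rest stay at the
    values in ``constants``.  The fluorescence factor K_tht (shared) and one
    baseline offset per curve enter linearly and are profiled out exactly at
    each iteration.  With ``normalize_curves`` (default) each curve's
    residuals are scaled by its dynamic range, so curves with very different
    fluorescence amplitudes contribute comparably — without this the
    near-flat low-concentration curves carry almost no statistical weight.
    The reported ``rss`` is then dimensionless.  Non-convergence is flagged
    on the returned :class:`FitResult` rather than raised.
    """
    curves = list(curves)
    if len({c.total_monomer for c in curves}) < 2:
        raise ValueError("global fit requires curves at >= 2 total concentrations")
    if free is None:
        free = DEFAULT_FREE[variant]
    free = tuple(free)
    info = VARIANTS[variant]
    for name in free:
        if name not in info.constants:
            raise ValueError(f"{name} is not a rate constant of {variant}")
    base = dict(constants)
    KineticModel(variant, base)  # validates completeness

    by_conc: dict[float, list] = {}
    for c in curves:
        by_conc.setdefault(float(c.total_monomer), []).append(c)
    conc_times = {conc: np.unique(np.concatenate([c.times for c in cs]))
                  for conc, cs in by_conc.items()}

    if normalize_curves:
        weights = np.concatenate([
            np.full(c.signal.size, 1.0 / max(np.ptp(c.signal), 1e-12))
            for c in curves])
    else:
        weights = np.ones(sum(c.signal.size for c in curves))
    y_obs = np.concatenate([c.signal for c in curves]) * weights
    n_obs = y_obs.size
    n_lin = 1 + (len(curves) if fit_baseline else 0)

    def predict_masses(theta):
        rc = dict(base)
        for name, value in zip(free, 10.0 ** np.asarray(theta)):
            rc[name] = value
        model = KineticModel(variant, rc)
        masses = {}
        for conc, tgrid in conc_times.items():
            masses[conc] = (tgrid, _simulate_mass(
                model, conc, tgrid, n_ladder, seed_length, seed_monomer_equiv,
                weighting, rtol, atol))
        return masses

    def design(masses):
        a = np.zeros((n_obs, n_lin))
        pos = 0
        for j, c in enumerate(curves):
            tgrid, m = masses[float(c.total_monomer)]
            mc = np.interp(c.times, tgrid, m)
            w = weights[pos:pos + c.times.size]
            a[pos:pos + c.times.size, 0] = mc * w
            if fit_baseline:
                a[pos:pos + c.times.size, 1 + j] = w
            pos += c.times.size
        return a

    def residuals(theta):
        try:
            masses = predict_masses(theta)
        except IntegrationError:
            return np.full(n_obs, 1e6)
        a = design(masses)
        coef, *_ = np.linalg.lstsq(a, y_obs, rcond=None)
        return a @ coef - y_obs

    x0 = np.log10([base[name] if base[name] > 0 else 1e-6 for name in free])
    lo, hi = x0 - bounds_decades, x0 + bounds_decades
    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.uniform(lo, hi))

    best = None
    for start in starts:
        try:
            sol = least_squares(residuals, start, bounds=(lo, hi),
                                method="trf", xtol=1e-10, ftol=1e-10)
        except Exception:  # noqa: BLE001 - keep scanning starts
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return FitResult(model=variant, params=dict(base), rss=float("inf"),
                         converged=False, n_starts=len(starts), free=free,
                         message="all starts failed")

    fitted = dict(base)
    for name, value in zip(free, 10.0 ** best.x):
        fitted[name] = value
    masses = predict_masses(best.x)
    a = design(masses)
    coef, *_ = np.linalg.lstsq(a, y_obs, rcond=None)
    fitted["k_tht"] = float(coef[0])
    if fit_baseline:
        fitted["baselines"] = {
            (c.total_monomer, c.replicate): float(coef[1 + j])
            for j, c in enumerate(curves)}
    resid = a @ coef - y_obs
    return FitResult(model=variant, params=fitted, rss=float(resid @ resid),
                     converged=bool(best.success), n_starts=len(starts),
                     free=free, message=str(best.message))


def compare_models(curves, candidates: dict, **fit_kwargs) -> pd.DataFrame:
    """Fit several variants to the same curves and tabulate their residuals.

    ``candidates`` maps variant name -> full rate-constant dict (starting
    values).  Returns a DataFrame sorted by RSS with one row per variant.
    """
    rows = []
    fits = {}
    for variant, constants in candidates.items():
        fit = global_fit_tht(curves, variant, constants, **fit_kwargs)
        fits[variant] = fit
        rows.append({"variant": variant, "rss": fit.rss,
                     "converged": fit.converged})
    frame = pd.DataFrame(rows).sort_values("rss").reset_index(drop=True)
    frame.attrs["fits"] = fits
    return frame
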