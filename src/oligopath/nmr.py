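"""NMR-side observables of an exchanging monomer/dimer/hexamer mixture.

Covers the quantities measured alongside the kinetics: combined amide
chemical-shift perturbations, shift-titration fits that estimate the dimer
and hexamer dissociation constants by grid search (with Monte-Carlo errors),
single-exponential decay fitting for relaxation and pulsed-field-gradient
diffusion data, TRACT rotational correlation times, paramagnetic relaxation
enhancements (Γ2), CPMG effective relaxation rates, and the
population-weighted apparent correlation time of the mixture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

from .equilibrium import (EquilibriumParams, PopulationFractions,
                          population_fractions, solve_equilibrium)

__all__ = [
    "TitrationSeries",
    "TitrationFit",
    "DecayCurve",
    "ExpFit",
    "CorrelationTimeModel",
    "combined_shift",
    "hexamer_saturation",
    "predict_titration",
    "fit_titration_grid",
    "monte_carlo_errors",
    "fit_exponential_decay",
    "tract_delta_r",
    "tract_tauc",
    "pre_gamma2",
    "classify_gamma2",
    "r2eff_from_intensities",
    "tauc_mixture",
]

# physical constants (SI)
_MU0 = 4.0e-7 * np.pi
_HBAR = 1.054571817e-34
_GAMMA_H = 2.6752218744e8     # rad s^-1 T^-1
_GAMMA_N = -2.7126e7          # rad s^-1 T^-1 (15N, negative)


def combined_shift(delta_h: float, delta_n: float) -> float:
    """Combined 1H/15N chemical-shift difference, sqrt((5*δH)^2 + δN^2) ppm.

    The 1H shift is up-weighted by 5 relative to 15N to put the two nuclei on
    a comparable ppm scale.  Symmetric under sign flips of either input.
    """
    dh = np.asarray(delta_h, dtype=float)
    dn = np.asarray(delta_n, dtype=float)
    if not (np.all(np.isfinite(dh)) and np.all(np.isfinite(dn))):
        raise ValueError("chemical shifts must be finite")
    out = np.sqrt((5.0 * dh) ** 2 + dn ** 2)
    return float(out) if out.ndim == 0 else out


@dataclass
class TitrationSeries:
    """Per-residue combined shifts Δδ (ppm) over a concentration panel (μM)."""

    concentrations: np.ndarray
    shifts: pd.DataFrame          # rows: residue id, columns: concentrations

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be sorted increasing")
        if list(self.shifts.columns) != list(self.concentrations):
            self.shifts = self.shifts.loc[:, list(self.concentrations)]
        if not np.all(np.isfinite(self.shifts.to_numpy())):
            raise ValueError("shifts must be finite")

    @property
    def residues(self) -> list:
        return list(self.shifts.index)


def hexamer_saturation(concs, params: EquilibriumParams,
                       mode: str = "hexamer") -> np.ndarray:
    """Fractional saturation of the titration observable at each concentration.

    ``mode="hexamer"`` (default) reads the saturating observable as the
    fraction of monomer units in hexamers, 6[X6]/[M_tot]; ``mode="oligomer"``
    uses the fraction in any oligomer (dimer + hexamer), appropriate when the
    monomer-dimer exchange dominates the shift change.
    """
    if mode not in ("hexamer", "oligomer"):
        raise ValueError("mode must be 'hexamer' or 'oligomer'")
    out = np.empty(np.size(concs))
    for j, c in enumerate(np.atleast_1d(np.asarray(concs, dtype=float))):
        if c == 0:
            out[j] = 0.0
            continue
        frac = population_fractions(solve_equilibrium(float(c), params))
        out[j] = frac.p_hex if mode == "hexamer" else frac.p_dim + frac.p_hex
    return out


def predict_titration(concs, params: EquilibriumParams, bmax,
                      mode: str = "hexamer") -> np.ndarray:
    """Predicted Δδ(c) = Bmax * saturation(c) for one residue (Bmax scalar)
    or several (Bmax array, result shape (n_residues, n_concs))."""
    sat = hexamer_saturation(concs, params, mode=mode)
    bmax = np.asarray(bmax, dtype=float)
    if bmax.ndim == 0:
        return float(bmax) * sat
    return np.outer(bmax, sat)


@dataclass
class TitrationFit:
    """Best grid point of a (Kd_dim, Kd_hex) search with per-residue Bmax."""

    kd_dimer: float               # μM
    kd_hexamer: float             # M^2
    bmax: dict                    # residue -> ppm
    rss: float
    rss_surface: np.ndarray       # (len(dimer grid), len(hexamer grid))
    kd_dimer_grid: np.ndarray
    kd_hexamer_grid: np.ndarray
    series: TitrationSeries
    mode: str = "hexamer"

    def predicted(self) -> pd.DataFrame:
        params = EquilibriumParams(self.kd_dimer, self.kd_hexamer)
        sat = hexamer_saturation(self.series.concentrations, params, self.mode)
        data = {c: {r: self.bmax[r] * s for r in self.series.residues}
                for c, s in zip(self.series.concentrations, sat)}
        return pd.DataFrame(data).loc[self.series.residues]

    def residuals(self) -> np.ndarray:
        return (self.series.shifts.to_numpy()
                - self.predicted().to_numpy()).ravel()


def fit_titration_grid(series: TitrationSeries, kd_dimer_grid,
                       kd_hexamer_grid, mode: str = "hexamer") -> TitrationFit:
    """Grid search over (Kd_dim, Kd_hex) with residue-wise Bmax profiled out.

    At each grid point the saturation curve is computed once and the
    per-residue Bmax that minimizes the squared error follows in closed form
    (Bmax_r = Σ_c s_c y_rc / Σ_c s_c^2, clipped at 0).  The full residual
    surface is returned together with the minimizing pair.  Kd_dim in μM,
    Kd_hex in M^2.
    """
    kd_dimer_grid = np.asarray(kd_dimer_grid, dtype=float)
    kd_hexamer_grid = np.asarray(kd_hexamer_grid, dtype=float)
    if kd_dimer_grid.size == 0 or kd_hexamer_grid.size == 0:
        raise ValueError("Kd grids must be non-empty")
    if np.any(kd_dimer_grid <= 0) or np.any(kd_hexamer_grid <= 0):
        raise ValueError("Kd grids must be positive")
    if series.concentrations.size < 3:
        raise ValueError("titration needs >= 3 concentrations")

    sats = _saturation_table(series.concentrations, kd_dimer_grid,
                             kd_hexamer_grid, mode)
    return _grid_fit_core(series, sats, kd_dimer_grid, kd_hexamer_grid, mode)


def _saturation_table(concs, kd_dimer_grid, kd_hexamer_grid,
                      mode: str) -> np.ndarray:
    """Saturation curves for every grid point, shape (n_dim, n_hex, n_conc)."""
    sats = np.empty((len(kd_dimer_grid), len(kd_hexamer_grid), len(concs)))
    for i, kd_d in enumerate(kd_dimer_grid):
        for j, kd_h in enumerate(kd_hexamer_grid):
            sats[i, j] = hexamer_saturation(
                concs, EquilibriumParams(kd_d, kd_h), mode)
    return sats


def _grid_fit_core(series: TitrationSeries, sats: np.ndarray,
                   kd_dimer_grid, kd_hexamer_grid, mode: str) -> TitrationFit:
    y = series.shifts.to_numpy()                        # (n_res, n_conc)
    denom = np.einsum("ijc,ijc->ij", sats, sats)        # (nd, nh)
    num = np.tensordot(y, sats, axes=([1], [2]))        # (n_res, nd, nh)
    with np.errstate(divide="ignore", invalid="ignore"):
        bmax = np.where(denom > 0, num / denom, 0.0)
    bmax = np.clip(bmax, 0.0, None)
    # rss = sum_r,c (y - bmax s)^2 expanded; valid with the clip applied
    surface = (np.sum(y * y)
               - 2.0 * np.sum(bmax * num, axis=0)
               + np.sum(bmax * bmax, axis=0) * denom)
    i, j = np.unravel_index(np.argmin(surface), surface.shape)
    return TitrationFit(
        kd_dimer=float(kd_dimer_grid[i]), kd_hexamer=float(kd_hexamer_grid[j]),
        bmax={r: float(b) for r, b in zip(series.residues, bmax[:, i, j])},
        rss=float(surface[i, j]), rss_surface=surface,
        kd_dimer_grid=np.asarray(kd_dimer_grid, dtype=float),
        kd_hexamer_grid=np.asarray(kd_hexamer_grid, dtype=float),
        series=series, mode=mode)


def monte_carlo_errors(fit: TitrationFit, n_iter: int = 100,
                       seed: int = 0) -> dict:
    """Monte-Carlo parameter spreads by residual resampling (seeded).

    Synthetic datasets are built as predicted + residuals resampled with
    replacement, refit on the same grids, and the standard deviation of each
    recovered parameter is returned ({"kd_dimer", "kd_hexamer",
    "bmax_<residue>"}).  Deterministic for a fixed seed.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    rng = np.random.default_rng(seed)
    predicted = fit.predicted().to_numpy()
    resid = fit.residuals()
    sats = _saturation_table(fit.series.concentrations, fit.kd_dimer_grid,
                             fit.kd_hexamer_grid, fit.mode)
    draws: dict[str, list] = {"kd_dimer": [], "kd_hexamer": []}
    for r in fit.series.residues:
        draws[f"bmax_{r}"] = []
    for _ in range(n_iter):
        noise = rng.choice(resid, size=predicted.shape, replace=True)
        shifts = pd.DataFrame(predicted + noise,
                              index=fit.series.residues,
                              columns=list(fit.series.concentrations))
        series = TitrationSeries(fit.series.concentrations, shifts)
        refit = _grid_fit_core(series, sats, fit.kd_dimer_grid,
                               fit.kd_hexamer_grid, fit.mode)
        draws["kd_dimer"].append(refit.kd_dimer)
        draws["kd_hexamer"].append(refit.kd_hexamer)
        for r in fit.series.residues:
            draws[f"bmax_{r}"].append(refit.bmax[r])
    return {name: float(np.std(values)) for name, values in draws.items()}


@dataclass
class DecayCurve:
    """An intensity decay: relaxation delay (s) or gradient strength (a.u.)."""

    abscissa: np.ndarray
    intensity: np.ndarray
    kind: str = "generic"     # tract_trosy | tract_antitrosy | pfg_diffusion | pre_r2 | generic

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.abscissa.size < 3:
            raise ValueError("decay curve needs >= 3 points")
        if self.abscissa.shape != self.intensity.shape:
            raise ValueError("abscissa and intensity must match in shape")


@dataclass
class ExpFit:
    """Single-exponential fit I = A exp(-r x)."""

    rate: float
    amplitude: float
    decaying: bool            # False flags non-decaying data (rate may be <= 0)


def fit_exponential_decay(curve: DecayCurve) -> ExpFit:
    """Least-squares fit of a single exponential to a decay curve.

    For diffusion data pass x = g^2 (the decay is exp(-d g^2)).  Data that do
    not decay are flagged (``decaying=False``) rather than rejected.
    """
    x = curve.abscissa
    y = curve.intensity
    # log-linear starting values where the data allow it
    if np.all(y > 0):
        slope, intercept = np.polyfit(x, np.log(y), 1)
        p0 = (float(np.exp(intercept)), float(-slope))
    else:
        p0 = (float(max(y.max(), 1e-12)), 1.0 / max(np.ptp(x), 1e-12))

    def model(xv, a, r):
        return a * np.exp(-r * xv)

    try:
        popt, _ = curve_fit(model, x, y, p0=p0, maxfev=10000)
        amp, rate = float(popt[0]), float(popt[1])
    except RuntimeError:
        amp, rate = p0
    decaying = rate > 0
    if not decaying:
        warnings.warn("decay fit returned a non-positive rate: data do not decay",
                      stacklevel=2)
    return ExpFit(rate=rate, amplitude=amp, decaying=decaying)


def _tract_constants(field_mhz: float, csa_ppm: float, r_nh_m: float,
                     theta_deg: float):
    b0 = 2.0 * np.pi * field_mhz * 1e6 / _GAMMA_H
    omega_n = abs(_GAMMA_N) * b0
    d = _MU0 * _HBAR * _GAMMA_H * abs(_GAMMA_N) / (4.0 * np.pi * r_nh_m ** 3)
    c = omega_n * abs(csa_ppm) * 1e-6
    p2 = 0.5 * (3.0 * np.cos(np.radians(theta_deg)) ** 2 - 1.0)
    return d, c, p2, omega_n


def tract_delta_r(tauc_ns: float, field_mhz: float, csa_ppm: float = -160.0,
                  r_nh_m: float = 1.02e-10, theta_deg: float = 17.0) -> float:
    """Forward TRACT model: ΔR = Rβ - Rα (s^-1) for a rigid rotor of given τc.

    ΔR = 2 η_xy with the transverse 15N CSA / N-H dipole cross-correlated
    relaxation rate η_xy = (d c / 8) P2(cosθ) [4J(0) + 3J(ωN)], using the
    rigid isotropic spectral density J(ω) = (2/5) τc / (1 + (ω τc)^2).
    The 15N CSA, N-H bond length and CSA/bond angle θ are configurable.
    """
    if tauc_ns <= 0:
        raise ValueError("tauc must be positive")
    d, c, p2, omega_n = _tract_constants(field_mhz, csa_ppm, r_nh_m, theta_deg)
    tau = tauc_ns * 1e-9

    def j(w):
        return 0.4 * tau / (1.0 + (w * tau) ** 2)

    eta = 0.125 * d * c * p2 * (4.0 * j(0.0) + 3.0 * j(omega_n))
    return 2.0 * eta


def tract_tauc(r_alpha: float, r_beta: float, field_mhz: float,
               csa_ppm: float = -160.0, r_nh_m: float = 1.02e-10,
               theta_deg: float = 17.0) -> float:
    """Rotational correlation time (ns) from TROSY/anti-TROSY relaxation rates.

    Inverts the monotone forward model ΔR(τc) for ΔR = Rβ - Rα; a
    non-positive ΔR (no net cross-correlation, i.e. not a tumbling
    macromolecule) is rejected.
    """
    delta_r = r_beta - r_alpha
    if delta_r <= 0:
        raise ValueError("Rβ must exceed Rα for a tumbling protein (ΔR > 0)")

    def f(tau_ns):
        return tract_delta_r(tau_ns, field_mhz, csa_ppm, r_nh_m, theta_deg) - delta_r

    lo, hi = 1e-4, 1e4
    if f(hi) < 0:
        raise ValueError("ΔR exceeds the rigid-rotor range of the forward model")
    return float(brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))


def pre_gamma2(r2_para: float, r2_dia: float) -> float:
    """Paramagnetic relaxation enhancement Γ2 = R2,para - R2,dia (s^-1)."""
    g = np.asarray(r2_para, dtype=float) - np.asarray(r2_dia, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("relaxation rates must be finite")
    return float(g) if g.ndim == 0 else g


def classify_gamma2(gamma2: float, moderate: float = 20.0,
                    strong: float = 50.0) -> str:
    """Bin a Γ2 rate: 'gray' (insignificant, < 20 s^-1, including negative
    noise-level values), 'yellow' (> 20 s^-1) or 'red' (> 50 s^-1)."""
    if gamma2 > strong:
        return "red"
    if gamma2 > moderate:
        return "yellow"
    return "gray"


def r2eff_from_intensities(i_x, i_0, tau_cpmg: float):
    """CPMG effective transverse relaxation rate, -ln(I_x/I_0)/τ_cpmg (s^-1).

    I_x is the peak intensity with the CPMG train applied, I_0 the reference
    intensity, τ_cpmg the fixed relaxation delay (s).
    """
    ix = np.asarray(i_x, dtype=float)
    i0 = np.asarray(i_0, dtype=float)
    if tau_cpmg <= 0:
        raise ValueError("tau_cpmg must be positive")
    if np.any(ix <= 0) or np.any(i0 <= 0):
        raise ValueError("intensities must be positive")
    out = -np.log(ix / i0) / tau_cpmg
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CorrelationTimeModel:
    """Rotational correlation times (ns) of each species.

    Defaults are hydrodynamic estimates for the ΔN6 monomer, dimer and
    hexamer structural models (9.8, 18.5 and 60.3 ns).
    """

    tau_mon: float = 9.8
    tau_dim: float = 18.5
    tau_hex: float = 60.3

    def __post_init__(self) -> None:
        if not (0 < self.tau_mon < self.tau_dim < self.tau_hex):
            raise ValueError("need 0 < tau_mon < tau_dim < tau_hex")


def tauc_mixture(fractions: PopulationFractions,
                 model: CorrelationTimeModel | None = None) -> float:
    """Population-weighted apparent correlation time of the fast-exchange mixture,

        τc,app = p_mon τc,mon + p_dim τc,dim + p_hex τc,hex   (ns),

    bounded by [τc,mon, τc,hex].  Tetramer-containing mixtures are not
    supported by the three-species correlation-time model.
    """
    if model is None:
        model = CorrelationTimeModel()
    if fractions.p_tet > 1e-12:
        raise ValueError("three-species correlation-time model cannot weight a tetramer")
    return (fractions.p_mon * model.tau_mon
            + fractions.p_dim * model.tau_dim
            + fractions.p_hex * model.tau_hex)
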