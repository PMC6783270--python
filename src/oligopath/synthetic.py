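"""Synthetic datasets with the statistical structure of the real assays.

Every input the analysis consumes can be generated here: seeded ThT
elongation curves over a concentration panel, per-residue chemical-shift
titrations, and exponential intensity decays (TRACT pairs, paramagnetic /
diamagnetic R2 pairs, PFG diffusion ramps).  All randomness flows through a
single seeded generator, so a fixed seed reproduces a dataset bit for bit,
and each generator returns its ground-truth parameters alongside the data.

Noise is homoscedastic Gaussian on each observable with standard deviation
``sigma`` times the curve's dynamic range (default 5%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nmr
from .equilibrium import EquilibriumParams
from .kinetics import (FibrilDistribution, KineticModel, ThTCurve,
                       integrate_model, tht_signal)

__all__ = [
    "SyntheticSpec",
    "GENERATING_RATE_CONSTANTS",
    "DEFAULT_BMAX_PPM",
    "make_tht_dataset",
    "make_titration_dataset",
    "make_decay_dataset",
    "standard_tht_corpus",
]

#: Generating rate constants per model variant (μM/h unit system).  The
#: hexamer-addition set carries the working Kds (dimer 50 μM, hexamer
#: 1.9e-9 M^2 = 1900 μM^2) with oligomer exchange much faster than
#: elongation, and an elongation rate chosen so that seeded growth is
#: negligible at 50 μM but fast above ~200 μM total protein.
GENERATING_RATE_CONSTANTS: dict[str, dict] = {
    "monomer_addition": {"ke": 0.1, "ke_rev": 1e-3},
    "monomer_exchange": {"k1": 2.0, "k1_rev": 2.0, "ke": 0.2, "ke_rev": 1e-3},
    "dimer_addition": {"k1": 100.0, "k1_rev": 5000.0, "ke": 0.1, "ke_rev": 1e-3},
    "hexamer_addition": {"k1": 100.0, "k1_rev": 5000.0,
                         "k2": 1.0, "k2_rev": 1900.0,
                         "ke": 0.2, "ke_rev": 1e-3},
    "mdth": {"k1": 100.0, "k1_rev": 5000.0,
             "k2": 10.0, "k2_rev": 950.0,
             "k3": 10.0, "k3_rev": 200.0,
             "ke": 0.2, "ke_rev": 1e-3},
}

#: Maximum combined-shift amplitudes (ppm) for the ten reporter residues
#: fitted in the titration, on the scale of real amide perturbations.
DEFAULT_BMAX_PPM: dict[int, float] = {
    11: 0.35, 12: 0.30, 23: 0.12, 26: 0.22, 50: 0.18,
    51: 0.28, 52: 0.15, 67: 0.10, 68: 0.25, 97: 0.08,
}


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic corpus.

    The ThT panel mirrors the seeded assays (five concentrations spanning
    50-500 μM, five replicates, 20 μM monomer-equivalent seeds); the
    titration panel mirrors the shift measurements (10-410 μM).
    """

    seed: int = 0
    sigma: float = 0.05                      # noise sd as fraction of dynamic range
    tht_concentrations: tuple = (50.0, 125.0, 240.0, 410.0, 500.0)
    titration_concentrations: tuple = (10.0, 20.0, 100.0, 200.0, 410.0)
    n_replicates: int = 5
    seed_monomer_equiv: float = 20.0         # μM
    seed_length: int = 200                   # monomers per seed particle
    n_ladder: int = 200                      # ladder length N
    t_end_h: float = 50.0
    n_times: int = 61
    k_tht: float = 1.0                       # a.u. per μM elongated monomer
    baseline: float = 2.0                    # seed ThT background, a.u.
    kd_dimer: float = 50.0                   # μM, titration truth
    kd_hexamer: float = 10.0e-9              # M^2, titration truth
    bmax: dict = field(default_factory=lambda: dict(DEFAULT_BMAX_PPM))

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.t_end_h, self.n_times)


def make_tht_dataset(spec: SyntheticSpec, variant: str = "hexamer_addition",
                     constants: dict | None = None,
                     n_ladder: int | None = None,
                     n_replicates: int | None = None):
    """Simulate the seeded ThT corpus: curves at each panel concentration.

    Returns ``(curves, truth)`` where curves is a flat list of
    :class:`~oligopath.kinetics.ThTCurve` (n_concentrations x n_replicates)
    and truth records every generating parameter.  With ``sigma == 0`` the
    replicates equal the noiseless model output exactly.
    """
    constants = dict(GENERATING_RATE_CONSTANTS[variant] if constants is None
                     else constants)
    n_ladder = spec.n_ladder if n_ladder is None else n_ladder
    n_reps = spec.n_replicates if n_replicates is None else n_replicates
    model = KineticModel(variant, constants)
    times = spec.times()
    rng = spec.rng()
    curves: list[ThTCurve] = []
    for conc in spec.tht_concentrations:
        fib = FibrilDistribution.from_seeds(spec.seed_monomer_equiv,
                                            spec.seed_length, n_ladder)
        with warnings.catch_warnings():
            # fibrils completing the ladder at high concentration is the
            # intended end state of the corpus, not a truncation artifact
            warnings.simplefilter("ignore")
            traj = integrate_model(model, conc, fib, times)
        clean = tht_signal(traj, spec.k_tht, spec.baseline)
        scale = spec.sigma * np.ptp(clean.signal)
        for rep in range(n_reps):
            noise = rng.normal(0.0, scale, size=times.size) if scale > 0 else 0.0
            curves.append(ThTCurve(times=times.copy(),
                                   signal=clean.signal + noise,
                                   total_monomer=conc, replicate=rep,
                                   k_tht=spec.k_tht))
    truth = {
        "variant": variant, "rate_constants": constants,
        "k_tht": spec.k_tht, "baseline": spec.baseline,
        "n_ladder": n_ladder, "seed_length": spec.seed_length,
        "seed_monomer_equiv": spec.seed_monomer_equiv,
        "sigma": spec.sigma, "seed": spec.seed,
        "concentrations_uM": list(spec.tht_concentrations),
        "n_replicates": n_reps,
    }
    return curves, truth


def standard_tht_corpus(seed: int = 0, variant: str = "hexamer_addition",
                        sigma: float = 0.05, n_ladder: int | None = None):
    """The standard five-concentration, five-replicate seeded benchmark."""
    spec = SyntheticSpec(seed=seed, sigma=sigma)
    return make_tht_dataset(spec, variant=variant, n_ladder=n_ladder)


def make_titration_dataset(spec: SyntheticSpec, mode: str = "hexamer"):
    """Simulate the per-residue shift titration over the concentration panel.

    Noise sd is ``sigma`` times each residue's dynamic range.  Returns
    ``(series, truth)``.
    """
    params = EquilibriumParams(spec.kd_dimer, spec.kd_hexamer)
    concs = np.asarray(spec.titration_concentrations, dtype=float)
    residues = list(spec.bmax)
    clean = nmr.predict_titration(concs, params,
                                  np.array([spec.bmax[r] for r in residues]),
                                  mode=mode)
    rng = spec.rng()
    noisy = clean.copy()
    for i in range(len(residues)):
        scale = spec.sigma * np.ptp(clean[i])
        if scale > 0:
            noisy[i] = clean[i] + rng.normal(0.0, scale, size=concs.size)
    shifts = pd.DataFrame(noisy, index=residues, columns=list(concs))
    series = nmr.TitrationSeries(concs, shifts)
    truth = {
        "kd_dimer_uM": spec.kd_dimer, "kd_hexamer_M2": spec.kd_hexamer,
        "bmax_ppm": dict(spec.bmax), "mode": mode,
        "sigma": spec.sigma, "seed": spec.seed,
        "concentrations_uM": list(concs),
    }
    return series, truth


def make_decay_dataset(spec: SyntheticSpec, kind: str,
                       tauc_ns: float = 20.0, field_mhz: float = 750.0,
                       r2_dia: float = 15.0, gamma2: float = 35.0,
                       r2_base: float = 30.0, diffusion_d: float = 0.02):
    """Simulate exponential intensity decays of the given kind.

    kind:
        * ``"tract"`` - a TROSY/anti-TROSY pair generated from ``tauc_ns``
          via the forward TRACT model (delays 0.002-0.064 s);
        * ``"pre_r2"`` - a paramagnetic/diamagnetic pair with PRE ``gamma2``
          on top of ``r2_dia`` (delays 0.0016-0.016 s);
        * ``"pfg_diffusion"`` - S/S0 = exp(-d g^2) over a gradient ramp.

    Returns ``(curves, truth)`` with curves a dict keyed by curve kind.
    """
    rng = spec.rng()

    def noisy(x, clean, label):
        scale = spec.sigma * np.ptp(clean)
        noise = rng.normal(0.0, scale, size=x.size) if scale > 0 else 0.0
        return nmr.DecayCurve(abscissa=x, intensity=clean + noise, kind=label)

    if kind == "tract":
        delays = np.linspace(0.002, 0.064, 16)
        delta_r = nmr.tract_delta_r(tauc_ns, field_mhz)
        r_alpha = r2_base - delta_r / 2.0
        r_beta = r2_base + delta_r / 2.0
        curves = {
            "tract_trosy": noisy(delays, np.exp(-r_alpha * delays), "tract_trosy"),
            "tract_antitrosy": noisy(delays, np.exp(-r_beta * delays),
                                     "tract_antitrosy"),
        }
        truth = {"tauc_ns": tauc_ns, "field_mhz": field_mhz,
                 "r_alpha": r_alpha, "r_beta": r_beta}
    elif kind == "pre_r2":
        delays = np.linspace(0.0016, 0.016, 10)
        r2_para = r2_dia + gamma2
        curves = {
            "pre_r2_dia": noisy(delays, np.exp(-r2_dia * delays),
                                "pre_r2_dia"),
            "pre_r2_para": noisy(delays, np.exp(-r2_para * delays),
                                 "pre_r2_para"),
        }
        truth = {"gamma2": gamma2, "r2_dia": r2_dia, "r2_para": r2_para}
    elif kind == "pfg_diffusion":
        g = np.linspace(1.0, 12.0, 12)
        curves = {"pfg_diffusion": noisy(g, np.exp(-diffusion_d * g * g),
                                         "pfg_diffusion")}
        truth = {"diffusion_d": diffusion_d}
    else:
        raise ValueError("kind must be 'tract', 'pre_r2' or 'pfg_diffusion'")
    truth.update({"sigma": spec.sigma, "seed": spec.seed})
    return curves, truth
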