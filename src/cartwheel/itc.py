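"""1:1 binding model: occupancy, synthetic ITC titrations, isotherm fitting.

Covers the calorimetry-adjacent calculations of the monobody work: the exact
quadratic fraction-bound used to choose monobody concentrations for the AFM
assay ("at least 70% bound given the ITC K_D"), forward simulation of
per-injection heats for a MicroCal-style perfusion cell, and nonlinear
least-squares recovery of the dissociation constant K_D, binding enthalpy
dH and stoichiometry n from a titration series.

Units: concentrations in uM (K_D in nM where noted), volumes in uL, heats in
ucal, dH in kcal/mol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TitrationSeries",
    "BindingFit",
    "FitFailure",
    "fraction_bound",
    "simulate_titration",
    "fit_titration",
]

KCAL_TO_UCAL = 1e9
#: heat (ucal) = dH (kcal/mol) * concentration (uM) * volume (uL) * this
_HEAT_SCALE = 1e-12 * KCAL_TO_UCAL  # uM * uL = 1e-12 mol


class FitFailure(RuntimeError):
    """Raised when the isotherm fit does not converge."""


@dataclass
class TitrationSeries:
    """Integrated per-injection heats of one ITC run.

    The binder (monobody) sits in the syringe at ``syringe_conc`` and is
    titrated into the cell containing the target at ``cell_conc``."""

    cell_volume: float  # uL
    cell_conc: float  # uM
    syringe_conc: float  # uM
    injection_volumes: np.ndarray  # uL
    heats: np.ndarray  # ucal

    def __post_init__(self):
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        self.heats = np.asarray(self.heats, dtype=float)
        if self.cell_volume <= 0 or self.cell_conc <= 0 or self.syringe_conc <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if self.injection_volumes.shape != self.heats.shape:
            raise ValueError("need one heat per injection")
        if np.any(self.injection_volumes >= self.cell_volume):
            raise ValueError("injection volume must be far below the cell volume")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"injection_volume_ul": self.injection_volumes, "heat_ucal": self.heats}
        )

    def write_csv(self, path: str) -> None:
        import json

        self.to_frame().to_csv(path, index=False)
        with open(str(path) + ".json", "w") as fh:
            json.dump(
                {
                    "cell_volume_ul": self.cell_volume,
                    "cell_conc_uM": self.cell_conc,
                    "syringe_conc_uM": self.syringe_conc,
                },
                fh,
            )

    @classmethod
    def read_csv(cls, path: str) -> "TitrationSeries":
        import json

        import pandas as pd

        df = pd.read_csv(path)
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        return cls(
            cell_volume=meta["cell_volume_ul"],
            cell_conc=meta["cell_conc_uM"],
            syringe_conc=meta["syringe_conc_uM"],
            injection_volumes=df["injection_volume_ul"].to_numpy(),
            heats=df["heat_ucal"].to_numpy(),
        )


@dataclass(frozen=True)
class BindingFit:
    """Point estimates and diagnostics of a 1:1 isotherm fit."""

    kd: float  # nM
    dh: float  # kcal/mol
    n_stoich: float
    heat_offset: float  # ucal per injection
    residual_rms: float  # ucal
    covariance: np.ndarray | None = None  # over (log10 kd, dh, n, offset)


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------

def fraction_bound(ligand_total: float, protein_total: float, kd: float) -> float:
    """Exact equilibrium fraction of protein in complex for 1:1 binding.

    Solves the quadratic mass-action balance
    ``complex = ((P + L + K) - sqrt((P + L + K)^2 - 4 P L)) / 2`` and returns
    complex / P.  Concentrations in uM, ``kd`` in nM.  Reduces to the
    excess-ligand form L / (L + K) as P -> 0, and is never above it.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    if ligand_total < 0 or protein_total < 0:
        raise ValueError("concentrations must be non-negative")
    if protein_total == 0:
        raise ValueError("fraction bound undefined for zero protein")
    if ligand_total == 0:
        return 0.0
    K = kd * 1e-3  # nM -> uM
    P, L = protein_total, ligand_total
    s = P + L + K
    complex_ = (s - np.sqrt(s * s - 4.0 * P * L)) / 2.0
    return float(complex_ / P)


def _complex_conc(P: float, L: float, K_uM: float) -> float:
    s = P + L + K_uM
    disc = max(s * s - 4.0 * P * L, 0.0)
    return (s - np.sqrt(disc)) / 2.0


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def _injection_heats(
    kd_nM: float,
    dh: float,
    n_stoich: float,
    cell_volume: float,
    cell_conc: float,
    syringe_conc: float,
    injection_volumes: np.ndarray,
) -> np.ndarray:
    """Per-injection heats (ucal) for the perfusion (overflow) cell model.

    Each injection of dV first displaces cell contents, scaling every
    concentration by (1 - dV/V0), then delivers dV * syringe_conc / V0 of
    titrant.  The heat of injection i is dH times the newly formed complex,
    V0 * (C_i - C_{i-1} * (1 - dV/V0))."""
    K = kd_nM * 1e-3
    V0 = cell_volume
    P = cell_conc  # total target in cell (uM)
    L = 0.0
    C_prev = 0.0
    heats = np.empty(len(injection_volumes))
    for i, dV in enumerate(injection_volumes):
        f = 1.0 - dV / V0
        P *= f
        L = L * f + syringe_conc * dV / V0
        C = _complex_conc(n_stoich * P, L, K)
        heats[i] = dh * (C - C_prev * f) * V0 * _HEAT_SCALE
        C_prev = C
    return heats


def simulate_titration(
    kd: float,
    dh: float,
    n_stoich: float = 1.0,
    cell_volume: float = 200.0,
    cell_conc: float = 10.0,
    syringe_conc: float = 100.0,
    injection_volumes: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> TitrationSeries:
    """Simulate a titration (defaults: 20 x 2 uL into a 200 uL cell, target
    10 uM, titrant 100 uM — the tenfold syringe excess used for 1:1
    complexes).  ``kd`` in nM, ``dh`` in kcal/mol; Gaussian heat noise of SD
    ``noise_sd`` ucal is added deterministically per seed."""
    if kd <= 0 or n_stoich <= 0:
        raise ValueError("kd and n_stoich must be positive")
    if injection_volumes is None:
        injection_volumes = np.full(20, 2.0)
    injection_volumes = np.asarray(injection_volumes, dtype=float)
    if len(injection_volumes) < 5:
        raise ValueError("need at least 5 injections")
    heats = _injection_heats(
        kd, dh, n_stoich, cell_volume, cell_conc, syringe_conc, injection_volumes
    )
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd, size=heats.shape)
    return TitrationSeries(
        cell_volume=cell_volume,
        cell_conc=cell_conc,
        syringe_conc=syringe_conc,
        injection_volumes=injection_volumes,
        heats=heats,
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_titration(
    series: TitrationSeries,
    init: tuple[float, float, float, float] | None = None,
    exclude_first: bool = True,
    max_nfev: int = 2000,
) -> BindingFit:
    """Least-squares fit of (K_D, dH, n, heat offset) to a titration.

    The first injection is excluded by default (standard MicroCal practice:
    its volume is unreliable).  Initialisation, when not given, is the
    deterministic heuristic n = 1, dH from the first fitted-range heat,
    K_D from the c ~ 10 rule of thumb.  Warns when the Wiseman c-value
    n * P / K_D is outside [0.5, 1000], where K_D is poorly constrained.
    Raises :class:`FitFailure` on non-convergence."""
    mask = np.ones(len(series.heats), dtype=bool)
    if exclude_first:
        mask[0] = False
    if mask.sum() < 5:
        raise ValueError("need at least 5 informative injections")
    obs = series.heats[mask]

    if init is None:
        mol_per_inj = (
            series.injection_volumes[mask][0] * series.syringe_conc * _HEAT_SCALE
        )
        dh0 = obs[0] / mol_per_inj if mol_per_inj else -10.0
        kd0 = max(series.cell_conc * 1e3 / 10.0, 1.0)  # nM, c ~ 10 heuristic
        init = (kd0, dh0, 1.0, 0.0)

    def residuals(theta):
        log_kd, dh, n, offset = theta
        model = _injection_heats(
            10.0**log_kd, dh, n,
            series.cell_volume, series.cell_conc, series.syringe_conc,
            series.injection_volumes,
        )
        return model[mask] + offset - obs

    x0 = np.array([np.log10(init[0]), init[1], init[2], init[3]])
    sol = least_squares(
        residuals, x0,
        bounds=([-3, -1e4, 1e-3, -np.inf], [9, 1e4, 1e3, np.inf]),
        max_nfev=max_nfev,
    )
    if not sol.success:
        raise FitFailure(f"isotherm fit did not converge: {sol.message}")
    log_kd, dh, n, offset = sol.x
    kd = float(10.0**log_kd)

    c_value = n * series.cell_conc / (kd * 1e-3)
    if not 0.5 <= c_value <= 1000.0:
        warnings.warn(
            f"Wiseman c-value {c_value:.3g} outside [0.5, 1000]; "
            "K_D is poorly determined in this regime",
            RuntimeWarning,
            stacklevel=2,
        )

    dof = max(len(obs) - 4, 1)
    rms = float(np.sqrt(2.0 * sol.cost / len(obs)))
    cov = None
    try:
        JTJ = sol.jac.T @ sol.jac
        cov = np.linalg.inv(JTJ) * (2.0 * sol.cost / dof)
    except np.linalg.LinAlgError:
        pass
    return BindingFit(
        kd=kd, dh=float(dh), n_stoich=float(n), heat_offset=float(offset),
        residual_rms=rms, covariance=cov,
    )
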