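"""Thermodynamic post-processing: blocking errors, densities, excess
mixing properties, and finite-difference response functions.

Statistical errors of time-correlated series use the Flyvbjerg-Petersen
multilevel blocking transformation: repeated pairwise averaging until the
standard error of the blocked mean stops growing (the plateau), which is
the unbiased error estimate for correlated data.

Heat capacity c_p = (dH/dT)_p and thermal expansivity
alpha_p = v^-1 (dv/dT)_p are obtained from time-averaged H and v at a few
temperatures by a linear (least-squares slope) approximation; with three
equispaced temperatures this equals the central difference.  The quoted
uncertainty is half the maximum change between adjacent two-point slopes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import ThermoSeries

__all__ = [
    "BlockingResult",
    "ExcessProperty",
    "ResponseFunction",
    "block_average",
    "mean_density",
    "excess_molar_volume",
    "excess_enthalpy",
    "heat_capacity",
    "thermal_expansivity",
    "cp_correction_factor",
    "apply_cp_correction",
]


@dataclass
class BlockingResult:
    mean: float
    se_levels: np.ndarray  # standard error of the mean at each blocking level
    se_uncertainty: np.ndarray  # one-sigma uncertainty of each level's SE
    plateau_se: float
    plateau_level: int
    converged: bool  # False when no plateau was reached before data ran out

    @property
    def naive_se(self) -> float:
        return float(self.se_levels[0])


def block_average(series: np.ndarray) -> BlockingResult:
    """Flyvbjerg-Petersen blocking estimate of the mean and its error.

    The series is pairwise-averaged level by level; the standard error
    per level is std/sqrt(n_blocks).  The plateau is the first level
    whose SE agrees with the next level's within that level's own
    uncertainty, SE/sqrt(2(n-1)).  For uncorrelated data this is level
    0 (the naive SE); positively correlated data plateau higher.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 8:
        raise ValueError("blocking needs at least 8 samples")
    mean = float(x.mean())
    ses: list[float] = []
    dses: list[float] = []
    while len(x) >= 4:
        n = len(x)
        var = x.var(ddof=1)
        se = np.sqrt(var / n)
        ses.append(float(se))
        dses.append(float(se / np.sqrt(2.0 * (n - 1))))
        if n % 2 == 1:
            x = x[:-1]
        x = 0.5 * (x[0::2] + x[1::2])
    se_levels = np.array(ses)
    se_unc = np.array(dses)
    plateau_level = None
    for level in range(len(ses) - 1):
        if abs(ses[level + 1] - ses[level]) <= se_unc[level + 1]:
            plateau_level = level + 1
            break
    if plateau_level is None:
        # no plateau: report the largest (most conservative) estimate
        plateau_level = int(np.argmax(se_levels))
        converged = False
    else:
        converged = True
    return BlockingResult(
        mean=mean,
        se_levels=se_levels,
        se_uncertainty=se_unc,
        plateau_se=float(se_levels[plateau_level]),
        plateau_level=plateau_level,
        converged=converged,
    )


def mean_density(thermo: ThermoSeries) -> tuple[float, float]:
    """Blocked mean and error of the density column (g/cm^3)."""
    if thermo.density is None:
        raise ValueError("series has no density column")
    res = block_average(thermo.density)
    return res.mean, res.plateau_se


@dataclass
class ExcessProperty:
    """Mixture property minus the mole-fraction-weighted pure values."""

    x_water: float
    mixture: float
    pure_il: float
    pure_water: float

    @property
    def ideal(self) -> float:
        return self.x_water * self.pure_water + (1.0 - self.x_water) * self.pure_il

    @property
    def excess(self) -> float:
        return self.mixture - self.ideal


def excess_molar_volume(
    x_water: float, v_mix: float, v_il_pure: float, v_water_pure: float
) -> ExcessProperty:
    """v^E = v_mix - (x v_w + (1-x) v_il), molar basis (one IL pair and
    one water each count as one mole of "molecules")."""
    if not 0.0 <= x_water <= 1.0:
        raise ValueError("x_water must be a mole fraction in [0, 1]")
    return ExcessProperty(x_water, v_mix, v_il_pure, v_water_pure)


def excess_enthalpy(
    x_water: float, h_mix: float, h_il_pure: float, h_water_pure: float
) -> ExcessProperty:
    """h^E analogous to the excess molar volume."""
    if not 0.0 <= x_water <= 1.0:
        raise ValueError("x_water must be a mole fraction in [0, 1]")
    return ExcessProperty(x_water, h_mix, h_il_pure, h_water_pure)


@dataclass
class ResponseFunction:
    """A fitted response coefficient with its slope-change uncertainty."""

    kind: str  # "heat_capacity" | "thermal_expansivity"
    per_mass: float | None  # J g^-1 K^-1 for c_p
    per_mole: float | None  # J mol^-1 K^-1 for c_p
    value: float  # c_p slope (J/K) or alpha_p (K^-1)
    uncertainty: float
    uncertainty_per_mass: float | None
    uncertainty_per_mole: float | None
    temperatures: tuple[float, ...]


def _slope_and_spread(temps: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    """Least-squares slope plus half the maximum adjacent-slope change."""
    order = np.argsort(temps)
    temps, values = temps[order], values[order]
    slope = float(np.polyfit(temps, values, 1)[0])
    if len(temps) < 3:
        return slope, 0.0
    two_point = np.diff(values) / np.diff(temps)
    spread = float(np.max(np.abs(np.diff(two_point))) / 2.0)
    return slope, spread


def heat_capacity(
    temps: np.ndarray,
    h_means: np.ndarray,
    mass: float | None = None,
    moles: float | None = None,
) -> ResponseFunction:
    """c_p from time-averaged total enthalpy H(T) (energy units of the
    input per kelvin; per-gram and per-mole values when mass/moles given)."""
    temps = np.asarray(temps, dtype=float)
    h_means = np.asarray(h_means, dtype=float)
    if len(temps) < 2:
        raise ValueError("heat capacity needs at least 2 temperatures")
    slope, spread = _slope_and_spread(temps, h_means)
    return ResponseFunction(
        kind="heat_capacity",
        per_mass=slope / mass if mass else None,
        per_mole=slope / moles if moles else None,
        value=slope,
        uncertainty=spread,
        uncertainty_per_mass=spread / mass if mass else None,
        uncertainty_per_mole=spread / moles if moles else None,
        temperatures=tuple(sorted(float(t) for t in temps)),
    )


def thermal_expansivity(
    temps: np.ndarray, v_means: np.ndarray, t_ref: float | None = None
) -> ResponseFunction:
    """alpha_p = (1/v) dv/dT with v evaluated at the reference (middle)
    temperature."""
    temps = np.asarray(temps, dtype=float)
    v_means = np.asarray(v_means, dtype=float)
    if len(temps) < 2:
        raise ValueError("thermal expansivity needs at least 2 temperatures")
    slope, spread = _slope_and_spread(temps, v_means)
    order = np.argsort(temps)
    if t_ref is None:
        t_ref = float(temps[order][len(temps) // 2])
    v_ref = float(np.interp(t_ref, temps[order], v_means[order]))
    if v_ref <= 0:
        raise ValueError("reference volume must be positive")
    return ResponseFunction(
        kind="thermal_expansivity",
        per_mass=None,
        per_mole=None,
        value=slope / v_ref,
        uncertainty=spread / v_ref,
        uncertainty_per_mass=None,
        uncertainty_per_mole=None,
        temperatures=tuple(sorted(float(t) for t in temps)),
    )


def cp_correction_factor(cp_sim_pure_water: float, cp_exp: float = 4.184) -> float:
    """Experimental-over-simulated heat-capacity ratio for pure water,
    used as a multiplicative correction for simulated c_p values."""
    if cp_sim_pure_water <= 0:
        raise ValueError("simulated heat capacity must be positive")
    return cp_exp / cp_sim_pure_water


def apply_cp_correction(
    table: pd.DataFrame, factor: float, columns: tuple[str, ...] = ("cp_mass", "cp_molar")
) -> pd.DataFrame:
    """Scale the c_p columns of a results table by the correction factor."""
    out = table.copy()
    for col in columns:
        if col in out.columns:
            out[col] = out[col] * factor
    return out
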