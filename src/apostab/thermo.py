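"""Two-state unfolding thermodynamics.

Covers the biophysical validation arm of the pipeline:

- percent alpha-helix from mean residue ellipticity at 222 nm,
  ``% helix = (-[theta]222 + 3000) / (36000 + 3000) * 100``;
- Boltzmann sigmoid fits of thermal (CD theta222 vs T) and chemical
  (tryptophan lambda-max vs [GdnHCl]) denaturation transitions;
- apparent van't Hoff enthalpy from the fitted transition width,
  ``dH = R * Tm_K**2 / a`` (R in kcal/mol/K, widths in K);
- linear extrapolation method (LEM) free energy: within the transition,
  ``dG(D) = -RT ln(f_u/(1-f_u))`` is linear in denaturant, ``dG = dG0 - m*D``,
  giving the zero-denaturant stability dG0 and the m-value.

All thermodynamic arithmetic is in Kelvin; interfaces are in Celsius.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .estimators import BoltzmannSigmoid

R_KCAL = 1.987e-3  # gas constant, kcal / (mol K)
CELSIUS_OFFSET = 273.15
LEM_TEMPERATURE_K = 298.15  # dG evaluated at 25 C

__all__ = [
    "R_KCAL",
    "CELSIUS_OFFSET",
    "TwoStateFit",
    "LEMResult",
    "HelicityResult",
    "ChemDenatSeries",
    "CDThermalScan",
    "helicity_from_theta222",
    "mean_residue_ellipticity",
    "boltzmann_fit",
    "vant_hoff_dH",
    "chem_denat_midpoint",
    "lem_free_energy",
]


@dataclass
class CDThermalScan:
    """CD ellipticity at 222 nm versus temperature for one condition."""

    protein: str
    temperatures: np.ndarray
    theta222: np.ndarray
    compound: str | None = None
    conc_mM: float | None = None

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.theta222 = np.asarray(self.theta222, dtype=float)
        if len(self.temperatures) < 8:
            raise ValueError("thermal scan needs at least 8 points")
        if not np.all(np.diff(self.temperatures) > 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclass
class ChemDenatSeries:
    """Tryptophan lambda-max versus GdnHCl concentration for one condition."""

    protein: str
    denaturant_M: np.ndarray
    lambda_max_nm: np.ndarray
    compound: str | None = None
    conc_mM: float | None = None

    def __post_init__(self) -> None:
        self.denaturant_M = np.asarray(self.denaturant_M, dtype=float)
        self.lambda_max_nm = np.asarray(self.lambda_max_nm, dtype=float)
        if np.any(self.denaturant_M < 0):
            raise ValueError("denaturant concentrations must be nonnegative")
        if not np.all(np.diff(self.denaturant_M) > 0):
            raise ValueError("denaturant concentrations must be increasing")


@dataclass
class TwoStateFit:
    """Boltzmann sigmoid fit summary (thermal or chemical axis)."""

    midpoint: float
    width: float
    pre: float
    post: float
    pre_slope: float
    post_slope: float
    rmse: float
    converged: bool
    extrapolated: bool
    covariance: np.ndarray | None = None
    axis: str = "temperature_C"  # or "denaturant_M"
    estimator: BoltzmannSigmoid | None = field(default=None, repr=False)

    @property
    def tm_c(self) -> float:
        return self.midpoint

    @property
    def d_half(self) -> float:
        return self.midpoint


@dataclass
class LEMResult:
    """Linear-extrapolation-method stability estimate."""

    dg0: float  # kcal/mol at zero denaturant
    m_value: float  # kcal/mol/M
    d_half: float  # M, = dg0/m for an exact two-state series
    n_points: int
    r_squared: float


@dataclass
class HelicityResult:
    theta222: float
    percent_helix: float
    clamped: bool


def helicity_from_theta222(theta222: float) -> HelicityResult:
    """Percent alpha-helix from [theta]222 (deg cm^2 dmol^-1).

    Uses the linear calibration anchored at +3000 (0% helix) and
    -36000 (100% helix); values outside [0, 100] are clamped and flagged.
    """
    theta222 = float(theta222)
    if not np.isfinite(theta222):
        raise ValueError("theta222 must be finite")
    raw = (-theta222 + 3000.0) / (36000.0 + 3000.0) * 100.0
    clamped = raw < 0.0 or raw > 100.0
    return HelicityResult(theta222, float(np.clip(raw, 0.0, 100.0)), clamped)


def mean_residue_ellipticity(
    theta_obs_mdeg: float, conc_mg_ml: float, path_cm: float, mrw: float = 115.4
) -> float:
    """Convert raw machine ellipticity (mdeg) to mean residue ellipticity.

    ``[theta] = theta_obs * MRW / (10 * l * c)`` with path in cm and protein
    concentration in mg/ml.  MRW defaults to 115.4 (243-residue apoA-I).
    """
    if conc_mg_ml <= 0 or path_cm <= 0:
        raise ValueError("concentration and path length must be positive")
    return theta_obs_mdeg * mrw / (10.0 * path_cm * conc_mg_ml)


def boltzmann_fit(x, y, sloped_baselines: bool = False, axis: str = "temperature_C") -> TwoStateFit:
    """Fit a two-state Boltzmann sigmoid; see :class:`~apostab.estimators.BoltzmannSigmoid`."""
    est = BoltzmannSigmoid(sloped_baselines=sloped_baselines).fit(np.asarray(x, float), y)
    return TwoStateFit(
        midpoint=est.midpoint_,
        width=est.width_,
        pre=est.pre_,
        post=est.post_,
        pre_slope=est.pre_slope_,
        post_slope=est.post_slope_,
        rmse=est.rmse_,
        converged=est.converged_,
        extrapolated=est.extrapolated_,
        covariance=est.covariance_,
        axis=axis,
        estimator=est,
    )


def vant_hoff_dH(fit: TwoStateFit) -> float:
    """Apparent (relative) van't Hoff enthalpy in kcal/mol.

    At the midpoint the unfolding equilibrium constant satisfies
    ``d ln K / dT = 1/a`` for a Boltzmann transition of width ``a``, so
    ``dH = R * Tm_K**2 / a``.  Depends only on the transition's location and
    width in temperature units — invariant to the observable's scale.
    """
    if not fit.converged:
        raise ValueError("cannot derive dH from an unconverged fit")
    if fit.width <= 0:
        raise ValueError("transition width must be positive")
    if fit.axis != "temperature_C":
        raise ValueError("van't Hoff dH requires a thermal-axis fit")
    tm_k = fit.midpoint + CELSIUS_OFFSET
    return R_KCAL * tm_k**2 / fit.width


def chem_denat_midpoint(series: ChemDenatSeries, sloped_baselines: bool = False) -> TwoStateFit:
    """D1/2 from a lambda-max vs denaturant series (Boltzmann fit).

    Baselines default to flat: lambda-max is bounded (310-420 nm) and does
    not drift linearly with GdnHCl.
    """
    if len(series.denaturant_M) < 6:
        raise ValueError("need at least 6 denaturant points")
    return boltzmann_fit(
        series.denaturant_M, series.lambda_max_nm,
        sloped_baselines=sloped_baselines, axis="denaturant_M",
    )


def lem_free_energy(
    series: ChemDenatSeries,
    fit: TwoStateFit | None = None,
    window: tuple[float, float] = (0.1, 0.9),
    temperature_k: float = LEM_TEMPERATURE_K,
) -> LEMResult:
    """Zero-denaturant free energy by the linear extrapolation method.

    Per-point unfolded fractions come from the fitted baselines; points with
    f_u inside ``window`` (default 0.1-0.9) define K = f_u/(1-f_u) and
    dG(D) = -RT ln K, which is regressed linearly on D.  The intercept is
    dG0 (kcal/mol), the negated slope the m-value (kcal/mol/M).
    """
    if fit is None:
        fit = chem_denat_midpoint(series)
    if not fit.converged:
        raise ValueError("LEM requires a converged two-state fit")

    d = series.denaturant_M
    y = series.lambda_max_nm
    pre = fit.pre + fit.pre_slope * d
    post = fit.post + fit.post_slope * d
    span = post - pre
    if np.any(span == 0):
        raise ValueError("degenerate baselines: zero transition amplitude")
    f_u = (y - pre) / span

    lo, hi = window
    mask = (f_u > lo) & (f_u < hi)
    if int(mask.sum()) < 3:
        raise ValueError(
            f"only {int(mask.sum())} points with f_u in ({lo}, {hi}); need >= 3"
        )
    k = f_u[mask] / (1.0 - f_u[mask])
    dg = -R_KCAL * temperature_k * np.log(k)
    slope, intercept = np.polyfit(d[mask], dg, 1)
    pred = slope * d[mask] + intercept
    ss_res = float(np.sum((dg - pred) ** 2))
    ss_tot = float(np.sum((dg - dg.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    m_value = -float(slope)
    if m_value <= 0:
        raise ValueError("nonpositive m-value: series is not a two-state unfolding")
    dg0 = float(intercept)
    return LEMResult(dg0=dg0, m_value=m_value, d_half=dg0 / m_value,
                     n_points=int(mask.sum()), r_squared=r2)
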