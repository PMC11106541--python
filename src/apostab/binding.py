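"""EC50 estimation from Tm dose-response and ITC titrations.

Both response families are described by a one-site hyperbola on total ligand
concentration, ``response(c) = baseline + amplitude*c/(ec50 + c)`` — the
"simple binding model" convention that reports an EC50 rather than Kd/n.

For ITC, raw per-injection heats are blank-corrected injection-for-injection
(drug-into-buffer titration of identical schedule), the ligand concentration
in the cell is tracked with the perfusion (constant-volume overflow)
convention, and the cumulative corrected heat is fitted to
``Q(c) = q_max*c/(ec50 + c)``.  The per-injection (derivative) form is
retained as an internal cross-check; the two agree exactly on noiseless data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimators import HyperbolicBinding

__all__ = [
    "DoseResponseSeries",
    "BindingFit",
    "ITCExperiment",
    "fit_tm_dose",
    "ligand_concentration",
    "correct_itc",
    "fit_itc",
    "fit_itc_per_injection",
]


@dataclass
class DoseResponseSeries:
    """Apparent Tm versus compound concentration."""

    compound: str
    protein: str
    conc_mM: np.ndarray
    tm_c: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.conc_mM = np.asarray(self.conc_mM, dtype=float)
        self.tm_c = np.asarray(self.tm_c, dtype=float)
        if np.any(self.conc_mM < 0):
            raise ValueError("concentrations must be nonnegative")
        if len(np.unique(self.conc_mM)) < 4:
            raise ValueError("need at least 4 distinct concentrations")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)


@dataclass
class BindingFit:
    """One-site hyperbola fit summary."""

    ec50_mM: float
    amplitude: float
    baseline: float
    rmse: float
    converged: bool
    extrapolated: bool
    covariance: np.ndarray | None = None
    estimator: HyperbolicBinding | None = field(default=None, repr=False)


@dataclass
class ITCExperiment:
    """A titration: sequential ligand injections into the protein cell.

    The blank arrays hold a control titration of the drug into buffer with
    an injection schedule matching the sample injection-for-injection.
    """

    cell_volume_ul: float
    cell_conc_uM: float
    syringe_conc_mM: float
    injection_volumes_ul: np.ndarray
    heats: np.ndarray
    blank_heats: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.injection_volumes_ul = np.asarray(self.injection_volumes_ul, dtype=float)
        self.heats = np.asarray(self.heats, dtype=float)
        if self.cell_volume_ul <= 0 or self.cell_conc_uM <= 0 or self.syringe_conc_mM <= 0:
            raise ValueError("cell volume, cell concentration and syringe concentration must be positive")
        if np.any(self.injection_volumes_ul <= 0):
            raise ValueError("injection volumes must be positive")
        if len(self.heats) != len(self.injection_volumes_ul):
            raise ValueError("heats and injection volumes differ in length")
        if self.blank_heats is not None:
            self.blank_heats = np.asarray(self.blank_heats, dtype=float)
            if len(self.blank_heats) != len(self.heats):
                raise ValueError("blank schedule does not match sample schedule")


def fit_tm_dose(series: DoseResponseSeries, fix_baseline: bool = False) -> BindingFit:
    """EC50 from an apparent-Tm dose response.

    Weighted by 1/SD^2 when replicate SDs are given.  ``fix_baseline`` pins
    the zero-dose Tm instead of fitting it.
    """
    est = HyperbolicBinding(fix_baseline=fix_baseline).fit(
        series.conc_mM, series.tm_c, sample_sd=series.sd
    )
    return BindingFit(
        ec50_mM=est.ec50_,
        amplitude=est.amplitude_,
        baseline=est.baseline_,
        rmse=est.rmse_,
        converged=est.converged_,
        extrapolated=est.extrapolated_,
        covariance=est.covariance_,
        estimator=est,
    )


def ligand_concentration(
    cell_volume_ul: float, syringe_conc_mM: float, injection_volumes_ul
) -> np.ndarray:
    """Cumulative ligand concentration (mM) in the cell after each injection.

    Perfusion convention: the cell volume V stays constant; each injection of
    volume v displaces an equal volume, attenuating everything already in the
    cell by (1 - v/V) before adding v/V of syringe stock:

        c_i = c_{i-1} * (1 - v_i/V) + c_syr * v_i/V
    """
    v = np.asarray(injection_volumes_ul, dtype=float)
    out = np.empty(len(v))
    c = 0.0
    for i, vi in enumerate(v):
        f = vi / cell_volume_ul
        c = c * (1.0 - f) + syringe_conc_mM * f
        out[i] = c
    return out


def correct_itc(exp: ITCExperiment) -> tuple[np.ndarray, np.ndarray]:
    """Blank-corrected per-injection heats and the ligand concentration series.

    Returns ``(corrected_heats, ligand_conc_mM)``; corrected heat i is
    ``raw_i - blank_i``, removing heats of dilution and mixing not related to
    the drug-protein interaction.
    """
    if exp.blank_heats is None:
        raise ValueError("no blank titration attached to this experiment")
    corrected = exp.heats - exp.blank_heats
    conc = ligand_concentration(
        exp.cell_volume_ul, exp.syringe_conc_mM, exp.injection_volumes_ul
    )
    return corrected, conc


def fit_itc(corrected_heats, ligand_conc_mM) -> BindingFit:
    """EC50 from cumulative corrected heat versus ligand concentration.

    The cumulative heat is fitted to ``Q(c) = q_max*c/(ec50 + c)`` (through
    the origin: no ligand, no heat).  Flags ``extrapolated`` when the
    titration never reaches the fitted EC50.
    """
    q = np.cumsum(np.asarray(corrected_heats, dtype=float))
    c = np.asarray(ligand_conc_mM, dtype=float)
    if len(q) < 6:
        raise ValueError("need at least 6 injections")
    if np.allclose(q, 0.0):
        return BindingFit(np.nan, 0.0, 0.0, 0.0, converged=False, extrapolated=False)
    est = HyperbolicBinding(through_origin=True).fit(c, q)
    return BindingFit(
        ec50_mM=est.ec50_,
        amplitude=est.amplitude_,
        baseline=est.baseline_,
        rmse=est.rmse_,
        converged=est.converged_,
        extrapolated=est.extrapolated_,
        covariance=est.covariance_,
        estimator=est,
    )


def fit_itc_per_injection(corrected_heats, ligand_conc_mM) -> BindingFit:
    """EC50 from the per-injection (derivative) heat form — internal oracle.

    Models injection i's heat as ``Q(c_i) - Q(c_{i-1})`` with the same
    hyperbolic Q; on noiseless data this matches :func:`fit_itc` exactly.
    """
    dq = np.asarray(corrected_heats, dtype=float)
    c = np.asarray(ligand_conc_mM, dtype=float)
    if len(dq) < 6:
        raise ValueError("need at least 6 injections")
    c_prev = np.concatenate([[0.0], c[:-1]])

    from scipy.optimize import curve_fit

    def model(x, ec50, qmax):
        ci, cp = x
        return qmax * ci / (ec50 + ci) - qmax * cp / (ec50 + cp)

    if np.allclose(dq, 0.0):
        return BindingFit(np.nan, 0.0, 0.0, 0.0, converged=False, extrapolated=False)
    p0 = [float(np.median(c)), float(np.sum(dq))]
    popt, pcov = curve_fit(model, (c, c_prev), dq, p0=p0,
                           bounds=([1e-12, -np.inf], [np.inf, np.inf]), maxfev=20000)
    resid = dq - model((c, c_prev), *popt)
    return BindingFit(
        ec50_mM=float(popt[0]),
        amplitude=float(popt[1]),
        baseline=0.0,
        rmse=float(np.sqrt(np.mean(resid**2))),
        converged=True,
        extrapolated=bool(c.max() < popt[0]),
        covariance=pcov,
    )
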