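"""Primary-screen hit calling and the ANS-ratio orthogonal screen.

A compound is a primary (TSA) hit when it makes the destabilized mutant melt
like the wild type: the apparent Tm shifts up by at least ``min_shift``,
lands within ``max_wt_gap`` of the WT reference Tm, and the min-max
normalized melt curve is within ``max_curve_rmsd`` of the WT reference
curve.  Compound-alone wells with substantial fluorescence dynamic range are
interference-flagged and excluded.

The orthogonal screen measures ANS (hydrophobic-probe) emission for WT and
mutant protein with each candidate: the destabilized mutant exposes more
hydrophobic surface and binds more ANS, so the WT/mutant peak-intensity
ratio sits well below 1 without compound and rises toward 1 when a compound
corrects the mutant's fold.  Candidates pass when the ratio increase over the
no-compound control is significant by Welch's t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.signal import savgol_filter

from .meltcurves import MeltCurve, TmCall

__all__ = [
    "CompoundRecord",
    "HitCriteria",
    "WellResult",
    "AnsSpectrum",
    "AnsRatioResult",
    "normalized_curve_rmsd",
    "select_hits",
    "ans_peak",
    "ans_ratio_test",
]


@dataclass(frozen=True)
class CompoundRecord:
    """One library compound and its screen-plate position."""

    compound_id: str
    library: str
    plate: int
    well: str
    name: str | None = None
    conc_mM: float = 0.1

    def __post_init__(self) -> None:
        if self.conc_mM <= 0:
            raise ValueError("screen concentration must be positive")


@dataclass
class HitCriteria:
    """Thresholds for primary-screen hit calling (all positive).

    min_shift : minimum Tm(mut+compound) - Tm(mut) in °C.
    max_wt_gap : maximum |Tm(mut+compound) - Tm(WT)| in °C.
    max_curve_rmsd : maximum normalized-curve RMSD versus the WT reference.
    interference_ratio : compound-alone dynamic range, as a fraction of the
        plate's median sample dynamic range, above which the well is
        excluded as compound interference.
    """

    min_shift: float = 5.0
    max_wt_gap: float = 5.0
    max_curve_rmsd: float = 0.10
    interference_ratio: float = 0.5

    def __post_init__(self) -> None:
        for name in ("min_shift", "max_wt_gap", "max_curve_rmsd", "interference_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class WellResult:
    compound: CompoundRecord
    call: TmCall
    shift_c: float | None = None
    wt_gap_c: float | None = None
    curve_rmsd: float | None = None
    interference: bool = False
    hit: bool = False
    reason: str = ""


@dataclass
class AnsSpectrum:
    """ANS emission spectrum (ex 395 nm, em 425-600 nm) for one sample."""

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    protein: str | None = None
    compound: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.wavelengths_nm) != len(self.intensities):
            raise ValueError("wavelength/intensity length mismatch")
        if self.wavelengths_nm.min() < 425 - 1e-9 or self.wavelengths_nm.max() > 600 + 1e-9:
            raise ValueError("ANS emission grid must lie within 425-600 nm")


@dataclass
class AnsRatioResult:
    compound: str | None
    ratio: float  # mean F_WT/F_mut at each protein's own peak
    replicate_ratios: np.ndarray
    control_mean: float
    p_value: float | None
    passed: bool
    flags: set[str] = field(default_factory=set)


def normalized_curve_rmsd(curve_a: MeltCurve, curve_b: MeltCurve) -> float:
    """RMS difference between min-max normalized curves on their common grid.

    Invariant to any vertical affine transform of either curve.  Both curves
    are linearly interpolated onto the union of their temperature points
    within the overlapping range.
    """
    lo = max(curve_a.temperatures[0], curve_b.temperatures[0])
    hi = min(curve_a.temperatures[-1], curve_b.temperatures[-1])
    if lo >= hi:
        raise ValueError("curves have no overlapping temperature range")
    grid = np.union1d(curve_a.temperatures, curve_b.temperatures)
    grid = grid[(grid >= lo) & (grid <= hi)]

    def norm(curve: MeltCurve) -> np.ndarray:
        y = np.interp(grid, curve.temperatures, curve.fluorescence)
        rng = y.max() - y.min()
        if rng == 0:
            return np.zeros_like(y)
        return (y - y.min()) / rng

    return float(np.sqrt(np.mean((norm(curve_a) - norm(curve_b)) ** 2)))


def select_hits(
    wells: list[tuple[CompoundRecord, MeltCurve, TmCall]],
    wt_ref: tuple[TmCall, MeltCurve],
    mut_ref: tuple[TmCall, MeltCurve],
    criteria: HitCriteria | None = None,
    compound_alone_range: dict[str, float] | None = None,
    median_sample_range: float | None = None,
) -> list[WellResult]:
    """Flag hits among screened wells against WT and mutant references.

    ``compound_alone_range`` maps compound_id -> dynamic range (AU) of the
    matching protein-free well; compared against ``interference_ratio`` times
    ``median_sample_range`` (computed from the input curves if not given).
    Deterministic and independent of well order.
    """
    criteria = criteria or HitCriteria()
    wt_call, wt_curve = wt_ref
    mut_call, mut_curve = mut_ref
    if wt_call is None or mut_call is None or not wt_call.ok or not mut_call.ok:
        raise ValueError("valid WT and mutant reference Tm calls are required")

    if median_sample_range is None:
        ranges = [c.dynamic_range for _, c, _ in wells]
        median_sample_range = float(np.median(ranges)) if ranges else 0.0
    interference_cutoff = criteria.interference_ratio * median_sample_range

    out: list[WellResult] = []
    for rec, curve, call in wells:
        res = WellResult(compound=rec, call=call)
        if compound_alone_range is not None:
            alone = compound_alone_range.get(rec.compound_id, 0.0)
            res.interference = alone > interference_cutoff
        if not call.ok:
            res.reason = "no_tm_call"
            out.append(res)
            continue
        res.shift_c = call.tm_c - mut_call.tm_c
        res.wt_gap_c = abs(call.tm_c - wt_call.tm_c)
        res.curve_rmsd = normalized_curve_rmsd(curve, wt_curve)
        if res.interference:
            res.reason = "compound_interference"
        elif res.shift_c < criteria.min_shift:
            res.reason = "shift_below_min"
        elif res.wt_gap_c > criteria.max_wt_gap:
            res.reason = "wt_gap_exceeded"
        elif res.curve_rmsd > criteria.max_curve_rmsd:
            res.reason = "curve_dissimilar"
        else:
            res.hit = True
        out.append(res)
    return out


def ans_peak(spectrum: AnsSpectrum, window: int = 7, order: int = 2) -> tuple[float, float, bool]:
    """(peak wavelength nm, peak intensity AU, flagged) of the smoothed spectrum.

    ``flagged`` is True for an all-zero (or negative-only) spectrum, whose
    peak intensity is reported as 0.
    """
    y = spectrum.intensities
    if len(y) > window:
        y = savgol_filter(y, window, order)
    if np.all(spectrum.intensities <= 0):
        return float(spectrum.wavelengths_nm[0]), 0.0, True
    i = int(np.argmax(y))
    return float(spectrum.wavelengths_nm[i]), float(y[i]), False


def ans_ratio_test(
    wt_reps: list[AnsSpectrum],
    mut_reps: list[AnsSpectrum],
    control_ratios,
    alpha: float = 0.01,
    compound: str | None = None,
) -> AnsRatioResult:
    """WT/mutant ANS peak-intensity ratio with a Welch test against control.

    The ratio is taken at each protein's own peak intensity (robust to small
    peak-wavelength shifts).  Pass requires the compound-treated mean ratio
    to exceed the control mean AND p < alpha.  With a single replicate pair
    no test is possible; the result is flagged and not passed.
    """
    if len(wt_reps) != len(mut_reps) or len(wt_reps) == 0:
        raise ValueError("need matched WT/mutant replicate spectra")
    ratios = []
    flags: set[str] = set()
    for wt, mut in zip(wt_reps, mut_reps):
        _, wt_peak, wt_flag = ans_peak(wt)
        _, mut_peak, mut_flag = ans_peak(mut)
        if wt_flag or mut_flag or mut_peak <= 0:
            flags.add("degenerate_spectrum")
            continue
        ratios.append(wt_peak / mut_peak)
    ratios = np.asarray(ratios, dtype=float)
    control_ratios = np.asarray(control_ratios, dtype=float)
    if len(ratios) == 0:
        return AnsRatioResult(compound, np.nan, ratios, float(np.mean(control_ratios)),
                              None, False, flags | {"no_usable_replicates"})
    if len(ratios) < 2 or len(control_ratios) < 2:
        flags.add("single_replicate")
        return AnsRatioResult(compound, float(ratios.mean()), ratios,
                              float(control_ratios.mean()), None, False, flags)
    if ratios.std(ddof=1) == 0 and control_ratios.std(ddof=1) == 0:
        p = 1.0 if ratios.mean() == control_ratios.mean() else 0.0
    else:
        _, p = stats.ttest_ind(ratios, control_ratios, equal_var=False)
        p = float(p)
    passed = bool(ratios.mean() > control_ratios.mean() and p < alpha)
    return AnsRatioResult(compound, float(ratios.mean()), ratios,
                          float(control_ratios.mean()), p, passed, flags)
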