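"""Macrophage viability and cholesterol-efflux statistics.

Viability (MTT, formazan absorbance at 550 nm) is expressed relative to
untreated control wells set to 100%.  Cholesterol efflux partitions labelled
cholesterol counts between medium and cells; the ABCA1-specific (net) efflux
is the cAMP-stimulated minus the unstimulated efflux.  Group comparisons use
Welch's t-test with the conventional figure-legend significance tiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ViabilityRecord",
    "EffluxRecord",
    "GroupComparison",
    "viability_percent",
    "efflux_percent",
    "net_abca1_efflux",
    "compare_groups",
    "SIGNIFICANCE_TIERS",
]

# (alpha, label), most stringent first; matches the figure-legend convention
SIGNIFICANCE_TIERS: tuple[tuple[float, str], ...] = (
    (0.0001, "***"),
    (0.005, "**"),
    (0.05, "*"),
)


@dataclass
class ViabilityRecord:
    """Replicate MTT absorbances for one compound/concentration, with controls."""

    compound: str
    conc_mM: float
    absorbances: np.ndarray
    control_absorbances: np.ndarray

    def __post_init__(self) -> None:
        self.absorbances = np.asarray(self.absorbances, dtype=float)
        self.control_absorbances = np.asarray(self.control_absorbances, dtype=float)
        if len(self.absorbances) < 2 or len(self.control_absorbances) < 2:
            raise ValueError("need at least 2 replicates per arm")
        if np.any(self.absorbances < 0) or np.any(self.control_absorbances < 0):
            raise ValueError("absorbances must be nonnegative")


@dataclass
class EffluxRecord:
    """Replicate (cpm_medium, cpm_cells) pairs for one efflux condition."""

    protein: str
    camp_treated: bool
    cpm_medium: np.ndarray
    cpm_cells: np.ndarray
    compound: str | None = None
    conc_mM: float | None = None

    def __post_init__(self) -> None:
        self.cpm_medium = np.asarray(self.cpm_medium, dtype=float)
        self.cpm_cells = np.asarray(self.cpm_cells, dtype=float)
        if len(self.cpm_medium) != len(self.cpm_cells):
            raise ValueError("medium and cell counts differ in length")
        if np.any(self.cpm_medium < 0) or np.any(self.cpm_cells < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(self.cpm_medium + self.cpm_cells <= 0):
            raise ValueError("total counts must be positive in every replicate")

    def efflux_percents(self) -> np.ndarray:
        return efflux_percent(self.cpm_medium, self.cpm_cells)


@dataclass
class GroupComparison:
    labels: tuple[str, str]
    means: tuple[float, float]
    sds: tuple[float, float]
    statistic: float
    p_value: float
    tier: str  # "", "*", "**" or "***"


def viability_percent(record: ViabilityRecord) -> tuple[float, float]:
    """Mean and SD of per-replicate viability, percent of the control mean."""
    ctrl = float(record.control_absorbances.mean())
    if ctrl <= 0:
        raise ValueError("control mean absorbance must be positive")
    pct = 100.0 * record.absorbances / ctrl
    return float(pct.mean()), float(pct.std(ddof=1))


def efflux_percent(cpm_medium, cpm_cells):
    """Percent of total counts released into the medium.

    ``100 * medium / (medium + cells)``; always in [0, 100] and invariant to
    scaling both counts by the same positive factor.
    """
    med = np.asarray(cpm_medium, dtype=float)
    cel = np.asarray(cpm_cells, dtype=float)
    if np.any(med < 0) or np.any(cel < 0):
        raise ValueError("counts must be nonnegative")
    total = med + cel
    if np.any(total <= 0):
        raise ValueError("total counts must be positive")
    # divide before scaling: med/total <= 1 exactly, so the bound holds in floats
    return (med / total) * 100.0


def net_abca1_efflux(plus_camp: EffluxRecord, minus_camp: EffluxRecord) -> tuple[float, float]:
    """ABCA1-mediated (cAMP-dependent) efflux: mean(+cAMP) - mean(-cAMP).

    SDs of the two arms are propagated in quadrature.  The two records must
    describe the same protein/compound/concentration condition.
    """
    if not plus_camp.camp_treated or minus_camp.camp_treated:
        raise ValueError("expected one +cAMP and one -cAMP record, in that order")
    for attr in ("protein", "compound", "conc_mM"):
        if getattr(plus_camp, attr) != getattr(minus_camp, attr):
            raise ValueError(f"condition mismatch between +/-cAMP records: {attr}")
    a = plus_camp.efflux_percents()
    b = minus_camp.efflux_percents()
    net = float(a.mean() - b.mean())
    sd = float(np.sqrt(a.std(ddof=1) ** 2 + b.std(ddof=1) ** 2)) if len(a) > 1 and len(b) > 1 else np.nan
    return net, sd


def _tier(p: float) -> str:
    for alpha, label in SIGNIFICANCE_TIERS:
        if p < alpha:
            return label
    return ""


def compare_groups(a, b, labels: tuple[str, str] = ("a", "b")) -> GroupComparison:
    """Welch two-sample t-test with figure-legend significance tiers."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 replicates per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # degenerate: no within-group variance -> no basis for a t-test
        p = 1.0 if a.mean() == b.mean() else 0.0
        t = 0.0 if a.mean() == b.mean() else np.inf
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
        t, p = float(t), float(p)
    return GroupComparison(
        labels=labels,
        means=(float(a.mean()), float(b.mean())),
        sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        statistic=t,
        p_value=p,
        tier=_tier(p),
    )
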