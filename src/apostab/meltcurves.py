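"""Single melt-curve processing for thermal shift (DSF) assays.

A melt curve is the fluorescence of an environment-sensitive dye (e.g. SYPRO
Orange) recorded while the sample temperature is ramped.  The apparent melting
temperature Tm is read off as the location of the minimum of the negative
first derivative -dF/dT, after light smoothing.  The functions here implement
that chain — :func:`smooth`, :func:`neg_derivative`, :func:`call_tm` — plus
quality flags so that protein-free or dye-only wells never yield a Tm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "MeltCurve",
    "DerivativeCurve",
    "TmCall",
    "smooth",
    "neg_derivative",
    "call_tm",
    "tm_from_curve",
]


@dataclass
class MeltCurve:
    """Temperature-indexed fluorescence for one well.

    Parameters
    ----------
    well : str
        Plate-well identifier, e.g. ``"A1"``.
    temperatures : ndarray
        Strictly increasing, in degrees Celsius; at least 5 points.
    fluorescence : ndarray
        Same length as ``temperatures``, arbitrary units.
    protein, compound : str or None
        Sample annotations; ``compound`` is None for protein-only wells.
    conc_mM : float or None
        Compound concentration in mM.
    metadata : dict
        Free-form provenance (generative parameters, plate, role ...).
    """

    well: str
    temperatures: np.ndarray
    fluorescence: np.ndarray
    protein: str | None = None
    compound: str | None = None
    conc_mM: float | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.ndim != 1 or self.fluorescence.ndim != 1:
            raise ValueError("temperatures and fluorescence must be 1-D")
        if len(self.temperatures) != len(self.fluorescence):
            raise ValueError("temperatures and fluorescence differ in length")
        if len(self.temperatures) < 5:
            raise ValueError("melt curve needs at least 5 points")
        if not np.all(np.diff(self.temperatures) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValueError("fluorescence contains non-finite values")

    @property
    def dynamic_range(self) -> float:
        """Max minus min fluorescence (AU)."""
        return float(self.fluorescence.max() - self.fluorescence.min())


@dataclass
class DerivativeCurve:
    """Negative first derivative -dF/dT of a melt curve."""

    temperatures: np.ndarray
    neg_dfdt: np.ndarray
    source_range: float = 0.0  # dynamic range (AU) of the source fluorescence

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.neg_dfdt = np.asarray(self.neg_dfdt, dtype=float)
        if len(self.temperatures) != len(self.neg_dfdt):
            raise ValueError("length mismatch in derivative curve")


@dataclass
class TmCall:
    """Apparent-Tm call with quality flags.

    ``tm_c`` is None when the curve is flat (no transition to call); the
    ``flags`` set then contains ``"flat_curve"``.
    """

    tm_c: float | None
    depth: float | None
    window: tuple[float, float]
    flags: set[str] = field(default_factory=set)

    @property
    def ok(self) -> bool:
        return self.tm_c is not None


def smooth(curve: MeltCurve, window: int = 7, order: int = 2) -> MeltCurve:
    """Savitzky-Golay smoothing of the fluorescence trace.

    ``window`` must be odd and >= 3; ``order`` < ``window``.  Exact on
    polynomial signals of degree <= ``order``.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("smoothing window must be an odd integer >= 3")
    if order >= window:
        raise ValueError("polynomial order must be smaller than the window")
    if window >= len(curve.temperatures):
        raise ValueError("smoothing window must be shorter than the curve")
    y = savgol_filter(curve.fluorescence, window, order)
    meta = dict(curve.metadata)
    meta["smoothing"] = {"window": window, "order": order}
    return replace(curve, fluorescence=y, metadata=meta)


def neg_derivative(curve: MeltCurve) -> DerivativeCurve:
    """-dF/dT by central divided differences (one-sided at the endpoints).

    Handles non-uniform temperature grids; duplicate temperatures are
    rejected upstream by the MeltCurve invariant.
    """
    t, f = curve.temperatures, curve.fluorescence
    dfdt = np.gradient(f, t)
    return DerivativeCurve(t, -dfdt, source_range=curve.dynamic_range)


def _parabolic_vertex(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through points i-1, i, i+1 (grid minimum refinement)."""
    if i == 0 or i == len(x) - 1:
        return float(x[i]), float(y[i])
    x0, x1, x2 = x[i - 1 : i + 2]
    y0, y1, y2 = y[i - 1 : i + 2]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a <= 0:  # not convex around the minimum; keep the grid point
        return float(x[i]), float(y[i])
    xv = -b / (2 * a)
    c = (
        y0
        - a * x0**2
        - b * x0
    )
    yv = a * xv**2 + b * xv + c
    # never leave the bracketing interval
    xv = float(np.clip(xv, x0, x2))
    return xv, float(yv)


def call_tm(
    deriv: DerivativeCurve,
    search: tuple[float, float] | None = None,
    flat_threshold: float = 0.0,
    multi_min_depth: float = 0.10,
) -> TmCall:
    """Call the apparent Tm as the minimum of -dF/dT inside ``search``.

    The grid minimum is refined by a 3-point parabola.  Flags:

    - ``flat_curve``: source dynamic range <= ``flat_threshold`` (AU); no Tm
      is returned.  A threshold of ~5% of the plate's median sample dynamic
      range keeps compound-only and dye-only wells from producing calls.
    - ``edge_minimum``: the grid minimum touches a window edge.
    - ``multiple_minima``: a second local minimum lies within
      ``multi_min_depth`` of the global one (fraction of the derivative's
      in-window range).
    """
    t, d = deriv.temperatures, deriv.neg_dfdt
    if search is None:
        search = (float(t[0]) + 2.0, float(t[-1]) - 2.0)
    lo, hi = search
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9 or lo >= hi:
        raise ValueError("search window must lie inside the data range")

    # 1e-9 absolute floor: smoothing a constant trace leaves float dust
    if deriv.source_range <= max(flat_threshold, 1e-9):
        return TmCall(None, None, (lo, hi), flags={"flat_curve"})

    mask = (t >= lo) & (t <= hi)
    idx = np.flatnonzero(mask)
    if len(idx) < 3:
        raise ValueError("search window contains fewer than 3 points")
    tw, dw = t[idx], d[idx]

    j = int(np.argmin(dw))
    flags: set[str] = set()
    if j == 0 or j == len(dw) - 1:
        flags.add("edge_minimum")

    # secondary local minima within multi_min_depth of the global minimum
    rng = float(dw.max() - dw.min())
    if rng > 0:
        interior = np.arange(1, len(dw) - 1)
        local_min = interior[(dw[interior] < dw[interior - 1]) & (dw[interior] <= dw[interior + 1])]
        close = [k for k in local_min if k != j and (dw[k] - dw[j]) <= multi_min_depth * rng]
        if close:
            flags.add("multiple_minima")

    tm, depth = _parabolic_vertex(tw, dw, j)
    tm = float(np.clip(tm, lo, hi))
    return TmCall(tm, depth, (lo, hi), flags=flags)


def tm_from_curve(
    curve: MeltCurve,
    window: int = 7,
    order: int = 2,
    search: tuple[float, float] | None = None,
    flat_threshold: float = 0.0,
) -> TmCall:
    """Convenience chain: smooth -> -dF/dT -> call_tm."""
    return call_tm(neg_derivative(smooth(curve, window, order)), search, flat_threshold)
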