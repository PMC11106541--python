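"""Scikit-learn-style nonlinear curve estimators.

Two regressors carry all of the package's nonlinear least-squares work:

``BoltzmannSigmoid``
    The two-state unfolding sigmoid
    ``y = y_pre + (y_post - y_pre) / (1 + exp((x50 - x)/a))``,
    optionally with linear pre/post baselines.  ``x`` may be a temperature
    (°C) or a denaturant concentration (M); ``x50`` is then the apparent Tm
    or the denaturation midpoint D1/2, and ``a`` the transition width.

``HyperbolicBinding``
    The one-site binding hyperbola
    ``y = baseline + amplitude * c / (ec50 + c)``
    used for apparent-Tm dose responses and ITC cumulative heats.

Both follow the estimator contract: ``fit(X, y)``, ``predict(X)``,
``get_params``/``set_params``, fitted attributes with trailing underscores.
Fit failures set ``converged_ = False`` instead of raising, so plate-scale
batch fitting never aborts on one bad well.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["BoltzmannSigmoid", "HyperbolicBinding"]


def _as_1d(X) -> np.ndarray:
    x = np.asarray(X, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x[:, 0]
    if x.ndim != 1:
        raise ValueError("expected a 1-D array or single-column 2-D array")
    return x


class BoltzmannSigmoid(RegressorMixin, BaseEstimator):
    """Two-state (Boltzmann) sigmoid fit by bounded nonlinear least squares.

    Parameters
    ----------
    sloped_baselines : bool, default False
        Fit linear pre- and post-transition baselines instead of constants.
        Recommended ON for CD thermal scans, OFF for bounded observables
        such as tryptophan lambda-max.

    Attributes
    ----------
    midpoint_ : float
        Transition midpoint (Tm or D1/2), in the units of ``X``.
    width_ : float
        Transition width ``a`` (> 0), same units.
    pre_, post_ : float
        Baseline values (intercepts when ``sloped_baselines``).
    pre_slope_, post_slope_ : float
        Baseline slopes (0.0 when ``sloped_baselines=False``).
    covariance_ : ndarray
        Parameter covariance from the fit.
    rmse_ : float
    converged_ : bool
    extrapolated_ : bool
        True when the fitted midpoint falls outside the data range.
    """

    def __init__(self, sloped_baselines: bool = False):
        self.sloped_baselines = sloped_baselines

    @staticmethod
    def _model_flat(x, x50, a, y_pre, y_post):
        s = 1.0 / (1.0 + np.exp(np.clip((x50 - x) / a, -500, 500)))
        return y_pre + (y_post - y_pre) * s

    @staticmethod
    def _model_sloped(x, x50, a, y_pre, y_post, m_pre, m_post):
        s = 1.0 / (1.0 + np.exp(np.clip((x50 - x) / a, -500, 500)))
        pre = y_pre + m_pre * x
        post = y_post + m_post * x
        return pre + (post - pre) * s

    def _initial_guess(self, x: np.ndarray, y: np.ndarray) -> list[float]:
        # sign-agnostic: works for rising fluorescence and falling |theta222|
        y_lo, y_hi = float(y[0]), float(y[-1])
        span = y_hi - y_lo
        if span == 0:
            span = float(y.max() - y.min()) or 1.0
        half = y_lo + span / 2.0
        # x at half dynamic range, scanning in x order
        crossings = np.flatnonzero(np.diff(np.sign(y - half)) != 0)
        x50 = float(x[crossings[0]]) if len(crossings) else float(np.median(x))
        a = (x[-1] - x[0]) / 10.0
        guess = [x50, a, y_lo, y_hi]
        if self.sloped_baselines:
            guess += [0.0, 0.0]
        return guess

    def fit(self, X, y):
        x = _as_1d(X)
        y = np.asarray(y, dtype=float)
        if len(x) != len(y):
            raise ValueError("X and y differ in length")
        if len(x) < 6:
            raise ValueError("need at least 6 points for a two-state fit")
        if not np.all(np.diff(x) > 0):
            raise ValueError("X must be strictly increasing")

        model = self._model_sloped if self.sloped_baselines else self._model_flat
        p0 = self._initial_guess(x, y)
        nparam = len(p0)
        lower = [-np.inf] * nparam
        upper = [np.inf] * nparam
        lower[1] = 1e-9  # width strictly positive
        self.converged_ = True
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, pcov = curve_fit(
                    model, x, y, p0=p0, bounds=(lower, upper), maxfev=20000
                )
        except (RuntimeError, ValueError):
            popt = np.array(p0)
            pcov = np.full((nparam, nparam), np.nan)
            self.converged_ = False

        self.midpoint_ = float(popt[0])
        self.width_ = float(popt[1])
        self.pre_ = float(popt[2])
        self.post_ = float(popt[3])
        if self.sloped_baselines:
            self.pre_slope_ = float(popt[4])
            self.post_slope_ = float(popt[5])
        else:
            self.pre_slope_ = 0.0
            self.post_slope_ = 0.0
        self.covariance_ = pcov
        resid = y - model(x, *popt)
        self.rmse_ = float(np.sqrt(np.mean(resid**2)))
        self.extrapolated_ = not (x[0] <= self.midpoint_ <= x[-1])
        self.x_range_ = (float(x[0]), float(x[-1]))
        return self

    def predict(self, X):
        check_is_fitted(self, "midpoint_")
        x = _as_1d(X)
        if self.sloped_baselines:
            return self._model_sloped(
                x, self.midpoint_, self.width_, self.pre_, self.post_,
                self.pre_slope_, self.post_slope_,
            )
        return self._model_flat(x, self.midpoint_, self.width_, self.pre_, self.post_)

    def fraction_unfolded(self, X):
        """Fraction in the post-transition state at each x, from the fitted baselines."""
        check_is_fitted(self, "midpoint_")
        x = _as_1d(X)
        return 1.0 / (1.0 + np.exp(np.clip((self.midpoint_ - x) / self.width_, -500, 500)))


class HyperbolicBinding(RegressorMixin, BaseEstimator):
    """One-site binding hyperbola ``baseline + amplitude*c/(ec50+c)``.

    Parameters
    ----------
    fix_baseline : bool, default False
        Pin the baseline to the mean response at c = 0 (requires zero-dose
        points) instead of fitting it.
    through_origin : bool, default False
        Force ``baseline = 0`` (ITC cumulative heat convention).

    Attributes
    ----------
    ec50_ : float
        Half-saturation concentration, in the units of ``X`` (mM here).
    amplitude_ : float
        Saturating response change.
    baseline_ : float
    covariance_ : ndarray
    rmse_ : float
    converged_ : bool
    extrapolated_ : bool
        True when max(c) < fitted ec50 (saturation never approached).
    """

    def __init__(self, fix_baseline: bool = False, through_origin: bool = False):
        self.fix_baseline = fix_baseline
        self.through_origin = through_origin

    def fit(self, X, y, sample_sd=None):
        c = _as_1d(X)
        y = np.asarray(y, dtype=float)
        if len(c) != len(y):
            raise ValueError("X and y differ in length")
        if np.any(c < 0):
            raise ValueError("concentrations must be nonnegative")
        if len(np.unique(c)) < 4:
            raise ValueError("need at least 4 distinct concentrations")

        sigma = None
        if sample_sd is not None:
            sigma = np.asarray(sample_sd, dtype=float)
            sigma = np.where(sigma > 0, sigma, np.nanmin(sigma[sigma > 0]) if np.any(sigma > 0) else 1.0)

        baseline0 = float(np.mean(y[c == 0])) if np.any(c == 0) else float(y[np.argmin(c)])
        if self.through_origin:
            baseline0 = 0.0
        span = float(y[np.argmax(c)] - baseline0)
        if span == 0:
            span = float(y.max() - y.min())
        ec50_0 = float(np.median(c[c > 0])) if np.any(c > 0) else 1.0

        self.converged_ = True
        fixed_base = self.fix_baseline or self.through_origin
        if fixed_base:
            def model(cc, ec50, amp):
                return baseline0 + amp * cc / (ec50 + cc)
            p0 = [ec50_0, span if span != 0 else 1.0]
            bounds = ([1e-12, -np.inf], [np.inf, np.inf])
        else:
            def model(cc, ec50, amp, base):
                return base + amp * cc / (ec50 + cc)
            p0 = [ec50_0, span if span != 0 else 1.0, baseline0]
            bounds = ([1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf])

        if np.allclose(y, y[0]):
            self.converged_ = False
            popt = np.array(p0)
            pcov = np.full((len(p0), len(p0)), np.nan)
        else:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", OptimizeWarning)
                    popt, pcov = curve_fit(
                        model, c, y, p0=p0, sigma=sigma, bounds=bounds,
                        maxfev=20000,
                    )
            except (RuntimeError, ValueError):
                popt = np.array(p0)
                pcov = np.full((len(p0), len(p0)), np.nan)
                self.converged_ = False

        self.ec50_ = float(popt[0])
        self.amplitude_ = float(popt[1])
        self.baseline_ = baseline0 if fixed_base else float(popt[2])
        self.covariance_ = pcov
        resid = y - model(c, *popt)
        self.rmse_ = float(np.sqrt(np.mean(resid**2)))
        self.extrapolated_ = bool(self.converged_ and c.max() < self.ec50_)
        if self.converged_ and self.ec50_ <= 0:
            self.converged_ = False
        return self

    def predict(self, X):
        check_is_fitted(self, "ec50_")
        c = _as_1d(X)
        return self.baseline_ + self.amplitude_ * c / (self.ec50_ + c)
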