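"""Single-group cosinor fitting and rhythm arithmetic.

The cosinor model is the sinusoidal regression

    Y_i = A * cos(2*pi/P * (t_i - phi)) + M + eps_i,   eps_i ~ N(0, sigma^2)

with period ``P`` (24 h for circadian data), amplitude ``A >= 0``, acrophase
``phi`` (peak time, hours in ``[0, P)``) and MESOR ``M`` (rhythm-adjusted
mean).  Expanding the cosine linearizes the model to

    Y_i = a * sin(w t_i) + b * cos(w t_i) + M,   w = 2*pi/P

with ``a = A sin(w phi)``, ``b = A cos(w phi)``, so the fit is ordinary least
squares and ``(A, phi) = (sqrt(a^2+b^2), atan2(a, b)/w mod P)``.

Conventions used throughout the package:

* ``sigma^2`` is the maximum-likelihood estimate RSS/n (denominator ``n``,
  not ``n - 3``) so that ``loglik`` is the exactly maximized Gaussian
  likelihood entering every likelihood-ratio statistic downstream.
* ``phi`` of a flat fit is 0 with the ``degenerate`` flag set; callers must
  check the flag before interpreting the phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CosinorFit",
    "fit_cosinor",
    "rhythm_test",
    "wrap_phase_diff",
    "r2_from_snr",
    "snr_from_r2",
    "gaussian_loglik",
    "design_matrix",
]

#: relative residual threshold below which a fit counts as numerically perfect
DEGENERATE_RTOL = 1e-12
#: absolute amplitude below which the phase is unidentifiable
DEGENERATE_AMP = 1e-12

MIN_SAMPLES = 5


@dataclass(frozen=True)
class CosinorFit:
    """Maximum-likelihood cosinor fit for one biomarker in one group.

    Attributes
    ----------
    a, b : float
        Linearized sine / cosine coefficients (expression units).
    amplitude : float
        ``A = sqrt(a^2 + b^2) >= 0``.
    phase : float
        Peak time in hours, ``[0, period)``; 0 by convention when degenerate.
    mesor : float
        Rhythm-adjusted mean ``M``.
    sigma : float
        Residual SD, MLE convention ``sqrt(RSS / n)``.
    r2 : float
        Coefficient of determination of the rhythm, in ``[0, 1]``.
    loglik : float
        Maximized Gaussian log-likelihood; ``+inf`` for a zero-residual fit.
    n : int
        Sample count.
    p_rhythm : float
        Rhythmicity p-value (full model vs intercept-only).
    degenerate : bool
        True when residuals are numerically zero or the amplitude is
        numerically zero.
    period : float
        Period ``P`` in hours.
    """

    a: float
    b: float
    amplitude: float
    phase: float
    mesor: float
    sigma: float
    r2: float
    loglik: float
    n: int
    p_rhythm: float
    degenerate: bool
    period: float

    @property
    def snr(self) -> float:
        """Signal-to-noise ratio A / sigma (``inf`` for a noise-free fit)."""
        if self.sigma == 0.0:
            return math.inf if self.amplitude > 0 else 0.0
        return self.amplitude / self.sigma

    def predict(self, t: np.ndarray) -> np.ndarray:
        """Fitted curve ``A cos(w (t - phi)) + M`` evaluated at times ``t``."""
        w = 2.0 * math.pi / self.period
        return self.amplitude * np.cos(w * (np.asarray(t, float) - self.phase)) + self.mesor


def design_matrix(t: np.ndarray, period: float) -> np.ndarray:
    """Cosinor design ``[sin(wt), cos(wt), 1]`` with ``w = 2 pi / period``."""
    t = np.asarray(t, dtype=float)
    w = 2.0 * math.pi / period
    return np.column_stack([np.sin(w * t), np.cos(w * t), np.ones_like(t)])


def gaussian_loglik(rss: float, n: int) -> float:
    """Maximized Gaussian log-likelihood ``-(n/2)(log(2 pi sigma^2) + 1)``.

    ``sigma^2 = rss / n`` is profiled out; returns ``+inf`` when ``rss`` is 0.
    """
    if rss <= 0.0:
        return math.inf
    return -0.5 * n * (math.log(2.0 * math.pi * rss / n) + 1.0)


def _check_inputs(y: np.ndarray, t: np.ndarray, period: float) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    t = np.asarray(t, dtype=float).ravel()
    if y.shape != t.shape:
        raise ValueError(f"y and t have different lengths ({y.size} vs {t.size})")
    if y.size < MIN_SAMPLES:
        raise ValueError(
            f"cosinor fit needs at least {MIN_SAMPLES} samples, got {y.size}"
        )
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(t)):
        raise ValueError("y and t must be finite")
    if not period > 0:
        raise ValueError(f"period must be positive, got {period}")
    return y, t


def _ols_rss(y: np.ndarray, t: np.ndarray, period: float) -> tuple[np.ndarray, float]:
    """OLS coefficients (a, b, M) and residual sum of squares."""
    X = design_matrix(t, period)
    # rank check: all t congruent mod P collapses sin/cos to constants
    if np.linalg.matrix_rank(X, tol=1e-10) < 3:
        tmod = np.unique(np.round(np.mod(t, period), 9))
        raise ValueError(
            "rank-deficient cosinor design: sampling times "
            f"{tmod.tolist()} (mod period={period}) do not identify the rhythm"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    return beta, rss


def fit_cosinor(
    y: np.ndarray,
    t: np.ndarray,
    period: float = 24.0,
    rhythm_method: str = "F",
) -> CosinorFit:
    """Fit the cosinor model to one biomarker by ordinary least squares.

    Parameters
    ----------
    y : array-like
        Observations (log-scale expression), length ``n >= 5``.
    t : array-like
        Sampling times in hours (Zeitgeber Time; used mod ``period``).
    period : float
        Rhythm period ``P`` in hours, default 24.
    rhythm_method : {"F", "LRT"}
        Test used to populate ``p_rhythm``.

    Returns
    -------
    CosinorFit

    Raises
    ------
    ValueError
        For ``n < 5`` or a rank-deficient time design.
    """
    y, t = _check_inputs(y, t, period)
    n = y.size
    beta, rss = _ols_rss(y, t, period)
    a, b, mesor = (float(v) for v in beta)
    amplitude = math.hypot(a, b)
    tss = float(np.sum((y - y.mean()) ** 2))

    degenerate = (tss > 0 and rss < DEGENERATE_RTOL * tss) or amplitude < DEGENERATE_AMP
    if tss == 0.0:
        # constant signal: nothing to explain
        rss = 0.0
        degenerate = True

    if amplitude < DEGENERATE_AMP:
        phase = 0.0
    else:
        w = 2.0 * math.pi / period
        phase = math.atan2(a, b) / w % period

    sigma = math.sqrt(max(rss, 0.0) / n)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    r2 = min(max(r2, 0.0), 1.0)
    loglik = gaussian_loglik(rss, n)

    _, _, p_rhythm = _rhythm_test_from_rss(tss, rss, n, rhythm_method)

    return CosinorFit(
        a=a,
        b=b,
        amplitude=amplitude,
        phase=phase,
        mesor=mesor,
        sigma=sigma,
        r2=r2,
        loglik=loglik,
        n=n,
        p_rhythm=p_rhythm,
        degenerate=degenerate,
        period=period,
    )


def _rhythm_test_from_rss(
    rss0: float, rss1: float, n: int, method: str
) -> tuple[float, int | tuple[int, int], float]:
    method = method.upper()
    if method not in {"F", "LRT"}:
        raise ValueError(f"unknown rhythm test method {method!r}; use 'F' or 'LRT'")
    if rss0 <= 0.0:
        # flat data: the rhythm explains nothing
        return (0.0, 2 if method == "LRT" else (2, n - 3), 1.0)
    if rss1 < DEGENERATE_RTOL * rss0:
        # numerically perfect rhythm: +inf sentinel, p = 0
        return (math.inf, 2 if method == "LRT" else (2, n - 3), 0.0)
    if method == "LRT":
        stat = n * math.log(rss0 / rss1)
        return stat, 2, float(stats.chi2.sf(stat, 2))
    stat = ((rss0 - rss1) / 2.0) / (rss1 / (n - 3))
    return stat, (2, n - 3), float(stats.f.sf(stat, 2, n - 3))


def rhythm_test(
    y: np.ndarray, t: np.ndarray, period: float = 24.0, method: str = "F"
) -> tuple[float, int | tuple[int, int], float]:
    """Test for rhythmicity against the intercept-only null.

    ``method="F"`` uses the exact finite-sample F test with degrees of
    freedom ``(2, n - 3)``; ``method="LRT"`` the asymptotic likelihood-ratio
    statistic ``n log(RSS0 / RSS1)`` against chi-square(2).  A numerically
    perfect fit returns ``(inf, df, 0.0)``.

    Returns
    -------
    (statistic, df, p_value)
        ``df`` is the integer chi-square df for the LRT and the pair
        ``(2, n - 3)`` for the F test.
    """
    y, t = _check_inputs(y, t, period)
    n = y.size
    _, rss1 = _ols_rss(y, t, period)
    rss0 = float(np.sum((y - y.mean()) ** 2))
    return _rhythm_test_from_rss(rss0, rss1, n, method)


def wrap_phase_diff(phi_ref: float, phi_cmp: float, period: float = 24.0) -> float:
    """Circular phase difference ``phi_cmp - phi_ref`` wrapped to ``(-P/2, P/2]``.

    Positive values mean the comparison group peaks later than the reference.
    The antipodal difference maps to ``+P/2`` (never ``-P/2``).
    """
    if not (np.isfinite(phi_ref) and np.isfinite(phi_cmp)):
        raise ValueError("phases must be finite")
    d = (phi_cmp - phi_ref) % period
    if d > period / 2.0:
        d -= period
    return float(d)


def r2_from_snr(snr: float) -> float:
    """Population cosinor R^2 implied by a signal-to-noise ratio ``A/sigma``.

    Under sampling spread uniformly over the cycle the rhythm contributes
    variance ``A^2/2`` on top of noise variance ``sigma^2``, so

        R^2 = (A^2/2) / (A^2/2 + sigma^2) = snr^2 / (snr^2 + 2).

    Strictly increasing in ``snr``; 0 at ``snr = 0``.
    """
    if snr < 0:
        raise ValueError(f"snr must be nonnegative, got {snr}")
    return snr * snr / (snr * snr + 2.0)


def snr_from_r2(r2: float) -> float:
    """Inverse of :func:`r2_from_snr`: ``sqrt(2 r2 / (1 - r2))``."""
    if not 0.0 <= r2 < 1.0:
        raise ValueError(f"r2 must lie in [0, 1), got {r2}")
    return math.sqrt(2.0 * r2 / (1.0 - r2))
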