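"""Clench (Michaelis-Menten-type) saturation model for accumulation curves.

The model

    S(t) = a * t / (1 + b * t)

predicts richness at sampling effort ``t`` (nights); ``a`` is the initial
accumulation rate (taxa per night) and ``b`` a shape parameter, so the
asymptotic richness is ``a / b``.  Fitting it to an averaged accumulation
curve lets surveys of unequal length be extrapolated and compared, and
the effort needed to reach a fraction ``q`` of the asymptote has the
closed form ``t_q = q / ((1 - q) * b)`` — e.g. ``9 / b`` nights for the
customary 90 % completeness threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .accumulation import AccumulationCurve

__all__ = [
    "ClenchFit",
    "clench_predict",
    "fit_clench",
    "effort_to_fraction",
    "effort_to_fraction_nights",
    "average_fits",
]


@dataclass
class ClenchFit:
    """Fitted Clench parameters for one sampling unit (or their average)."""

    a: float
    b: float
    residual_sse: float | None = None
    converged: bool = False

    @property
    def asymptote(self) -> float:
        """Estimated asymptotic richness a/b."""
        return self.a / self.b


def clench_predict(a: float, b: float, t):
    """Predicted richness ``a*t / (1 + b*t)`` at effort ``t`` (vectorized)."""
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ValueError("effort t must be nonnegative")
    out = a * t / (1.0 + b * t)
    return float(out) if out.ndim == 0 else out


def fit_clench(
    curve: AccumulationCurve,
    weights: Sequence[float] | None = None,
    strict: bool = False,
    xtol: float = 1e-8,
    max_iter: int = 10_000,
) -> ClenchFit:
    """Nonlinear least-squares fit of the Clench model to a mean curve.

    Initialized at ``a0 = S(1)`` and ``b0 = a0 / S(T)`` so the starting
    asymptote equals the observed maximum.  ``weights`` (e.g. ``1/sd``)
    weight the residuals; by default the permutation-mean curve is fitted
    unweighted.  Non-convergence flags the fit, or raises in ``strict``
    mode.
    """
    t = np.asarray(curve.effort, dtype=float)
    s = np.asarray(curve.mean_richness, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 effort levels to fit two parameters")
    if s[-1] <= 0:
        raise ValueError("cannot fit an all-zero accumulation curve")
    a0 = max(s[0], 1e-6)
    b0 = a0 / s[-1]
    sigma = None if weights is None else 1.0 / np.asarray(weights, dtype=float)
    try:
        popt, _ = curve_fit(
            lambda tt, a, b: a * tt / (1.0 + b * tt),
            t,
            s,
            p0=(a0, b0),
            sigma=sigma,
            bounds=((1e-12, 1e-12), (np.inf, np.inf)),
            xtol=xtol,
            maxfev=max_iter,
        )
        a, b = float(popt[0]), float(popt[1])
        converged = True
    except RuntimeError:
        a, b, converged = float("nan"), float("nan"), False
    if not converged and strict:
        raise RuntimeError("Clench fit did not converge")
    sse = float(np.sum((s - a * t / (1.0 + b * t)) ** 2)) if converged else None
    return ClenchFit(a=a, b=b, residual_sse=sse, converged=converged)


def effort_to_fraction(fit: ClenchFit, q: float = 0.9) -> float:
    """Effort at which the fitted curve reaches fraction ``q`` of a/b.

    Solves ``S(t) = q * a/b`` exactly: ``t_q = q / ((1 - q) * b)``.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie strictly between 0 and 1 (the asymptote is unreachable)")
    if not (fit.b > 0):
        raise ValueError("invalid fit: b must be positive")
    return q / ((1.0 - q) * fit.b)


def effort_to_fraction_nights(fit: ClenchFit, q: float = 0.9) -> int:
    """Same as :func:`effort_to_fraction`, rounded up to whole nights."""
    return math.ceil(effort_to_fraction(fit, q) - 1e-9)


def average_fits(fits: Sequence[ClenchFit]) -> ClenchFit:
    """Average Clench fits across sampling units (arithmetic mean of a, b).

    Note the averaged asymptote is ``mean(a)/mean(b)``, which in general
    differs from the mean of the per-unit asymptotes.
    """
    if not fits:
        raise ValueError("no fits to average")
    bad = [i for i, f in enumerate(fits) if not f.converged]
    if bad:
        raise ValueError(f"cannot average non-converged fits (unit indices {bad})")
    return ClenchFit(
        a=float(np.mean([f.a for f in fits])),
        b=float(np.mean([f.b for f in fits])),
        residual_sse=None,
        converged=True,
    )
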