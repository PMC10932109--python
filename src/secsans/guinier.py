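"""Guinier analysis: Rg and I(0) from the low-Q limit.

At small Q·Rg the scattering of any particle follows the Guinier law
``I(Q) = I(0) exp(-Q^2 Rg^2 / 3)``, so a weighted linear fit of ln I against
Q^2 over a low-Q window yields the radius of gyration and forward scattering.
The window can be given explicitly, selected automatically, or pinned to a
Q·Rg band (the form results are usually reported in).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import ScatteringCurve


@dataclass(frozen=True)
class GuinierResult:
    """Outcome of a Guinier fit.

    ``window`` is the half-open index range (start, stop) used; ``qrg_bounds``
    the Q·Rg values at its first and last points; ``fit_quality`` the R^2 of
    the linear fit of ln I vs Q^2.
    """

    rg: float
    i0: float
    window: tuple[int, int]
    qrg_bounds: tuple[float, float]
    fit_quality: float

    def __post_init__(self) -> None:
        if self.rg <= 0 or self.i0 <= 0:
            raise ValueError("rg and i0 must be positive")


def _wls_lnI(curve: ScatteringCurve, lo: int, hi: int) -> tuple[float, float, float]:
    """Weighted linear fit of ln I vs Q^2 on [lo, hi); returns slope, intercept, R^2."""
    q2 = curve.q[lo:hi] ** 2
    i = curve.intensity[lo:hi]
    if np.any(i <= 0):
        raise ValueError("nonpositive intensity inside Guinier window")
    y = np.log(i)
    if curve.sigma is not None:
        w = (i / curve.sigma[lo:hi]) ** 2  # sigma_lnI = sigma/I
    else:
        w = np.ones_like(y)
    W = np.sum(w)
    xm = np.sum(w * q2) / W
    ym = np.sum(w * y) / W
    sxx = np.sum(w * (q2 - xm) ** 2)
    sxy = np.sum(w * (q2 - xm) * (y - ym))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * q2)
    ss_res = np.sum(w * resid**2)
    ss_tot = np.sum(w * (y - ym) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return slope, intercept, r2


def fit_guinier(
    curve: ScatteringCurve,
    window: tuple[int, int] | None = None,
    qrg_limit: float = 1.3,
) -> GuinierResult:
    """Guinier fit over an index window (auto-selected when ``window`` is None).

    Raises on windows shorter than 5 points, nonpositive intensities inside
    the window, or a positive slope (no Guinier regime).
    """
    if window is None:
        window = auto_window(curve, qrg_limit=qrg_limit)
    lo, hi = window
    if hi - lo < 5:
        raise ValueError("Guinier window must contain at least 5 points")
    slope, intercept, r2 = _wls_lnI(curve, lo, hi)
    if slope >= 0:
        raise ValueError("positive Guinier slope: no Guinier regime in window")
    rg = float(np.sqrt(-3.0 * slope))
    i0 = float(np.exp(intercept))
    return GuinierResult(
        rg=rg,
        i0=i0,
        window=(lo, hi),
        qrg_bounds=(float(curve.q[lo] * rg), float(curve.q[hi - 1] * rg)),
        fit_quality=float(r2),
    )


def fit_guinier_qrg(
    curve: ScatteringCurve,
    qrg_min: float,
    qrg_max: float,
    max_iter: int = 50,
) -> GuinierResult:
    """Self-consistent Guinier fit over the band qrg_min < Q·Rg < qrg_max.

    Starting from a fit over the whole positive-intensity low-Q region, the
    point selection is re-derived from the current Rg until the window is
    stable.  This reproduces analyses quoted as e.g. ``0.35 < QRg < 1.26``.
    """
    if not (0 <= qrg_min < qrg_max):
        raise ValueError("require 0 <= qrg_min < qrg_max")
    # initial guess: fit over first half of the curve
    lo, hi = 0, max(5, len(curve) // 2)
    rg = fit_guinier(curve, (lo, hi)).rg
    for _ in range(max_iter):
        qrg = curve.q * rg
        sel = np.nonzero((qrg > qrg_min) & (qrg < qrg_max))[0]
        if sel.size < 5:
            raise ValueError("fewer than 5 points inside the requested QRg band")
        new = (int(sel[0]), int(sel[-1] + 1))
        res = fit_guinier(curve, new)
        if new == (lo, hi):
            return res
        lo, hi = new
        rg = res.rg
    return res


def auto_window(curve: ScatteringCurve, qrg_limit: float = 1.3) -> tuple[int, int]:
    """Deterministic automatic Guinier-window selection.

    The upper edge is capped self-consistently at Q·Rg <= ``qrg_limit``;
    leading points are then dropped one at a time while the first point lies
    more than two standardized residuals above the fit (guards against low-Q
    aggregate upturns without nibbling smooth curves).
    """
    if qrg_limit <= 0:
        raise ValueError("qrg_limit must be positive")
    n = len(curve)
    pos = curve.intensity > 0
    lo = int(np.argmax(pos))
    if not pos[lo:].all() or n - lo < 5:
        # restrict to the leading positive run
        run_end = lo + int(np.argmin(pos[lo:])) if not pos[lo:].all() else n
        if run_end - lo < 5:
            raise ValueError("no usable window with >= 5 positive points")
        n = run_end

    def cap(lo: int) -> tuple[int, float]:
        hi = min(n, lo + max(5, (n - lo) // 2))
        for _ in range(50):
            res = fit_guinier(curve, (lo, hi))
            qrg = curve.q * res.rg
            new_hi = int(np.searchsorted(qrg, qrg_limit, side="right"))
            new_hi = min(max(new_hi, lo + 5), n)
            if new_hi == hi:
                return hi, res.fit_quality
            hi = new_hi
        return hi, res.fit_quality

    def leading_outlier(lo: int, hi: int) -> bool:
        slope, intercept, _ = _wls_lnI(curve, lo, hi)
        q2 = curve.q[lo:hi] ** 2
        resid = np.log(curve.intensity[lo:hi]) - (intercept + slope * q2)
        spread = float(np.std(resid[1:])) or 1e-30
        return resid[0] > 2.0 * spread

    best_lo = lo
    hi, _ = cap(lo)
    while hi - (best_lo + 1) >= 5 and leading_outlier(best_lo, hi):
        best_lo += 1
        try:
            hi, _ = cap(best_lo)
        except ValueError:
            break
    if hi - best_lo < 5:
        raise ValueError("no window with >= 5 points satisfies the QRg cap")
    return (best_lo, hi)
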