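"""Regularized indirect Fourier transform: P(r) from I(Q).

The pair-distance distribution P(r) is related to the measured intensity by

    I(Q) = 4 pi  integral_0^Dmax  P(r) sin(Qr)/(Qr) dr

and is recovered here by solving the discretized linear inverse problem with a
second-difference smoothness penalty, endpoint values pinned to zero
(P(0) = P(Dmax) = 0).  The regularization weight is chosen by the L-curve
corner when not supplied.  The radius of gyration follows as the second
moment of P(r),

    Rg^2 = integral r^2 P(r) dr / (2 integral P(r) dr),

and the forward scattering as I(0) = 4 pi integral P(r) dr.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import ScatteringCurve

DEFAULT_N_R = 101


@dataclass(frozen=True)
class PairDistribution:
    """P(r) on a uniform grid over [0, dmax], with the regularization weight
    used and the reduced chi^2 of the back-transformed curve against the data."""

    r: np.ndarray
    pr: np.ndarray
    dmax: float
    alpha: float
    fit_chi2: float

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        p = np.asarray(self.pr, dtype=float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "pr", p)
        if r.shape != p.shape or r.ndim != 1:
            raise ValueError("r and pr must be 1-D arrays of equal length")
        if abs(r[0]) > 1e-12 or abs(r[-1] - self.dmax) > 1e-9 * self.dmax:
            raise ValueError("r grid must run from 0 to dmax inclusive")
        if abs(p[0]) > 1e-12 or abs(p[-1]) > 1e-12:
            raise ValueError("P(0) and P(dmax) must vanish")


def _design_matrix(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Trapezoid-quadrature matrix K with I = K @ pr."""
    dr = r[1] - r[0]
    w = np.full(r.size, dr)
    w[0] = w[-1] = dr / 2.0
    qr = np.outer(q, r)
    return 4.0 * np.pi * np.sinc(qr / np.pi) * w[None, :]


def _solve(KW: np.ndarray, yW: np.ndarray, L: np.ndarray, alpha: float) -> np.ndarray:
    A = KW.T @ KW + alpha * (L.T @ L)
    return np.linalg.solve(A, KW.T @ yW)


def compute_pr(
    curve: ScatteringCurve,
    dmax: float,
    alpha: float | None = None,
    n_r: int = DEFAULT_N_R,
) -> PairDistribution:
    """Invert I(Q) to P(r) on [0, dmax] with smoothness regularization.

    When ``alpha`` is None it is picked at the corner of the L-curve
    (data misfit vs. second-difference roughness) over a log-spaced grid.
    ``fit_chi2`` is the reduced chi^2 of the back-transform against the data
    (unit weights when the curve has no uncertainties).
    """
    if dmax <= 0:
        raise ValueError("dmax must be positive")
    if n_r < 10:
        raise ValueError("n_r too small")
    if len(curve) < n_r // 4:
        raise ValueError(
            "too few data points for the requested r grid; use a coarser grid (smaller n_r)"
        )
    r = np.linspace(0.0, dmax, n_r)
    K = _design_matrix(curve.q, r)
    sigma = curve.sigma if curve.sigma is not None else np.ones_like(curve.q)
    KW = K / sigma[:, None]
    yW = curve.intensity / sigma
    # endpoints pinned to zero: solve for interior values only
    Ki = KW[:, 1:-1]
    # second difference operator acting on the full (zero-padded) vector
    n_int = n_r - 2
    L = np.zeros((n_r, n_int))
    for j in range(n_int):
        col = np.zeros(n_r)
        col[j] += 1.0
        col[j + 1] += -2.0
        col[j + 2] += 1.0
        L[:, j] = col
    scale = np.trace(Ki.T @ Ki) / np.trace(L.T @ L)

    if alpha is None:
        alphas = scale * np.logspace(-8, 2, 31)
        rho = np.empty_like(alphas)
        eta = np.empty_like(alphas)
        sols = []
        for k, a in enumerate(alphas):
            p = _solve(Ki, yW, L, a)
            sols.append(p)
            rho[k] = np.log(np.sum((Ki @ p - yW) ** 2) + 1e-300)
            eta[k] = np.log(np.sum((L @ p) ** 2) + 1e-300)
        # L-curve corner: maximum curvature of (rho, eta) by central differences
        d1r, d1e = np.gradient(rho), np.gradient(eta)
        d2r, d2e = np.gradient(d1r), np.gradient(d1e)
        curv = (d1r * d2e - d2r * d1e) / np.power(d1r**2 + d1e**2, 1.5) + 1e-300
        k_best = int(np.argmax(curv[2:-2])) + 2
        alpha = float(alphas[k_best])
        p_int = sols[k_best]
    else:
        p_int = _solve(Ki, yW, L, alpha)

    pr = np.zeros(n_r)
    pr[1:-1] = p_int
    chi2 = float(np.sum((Ki @ p_int - yW) ** 2)) / len(curve)
    return PairDistribution(r=r, pr=pr, dmax=float(dmax), alpha=float(alpha), fit_chi2=chi2)


def back_transform(pr: PairDistribution, q: np.ndarray) -> np.ndarray:
    """Forward map of P(r) back to I(Q) (the fitted curve)."""
    return _design_matrix(np.asarray(q, dtype=float), pr.r) @ pr.pr


def rg_from_pr(pr: PairDistribution) -> tuple[float, float]:
    """(Rg, I(0)) from the second moment and integral of P(r), by trapezoid rule."""
    s0 = float(np.trapezoid(pr.pr, pr.r))
    if s0 <= 0:
        raise ValueError("integral of P(r) must be positive")
    s2 = float(np.trapezoid(pr.r**2 * pr.pr, pr.r))
    if s2 <= 0:
        raise ValueError("second moment of P(r) must be positive")
    rg = float(np.sqrt(s2 / (2.0 * s0)))
    i0 = 4.0 * np.pi * s0
    return rg, i0


def scan_dmax(
    curve: ScatteringCurve,
    candidates: list[float] | np.ndarray,
    alpha: float | None = None,
    chi2_slack: float = 0.05,
    negativity_level: float = 0.01,
    n_r: int = DEFAULT_N_R,
) -> tuple[float, list[dict]]:
    """Pick Dmax from candidates: the smallest whose fit chi^2 is within
    ``chi2_slack`` of the global minimum and whose P(r) has no negative
    excursion beyond ``negativity_level`` of max(P).

    Returns (best, per-candidate diagnostics).  Falls back to the global-chi^2
    minimizer when no candidate passes the negativity screen.
    """
    candidates = list(np.atleast_1d(np.asarray(candidates, dtype=float)))
    if not candidates:
        raise ValueError("empty candidate list")
    diags = []
    for d in sorted(candidates):
        p = compute_pr(curve, d, alpha=alpha, n_r=n_r)
        neg = float(-min(0.0, p.pr.min()) / max(p.pr.max(), 1e-300))
        try:
            rg, i0 = rg_from_pr(p)
        except ValueError:
            rg, i0 = np.nan, np.nan
        diags.append(
            {"dmax": d, "fit_chi2": p.fit_chi2, "negativity": neg, "rg": rg, "i0": i0}
        )
    chi2_min = min(d["fit_chi2"] for d in diags)
    ok = [
        d
        for d in diags
        if d["fit_chi2"] <= chi2_min * (1.0 + chi2_slack) and d["negativity"] <= negativity_level
    ]
    if ok:
        best = min(ok, key=lambda d: d["dmax"])["dmax"]
    else:
        best = min(diags, key=lambda d: d["fit_chi2"])["dmax"]
    return float(best), diags


def write_pr(pr: PairDistribution, path) -> None:
    """3-column text output (r, P(r), placeholder sigma 0)."""
    np.savetxt(
        path,
        np.column_stack([pr.r, pr.pr, np.zeros_like(pr.r)]),
        header=f"r(A) P(r) sigma  dmax={pr.dmax} alpha={pr.alpha} chi2={pr.fit_chi2}",
    )
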