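"""Analytic form factors and weighted least-squares model fitting.

Implements the orientation-averaged sphere, circular-cylinder and
elliptical-cylinder form factors, all normalized to 1 at Q = 0 so that the
``scale`` parameter carries the aggregate forward scattering
``n (delta rho)^2 V^2`` of the absolute-intensity expression, and the dilute
assumption S(Q) = 1 holds throughout.

The elliptical cylinder has a cross-section with minor radius ``a`` and major
radius ``nu * a`` and length ``L``.  Its orientation average is a double
quadrature: the outer integral over the axis tilt x in [0, 1] carries the
longitudinal factor ``[sin(t)/t]^2`` at ``t = Q L x / 2``; the inner integral
over the cross-section angle y in [0, pi] evaluates ``Lambda_1(t) = 2 J1(t)/t``
(cylindrical first-order Bessel) at the effective radius
``a sqrt((1+nu^2)/2 + (1-nu^2)/2 cos y)`` scaled by ``Q sqrt(1-x^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import least_squares
from scipy.special import j1 as bessel_j1

from .curves import ScatteringCurve

DEFAULT_QUAD_POINTS = 76
_MIN_QUAD_POINTS = 8


@dataclass(frozen=True)
class EllipticalCylinderParams:
    """Geometry and amplitude of the elliptical-cylinder model.

    minor_radius ``a`` (A), axis_ratio ``nu = major/minor`` (>= 1),
    length ``L`` (A), multiplicative ``scale`` and additive ``background``
    in curve units.
    """

    minor_radius: float
    axis_ratio: float
    length: float
    scale: float = 1.0
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.minor_radius <= 0 or self.length <= 0 or self.scale <= 0:
            raise ValueError("minor_radius, length and scale must be positive")
        if self.axis_ratio < 1.0:
            raise ValueError("axis_ratio must be >= 1 (normalize the ellipse)")
        if self.background < 0:
            raise ValueError("background must be nonnegative")

    @property
    def major_radius(self) -> float:
        return self.axis_ratio * self.minor_radius

    @property
    def rg(self) -> float:
        """Coordinate radius of gyration: Rg^2 = (a^2 + (nu a)^2)/4 + L^2/12."""
        a, b, L = self.minor_radius, self.major_radius, self.length
        return float(np.sqrt((a**2 + b**2) / 4.0 + L**2 / 12.0))

    @property
    def max_chord(self) -> float:
        """Longest intra-particle distance sqrt(L^2 + (2 nu a)^2)."""
        return float(np.hypot(self.length, 2.0 * self.major_radius))


@dataclass(frozen=True)
class FitResult:
    params: dict
    uncertainties: dict
    reduced_chi2: float
    n_points: int

    def __post_init__(self) -> None:
        if self.reduced_chi2 < 0:
            raise ValueError("reduced_chi2 must be nonnegative")
        if any(v < 0 for v in self.uncertainties.values()):
            raise ValueError("uncertainties must be nonnegative")


@lru_cache(maxsize=8)
def _gauss(n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = leggauss(n)
    return x, w


def _sinc(t: np.ndarray) -> np.ndarray:
    """sin(t)/t with the t -> 0 limit."""
    return np.sinc(t / np.pi)


def intensity_sphere(q: np.ndarray, radius: float) -> np.ndarray:
    """Normalized sphere form factor [3 (sin x - x cos x)/x^3]^2, x = qR."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    x = np.asarray(q, dtype=float) * radius
    amp = np.where(
        x < 1e-4,
        1.0 - x**2 / 10.0,
        3.0 * (np.sin(x) - x * np.cos(x)) / np.where(x == 0, 1.0, x) ** 3,
    )
    return amp**2


def intensity_cylinder(
    q: np.ndarray, radius: float, length: float, n_points: int = DEFAULT_QUAD_POINTS
) -> np.ndarray:
    """Normalized circular-cylinder form factor (single orientational integral)."""
    if radius <= 0 or length <= 0:
        raise ValueError("radius and length must be positive")
    if n_points < _MIN_QUAD_POINTS:
        raise ValueError(f"need at least {_MIN_QUAD_POINTS} quadrature points")
    q = np.asarray(q, dtype=float)
    xg, wg = _gauss(n_points)
    x = 0.5 * (xg + 1.0)  # [0, 1]
    wx = 0.5 * wg
    qx = q[:, None] * x[None, :]
    long_t = qx * (length / 2.0)
    cross_t = q[:, None] * np.sqrt(np.clip(1.0 - x**2, 0.0, 1.0))[None, :] * radius
    lam = _lambda1(cross_t)
    return np.sum(wx * _sinc(long_t) ** 2 * lam**2, axis=1)


def _lambda1(t: np.ndarray) -> np.ndarray:
    """Lambda_1(t) = 2 J1(t)/t with the t -> 0 limit of 1."""
    small = np.abs(t) < 1e-6
    safe = np.where(small, 1.0, t)
    return np.where(small, 1.0 - t**2 / 8.0, 2.0 * bessel_j1(safe) / safe)


def intensity_elliptical_cylinder(
    q: np.ndarray,
    params: EllipticalCylinderParams,
    n_points: int = DEFAULT_QUAD_POINTS,
) -> np.ndarray:
    """Orientation-averaged elliptical-cylinder intensity (scale + background applied)."""
    if n_points < _MIN_QUAD_POINTS:
        raise ValueError(f"need at least {_MIN_QUAD_POINTS} quadrature points")
    q = np.asarray(q, dtype=float)
    a, nu, L = params.minor_radius, params.axis_ratio, params.length
    xg, wg = _gauss(n_points)
    x = 0.5 * (xg + 1.0)            # axis tilt in [0, 1]
    wx = 0.5 * wg
    y = 0.5 * np.pi * (xg + 1.0)    # cross-section angle in [0, pi]
    wy = 0.5 * np.pi * wg / np.pi   # includes the 1/pi normalization

    r_eff = a * np.sqrt((1.0 + nu**2) / 2.0 + (1.0 - nu**2) / 2.0 * np.cos(y))
    sin_tilt = np.sqrt(np.clip(1.0 - x**2, 0.0, 1.0))
    # t[iq, ix, iy] = Q sqrt(1-x^2) r_eff(y)
    t = q[:, None, None] * sin_tilt[None, :, None] * r_eff[None, None, :]
    psi = np.sum(wy[None, None, :] * _lambda1(t) ** 2, axis=2)
    long_t = q[:, None] * x[None, :] * (L / 2.0)
    pq = np.sum(wx[None, :] * psi * _sinc(long_t) ** 2, axis=1)
    return params.scale * pq + params.background


_MODELS = {
    "sphere": (("radius",), lambda q, p: p["scale"] * intensity_sphere(q, p["radius"]) + p["background"]),
    "cylinder": (
        ("radius", "length"),
        lambda q, p: p["scale"] * intensity_cylinder(q, p["radius"], p["length"]) + p["background"],
    ),
    "elliptical_cylinder": (
        ("minor_radius", "axis_ratio", "length"),
        lambda q, p: intensity_elliptical_cylinder(
            q,
            EllipticalCylinderParams(
                p["minor_radius"], p["axis_ratio"], p["length"], p["scale"], p["background"]
            ),
        ),
    ),
}


def model_intensity(model: str, q: np.ndarray, params: dict) -> np.ndarray:
    """Evaluate a named model; ``params`` must hold its geometry plus scale/background."""
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(_MODELS)}")
    p = {"scale": 1.0, "background": 0.0, **params}
    return _MODELS[model][1](q, p)


def fit_model(
    curve: ScatteringCurve,
    model: str,
    init: dict,
    bounds: dict | None = None,
    fit_background: bool = False,
    max_nfev: int = 2000,
) -> FitResult:
    """Bounded weighted least squares of a named form-factor model.

    Minimizes sum(((I_data - I_model)/sigma)^2); parameter order and free set
    are the model geometry plus ``scale`` (and ``background`` when
    ``fit_background``).  1-sigma uncertainties come from the Jacobian-based
    covariance at the optimum.  Deterministic given ``init``.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}")
    if curve.sigma is None:
        raise ValueError("fit_model requires a curve with uncertainties")
    geom = _MODELS[model][0]
    free = list(geom) + ["scale"] + (["background"] if fit_background else [])
    fixed = {"background": 0.0, **{k: v for k, v in init.items() if k not in free}}
    bounds = bounds or {}
    lo = np.array([bounds.get(k, (1e-12, np.inf))[0] for k in free])
    hi = np.array([bounds.get(k, (1e-12, np.inf))[1] for k in free])
    x0 = np.array([init[k] for k in free], dtype=float)
    if np.any(x0 < lo) or np.any(x0 > hi):
        raise ValueError("init must lie within bounds")

    def resid(x: np.ndarray) -> np.ndarray:
        p = {**fixed, **dict(zip(free, x))}
        return (curve.intensity - model_intensity(model, curve.q, p)) / curve.sigma

    sol = least_squares(resid, x0, bounds=(lo, hi), max_nfev=max_nfev, method="trf")
    if not sol.success:
        raise RuntimeError(
            f"fit did not converge ({sol.message}); best-so-far: "
            f"{dict(zip(free, sol.x))}"
        )
    n, p = len(curve), len(free)
    chi2 = float(np.sum(sol.fun**2))
    red = chi2 / max(n - p, 1)
    # covariance from J^T J (scaled by reduced chi^2, standard practice)
    _, s, vt = np.linalg.svd(sol.jac, full_matrices=False)
    s = np.where(s > s[0] * 1e-12, s, np.inf)
    cov = (vt.T / s**2) @ vt * red
    err = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    params = {**fixed, **dict(zip(free, sol.x.tolist()))}
    return FitResult(
        params=params,
        uncertainties=dict(zip(free, err.tolist())),
        reduced_chi2=red,
        n_points=n,
    )
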