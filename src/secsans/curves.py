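"""Core scattering-curve containers, rebinning, resolution smearing and Kratky analysis.

The :class:`ScatteringCurve` is the common currency between every stage of the
analysis chain: synthetic frame generation, Guinier fits, indirect Fourier
transforms, form-factor fits and shape reconstruction all consume and produce
it.  Q is the magnitude of the scattering vector, ``Q = 4 pi sin(theta) / lambda``
with ``theta`` half the scattering angle, in inverse Angstrom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
from numpy.polynomial.legendre import leggauss


class KratkyClass(str, Enum):
    """Qualitative compactness call from a Kratky profile."""

    FOLDED = "folded"
    UNFOLDED = "unfolded"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ScatteringCurve:
    """A one-dimensional scattering curve I(Q).

    Parameters
    ----------
    q:
        Scattering-vector magnitudes in 1/Angstrom, strictly increasing, > 0.
    intensity:
        Differential cross-section per unit volume (arbitrary units or 1/cm).
    sigma:
        Optional 1-sigma uncertainties, same units as ``intensity``, > 0.
    label:
        Free-text tag carried through the pipeline.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", i)
        if q.ndim != 1 or i.shape != q.shape:
            raise ValueError("q and intensity must be 1-D arrays of equal length")
        if q.size == 0:
            raise ValueError("empty curve")
        if not np.all(q > 0):
            raise ValueError("all q must be positive")
        if not np.all(np.diff(q) > 0):
            raise ValueError("q must be strictly increasing")
        if not np.all(np.isfinite(i)):
            raise ValueError("intensity must be finite everywhere")
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            object.__setattr__(self, "sigma", s)
            if s.shape != q.shape:
                raise ValueError("sigma must match q in length")
            if not np.all(s > 0):
                raise ValueError("sigma must be positive wherever present")

    def __len__(self) -> int:
        return self.q.size

    def scaled(self, factor: float) -> "ScatteringCurve":
        """Return a copy with intensity (and sigma) multiplied by ``factor``."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return replace(
            self,
            intensity=self.intensity * factor,
            sigma=None if self.sigma is None else self.sigma * factor,
        )

    def restricted(self, qmin: float = 0.0, qmax: float = np.inf) -> "ScatteringCurve":
        """Return the sub-curve with qmin <= q <= qmax."""
        m = (self.q >= qmin) & (self.q <= qmax)
        if not m.any():
            raise ValueError("no points in requested q range")
        return replace(
            self,
            q=self.q[m],
            intensity=self.intensity[m],
            sigma=None if self.sigma is None else self.sigma[m],
        )


@dataclass(frozen=True)
class ResolutionSpec:
    """Instrumental wavelength-resolution description.

    ``wavelength_spread`` is the fractional FWHM of the (velocity-selector)
    wavelength band, e.g. 0.10 for a 6 A +/- 10% beam.
    """

    wavelength: float = 6.0
    wavelength_spread: float = 0.10

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if not (0.0 <= self.wavelength_spread < 1.0):
            raise ValueError("wavelength_spread must lie in [0, 1)")


@dataclass(frozen=True)
class KratkyProfile:
    q: np.ndarray
    q2i: np.ndarray
    classification: KratkyClass


FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.355


def read_curve(path: str | Path, label: str = "") -> ScatteringCurve:
    """Read a whitespace-delimited (Q, I[, sigma]) text file; '#' starts a comment."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 columns (Q, I)")
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return ScatteringCurve(data[:, 0], data[:, 1], sigma, label=label or str(path))


def write_curve(curve: ScatteringCurve, path: str | Path, header: str = "") -> None:
    """Write a curve as 3-column text (sigma written as 0 when absent)."""
    sigma = curve.sigma if curve.sigma is not None else np.zeros_like(curve.q)
    cols = np.column_stack([curve.q, curve.intensity, sigma])
    head = header or f"Q(1/A) I sigma  [{curve.label}]"
    np.savetxt(path, cols, header=head)


def rebin_curve(curve: ScatteringCurve, n_bins: int) -> ScatteringCurve:
    """Rebin to ``n_bins`` contiguous index bins.

    Intensities are averaged with inverse-variance weights (plain means when no
    sigma is present); the pooled sigma of each bin is ``1/sqrt(sum 1/sigma_i^2)``
    and the bin Q is the mean of the member Q values.
    """
    if n_bins <= 0:
        raise ValueError("n_bins must be positive")
    if n_bins > len(curve):
        raise ValueError(f"n_bins={n_bins} exceeds point count {len(curve)}")
    idx_groups = np.array_split(np.arange(len(curve)), n_bins)
    q_out = np.empty(n_bins)
    i_out = np.empty(n_bins)
    s_out = np.empty(n_bins) if curve.sigma is not None else None
    for k, idx in enumerate(idx_groups):
        q_out[k] = curve.q[idx].mean()
        if curve.sigma is None:
            i_out[k] = curve.intensity[idx].mean()
        else:
            w = 1.0 / curve.sigma[idx] ** 2
            i_out[k] = np.sum(w * curve.intensity[idx]) / np.sum(w)
            s_out[k] = 1.0 / np.sqrt(np.sum(w))
    return ScatteringCurve(q_out, i_out, s_out, label=curve.label)


def smear_resolution(
    model_curve: ScatteringCurve,
    res: ResolutionSpec,
    n_kernel: int = 31,
) -> ScatteringCurve:
    """Smear a noise-free model curve with a Gaussian wavelength-spread kernel.

    The fractional wavelength FWHM maps to a relative Gaussian width in Q,
    ``sigma_q / q = (dlambda/lambda) / 2.355``.  The kernel is truncated at
    +/- 3 sigma, clipped to the measured Q support and renormalized, so a
    constant curve is conserved exactly.  Model values between grid nodes are
    linearly interpolated.
    """
    if res.wavelength_spread == 0.0:
        return model_curve
    rel_sigma = res.wavelength_spread / FWHM_TO_SIGMA
    q = model_curve.q
    # Gauss-Legendre nodes on [-3, 3] sigma units
    x, w = leggauss(n_kernel)
    u = 3.0 * x  # kernel offsets in sigma units
    gw = 3.0 * w * np.exp(-0.5 * u**2)
    q_samp = q[:, None] * (1.0 + rel_sigma * u[None, :])
    inside = (q_samp >= q[0]) & (q_samp <= q[-1])
    vals = np.interp(np.clip(q_samp, q[0], q[-1]), q, model_curve.intensity)
    wts = gw[None, :] * inside
    norm = wts.sum(axis=1)
    smeared = (wts * vals).sum(axis=1) / norm
    return ScatteringCurve(q, smeared, None, label=model_curve.label)


def compute_kratky(
    curve: ScatteringCurve,
    peak_over_tail: float = 1.5,
    plateau_slope_tol: float = 0.05,
) -> KratkyProfile:
    """Build the Kratky profile Q^2 I(Q) and classify compactness.

    Folded (compact) particles show a bell-shaped interior peak that decays at
    high Q; unfolded chains level off to a plateau.  The call is threshold
    based: *folded* when an interior maximum exceeds ``peak_over_tail`` times
    the median of the final third of the profile; *unfolded* when the final
    third is flat (relative slope within ``plateau_slope_tol`` of zero) without
    such a peak; *indeterminate* otherwise.
    """
    q2i = curve.q**2 * curve.intensity
    n = len(curve)
    if n < 10:
        warnings.warn("fewer than 10 points: Kratky classification indeterminate")
        return KratkyProfile(curve.q, q2i, KratkyClass.INDETERMINATE)

    tail = q2i[2 * n // 3 :]
    tail_median = float(np.median(tail))
    imax = int(np.argmax(q2i))
    peak = float(q2i[imax])
    interior_peak = 0 < imax < n - 1

    # relative slope of the final third, normalized by its mean level
    qt = curve.q[2 * n // 3 :]
    mean_level = float(np.mean(tail))
    if mean_level > 0:
        slope = np.polyfit(qt, tail, 1)[0]
        rel_slope = slope * (qt[-1] - qt[0]) / mean_level
    else:
        rel_slope = 0.0

    if interior_peak and tail_median > 0 and peak > peak_over_tail * tail_median:
        cls = KratkyClass.FOLDED
    elif abs(rel_slope) <= plateau_slope_tol and (
        not interior_peak or peak <= peak_over_tail * max(tail_median, 0.0)
    ):
        cls = KratkyClass.UNFOLDED
    else:
        cls = KratkyClass.INDETERMINATE
    return KratkyProfile(curve.q, q2i, cls)
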