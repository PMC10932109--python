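import numpy as np
import pytest

from secsans.curves import ResolutionSpec, ScatteringCurve, smear_resolution
from secsans.formfactor import EllipticalCylinderParams, intensity_elliptical_cylinder

# Table-analog geometries: elongated (2:2-like) and compact (2:1-like) species
HIGH_MW = EllipticalCylinderParams(13.49, 2.06, 100.0, scale=0.075)
LOW_MW = EllipticalCylinderParams(14.64, 2.07, 73.0, scale=0.072)
D22_RESOLUTION = ResolutionSpec(wavelength=6.0, wavelength_spread=0.10)


@pytest.fixture(scope="session")
def q_grid():
    """Extended analysis grid reaching below the instrument minimum."""
    return np.linspace(0.005, 0.25, 200)


@pytest.fixture(scope="session")
def low_mw_curve(q_grid):
    """Noise-free low-MW elliptical-cylinder curve (unsmeared, unit scale)."""
    p = EllipticalCylinderParams(LOW_MW.minor_radius, LOW_MW.axis_ratio, LOW_MW.length)
    return ScatteringCurve(q_grid, intensity_elliptical_cylinder(q_grid, p), label="low_mw")


@pytest.fixture(scope="session")
def low_mw_smeared(low_mw_curve):
    return smear_resolution(low_mw_curve, D22_RESOLUTION)


@pytest.fixture(scope="session")
def high_mw_smeared(q_grid):
    p = EllipticalCylinderParams(HIGH_MW.minor_radius, HIGH_MW.axis_ratio, HIGH_MW.length)
    raw = ScatteringCurve(q_grid, intensity_elliptical_cylinder(q_grid, p), label="high_mw")
    return smear_resolution(raw, D22_RESOLUTION)


def uniform_ellipse_points(rng, n, a, b):
    """n uniform points in an ellipse with semi-axes a, b."""
    u = rng.random(n)
    th = 2.0 * np.pi * rng.random(n)
    return np.column_stack([a * np.sqrt(u) * np.cos(th), b * np.sqrt(u) * np.sin(th)])


def cylinder_point_cloud(rng, n, params: EllipticalCylinderParams):
    """Uniform point cloud filling an elliptical cylinder."""
    xy = uniform_ellipse_points(rng, n, params.minor_radius, params.major_radius)
    z = rng.uniform(-params.length / 2, params.length / 2, n)
    return np.column_stack([xy, z])


def qmc_cylinder_formfactor(params: EllipticalCylinderParams, q, n_pairs_log2=22, seed=5, dr=0.05):
    """Quasi-Monte-Carlo Debye estimate of the normalized elliptical-cylinder
    form factor: Sobol pairs of uniform points in the body, sinc-transformed
    through a fine pair-distance histogram.  Independent of the quadrature
    implementation."""
    from scipy.stats import qmc

    a, b, L = params.minor_radius, params.major_radius, params.length
    eng = qmc.Sobol(6, seed=seed)
    nbin = int(np.ceil(params.max_chord / dr)) + 10
    hist = np.zeros(nbin)
    total = 0
    block_log2 = min(20, n_pairs_log2)
    for _ in range(2 ** max(0, n_pairs_log2 - block_log2)):
        s = eng.random(2**block_log2)

        def pts(u, v, w):
            return np.column_stack([
                a * np.sqrt(u) * np.cos(2 * np.pi * v),
                b * np.sqrt(u) * np.sin(2 * np.pi * v),
                L * (w - 0.5),
            ])

        d = np.linalg.norm(pts(s[:, 0], s[:, 1], s[:, 2]) - pts(s[:, 3], s[:, 4], s[:, 5]), axis=1)
        hist += np.bincount(np.minimum((d / dr + 0.5).astype(int), nbin - 1), minlength=nbin)
        total += len(s)
    centers = np.arange(nbin) * dr
    return (np.sinc(np.outer(np.asarray(q), centers) / np.pi) @ hist) / total


def sphere_point_cloud(rng, n, radius):
    pts = rng.uniform(-1.0, 1.0, (3 * n, 3))
    pts = pts[(pts**2).sum(1) <= 1.0][:n]
    assert len(pts) == n
    return pts * radius
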