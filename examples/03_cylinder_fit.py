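"""Elliptical-cylinder form-factor fit to a noisy synthetic curve.

Generates the compact-species curve with 2% counting-style noise and recovers
the cylinder geometry by bounded weighted least squares.
"""

import numpy as np

from secsans import EllipticalCylinderParams, ScatteringCurve, fit_model, intensity_elliptical_cylinder

truth = EllipticalCylinderParams(minor_radius=14.64, axis_ratio=2.07, length=73.0, scale=0.072)
q = np.linspace(0.005, 0.25, 120)
clean = intensity_elliptical_cylinder(q, truth)
rng = np.random.default_rng(1)
sigma = 0.02 * clean
curve = ScatteringCurve(q, clean + rng.normal(size=len(q)) * sigma, sigma)

fit = fit_model(
    curve,
    "elliptical_cylinder",
    init={"minor_radius": 12.0, "axis_ratio": 1.8, "length": 80.0, "scale": 0.06},
    bounds={
        "minor_radius": (5.0, 40.0),
        "axis_ratio": (1.0, 5.0),
        "length": (20.0, 200.0),
        "scale": (1e-6, 10.0),
    },
)

for name, true_val in [
    ("minor_radius", truth.minor_radius),
    ("axis_ratio", truth.axis_ratio),
    ("length", truth.length),
    ("scale", truth.scale),
]:
    print(f"{name:<13s}: {fit.params[name]:8.3f} +/- {fit.uncertainties[name]:.3f}   (true {true_val})")
print(f"reduced chi^2: {fit.reduced_chi2:.2f}  over {fit.n_points} points")
print()
print("A reduced chi^2 near 1 means the misfit is consistent with the noise;")
print("the recovered geometry matches the generator within its uncertainties.")
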