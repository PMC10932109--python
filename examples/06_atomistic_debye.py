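"""Neutron scattering from an atomistic model via the Debye formula.

Builds a small synthetic two-chain structure (PDB format, generated on the
fly), computes its solution SANS curve under an H2O buffer contrast, compares
the Guinier Rg with the direct coordinate second moment, and runs a coarse
rigid-body fit that recovers a planted displacement of the second chain.
"""

import numpy as np

from secsans import (
    ContrastParams,
    ScatteringCurve,
    SearchGrid,
    debye_intensity,
    fit_guinier,
    read_structure,
    rigid_body_fit,
    structure_rg,
)

# synthetic helical CA-only chains written as a PDB fixture
def write_chain(path, chain, n_res, origin):
    with open(path, "a") as fh:
        for i in range(1, n_res + 1):
            t = 0.4 * i
            x, y, z = origin[0] + 8 * np.cos(t), origin[1] + 8 * np.sin(t), origin[2] + 1.5 * i
            fh.write(
                f"ATOM  {i:5d}  CA  GLY {chain}{i:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )

open("scratch_complex.pdb", "w").close()
write_chain("scratch_complex.pdb", "A", 80, (0.0, 0.0, 0.0))
write_chain("scratch_complex.pdb", "B", 40, (25.0, 0.0, 20.0))

fixed = read_structure("scratch_complex.pdb", chain_filter="A")
mobile = read_structure("scratch_complex.pdb", chain_filter="B")
complex_ = fixed.concat(mobile)

contrast = ContrastParams(d2o_fraction=0.0, exchange_fraction=0.9)  # H2O buffer
q = np.linspace(0.004, 0.25, 120)
curve = debye_intensity(complex_, q, contrast)
print(f"I(0) of the complex     : {curve.intensity[0]:.1f} fm^2")
print(f"Guinier Rg of the curve : {fit_guinier(curve, qrg_limit=1.0).rg:.2f} A")
print(f"coordinate Rg (direct)  : {structure_rg(complex_, contrast):.2f} A")

# plant a displacement of chain B and recover it by exhaustive pose search
shift = np.array([6.0, 0.0, 0.0])
target = debye_intensity(fixed.concat(mobile.transformed(translation=shift)), q, contrast)
grid = SearchGrid(translations=np.array([[dx, 0.0, 0.0] for dx in (-6.0, 0.0, 6.0, 12.0)]))
best, chi2 = rigid_body_fit(fixed, mobile, target, grid, contrast)
print(f"recovered translation   : {best['translation']}  (planted {shift}),  chi^2 = {chi2:.2e}")
print()
print("The Guinier Rg of the Debye curve reproduces the contrast-weighted")
print("coordinate second moment; the pose search finds the planted shift.")
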