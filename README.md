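# secsans

Analysis of size-exclusion-chromatography-coupled small-angle neutron
scattering (SEC-SANS) data, built for resolving coexisting protein species —
such as the 2:1 and 2:2 complexes of the orange carotenoid protein (OCP) with
its fluorescence recovery protein (FRP) — that an ordinary SANS measurement
would average into a single uninterpretable curve.

SEC separates the species by size immediately before the neutron beam; each
30 s exposure ("frame") then carries the scattering of whatever is eluting.
This package covers the whole chain downstream of raw-data reduction:

- **Synthetic SEC-SANS runs** (`secsans.synth`): two overlapping Gaussian
  elution peaks of elliptical-cylinder species with counting-statistics
  noise and buffer background, fully seeded — the test bench for everything
  else.
- **Peak extraction**: scattergram construction, elution-peak detection, and
  inverse-variance peak averaging with background subtraction.
- **Guinier analysis** (`secsans.guinier`): weighted fits of
  `ln I = ln I(0) − Q²Rg²/3` with automatic or Q·Rg-banded window selection.
- **P(r) inversion** (`secsans.ift`): regularized indirect Fourier transform
  of `I(Q) = 4π ∫ P(r) sinc(Qr) dr`, L-curve choice of the smoothness weight,
  Dmax scanning, and `Rg² = ∫r²P dr / 2∫P dr`.
- **Kratky diagnostics** (`secsans.curves`): folded / unfolded classification
  from the shape of `Q²I(Q)`.
- **Form-factor fitting** (`secsans.formfactor`): orientation-averaged
  sphere, circular and elliptical cylinder (minor radius *a*, axis ratio *ν*,
  length *L*), bounded weighted least squares.
- **Ab initio shape reconstruction** (`secsans.abinitio`): simulated
  annealing of dummy-atom models on a close-packed lattice, P1 or P2
  symmetry, multipole (`Σ_lm |A_lm(Q)|²`) and exact Debye backends,
  alignment, averaging, and NSD scoring.
- **Atomistic scattering** (`secsans.atomistic`): Debye-formula curves from
  PDB structures with neutron contrast (implicit hydrogens, labile-H
  exchange, displaced-solvent correction) and a coarse two-block rigid-body
  fit.
- **Pipeline** (`secsans.pipeline`): run → fractions → per-fraction report
  (Guinier, P(r), Kratky, cylinder fit, optional reconstruction) as JSON or a
  plain-text table.

The library is used from Python; `examples/` holds one short narrative
script per capability.

## Worked example

`python examples/04_sec_sans_run.py` simulates a two-species run (elongated
particle eluting first, compact one second, peaks at frames 18 and 34 with
partial overlap, ~2% noise) and analyzes both fractions:

```
detected elution peaks at frames [18, 34] (generated at 18 and 34)
high-MW: 5 frames averaged, Guinier Rg 30.61 A (component: 30.60 A)
low-MW: 11 frames averaged, Guinier Rg 27.07 A (component: 26.58 A)

                         high_mw        low_mw
Guinier Rg (A)             30.61         27.07
Guinier I(0)             0.06823       0.05821
P(r) Rg (A)                31.99         26.63
P(r) I(0)                0.06987       0.05755
Dmax (A)                      98            76
Kratky                    folded        folded
Minor radius (A)           13.27         14.45
Axis ratio                  2.12          2.08
Length (A)                 97.67         72.78
chi^2                       1.10          1.10
```

Reading the table: the first-eluting fraction is the larger species (higher
Rg and Dmax); both are compact (folded Kratky shape); and the elliptical
cylinder fits recover the generating geometries — (13.49, 2.06, 100 Å) and
(14.64, 2.07, 73 Å) — from the noisy extracted curves, with reduced χ² near 1
as expected for noise-consistent data.

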