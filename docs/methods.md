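# Methods

This note records the models, numerical choices and known limits of the
package, in the order data flows through it.

## Scattering conventions

Curves are I(Q) with Q = 4π sin(θ)/λ, θ half the scattering angle, in Å⁻¹.
Dilute solutions are assumed throughout: the structure factor is fixed at
S(Q) = 1, so measured intensity is particle form factor times an overall
scale `n (Δρ)² V²` that the package never decomposes — form factors are
normalized to 1 at Q = 0 and a single `scale` parameter carries the rest.

Instrumental resolution is modelled as the wavelength band of a velocity
selector: a fractional FWHM spread Δλ/λ (default 10% at λ = 6 Å) maps to a
Gaussian kernel in Q with σ_q/q = (Δλ/λ)/2.355, truncated at ±3σ, clipped to
the measured Q support and renormalized. A constant curve is therefore
conserved exactly, and the kernel never amplifies a maximum. Smearing is
applied to model curves only; no stage attempts desmearing, matching how
indirect-transform and bead-model programs are used in practice.

## Synthetic SEC-SANS runs

The generator emulates the study conditions: two elliptical-cylinder species
— an elongated one (a = 13.49 Å, ν = 2.06, L = 100 Å, forward scattering
0.075) eluting first and a compact one (a = 14.64 Å, ν = 2.07, L = 73 Å,
0.072) second — on the instrument grid Q = 0.03–0.25 Å⁻¹, smeared as above.
Elution profiles are Gaussians in frame number (centers 18 and 34, widths 4
and 5 frames over 60 frames of 30 s), chosen to overlap partially as a real
chromatogram does; the paper-scale figures fix the geometries and forward
intensities while the elution parameterization is this package's own stated
configuration. The buffer background is flat (0.002) and noise is Gaussian
with σ = noise_scale·√I (counting-statistics shape; exact Poisson is
opt-in); noise_scale = 0.005 gives roughly 2% relative error near the peaks.
All randomness flows from one seed.

What the generator does **not** emulate: column dispersion and the mid-run
flow-rate change, detector geometry, transmission and thickness corrections,
incoherent background structure, or inter-particle interference. Passing
tests therefore demonstrate that the analysis chain is internally correct
and statistically calibrated on idealized mixtures — not that it is robust
to every artifact of real reduced data.

## Guinier analysis

Weighted least squares of ln I against Q², with σ_lnI = σ/I and an
unweighted fallback when uncertainties are absent; Rg = √(−3·slope),
I(0) = exp(intercept). Two window modes exist: an automatic one that caps
the upper edge self-consistently at Q·Rg ≤ 1.3 (configurable) and then
drops leading points only while the first point lies more than two
standardized residuals above the fit (so aggregate upturns are excluded but
smooth curves are not nibbled), and a banded mode that iterates the fit
until the point set equals {Q: qrg_min < Q·Rg < qrg_max}, reproducing
analyses quoted as e.g. 0.35 < QRg < 1.26. Published windows of that form
can begin below the instrument Qmin; analyses on such windows are run on an
extended grid (Q from 0.005 Å⁻¹) and the package treats the window purely
as configuration.

## Indirect Fourier transform

P(r) is represented on a uniform grid of 101 points on [0, Dmax] (about the
granularity classic IFT programs use; linear systems stay small), with
P(0) = P(Dmax) = 0 imposed by construction. The forward map is the
trapezoid discretization of I(Q) = 4π ∫ P(r) sinc(Qr) dr, and the solution
minimizes the weighted data misfit plus α times the squared second
difference of P. When α is not supplied it is chosen at the corner (maximum
curvature) of the log-log L-curve over 31 log-spaced candidates scaled to
the problem. Nonnegativity is not enforced — small oscillations are
permitted, as in common IFT practice — but the Dmax scan rejects candidates
whose P(r) dips below −1% of its maximum. The scan returns the smallest
candidate whose fit χ² is within 5% of the global minimum, which expresses
the usual preference for the shortest support compatible with the data; on
noise-free model curves it lands within one grid step of the true maximum
chord. Rg and I(0) come from trapezoid moments of P(r). With unit weights
(no σ given) the misfit is absolute, which is appropriate for the smooth
model curves used in validation; noisy experimental curves carry their own σ.

## Form factors and fitting

The elliptical cylinder is the orientation average of a double quadrature:
the outer integral over the axis tilt x ∈ [0, 1] carries [sin t/t]² at
t = QLx/2, the inner over the cross-section angle uses Λ₁(t) = 2J₁(t)/t at
effective radius a√((1+ν²)/2 + (1−ν²)/2·cos y), with J₁ the *cylindrical*
first-order Bessel function. Gauss–Legendre quadrature with 76 points per
axis (configurable) follows common small-angle practice; ν = 1 reduces
exactly to the single-integral circular cylinder. The cross-section kernel
is validated against an independent quasi-Monte-Carlo Debye oracle (Sobol
pairs of points filling the body, pair-distance histogram at 0.05 Å)
to < 1% over the instrument range, which pins the kernel convention
unambiguously. Coordinate identity used throughout:
Rg² = (a² + (νa)²)/4 + L²/12.

Fits are bounded trust-region least squares of (I_data − I_model)/σ;
1-σ uncertainties come from the SVD-based covariance at the optimum scaled
by the reduced χ². The additive background defaults to 0 and is fitted only
on request. The pipeline's cylinder fit multi-starts over a small
deterministic grid of (ν, L) initializations because the (L, ν) likelihood
is multimodal on noisy smeared data, and keeps the best reduced χ².

## Ab initio reconstruction

Beads of one radius sit on a face-centred-cubic lattice (12-neighbour close
packing, nearest-neighbour spacing = bead diameter) inside a search sphere
of diameter Dmax; default bead radius Dmax/40, with coarser beads
(≈ Dmax/18, ~550 sites) used in the desk-scale tests. The score is the
scale-optimized curve χ² on a ≤ 40-point rebin of the target (σ defaulting
to 1% of I for noise-free targets) plus a compactness penalty: the fraction
of beads with fewer than three neighbours, weighted by 1 by default.

The anneal starts from a randomly grown *connected* cluster of half the
sites, proposes single-bead toggles (symmetry-paired toggles under P2, whose
180°-about-z image is exact on the fcc lattice, so the P2 invariant holds by
construction), and accepts by Metropolis. Additions are restricted to sites
adjacent to the current model, which keeps the configuration effectively
connected and makes the compactness penalty meaningful. The starting
temperature defaults to the standard deviation of the score change over 100
random toggles, cooling is ×0.9 per stage, a stage is 20 moves per initial
bead, and the schedule stops after 3 low-acceptance stages without 1%
improvement (stall counting is suspended while the chain is still hot) or
100 stages. A zero-temperature quench (greedy passes over shuffled sites)
then polishes the best configuration, and pruning to the largest
(symmetric) connected component alternates with re-quenching until the
model is a single component. Every update of the model intensity is
incremental (cross-term bookkeeping against all candidate sites), which is
what makes desk-scale annealing affordable; the sums are refreshed from
scratch each stage to eliminate float drift. Runs are bit-reproducible from
the seed.

Model intensity backends: the exact Debye double sum, and the multipole
expansion I(Q) = Σ_l Σ_m |A_lm(Q)|² with
A_lm = √(4π) Σ_j g_j j_l(Qr_j) Y*_lm(Ω_j), truncated at
lmax = ⌈Qmax·rmax⌉ + 3 (sampling-theorem rule, auto-raised with a warning if
set lower). With this normalization the plane-wave addition theorem makes
the two backends mathematically identical, and tests hold them to < 1%;
both are modulated by the single-bead sphere form factor.

Alignment centers each model, rotates to principal axes with a
deterministic sign convention (third coordinate moment, falling back to the
largest loading — this makes alignment idempotent), and picks the best of
the four proper axis-flips by NSD against the first model. Averaging snaps
bead centers to cubic cells of the fcc pitch (diameter/√2, which separates
all lattice sites exactly) and keeps cells occupied in at least a fraction
`occupancy_cut` (default 0.5) of the runs, recording that fraction as the
bead occupancy. The averaging rule is this package's own. NSD is the
root-mean-square of cross nearest-neighbour distances, each direction
normalized by the reference spacing (per-set mean nearest-neighbour
spacing; bead diameter for single-bead sets; or an explicit override).

## Atomistic scattering

Structures come from PDB files via gemmi; heavy atoms carry implicit
hydrogens by standard united-atom counts (pH-7 protonation: Asp/Glu
deprotonated, Lys/Arg protonated, neutral His), with hydrogens on N/O/S
marked labile. Neutron weights are g = b − ρ_s·V with tabulated bound
coherent scattering lengths and per-atom displaced volumes (point
correction; no Gaussian-sphere excluded-volume refinement — adequate for
Q ≤ 0.25 Å⁻¹ and a documented limitation). Labile hydrogens scatter as a
(1 − x)·b_H + x·b_D mixture with x = D₂O fraction × exchange fraction
(default exchange 0.9); the solvent SLD interpolates H₂O/D₂O and the
buffer defaults to pure H₂O since no D₂O fraction is part of the study
conditions. The Debye sum is exact for ≤ 5000 atoms and switches to a
0.1 Å pair-distance histogram beyond (relative error ≲ (Q·dr)²/6 < 0.5%).
The rigid-body fit is an exhaustive search over a user-supplied grid of
rotations/translations of the mobile block, with a free overall scale,
optional resolution smearing, and a 2 Å steric-clash rejection — a coarse,
deterministic stand-in for normal-mode flexible fitting, which is out of
scope.

## Pipeline

For a run: scattergram (background-subtracted frame totals), peak detection
above 10% prominence, frame selection within ±1 elution σ of each peak,
inverse-variance averaging, then per fraction: Guinier (auto window), Dmax
scan over (2.6–4.6)×Rg, P(r), Kratky, multi-start cylinder fit, and
optionally bead-model reconstruction (5 runs by default when enabled, 20 in
full mode; disabled by default so the standard report stays interactive).
Stage failures are captured per fraction and the remaining stages still
run. Reports serialize to stable JSON (sorted keys, rounded floats), so
identical configuration and seeds give byte-identical output.

## Desk-scale problem sizes

The validation suite runs everything at sizes chosen for a single CPU:
200-point curves, 101-point P(r) grids, ~550-site reconstruction lattices
with 5 independent runs, 2²² Sobol pairs for the quadrature oracle, and
10-seed fit-recovery ensembles. These are the package's test settings, not
limits of the implementation; every size is a parameter.

## Known limitations

- No desmearing; smearing is forward-only.
- GNOM's perceptual criteria are not reproduced; the L-curve corner stands
  in for them.
- The compactness penalty is a neighbour-count heuristic, not DAMMIF's
  looseness energy; only P1/P2 symmetries are supported.
- United-atom hydrogen counts cover the 20 standard amino acids; ligands
  and waters get no implicit hydrogens.
- The rigid-body search is exhaustive on the given grid — it finds the best
  listed pose, not a continuous optimum.
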