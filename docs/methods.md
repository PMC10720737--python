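# Methods

`sfdimc` simulates spatial frequency domain imaging (SFDI) of a skin block
containing a surgical-incision-like wound, and implements the processing
and metrology needed to study how sharp *vertical* boundaries between
tissues of different reduced scattering distort SFDI images — the
partial-volume / edge-response error in apparent wound width.

## Model system

The tissue is a rectangular voxel grid (default 28 x 20 x 16 mm): lx is
large enough that the absorbing lateral faces cannot influence the central
profile, ly holds at least two fringe periods at the lowest spatial
frequency used (0.1 mm^-1), and lz = 16 mm with a 10 mm deep wound keeps
both media effectively semi-infinite.  The wound is a centered rectangular
block spanning the full y extent: width along x (0.5-6 mm), depth along z
from the surface.  Healthy skin is homogeneous with mua = 0.023 mm^-1 and
musp = 1.42 mm^-1 (typical values around 617 nm); wound states vary musp
over 0.473-4.73 mm^-1 at the same mua, since structural change during
healing expresses itself primarily in scattering.  Anisotropy is g = 0.9
(Henyey-Greenstein) for all tissues.

Wound boundaries are snapped to voxel faces symmetrically about the block
center; the snapped ("realized") width is reported and is what metrology
treats as ground truth, so sub-voxel specification error never leaks into
width-error statistics.

## Photon transport

Weighted hop-drop-spin Monte Carlo in the mcxyz tradition, voxel by voxel:

* hop: optical depth `tau = -ln(xi)` consumed at the local
  `mut = mua + mus`, with sub-stepping at voxel boundaries in
  heterogeneous regions;
* drop: weight fraction `mua/mut` deposited at each interaction;
* spin: Henyey-Greenstein deflection via the exact inverse transform,
  uniform azimuth;
* Russian roulette below weight 0.01 with survival chance 0.1
  (survivors rescaled 10x) — unbiased termination.

Illumination is a collimated fringe pattern: launch positions follow
`1 + M cos(2 pi f u + phase)` along the modulation axis (default y, so the
fringes are orthogonal to the wound's long axis) via a tabulated-CDF
inverse (32769 knots, bisection + linear interpolation; the position-grid
tabulation keeps the density accurate at its zeros when M = 1).

The top surface is index-matched by default: every upward crossing of z=0
escapes into the detector.  This mirrors an instrument that rejects
specular reflection with crossed polarizers and avoids asserting a
refractive index the model system does not pin down; an index-mismatched
mode (unpolarized Fresnel with total internal reflection, default
n = 1.4) is available for sensitivity checks and is the configuration used
when comparing against the diffusion forward model, whose `Reff(n)` term
models exactly that boundary.  Lateral and bottom faces absorb (photons
ledgered as lost); at the production lx = 28 mm this cannot affect the
central field.

Detection: an escape image binned at `bin_mm` (production 0.02 mm, desk
scale 0.05-0.1 mm), and optional nondestructive detector planes at
regular depth spacing that record the photon's current weight at every
downward plane crossing into `Weight_down(x, y, z)` — optionally only
after a minimum number of scattering events (the depth analyses use
min_scatters = 1 to exclude the ballistic beam).

Determinism: each photon runs an independent xorshift64* substream seeded
by splitmix64 from `(seed, photon_index)`, so detector grids are
bit-identical for a given seed and independent of execution order.

Two pure optimizations (identical physics, verified in the test suite by
running with them disabled): an exact per-voxel *safe distance* map lets
photons skip voxel stepping while provably inside one material and away
from lateral/bottom faces, and the bound, once read, is spent across
consecutive hops so that deep photons scatter many times between array
lookups.  Upward surface crossings are intersected analytically.

## SFDI processing

Three phase offsets (0, 2pi/3, 4pi/3) are simulated per frequency and
demodulated pixelwise:

    I_AC = (sqrt(2)/3) sqrt((I1-I2)^2 + (I1-I3)^2 + (I2-I3)^2)

The sqrt(2)/3 prefactor makes an ideal three-phase sinusoid of amplitude B
demodulate to exactly B; the literal constant 2/3 seen in parts of the
literature (returning sqrt(2) B) is available behind a flag.  Width
metrology is invariant to this global scale.  The DC image is the
three-phase mean.  The across-wound profile averages the AC image along
the modulation axis (Ny rows); the same operation applied to a recovered
musp map yields the musp profile.

Demodulating *noisy* images rectifies noise into a positive bias of order
sigma^2/(2B) per pixel.  Wound-profile metrology follows the
demodulate-then-average order (the bias is nearly common-mode there), but
absolute reflectance measurements (e.g. the diffusion-model comparison)
average the phase images over the unmodulated axis first and demodulate
the clean 1D traces.

Calibration ratios a raw AC image against a homogeneous reference of
known properties and multiplies by the reference's model reflectance,
cancelling source intensity and system transfer.  The forward model is
the standard semi-infinite diffusion approximation

    Rd(fx) = 3 A a' / ((mueff'/mutr + 1)(mueff'/mutr + 3A)),

with `mutr = mua + musp`, `a' = musp/mutr`,
`mueff' = sqrt(3 mua mutr + (2 pi fx)^2)`, `A = (1-Reff)/(2(1+Reff))` and
the standard `Reff(n)` polynomial.  Its known limitation matters here:
against two independent Monte Carlo implementations it agrees within
~1-5% at fx <= 0.1 mm^-1 (index-mismatched, n=1.4) but overestimates the
modulated reflectance of a g = 0.9 medium by >10% at fx = 0.2 mm^-1.
High-frequency response is dominated by shallow, few-scatter light for
which the diffusion limit does not hold.

The 2D lookup table tabulates (Rd_dc, Rd_ac) over a (mua, musp) grid via
the diffusion model (a Monte-Carlo-generated table would slot in the same
interface but is not implemented).  Inversion is piecewise-linear in
reflectance space — Delaunay triangulation of the forward points carrying
barycentric interpolation of (mua, musp) — which is the same scheme as
nearest-cell search plus local bilinear refinement but with a robust
off-the-shelf core.  Pixels outside the convex span of the table are
flagged, never extrapolated.  Grid density is the accuracy knob; the
round-trip guardrail (forward then invert, <= 5% max relative error over
100 interior pairs on a 50 x 50 grid with log-spaced mua) is part of the
test suite.

## Width and edge-response metrology

The skin baseline is the profile mean over the outer 25% of x per side,
excluding 2 mm at each extreme end where lateral-boundary losses dim the
simulated image.  Widths are measured at the threshold

    level = baseline + (1 - q) (extremum - baseline)

with crossings located by scanning outward from the extremum and linear
interpolation; q = 0.5 is FWHM.  **Threshold convention, prominently:**
q is measured from the *baseline* side, so q = 0.9 places the threshold
only 10% of the contrast away from the skin level — a near-baseline full
width that captures the full extent of the edge-response spill and
therefore overestimates sharp features.  The conventional reading "width
at 90% of the maximum intensity" (an absolute level at 0.9 x max) is a
*different, less spill-sensitive* measurement; both are expressible
through `estimate_width` (the absolute reading corresponds to
q = 1 - (0.9 max - baseline)/(extremum - baseline)).  Profiles whose
contrast falls below a noise floor (default 3x the baseline-region
standard deviation) raise a flat-profile error rather than returning a
meaningless width — this happens by construction when the wound's musp
approaches the skin's.  Width error is signed: measured minus realized.

Edge response at depth: xz slices of Weight_down (at the volume's y
center) are reduced to the iso-intensity contour at 70% of the
*in-wound-region* maximum, extracted by marching squares.  The contour
depth below the wound center minus that below the wound edge (`u_depth`)
quantifies the U-shaped distortion; an infinite homogeneous medium of the
wound's properties gives a flat contour by symmetry, which serves as the
reference ("ideal") curve.  Transition-shape comparisons align profiles
at their q = 0.9 crossing on a chosen side and resample onto a common
grid.

## Problem sizes

Production runs of record use 0.02 mm voxels/bins and 84e6 photons per
phase.  The package's default desk scale — chosen so the full study grid
runs on a single CPU in well under an hour — is 0.1 mm voxels/bins with
1e6 photons per phase; the apparent-width reproduction uses 0.05 mm
voxels with 5e6 photons per phase over three seeds, and the qualitative
sweep-grid checks (sign and ordering assertions, whose effect sizes are
an order of magnitude above shot noise) run at 5e5 photons per phase,
except the narrowest wound — snapped to 0.4 mm realized width at the
0.1 mm desk voxel, hence the grid's smallest contrast — which keeps 1e6
photons per phase to clear the flat-profile noise gate.
Width estimates at these scales carry a few-percent Monte Carlo scatter,
which is why acceptance checks quote seed-averaged values with explicit
tolerances.

## Known limitations

* The skin is a single homogeneous layer (no epidermis/dermis split), the
  wound is a rectangular block, and surfaces are flat.
* Absorption is held constant between skin and wound; only scattering
  varies.
* No polarization, fluorescence or time resolution; refractive index is
  uniform across tissues.
* The diffusion forward model (hence the LUT) inherits the
  diffusion-approximation error at high spatial frequency described
  above.
* Synthetic images contain only Monte Carlo shot noise — no camera dark
  noise, no projector nonlinearity, no height/profile variation — so
  passing tests bound algorithmic correctness, not instrument effects.
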