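# sfdimc

Monte Carlo simulation and processing of **spatial frequency domain
imaging (SFDI)** for vertically heterogeneous tissue — specifically, a
surgical-incision-like wound embedded in skin — to quantify how sharp
vertical boundaries between tissues of different reduced scattering
distort SFDI images (the partial-volume / edge-response error in apparent
wound width).

It is written for tissue-optics researchers and SFDI instrument designers
who want to predict, at the design stage, how accurately a wound of given
width and scattering contrast can be measured at a given spatial
frequency.

## What it does

* **Voxelized photon transport** (`sfdimc.transport`): weighted
  hop-drop-spin Monte Carlo with Henyey-Greenstein scattering (g = 0.9),
  Russian roulette, collimated *sinusoidal-fringe* launch densities
  `1 + M cos(2 pi f y + phase)`, a binned top-surface escape detector,
  and nondestructive depth planes recording the downward-crossing weight
  `Weight_down(x, y, z)`.  A numba inner loop traces ~5e4 photons/s per
  core at study scale; per-photon RNG substreams make runs bit-reproducible.
* **Wound geometry** (`sfdimc.geometry`): homogeneous blocks and the
  centered rectangular wound (width along x, full y extent, depth from
  the surface), with voxel-snapped ("realized") widths reported as
  ground truth.
* **SFDI processing** (`sfdimc.sfdi`): three-phase demodulation

      I_AC = (sqrt(2)/3) sqrt((I1-I2)^2 + (I1-I3)^2 + (I2-I3)^2),

  DC demodulation, y-averaged profiles `I_curve,AC(x)`, the standard
  semi-infinite diffusion forward model `Rd(mua, musp', fx, n)`,
  reference-phantom calibration, and 2D lookup-table inversion of
  (Rd_DC, Rd_AC) into per-pixel (mua, musp') maps.
* **Metrology** (`sfdimc.metrology`): full widths at configurable
  threshold fractions (q = 0.5 is FWHM; q = 0.9 sits 10% of the contrast
  from the skin baseline and captures the edge-response spill), signed
  width errors (measured - truth), 70%-of-maximum iso-contours of
  `Weight_down` xz slices with center/edge depths (`u_depth` quantifies
  the U-shaped edge response), and profile alignment for transition-shape
  comparison.
* **Experiments** (`sfdimc.experiments`): the width x musp' x fx sweep
  grid, absolute-reflectance normalization, deterministic fixtures, and a
  CLI (`sfdimc simulate | process | sweep | contour | fixtures`).

## Worked example

Simulate the 2 mm wide, 10 mm deep wound (wound musp' = 0.71 mm^-1 in
skin of 1.42 mm^-1, mua = 0.023 mm^-1, g = 0.9) at fx = 0.1 mm^-1 and
measure its apparent width:

```python
import sfdimc as m
from sfdimc.experiments import wound_profile

profile, realized = wound_profile(
    width_mm=2.0, wound_musp=0.71, frequency=0.1,
    n_photons=1_000_000, seed=1, voxel_mm=0.1, bin_mm=0.1,
)
for q in (0.5, 0.9):
    est = m.estimate_width(profile, q=q)
    rec = m.width_error(est, realized)
    print(f"q={q}: width {est.width:.2f} mm, error {rec.error:+.2f} mm")
```

Output from this exact invocation:

```
q=0.5: width 2.17 mm, error +0.17 mm
q=0.9: width 3.26 mm, error +1.26 mm
```

Both thresholds overestimate the 2.00 mm truth: diffuse light spills
across the vertical wound-skin boundary, and the effect grows as the
threshold approaches the skin baseline (q = 0.9).  The overestimation
shrinks with wider wounds, higher wound scattering and higher spatial
frequency — the central trade-off the package is built to map.

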