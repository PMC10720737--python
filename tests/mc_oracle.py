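"""Independent reference Monte Carlo for homogeneous semi-infinite media.

A deliberately separate implementation — vectorized numpy, analytic free
paths, no voxel grid, no lateral boundaries — used only as a cross-check
oracle for the production transport kernel.  Matched boundary, weighted
absorption, Henyey-Greenstein scattering, Russian roulette (threshold
0.01, survival 0.1).
"""

from __future__ import annotations

import numpy as np


def semi_infinite_rd(
    mua: float,
    musp: float,
    g: float,
    n_photons: int,
    seed: int,
    fxs=(0.0,),
    batch: int = 100_000,
):
    """Diffuse reflectance Rd(fx) via the point-source impulse response.

    All photons launch at the origin heading down; escaped weights are
    accumulated with ``cos(2 pi fx * y_exit)`` factors, whose expectation
    is the spatial-frequency response of the medium (the sine terms vanish
    by symmetry).  Returns an array aligned with ``fxs``.
    """
    mus = musp / (1.0 - g)
    mut = mua + mus
    rng = np.random.default_rng(seed)
    acc = np.zeros(len(fxs))
    total = 0
    while total < n_photons:
        nb = min(batch, n_photons - total)
        total += nb
        x = np.zeros(nb)
        y = np.zeros(nb)
        z = np.zeros(nb)
        ux = np.zeros(nb)
        uy = np.zeros(nb)
        uz = np.ones(nb)
        w = np.ones(nb)
        alive = np.ones(nb, bool)
        while alive.any():
            idx = np.flatnonzero(alive)
            s = -np.log1p(-rng.random(idx.size)) / mut
            nz = z[idx] + s * uz[idx]
            esc = nz < 0
            ei = idx[esc]
            if ei.size:
                t = -z[ei] / uz[ei]
                ye = y[ei] + t * uy[ei]
                for k, fx in enumerate(fxs):
                    acc[k] += np.sum(w[ei] * np.cos(2 * np.pi * fx * ye))
                alive[ei] = False
            ii = idx[~esc]
            x[ii] += s[~esc] * ux[ii]
            y[ii] += s[~esc] * uy[ii]
            z[ii] = nz[~esc]
            w[ii] *= mus / mut
            u = rng.random(ii.size)
            if g != 0.0:
                tmp = (1 - g * g) / (1 - g + 2 * g * u)
                ct = np.clip((1 + g * g - tmp * tmp) / (2 * g), -1.0, 1.0)
            else:
                ct = 2 * u - 1
            st = np.sqrt(np.clip(1 - ct * ct, 0, None))
            phi = 2 * np.pi * rng.random(ii.size)
            cp, sp = np.cos(phi), np.sin(phi)
            uzi, uxi, uyi = uz[ii], ux[ii], uy[ii]
            near = np.abs(uzi) > 0.99999
            den = np.sqrt(np.clip(1 - uzi**2, 1e-30, None))
            nux = np.where(
                near, st * cp, st * (uxi * uzi * cp - uyi * sp) / den + uxi * ct
            )
            nuy = np.where(
                near, st * sp, st * (uyi * uzi * cp + uxi * sp) / den + uyi * ct
            )
            nuz = np.where(near, np.sign(uzi) * ct, -st * cp * den + uzi * ct)
            nrm = np.sqrt(nux**2 + nuy**2 + nuz**2)
            ux[ii] = nux / nrm
            uy[ii] = nuy / nrm
            uz[ii] = nuz / nrm
            low = w[ii] < 0.01
            li = ii[low]
            surv = rng.random(li.size) < 0.1
            w[li[surv]] /= 0.1
            alive[li[~surv]] = False
    return acc / total
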