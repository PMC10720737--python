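"""Numba inner loop for voxelized photon transport.

Everything here is mechanical: the physics contract (hop lengths from the
local attenuation, weight drop ``mua/mut`` per interaction, Henyey-Greenstein
spin, Russian roulette, escape through the top face, nondestructive
downward-crossing detector planes) is documented on
:func:`sfdimc.transport.run_simulation`.

Two pure optimizations keep the walk fast without touching the physics:

* free flight — the per-voxel ``safe`` map bounds the distance to any
  material change or lateral/bottom exit, so hops shorter than the bound
  skip voxel-by-voxel stepping entirely (the top surface is excluded from
  the bound and upward crossings are intersected analytically);
* a travel *budget* — the safe bound, once read, is spent across several
  consecutive hops, so photons deep in homogeneous tissue do many
  scattering events without a single array lookup.

The RNG is a per-photon substream: photon ``i`` seeds an xorshift64* state
via two rounds of splitmix64 on ``(seed, i)``, so results are independent
of photon execution order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

U64 = np.uint64
_SM_GAMMA = U64(0x9E3779B97F4A7C15)
_SM_M1 = U64(0xBF58476D1CE4E5B9)
_SM_M2 = U64(0x94D049BB133111EB)
_XS_M = U64(0x2545F4914F6CDD1D)
_S12 = U64(12)
_S25 = U64(25)
_S27 = U64(27)
_S30 = U64(30)
_S31 = U64(31)
_S11 = U64(11)
_INV53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True, inline="always")
def _splitmix64(x):
    z = x + _SM_GAMMA
    z = (z ^ (z >> _S30)) * _SM_M1
    z = (z ^ (z >> _S27)) * _SM_M2
    return z ^ (z >> _S31)


@njit(cache=True, inline="always")
def _photon_state(seed, i):
    s = _splitmix64(_splitmix64(seed) + U64(i) * _SM_GAMMA)
    if s == U64(0):
        s = _SM_GAMMA
    return s


@njit(cache=True, inline="always")
def _next_uniform(state):
    """xorshift64*; returns (new_state, double in [0, 1))."""
    s = state
    s ^= s >> _S12
    s ^= s << _S25
    s ^= s >> _S27
    r = s * _XS_M
    return s, float(r >> _S11) * _INV53


@njit(cache=True, inline="always")
def _record_planes(
    wdown, x0, y0, z0, z1, ux, uy, uz, w, plane_dz, inv_bin, nbx, nby, npl
):
    # crossings of planes z = m*plane_dz with z0 < z <= z1 (downward segment)
    m = int(z0 / plane_dz) + 1
    zk = m * plane_dz
    while zk <= z1:
        if zk > z0:  # strict: a segment starting exactly on a plane skips it
            kk = m - 1
            if kk >= npl:
                return
            t = (zk - z0) / uz
            bx = int((x0 + t * ux) * inv_bin)
            by = int((y0 + t * uy) * inv_bin)
            if bx < 0:
                bx = 0
            elif bx >= nbx:
                bx = nbx - 1
            if by < 0:
                by = 0
            elif by >= nby:
                by = nby - 1
            wdown[bx, by, kk] += w
        m += 1
        zk = m * plane_dz


@njit(cache=True, inline="always")
def _fresnel_up(uz, n_rel):
    """Unpolarized Fresnel reflectance for an upward surface hit."""
    ci = -uz
    si2 = 1.0 - ci * ci
    sts2 = n_rel * n_rel * si2
    if sts2 >= 1.0:
        return 1.0  # total internal reflection
    ct_t = np.sqrt(1.0 - sts2)
    rs = (n_rel * ci - ct_t) / (n_rel * ci + ct_t)
    rp = (ci - n_rel * ct_t) / (ci + n_rel * ct_t)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, fastmath=True, boundscheck=False)
def trace_photons(
    labels,          # int8 (nx, ny, nz)
    safe,            # float32 (nx, ny, nz), same-material distance bound
    mua_t, mus_t, g_t,  # per-label tables
    dx,              # voxel size (mm)
    n_photons, seed,
    mod_axis,        # 0: modulate x, 1: modulate y
    inv_cdf,         # inverse-CDF table for the modulated coordinate; len 0 -> uniform
    bin_mm, escape,  # escape image (nbx, nby)
    plane_dz, wdown, min_scatters,  # plane_dz <= 0 disables weight_down
    roulette_threshold, roulette_chance,
    mismatched, n_rel,  # Fresnel tissue/ambient index ratio when mismatched
):
    nxv, nyv, nzv = labels.shape
    lx = nxv * dx
    ly = nyv * dx
    invdx = 1.0 / dx
    inv_bin = 1.0 / bin_mm
    nbx, nby = escape.shape
    npl = wdown.shape[2]
    nk = inv_cdf.shape[0]
    record = plane_dz > 0.0

    escaped = 0.0
    absorbed = 0.0
    lost = 0.0
    killed = 0.0

    for i in range(n_photons):
        st = _photon_state(U64(seed), i)

        # --- launch: z=0, collimated straight down ---
        st, u1 = _next_uniform(st)
        st, u2 = _next_uniform(st)
        if nk > 0:
            # invert the tabulated CDF (uniform position grid) by bisection
            lo = 0
            hi = nk - 1
            while hi - lo > 1:
                mid = (lo + hi) >> 1
                if inv_cdf[mid] <= u2:
                    lo = mid
                else:
                    hi = mid
            c0 = inv_cdf[lo]
            c1 = inv_cdf[hi]
            frac = (u2 - c0) / (c1 - c0) if c1 > c0 else 0.0
            mod_len = ly if mod_axis == 1 else lx
            m_coord = (lo + frac) * (mod_len / (nk - 1))
        else:
            m_coord = -1.0
        if mod_axis == 1:
            x = u1 * lx
            y = m_coord if nk > 0 else u2 * ly
        else:
            y = u1 * ly
            x = m_coord if nk > 0 else u2 * lx
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        ns = 0

        ix = 0
        iy = 0
        iz = 0
        lab = np.int8(0)
        mua = 0.0
        mus = 0.0
        mut = 1.0
        budget = 0.0  # guaranteed same-material travel allowance left
        alive = True

        while alive:
            st, u = _next_uniform(st)
            tau = -np.log(1.0 - u)

            # --- propagate until tau is consumed or the photon dies ---
            while True:
                s_need = tau / mut
                t_surf = (-z / uz) if uz < 0.0 else 1.0e30

                if s_need < budget and s_need < t_surf:
                    # lookup-free flight inside the spent-down safe bound
                    if record and uz > 0.0 and ns >= min_scatters:
                        _record_planes(
                            wdown, x, y, z, z + s_need * uz, ux, uy, uz, w,
                            plane_dz, inv_bin, nbx, nby, npl,
                        )
                    x += s_need * ux
                    y += s_need * uy
                    z += s_need * uz
                    budget -= s_need
                    break  # interact

                if t_surf < budget:
                    # clean analytic run up to the surface
                    xc = x + t_surf * ux
                    yc = y + t_surf * uy
                    do_escape = True
                    if mismatched:
                        st, u = _next_uniform(st)
                        if u < _fresnel_up(uz, n_rel):
                            do_escape = False
                    if do_escape:
                        bx = int(xc * inv_bin)
                        by = int(yc * inv_bin)
                        if bx < 0:
                            bx = 0
                        elif bx >= nbx:
                            bx = nbx - 1
                        if by < 0:
                            by = 0
                        elif by >= nby:
                            by = nby - 1
                        escape[bx, by] += w
                        escaped += w
                        alive = False
                        break
                    tau -= t_surf * mut
                    x = xc
                    y = yc
                    z = 0.0
                    uz = -uz
                    budget -= t_surf
                    continue

                # --- refresh the material and safe bound at this position ---
                ix = int(x * invdx)
                if ix < 0:
                    ix = 0
                elif ix >= nxv:
                    ix = nxv - 1
                iy = int(y * invdx)
                if iy < 0:
                    iy = 0
                elif iy >= nyv:
                    iy = nyv - 1
                iz = int(z * invdx)
                if iz < 0:
                    iz = 0
                elif iz >= nzv:
                    iz = nzv - 1
                lab = labels[ix, iy, iz]
                mua = mua_t[lab]
                mus = mus_t[lab]
                mut = mua + mus
                s_need = tau / mut
                budget = safe[ix, iy, iz]
                if (s_need < budget and s_need < t_surf) or t_surf < budget:
                    continue  # fly / surface-hit with the fresh bound

                # --- voxel-by-voxel stepping near boundaries ---
                budget = 0.0
                stepping = True
                while stepping:
                    lab = labels[ix, iy, iz]
                    mua = mua_t[lab]
                    mus = mus_t[lab]
                    mut = mua + mus
                    s_need = tau / mut

                    if ux > 0.0:
                        tx = ((ix + 1) * dx - x) / ux
                    elif ux < 0.0:
                        tx = (ix * dx - x) / ux
                    else:
                        tx = 1.0e30
                    if uy > 0.0:
                        ty = ((iy + 1) * dx - y) / uy
                    elif uy < 0.0:
                        ty = (iy * dx - y) / uy
                    else:
                        ty = 1.0e30
                    if uz > 0.0:
                        tz = ((iz + 1) * dx - z) / uz
                    elif uz < 0.0:
                        tz = (iz * dx - z) / uz
                    else:
                        tz = 1.0e30
                    if tx < 0.0:
                        tx = 0.0
                    if ty < 0.0:
                        ty = 0.0
                    if tz < 0.0:
                        tz = 0.0
                    db = tx
                    axis = 0
                    if ty < db:
                        db = ty
                        axis = 1
                    if tz < db:
                        db = tz
                        axis = 2

                    if s_need <= db:
                        # interaction inside this voxel
                        if record and uz > 0.0 and ns >= min_scatters:
                            _record_planes(
                                wdown, x, y, z, z + s_need * uz, ux, uy, uz,
                                w, plane_dz, inv_bin, nbx, nby, npl,
                            )
                        x += s_need * ux
                        y += s_need * uy
                        z += s_need * uz
                        stepping = False
                        break  # interact

                    x1 = x + db * ux
                    y1 = y + db * uy
                    z1 = z + db * uz
                    tau -= db * mut
                    if record and uz > 0.0 and ns >= min_scatters:
                        _record_planes(
                            wdown, x, y, z, z1, ux, uy, uz, w,
                            plane_dz, inv_bin, nbx, nby, npl,
                        )
                    x = x1
                    y = y1
                    z = z1
                    if axis == 0:
                        if ux > 0.0:
                            ix += 1
                            x = ix * dx
                            if ix >= nxv:
                                lost += w
                                alive = False
                                stepping = False
                        else:
                            x = ix * dx
                            ix -= 1
                            if ix < 0:
                                lost += w
                                alive = False
                                stepping = False
                    elif axis == 1:
                        if uy > 0.0:
                            iy += 1
                            y = iy * dx
                            if iy >= nyv:
                                lost += w
                                alive = False
                                stepping = False
                        else:
                            y = iy * dx
                            iy -= 1
                            if iy < 0:
                                lost += w
                                alive = False
                                stepping = False
                    else:
                        if uz > 0.0:
                            iz += 1
                            z = iz * dx
                            if iz >= nzv:
                                lost += w  # bottom face, ledgered with lateral
                                alive = False
                                stepping = False
                        else:
                            z = iz * dx
                            iz -= 1
                            if iz < 0:
                                # upward crossing of the top surface
                                do_escape = True
                                if mismatched:
                                    st, u = _next_uniform(st)
                                    if u < _fresnel_up(uz, n_rel):
                                        do_escape = False
                                if do_escape:
                                    bx = int(x * inv_bin)
                                    by = int(y * inv_bin)
                                    if bx < 0:
                                        bx = 0
                                    elif bx >= nbx:
                                        bx = nbx - 1
                                    if by < 0:
                                        by = 0
                                    elif by >= nby:
                                        by = nby - 1
                                    escape[bx, by] += w
                                    escaped += w
                                    alive = False
                                    stepping = False
                                else:
                                    uz = -uz
                                    iz = 0
                                    z = 0.0
                # the stepping loop exits only on death or interaction
                break

            if not alive:
                break

            # --- interaction: drop, spin, roulette ---
            absorbed += w * mua / mut
            w *= 1.0 - mua / mut
            ns += 1

            g = g_t[lab]
            st, u = _next_uniform(st)
            if g != 0.0:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
                ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                if ct > 1.0:
                    ct = 1.0
                elif ct < -1.0:
                    ct = -1.0
            else:
                ct = 2.0 * u - 1.0
            sth = np.sqrt(1.0 - ct * ct)
            st, u = _next_uniform(st)
            # azimuth: cos from libm, |sin| from the identity, sign from the
            # half of [0,1) the draw fell in (sin >= 0 iff u <= 1/2)
            cp = np.cos(6.283185307179586 * u)
            sp = np.sqrt(1.0 - cp * cp)
            if u > 0.5:
                sp = -sp
            if uz > 0.99999 or uz < -0.99999:
                ux = sth * cp
                uy = sth * sp
                uz = ct if uz > 0.0 else -ct
            else:
                den = np.sqrt(1.0 - uz * uz)
                inv_den = sth / den
                uxn = (ux * uz * cp - uy * sp) * inv_den + ux * ct
                uyn = (uy * uz * cp + ux * sp) * inv_den + uy * ct
                uzn = -sth * cp * den + uz * ct
                ux = uxn
                uy = uyn
                uz = uzn
            # one Newton step of 1/sqrt about 1 renormalizes to O(eps^2)
            corr = 1.5 - 0.5 * (ux * ux + uy * uy + uz * uz)
            ux *= corr
            uy *= corr
            uz *= corr

            if w < roulette_threshold:
                st, u = _next_uniform(st)
                if u < roulette_chance:
                    w /= roulette_chance
                else:
                    killed += w
                    alive = False

    out = np.empty(5)
    out[0] = float(n_photons)  # launched (unit initial weight)
    out[1] = escaped
    out[2] = absorbed
    out[3] = lost
    out[4] = killed
    return out


@njit(cache=True)
def hg_costheta_kernel(g, n, seed):
    """n HG deflection cosines from the same substream RNG as the tracer."""
    out = np.empty(n)
    st = _photon_state(U64(seed), 0)
    for i in range(n):
        st, u = _next_uniform(st)
        if g != 0.0:
            tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
            ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
            if ct > 1.0:
                ct = 1.0
            elif ct < -1.0:
                ct = -1.0
        else:
            ct = 2.0 * u - 1.0
        out[i] = ct
    return out
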