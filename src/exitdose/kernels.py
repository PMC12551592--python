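"""Numba kernels: analog photon transport, physics sampling, geometry stepping.

Everything here operates on flat arrays packed by the Python-facing modules
(:mod:`exitdose.materials`, :mod:`exitdose.geometry`, :mod:`exitdose.transport`).
The kernels are deliberately free of Python objects so a full study
(~10^7 histories) runs in minutes on one core.

Conventions
-----------
* IEC 61217 coordinates, cm; the beam travels along -Z from a source at +100.
* Energies in MeV; weights dimensionless.
* A particle state is (E, x, y, z, u, v, w, weight, history id, plane flags).
* Dose voxels are flat-indexed ``(idepth * nx + ix) * ny + iy``.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

M_EC2 = 0.510998950  # electron rest energy, MeV
ANNIH_E = 0.510998950
PAIR_THRESHOLD = 2.0 * M_EC2  # 1.022 MeV

_EPS_NUDGE = 1e-7  # cm, push past a boundary after crossing
_EPS_T = 1e-9  # minimum accepted boundary distance
_WORLD_HALF = 300.0  # cm, world bounding box half-extent
_STACK = 512

# shape codes
SHAPE_BOX = 0
SHAPE_YCYL = 1
SHAPE_YELLIP = 2

INF = 1e30


# ---------------------------------------------------------------------------
# counter-based random streams (splitmix64)
#
# Every history owns an independent stream keyed by (seed, history id,
# record ordinal, stage/replica tag).  This decouples histories from
# execution order, keeps buffer-overflow retries bit-identical, and gives
# true common-random-number pairing when the same seed is run through two
# geometries (the paired-seed case comparisons rely on this).
# ---------------------------------------------------------------------------

_U64_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_INV_2_53 = 1.0 / 9007199254740992.0


@njit(cache=True, inline="always")
def _mix64(z):
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def stream_init(seed, a, b, c):
    """Initial splitmix64 state for stream (seed, a, b, c)."""
    z = _mix64(np.uint64(seed) + _U64_GOLDEN)
    z = _mix64(z ^ (np.uint64(a) + np.uint64(0xD1B54A32D192ED03)))
    z = _mix64(z ^ (np.uint64(b) + np.uint64(0x8CB92BA72F3D8DD7)))
    z = _mix64(z ^ (np.uint64(c) + _U64_GOLDEN))
    return z


@njit(cache=True, inline="always")
def _u01(rst):
    """Next uniform double in [0, 1) from the stream state array."""
    rst[0] += _U64_GOLDEN
    return float(_mix64(rst[0]) >> np.uint64(11)) * _INV_2_53


def new_stream(seed, a=0, b=0, c=0):
    """Python-side stream constructor (uint64[1] state array)."""
    return np.array([stream_init(seed, a, b, c)], dtype=np.uint64)


# ---------------------------------------------------------------------------
# cross-section lookup
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _grid_index(E, loge0, dloge, ne):
    f = (math.log(E) - loge0) / dloge
    i = int(f)
    if i < 0:
        i = 0
    elif i > ne - 2:
        i = ne - 2
    return i, f - i


@njit(cache=True, inline="always")
def mu_total_kernel(mat, E, loge0, dloge, ne, lnmu):
    """Log-log interpolated total linear attenuation coefficient, 1/cm."""
    i, f = _grid_index(E, loge0, dloge, ne)
    return math.exp(lnmu[mat, i] * (1.0 - f) + lnmu[mat, i + 1] * f)


@njit(cache=True, inline="always")
def mu_partials_kernel(mat, E, loge0, dloge, ne, mu4):
    """Linearly interpolated partial linear coefficients (pe, inc, pair)."""
    i, f = _grid_index(E, loge0, dloge, ne)
    g = 1.0 - f
    pe = mu4[mat, i, 0] * g + mu4[mat, i + 1, 0] * f
    inc = mu4[mat, i, 1] * g + mu4[mat, i + 1, 1] * f
    pair = mu4[mat, i, 2] * g + mu4[mat, i + 1, 2] * f
    if E <= PAIR_THRESHOLD:
        pair = 0.0
    return pe, inc, pair


# ---------------------------------------------------------------------------
# physics sampling
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def compton_energy(E, costheta):
    return E / (1.0 + (E / M_EC2) * (1.0 - costheta))


@njit(cache=True)
def sample_compton_kernel(E, rst):
    """Kahn's rejection sampling of the Klein-Nishina distribution.

    Returns (scattered energy E', cos(theta)).  x = E/E'.
    """
    a = E / M_EC2
    t = 1.0 + 2.0 * a
    p1 = t / (t + 8.0)  # (1+2a)/(9+2a)
    while True:
        r1 = _u01(rst)
        r2 = _u01(rst)
        r3 = _u01(rst)
        if r1 <= p1:
            x = 1.0 + 2.0 * a * r2
            if r3 <= 4.0 * (1.0 / x - 1.0 / (x * x)):
                break
        else:
            x = t / (1.0 + 2.0 * a * r2)
            c = 1.0 - (x - 1.0) / a
            if r3 <= 0.5 * (c * c + 1.0 / x):
                break
    costheta = 1.0 - (x - 1.0) / a
    if costheta < -1.0:
        costheta = -1.0
    elif costheta > 1.0:
        costheta = 1.0
    return E / x, costheta


@njit(cache=True)
def sample_compton_many(E, n, seed):
    """Batch Klein-Nishina sampling (one stream per draw); returns (E', cos)."""
    out_e = np.empty(n)
    out_c = np.empty(n)
    rst = np.zeros(1, dtype=np.uint64)
    for i in range(n):
        rst[0] = stream_init(seed, i, 0, 7)
        out_e[i], out_c[i] = sample_compton_kernel(E, rst)
    return out_e, out_c


@njit(cache=True, inline="always")
def select_kind(pe, inc, pair, xi):
    """Interaction kind from partial coefficients: 0 pe, 1 compton, 2 pair.

    ``xi`` is uniform on [0, pe+inc+pair).
    """
    if xi < pe:
        return 0
    if xi < pe + inc:
        return 1
    return 2


@njit(cache=True)
def sample_kind_kernel(mat, E, loge0, dloge, ne, mu4, rst):
    pe, inc, pair = mu_partials_kernel(mat, E, loge0, dloge, ne, mu4)
    return select_kind(pe, inc, pair, _u01(rst) * (pe + inc + pair))


@njit(cache=True, inline="always")
def _isotropic(rst):
    w = 2.0 * _u01(rst) - 1.0
    phi = 2.0 * math.pi * _u01(rst)
    s = math.sqrt(max(0.0, 1.0 - w * w))
    return s * math.cos(phi), s * math.sin(phi), w


@njit(cache=True, inline="always")
def _rotate(u, v, w, costheta, phi):
    """Rotate direction (u,v,w) by polar angle theta about itself, azimuth phi."""
    sintheta = math.sqrt(max(0.0, 1.0 - costheta * costheta))
    cphi = math.cos(phi)
    sphi = math.sin(phi)
    if abs(w) < 0.999999:
        denom = math.sqrt(1.0 - w * w)
        un = u * costheta + sintheta * (u * w * cphi - v * sphi) / denom
        vn = v * costheta + sintheta * (v * w * cphi + u * sphi) / denom
        wn = w * costheta - sintheta * denom * cphi
    else:
        un = sintheta * cphi
        vn = sintheta * sphi
        wn = costheta if w > 0.0 else -costheta
    norm = math.sqrt(un * un + vn * vn + wn * wn)
    return un / norm, vn / norm, wn / norm


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _inside(code, p, x, y, z):
    if code == SHAPE_BOX:
        return (p[0] <= x < p[1]) and (p[2] <= y < p[3]) and (p[4] <= z < p[5])
    if code == SHAPE_YCYL:
        if not (p[3] <= y < p[4]):
            return False
        dx = x - p[0]
        dz = z - p[1]
        return dx * dx + dz * dz <= p[2] * p[2]
    # elliptical cylinder about Y
    if not (p[4] <= y < p[5]):
        return False
    dx = (x - p[0]) / p[2]
    dz = (z - p[1]) / p[3]
    return dx * dx + dz * dz <= 1.0


@njit(cache=True)
def locate_kernel(x, y, z, shape_code, params, nreg):
    """First region (priority order) containing the point; -1 = world air."""
    for i in range(nreg):
        if _inside(shape_code[i], params[i], x, y, z):
            return i
    return -1


@njit(cache=True, inline="always")
def _slab_interval(o, d, lo, hi, tin, tout):
    if d > 1e-14 or d < -1e-14:
        t1 = (lo - o) / d
        t2 = (hi - o) / d
        if t1 > t2:
            t1, t2 = t2, t1
        if t1 > tin:
            tin = t1
        if t2 < tout:
            tout = t2
    elif o < lo or o >= hi:
        return 1.0, -1.0  # miss
    return tin, tout


@njit(cache=True)
def region_interval(code, p, ox, oy, oz, ux, uy, uz):
    """Parametric interval [tin, tout] of ray inside a region (tin>tout: miss)."""
    tin = -INF
    tout = INF
    if code == SHAPE_BOX:
        tin, tout = _slab_interval(ox, ux, p[0], p[1], tin, tout)
        if tin > tout:
            return 1.0, -1.0
        tin, tout = _slab_interval(oy, uy, p[2], p[3], tin, tout)
        if tin > tout:
            return 1.0, -1.0
        tin, tout = _slab_interval(oz, uz, p[4], p[5], tin, tout)
        return tin, tout
    if code == SHAPE_YCYL:
        tin, tout = _slab_interval(oy, uy, p[3], p[4], tin, tout)
        if tin > tout:
            return 1.0, -1.0
        X = ox - p[0]
        Z = oz - p[1]
        A = ux * ux + uz * uz
        B = 2.0 * (X * ux + Z * uz)
        C = X * X + Z * Z - p[2] * p[2]
    else:
        tin, tout = _slab_interval(oy, uy, p[4], p[5], tin, tout)
        if tin > tout:
            return 1.0, -1.0
        X = (ox - p[0]) / p[2]
        Z = (oz - p[1]) / p[3]
        U = ux / p[2]
        W = uz / p[3]
        A = U * U + W * W
        B = 2.0 * (X * U + Z * W)
        C = X * X + Z * Z - 1.0
    if A < 1e-16:
        if C > 0.0:
            return 1.0, -1.0
        return tin, tout
    disc = B * B - 4.0 * A * C
    if disc < 0.0:
        return 1.0, -1.0
    sq = math.sqrt(disc)
    t1 = (-B - sq) / (2.0 * A)
    t2 = (-B + sq) / (2.0 * A)
    if t1 > tin:
        tin = t1
    if t2 < tout:
        tout = t2
    return tin, tout


@njit(cache=True)
def next_boundary(x, y, z, u, v, w, shape_code, params, nreg):
    """(distance to the nearest region-boundary candidate, world-exit distance)."""
    best = INF
    for i in range(nreg):
        tin, tout = region_interval(shape_code[i], params[i], x, y, z, u, v, w)
        if tin <= tout:
            if tin > _EPS_T and tin < best:
                best = tin
            if tout > _EPS_T and tout < best:
                best = tout
    # world bounding box exit
    tw = INF
    if u > 1e-14:
        tw = min(tw, (_WORLD_HALF - x) / u)
    elif u < -1e-14:
        tw = min(tw, (-_WORLD_HALF - x) / u)
    if v > 1e-14:
        tw = min(tw, (_WORLD_HALF - y) / v)
    elif v < -1e-14:
        tw = min(tw, (-_WORLD_HALF - y) / v)
    if w > 1e-14:
        tw = min(tw, (_WORLD_HALF - z) / w)
    elif w < -1e-14:
        tw = min(tw, (-_WORLD_HALF - z) / w)
    return best, tw


# ---------------------------------------------------------------------------
# dose scoring (per-history batch statistics via pending-flush)
# ---------------------------------------------------------------------------

N_COARSE = 124      # 2 mm bins over 0-248 mm
N_FINE = 100        # 0.02 mm bins over 248-250 mm
N_DEPTH = N_COARSE + N_FINE


@njit(cache=True, inline="always")
def _depth_index(depth_cm):
    if depth_cm < 0.0 or depth_cm > 25.0:
        return -1
    if depth_cm < 24.8:
        return int(depth_cm * 5.0)
    i = N_COARSE + int((depth_cm - 24.8) * 500.0)
    if i > N_DEPTH - 1:
        i = N_DEPTH - 1
    return i


@njit(cache=True, inline="always")
def _score_phantom(x, y, z, wt, edep, hid, gx0, gy0, ztop, nx, ny,
                   pend, pend_hid, s1, s2):
    idep = _depth_index(ztop - z)
    if idep < 0:
        return False
    ix = int((x - gx0) / 2.4)
    if ix < 0 or ix >= nx:
        return False
    iy = int((y - gy0) / 2.4)
    if iy < 0 or iy >= ny:
        return False
    idx = (idep * nx + ix) * ny + iy
    if pend_hid[idx] != hid:
        val = pend[idx]
        if val != 0.0:
            s1[idx] += val
            s2[idx] += val * val
            pend[idx] = 0.0
        pend_hid[idx] = hid
    pend[idx] += wt * edep
    return True


@njit(cache=True)
def flush_pending(pend, pend_hid, s1, s2):
    for idx in range(pend.shape[0]):
        val = pend[idx]
        if val != 0.0:
            s1[idx] += val
            s2[idx] += val * val
            pend[idx] = 0.0
        pend_hid[idx] = -1


# tally indices
T_LAUNCH_E = 0
T_DEP_PHANTOM = 1
T_DEP_ELSE = 2
T_ESCAPE_E = 3
T_CAPTURED_E = 4
T_LAUNCH_W = 5
T_CUTOFF_E = 6  # folded into deposits; kept for diagnostics


@njit(cache=True)
def _capture(ip, E, cx, cy, u, v, w, wt, hid,
             cap_E, cap_x, cap_y, cap_u, cap_v, cap_w, cap_wt, cap_hid,
             cap_plane, cap_n, plane_wsum, plane_count):
    plane_wsum[ip] += wt
    plane_count[ip] += 1
    n = cap_n[0]
    if n < cap_E.shape[0]:
        cap_E[n] = E
        cap_x[n] = cx
        cap_y[n] = cy
        cap_u[n] = u
        cap_v[n] = v
        cap_w[n] = w
        cap_wt[n] = wt
        cap_hid[n] = hid
        cap_plane[n] = ip
        cap_n[0] = n + 1
    else:
        cap_n[1] = 1  # overflow flag


@njit(cache=True)
def track_one(E0, x0, y0, z0, u0, v0, w0, wt0, hid, flags0,
              st_E, st_x, st_y, st_z, st_u, st_v, st_w, st_wt, st_fl,
              loge0, dloge, ne, mu4, lnmu, cutoff,
              fl_has, fl_kedge, fl_ledge, fl_kvac, fl_kyield, fl_klines,
              fl_kprobs, fl_lyield, fl_llines, fl_lprobs,
              shape_code, params, mat_idx, nreg, world_mat, phantom_reg,
              gx0, gy0, ztop, nx, ny, pend, pend_hid, s1, s2,
              plane_z, plane_dir, plane_term, nplanes,
              cap_E, cap_x, cap_y, cap_u, cap_v, cap_w, cap_wt, cap_hid,
              cap_plane, cap_n, plane_wsum, plane_count,
              tally, rst):
    """Transport one primary photon and all of its secondaries."""
    sp = 0
    st_E[0] = E0
    st_x[0] = x0
    st_y[0] = y0
    st_z[0] = z0
    st_u[0] = u0
    st_v[0] = v0
    st_w[0] = w0
    st_wt[0] = wt0
    st_fl[0] = flags0
    sp = 1
    while sp > 0:
        sp -= 1
        E = st_E[sp]
        x = st_x[sp]
        y = st_y[sp]
        z = st_z[sp]
        u = st_u[sp]
        v = st_v[sp]
        w = st_w[sp]
        wt = st_wt[sp]
        flags = st_fl[sp]
        alive = True
        while alive:
            ireg = locate_kernel(x, y, z, shape_code, params, nreg)
            mat = mat_idx[ireg] if ireg >= 0 else world_mat
            mu = mu_total_kernel(mat, E, loge0, dloge, ne, lnmu)
            if mu < 1e-12:
                s = INF
            else:
                s = -math.log(1.0 - _u01(rst)) / mu
            tb, tw = next_boundary(x, y, z, u, v, w, shape_code, params, nreg)
            tmove = s
            kind = 0  # 0 interact, 1 boundary, 2 world exit
            if tb < tmove:
                tmove = tb
                kind = 1
            if tw < tmove:
                tmove = tw
                kind = 2
            # plane crossings within (0, tmove]
            for _pass in range(nplanes):
                ip_best = -1
                tp_best = tmove
                for ip in range(nplanes):
                    if flags & (1 << (ip + 8)):  # processed this segment
                        continue
                    if w == 0.0:
                        continue
                    tp = (plane_z[ip] - z) / w
                    if _EPS_T < tp <= tp_best:
                        tp_best = tp
                        ip_best = ip
                if ip_best < 0:
                    break
                flags |= 1 << (ip_best + 8)
                matches = (plane_dir[ip_best] > 0 and w > 0.0) or \
                          (plane_dir[ip_best] < 0 and w < 0.0)
                if not matches:
                    continue
                cx = x + tp_best * u
                cy = y + tp_best * v
                if plane_term[ip_best] == 1:
                    _capture(ip_best, E, cx, cy, u, v, w, wt, hid,
                             cap_E, cap_x, cap_y, cap_u, cap_v, cap_w,
                             cap_wt, cap_hid, cap_plane, cap_n,
                             plane_wsum, plane_count)
                    tally[T_CAPTURED_E] += wt * E
                    alive = False
                    break
                if not (flags & (1 << ip_best)):
                    flags |= 1 << ip_best
                    _capture(ip_best, E, cx, cy, u, v, w, wt, hid,
                             cap_E, cap_x, cap_y, cap_u, cap_v, cap_w,
                             cap_wt, cap_hid, cap_plane, cap_n,
                             plane_wsum, plane_count)
            flags &= ~(255 << 8)  # clear per-segment plane marks
            if not alive:
                break
            x += tmove * u
            y += tmove * v
            z += tmove * w
            if kind == 2:
                tally[T_ESCAPE_E] += wt * E
                break
            if kind == 1:
                x += _EPS_NUDGE * u
                y += _EPS_NUDGE * v
                z += _EPS_NUDGE * w
                continue
            # --- interaction vertex in region ireg ---
            pe, inc, pair = mu_partials_kernel(mat, E, loge0, dloge, ne, mu4)
            tot = pe + inc + pair
            if tot <= 0.0:
                continue
            xi = _u01(rst) * tot
            edep = 0.0
            if xi < pe:
                # photoelectric absorption, optional fluorescence
                edep = E
                if fl_has[mat] == 1:
                    line = -1.0
                    if E > fl_kedge[mat] and _u01(rst) < fl_kvac[mat]:
                        if _u01(rst) < fl_kyield[mat]:
                            line = fl_klines[mat, 0] \
                                if _u01(rst) < fl_kprobs[mat, 0] \
                                else fl_klines[mat, 1]
                    elif E > fl_ledge[mat]:
                        if _u01(rst) < fl_lyield[mat]:
                            line = fl_llines[mat, 0] \
                                if _u01(rst) < fl_lprobs[mat, 0] \
                                else fl_llines[mat, 1]
                    if line > 0.0:
                        if line >= cutoff and sp < _STACK - 1:
                            du, dv, dw = _isotropic(rst)
                            st_E[sp] = line
                            st_x[sp] = x
                            st_y[sp] = y
                            st_z[sp] = z
                            st_u[sp] = du
                            st_v[sp] = dv
                            st_w[sp] = dw
                            st_wt[sp] = wt
                            st_fl[sp] = 0
                            sp += 1
                            edep = E - line
                alive = False
            elif xi < pe + inc:
                Eprime, costheta = sample_compton_kernel(E, rst)
                edep = E - Eprime
                if Eprime < cutoff:
                    edep = E
                    alive = False
                else:
                    phi = 2.0 * math.pi * _u01(rst)
                    u, v, w = _rotate(u, v, w, costheta, phi)
                    E = Eprime
                    flags &= 255  # keep capture-once bits
            else:
                # pair production: local annihilation approximation
                edep = E - PAIR_THRESHOLD
                du, dv, dw = _isotropic(rst)
                if ANNIH_E >= cutoff and sp < _STACK - 2:
                    st_E[sp] = ANNIH_E
                    st_x[sp] = x
                    st_y[sp] = y
                    st_z[sp] = z
                    st_u[sp] = du
                    st_v[sp] = dv
                    st_w[sp] = dw
                    st_wt[sp] = wt
                    st_fl[sp] = 0
                    sp += 1
                    st_E[sp] = ANNIH_E
                    st_x[sp] = x
                    st_y[sp] = y
                    st_z[sp] = z
                    st_u[sp] = -du
                    st_v[sp] = -dv
                    st_w[sp] = -dw
                    st_wt[sp] = wt
                    st_fl[sp] = 0
                    sp += 1
                else:
                    edep = E
                alive = False
            if edep > 0.0:
                if ireg == phantom_reg:
                    ok = _score_phantom(x, y, z, wt, edep, hid, gx0, gy0, ztop,
                                        nx, ny, pend, pend_hid, s1, s2)
                    if ok:
                        tally[T_DEP_PHANTOM] += wt * edep
                    else:
                        tally[T_DEP_ELSE] += wt * edep
                else:
                    tally[T_DEP_ELSE] += wt * edep


@njit(cache=True)
def run_source_histories(n_hist, hid0, inv_cdf, half_x, half_y, z_src,
                         st_E, st_x, st_y, st_z, st_u, st_v, st_w, st_wt, st_fl,
                         loge0, dloge, ne, mu4, lnmu, cutoff,
                         fl_has, fl_kedge, fl_ledge, fl_kvac, fl_kyield,
                         fl_klines, fl_kprobs, fl_lyield, fl_llines, fl_lprobs,
                         shape_code, params, mat_idx, nreg, world_mat,
                         phantom_reg,
                         gx0, gy0, ztop, nx, ny, pend, pend_hid, s1, s2,
                         plane_z, plane_dir, plane_term, nplanes,
                         cap_E, cap_x, cap_y, cap_u, cap_v, cap_w, cap_wt,
                         cap_hid, cap_plane, cap_n, plane_wsum, plane_count,
                         tally, seed):
    """Stage-1 driver: sample collimated source photons and track them.

    Each history h uses its own random stream (seed, hid, 0, 1).
    """
    ncdf = inv_cdf.shape[0]
    rst = np.zeros(1, dtype=np.uint64)
    for h in range(n_hist):
        hid = hid0 + h
        rst[0] = stream_init(seed, hid, 0, 1)
        q = _u01(rst) * (ncdf - 1)
        i = int(q)
        if i > ncdf - 2:
            i = ncdf - 2
        E = inv_cdf[i] * (1.0 - (q - i)) + inv_cdf[i + 1] * (q - i)
        xt = half_x * (2.0 * _u01(rst) - 1.0)
        yt = half_y * (2.0 * _u01(rst) - 1.0)
        dx = xt
        dy = yt
        dz = -z_src
        norm = math.sqrt(dx * dx + dy * dy + dz * dz)
        tally[T_LAUNCH_E] += E
        tally[T_LAUNCH_W] += 1.0
        track_one(E, 0.0, 0.0, z_src, dx / norm, dy / norm, dz / norm,
                  1.0, hid, 0,
                  st_E, st_x, st_y, st_z, st_u, st_v, st_w, st_wt, st_fl,
                  loge0, dloge, ne, mu4, lnmu, cutoff,
                  fl_has, fl_kedge, fl_ledge, fl_kvac, fl_kyield, fl_klines,
                  fl_kprobs, fl_lyield, fl_llines, fl_lprobs,
                  shape_code, params, mat_idx, nreg, world_mat, phantom_reg,
                  gx0, gy0, ztop, nx, ny, pend, pend_hid, s1, s2,
                  plane_z, plane_dir, plane_term, nplanes,
                  cap_E, cap_x, cap_y, cap_u, cap_v, cap_w, cap_wt, cap_hid,
                  cap_plane, cap_n, plane_wsum, plane_count,
                  tally, rst)
    flush_pending(pend, pend_hid, s1, s2)


@njit(cache=True)
def run_record_histories(rec_E, rec_x, rec_y, rec_z, rec_u, rec_v, rec_w,
                         rec_wt, rec_hid, recycle,
                         st_E, st_x, st_y, st_z, st_u, st_v, st_w, st_wt, st_fl,
                         loge0, dloge, ne, mu4, lnmu, cutoff,
                         fl_has, fl_kedge, fl_ledge, fl_kvac, fl_kyield,
                         fl_klines, fl_kprobs, fl_lyield, fl_llines, fl_lprobs,
                         shape_code, params, mat_idx, nreg, world_mat,
                         phantom_reg,
                         gx0, gy0, ztop, nx, ny, pend, pend_hid, s1, s2,
                         plane_z, plane_dir, plane_term, nplanes,
                         cap_E, cap_x, cap_y, cap_u, cap_v, cap_w, cap_wt,
                         cap_hid, cap_plane, cap_n, plane_wsum, plane_count,
                         tally, seed):
    """Stage-2 driver: replay phase-space records ``recycle`` times each.

    Replica r of the record with ordinal k within history hid uses the
    stream (seed, hid, k, 1000 + r): replicas are mutually independent and
    runs over the same record set pair across geometries.
    """
    inv = 1.0 / recycle
    rst = np.zeros(1, dtype=np.uint64)
    prev_hid = np.int64(-1)
    ordinal = 0
    for i in range(rec_E.shape[0]):
        if rec_hid[i] == prev_hid:
            ordinal += 1
        else:
            ordinal = 0
            prev_hid = rec_hid[i]
        wt = rec_wt[i] * inv
        for _r in range(recycle):
            rst[0] = stream_init(seed, rec_hid[i], ordinal, 1000 + _r)
            tally[T_LAUNCH_E] += wt * rec_E[i]
            tally[T_LAUNCH_W] += wt
            track_one(rec_E[i], rec_x[i], rec_y[i], rec_z[i],
                      rec_u[i], rec_v[i], rec_w[i], wt, rec_hid[i], 0,
                      st_E, st_x, st_y, st_z, st_u, st_v, st_w, st_wt, st_fl,
                      loge0, dloge, ne, mu4, lnmu, cutoff,
                      fl_has, fl_kedge, fl_ledge, fl_kvac, fl_kyield,
                      fl_klines, fl_kprobs, fl_lyield, fl_llines, fl_lprobs,
                      shape_code, params, mat_idx, nreg, world_mat,
                      phantom_reg,
                      gx0, gy0, ztop, nx, ny, pend, pend_hid, s1, s2,
                      plane_z, plane_dir, plane_term, nplanes,
                      cap_E, cap_x, cap_y, cap_u, cap_v, cap_w, cap_wt,
                      cap_hid, cap_plane, cap_n, plane_wsum, plane_count,
                      tally, rst)
    flush_pending(pend, pend_hid, s1, s2)
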