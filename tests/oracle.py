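"""Naive reference implementations of every surface-texture parameter.

Written independently of the package's engine: autocorrelation by direct
circular lag sums instead of FFT, spectra by an explicit DFT matrix, scalar
loops for extrema/gradients/ray marching, hand-rolled interpolation and
trapezoids.  Shared definitional constants (0.2 decay threshold, 1° rays,
0.5 px steps, material-ratio grids) follow the documented conventions.
"""

from __future__ import annotations

import math

import numpy as np

DECAY = 0.2
N_RAYS = 360
STEP = 0.5
MR_FINE = np.linspace(0.0, 100.0, 2001)
SK_GRID = np.linspace(0.0, 60.0, 601)


def _level(z):
    z = np.asarray(z, dtype=float)
    return z - z.mean()


def _interp_bearing(zs_desc, p):
    n = len(zs_desc)
    t = float(p) * (n - 1) / 100.0
    i0 = min(max(int(math.floor(t)), 0), n - 2)
    return zs_desc[i0] + (t - i0) * (zs_desc[i0 + 1] - zs_desc[i0])


def _acf_direct(z):
    """Normalised circular autocorrelation by per-lag products (no FFT)."""
    r, c = z.shape
    acf = np.empty((r, c))
    for a in range(r):
        for b in range(c):
            acf[a, b] = np.mean(z * np.roll(np.roll(z, -a, axis=0), -b, axis=1))
    acf = acf / acf[0, 0]
    # centre zero lag at (r//2, c//2) like fftshift
    return np.roll(np.roll(acf, r // 2, axis=0), c // 2, axis=1)


def _decay_lengths(z):
    m = _acf_direct(z)
    r, c = z.shape
    cy, cx = r // 2, c // 2
    rmax = min(r // 2, c // 2) - 1
    nsteps = int(math.floor(rmax / STEP))
    out = []
    for k in range(N_RAYS):
        th = math.radians(k)
        dx, dy = math.cos(th), math.sin(th)
        prev = 1.0
        rho_prev = 0.0
        decay = nsteps * STEP
        for s in range(1, nsteps + 1):
            rho = s * STEP
            x = cx + rho * dx
            y = cy + rho * dy
            x0, y0 = int(math.floor(x)), int(math.floor(y))
            x1, y1 = min(x0 + 1, c - 1), min(y0 + 1, r - 1)
            wx, wy = x - x0, y - y0
            val = (1 - wy) * ((1 - wx) * m[y0, x0] + wx * m[y0, x1]) + wy * (
                (1 - wx) * m[y1, x0] + wx * m[y1, x1]
            )
            if val < DECAY:
                decay = rho_prev + STEP * (prev - DECAY) / (prev - val)
                break
            prev, rho_prev = val, rho
        out.append(decay)
    return np.array(out)


def _dft_power(z):
    """Centred power spectrum via explicit DFT matrices (no FFT)."""
    r, c = z.shape
    er = np.exp(-2j * np.pi * np.outer(np.arange(r), np.arange(r)) / r)
    ec = np.exp(-2j * np.pi * np.outer(np.arange(c), np.arange(c)) / c)
    f = er @ z @ ec
    p = np.abs(f) ** 2
    return np.roll(np.roll(p, r // 2, axis=0), c // 2, axis=1)


def _half_plane(z):
    r, c = z.shape
    p = _dft_power(z)
    items = []
    for i in range(r):
        for j in range(c):
            fy, fx = i - r // 2, j - c // 2
            if (fy > 0) or (fy == 0 and fx > 0):
                items.append((p[i, j], fy, fx))
    return items


def _summits(z):
    r, c = z.shape
    out = []
    for i in range(1, r - 1):
        for j in range(1, c - 1):
            v = z[i, j]
            if all(
                v > z[i + di, j + dj]
                for di in (-1, 0, 1)
                for dj in (-1, 0, 1)
                if (di, dj) != (0, 0)
            ):
                out.append((i, j))
    return out


def _pits(z):
    return _summits(-z)


def _trapz(y, x):
    total = 0.0
    for i in range(len(x) - 1):
        total += (y[i] + y[i + 1]) / 2.0 * (x[i + 1] - x[i])
    return total


def oracle_parameters(values, pitch):
    """Every registry parameter of one raster, computed the slow way."""
    z = _level(values)
    r, c = z.shape
    n = z.size
    out = {}
    sq = math.sqrt(float(np.mean(z**2)))
    out["Sa"] = float(np.mean(np.abs(z)))
    out["Sq"] = sq
    if sq > 0:
        out["Ssk"] = float(np.mean(z**3)) / sq**3
        out["Sku"] = float(np.mean(z**4)) / sq**4
    out["Sp"] = float(z.max())
    out["Sv"] = float(-z.min())
    out["Sz"] = out["Sp"] + out["Sv"]

    summits = _summits(z)
    pits = _pits(z)
    peak_h = sorted((z[i, j] for i, j in summits), reverse=True)[:5]
    pit_h = sorted(z[i, j] for i, j in pits)[:5]
    ph = sum(peak_h) / len(peak_h) if peak_h else out["Sp"]
    pv = -sum(pit_h) / len(pit_h) if pit_h else out["Sv"]
    out["S10z"] = ph + pv

    # hybrid: gradients with central differences, one-sided at edges
    total = 0.0
    for i in range(r):
        for j in range(c):
            if 0 < i < r - 1:
                gy = (z[i + 1, j] - z[i - 1, j]) / (2 * pitch)
            elif i == 0:
                gy = (z[1, j] - z[0, j]) / pitch
            else:
                gy = (z[r - 1, j] - z[r - 2, j]) / pitch
            if 0 < j < c - 1:
                gx = (z[i, j + 1] - z[i, j - 1]) / (2 * pitch)
            elif j == 0:
                gx = (z[i, 1] - z[i, 0]) / pitch
            else:
                gx = (z[i, c - 1] - z[i, c - 2]) / pitch
            total += gx * gx + gy * gy
    out["Sdq"] = math.sqrt(total / n)

    area = 0.0
    for i in range(r - 1):
        for j in range(c - 1):
            z00, z01, z10, z11 = z[i, j], z[i, j + 1], z[i + 1, j], z[i + 1, j + 1]
            area += 0.5 * pitch * math.sqrt((z01 - z00) ** 2 + (z10 - z00) ** 2 + pitch**2)
            area += 0.5 * pitch * math.sqrt((z10 - z11) ** 2 + (z01 - z11) ** 2 + pitch**2)
    out["Sdr"] = (area / ((r - 1) * (c - 1) * pitch**2) - 1.0) * 100.0

    if summits:
        curv = []
        for i, j in summits:
            zxx = (z[i, j + 1] - 2 * z[i, j] + z[i, j - 1]) / pitch**2
            zyy = (z[i + 1, j] - 2 * z[i, j] + z[i - 1, j]) / pitch**2
            curv.append(-0.5 * (zxx + zyy))
        out["Ssc"] = sum(curv) / len(curv)
    else:
        out["Ssc"] = 0.0
    out["Sds"] = len(summits) / ((r - 2) * (c - 2) * pitch**2 / 1e6)

    # spatial
    if sq > 0 and min(r, c) >= 8:
        d = _decay_lengths(z)
        out["Sal"] = float(d.min() * pitch)
        out["Str"] = float(d.min() / d.max())
        items = _half_plane(z)
        best = None
        for p, fy, fx in items:
            if best is None or p > best[0] or (
                p == best[0] and (fy, fx) < (best[1], best[2])
            ):
                best = (p, fy, fx)
        out["Std"] = math.degrees(math.atan2(best[1], best[2])) % 180.0
        m = min(r, c)
        rings = {}
        for p, fy, fx in items:
            b = round(math.hypot(fy / r, fx / c) * m)
            rings[b] = rings.get(b, 0.0) + p
        rings.pop(0, None)
        bstar = max(sorted(rings), key=lambda b: (rings[b], -b))
        out["Srw"] = pitch * m / bstar
        bins = {}
        for p, fy, fx in items:
            ang = math.degrees(math.atan2(fy, fx)) % 180.0
            bins.setdefault(min(int(ang // 5), 35), []).append(p)
        sums = [sum(v) for v in bins.values()]
        out["Stdi"] = (sum(sums) / len(sums)) / max(sums)

    # functional / volume from the bearing curve
    if min(r, c) >= 8:
        zs = np.sort(z.ravel())[::-1]
        lo = [_interp_bearing(zs, p) for p in SK_GRID]
        hi = [_interp_bearing(zs, p + 40.0) for p in SK_GRID]
        slopes = [(h - l) / 40.0 for l, h in zip(lo, hi)]
        k = max(range(len(slopes)), key=lambda i: (slopes[i], -i))
        z0 = lo[k] + slopes[k] * (0.0 - SK_GRID[k])
        z100 = lo[k] + slopes[k] * (100.0 - SK_GRID[k])
        out["Sk"] = z0 - z100
        zeta = np.array([_interp_bearing(zs, p) for p in MR_FINE])

        def crossing(level):
            below = zeta <= level
            if not below.any():
                return 100.0
            i = int(np.argmax(below))
            if i == 0:
                return 0.0
            den = zeta[i - 1] - zeta[i]
            if den <= 0:
                return float(MR_FINE[i])
            return float(
                MR_FINE[i - 1] + (zeta[i - 1] - level) / den * (MR_FINE[i] - MR_FINE[i - 1])
            )

        smr1, smr2 = crossing(z0), crossing(z100)
        out["Smr1"], out["Smr2"] = smr1, smr2
        a1 = _trapz(np.clip(zeta - z0, 0.0, None), MR_FINE)
        a2 = _trapz(np.clip(z100 - zeta, 0.0, None), MR_FINE)
        out["Spk"] = 2.0 * a1 / smr1 if smr1 > 0 else 0.0
        out["Svk"] = 2.0 * a2 / (100.0 - smr2) if smr2 < 100 else 0.0

        def vm(p):
            cl = _interp_bearing(zs, p)
            return float(np.mean(np.clip(z - cl, 0.0, None)))

        def vv(p):
            cl = _interp_bearing(zs, p)
            return float(np.mean(np.clip(cl - z, 0.0, None)))

        if sq > 0:
            eta = _interp_bearing(zs, 5.0)
            if eta != 0:
                out["Sbi"] = sq / eta
            out["Sci"] = (vv(5.0) - vv(80.0)) / sq
            out["Svi"] = vv(80.0) / sq
        out["Sxp"] = _interp_bearing(zs, 2.5) - _interp_bearing(zs, 50.0)
        out["Sdc"] = _interp_bearing(zs, 20.0) - _interp_bearing(zs, 80.0)
        out["Vmp"] = vm(10.0)
        out["Vmc"] = vm(80.0) - vm(10.0)
        out["Vvc"] = vv(10.0) - vv(80.0)
        out["Vvv"] = vv(80.0)
    return out


def oracle_blur(values, k):
    """Anchored truncated k×k moving average by explicit window loops."""
    v = np.asarray(values, dtype=float)
    r, c = v.shape
    out = np.empty_like(v)
    for i in range(r):
        for j in range(c):
            out[i, j] = v[i : min(i + k, r), j : min(j + k, c)].mean()
    return out
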