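"""Areal surface-texture parameters (ISO-25178 / SPIP style) on 2D rasters.

The registry fixes a canonical, ordered set of 31 scalar texture descriptors
in five families:

* amplitude — statistical moments and extremes of the leveled height
  distribution (Sa, Sq, Ssk, Sku, Sp, Sv, Sz, S10z);
* hybrid — slope/area/curvature descriptors mixing heights with the lateral
  pitch (Sdq, Sdr, Ssc, Sds);
* spatial — autocorrelation and spectral descriptors (Sal, Str, Std, Srw,
  Stdi);
* functional — Abbott–Firestone bearing-curve descriptors (Sbi, Sci, Svi,
  Sk, Spk, Svk, Smr1, Smr2, Sxp, Sdc);
* volume — material/void volumes at the standard 10 %/80 % material ratios
  (Vmp, Vmc, Vvc, Vvv).

All parameters are defined about the mean surface: the raster is mean-leveled
internally before anything is computed.  Height-like quantities inherit the
raster's value units; Sdq is a dimensionless slope (per-nm gradient times
nm), Ssc is in 1/nm, Sds in 1/µm², Sal and Srw in nm, Sdr in %, and Str,
Stdi, Ssk, Sku, Smr1, Smr2 are dimensionless.

Exact numerical conventions (documented because windowed heatmap computation
must be bit-reproducible):

* Autocorrelation is the periodic (circular) autocorrelation.  Decay lengths
  are found by marching 360 rays (1° apart) outward from zero lag in 0.5 px
  steps with bilinear interpolation of the normalised autocorrelation,
  refining the first 0.2-crossing linearly.  Sal is the shortest decay
  length, Str the shortest/longest ratio.
* Std is the angle (degrees, [0, 180)) of the half-plane spectral component
  with maximal power; ties break toward smaller frequency indices.
* The bearing curve interpolates the descending-sorted heights linearly on a
  0–100 % material-ratio axis; Sk uses the minimal-slope 40 %-chord secant
  searched on a 0.1 % grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .io import ChannelImage


class UnknownParameterError(KeyError):
    """Parameter name not in the registry."""


class ScaleError(ValueError):
    """Window smaller than the parameter's minimum window size."""


class UndefinedParameterError(ArithmeticError):
    """Parameter undefined on this surface (e.g. moment ratios on a flat raster)."""


@dataclass(frozen=True)
class RegistryEntry:
    name: str
    family: str  # amplitude | hybrid | spatial | functional | volume
    min_window_px: int


@dataclass(frozen=True)
class ParameterRegistry:
    """Ordered, immutable list of parameter definitions."""

    entries: Tuple[RegistryEntry, ...]

    def __post_init__(self):
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names in registry")

    @property
    def names(self) -> List[str]:
        return [e.name for e in self.entries]

    def __contains__(self, name: str) -> bool:
        return any(e.name == name for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def entry(self, name: str) -> RegistryEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise UnknownParameterError(name)

    def subset(self, names: Iterable[str]) -> "ParameterRegistry":
        wanted = list(names)
        unknown = [n for n in wanted if n not in self]
        if unknown:
            raise UnknownParameterError(unknown)
        return ParameterRegistry(tuple(e for e in self.entries if e.name in wanted))

    def computable(self, window_px: int) -> List[str]:
        """Names computable on a window of the given side length."""
        return [e.name for e in self.entries if e.min_window_px <= window_px]


def _make_default_registry() -> ParameterRegistry:
    amp, hyb, spa, fun, vol = "amplitude", "hybrid", "spatial", "functional", "volume"
    spec = [
        # amplitude
        ("Sa", amp, 4), ("Sq", amp, 4), ("Ssk", amp, 4), ("Sku", amp, 4),
        ("Sp", amp, 4), ("Sv", amp, 4), ("Sz", amp, 4), ("S10z", amp, 4),
        # hybrid
        ("Sdq", hyb, 4), ("Sdr", hyb, 4), ("Ssc", hyb, 4), ("Sds", hyb, 4),
        # spatial
        ("Sal", spa, 8), ("Str", spa, 8), ("Std", spa, 8), ("Srw", spa, 8), ("Stdi", spa, 8),
        # functional (bearing curve)
        ("Sbi", fun, 8), ("Sci", fun, 8), ("Svi", fun, 8),
        ("Sk", fun, 8), ("Spk", fun, 8), ("Svk", fun, 8),
        ("Smr1", fun, 8), ("Smr2", fun, 8), ("Sxp", fun, 8), ("Sdc", fun, 8),
        # volume
        ("Vmp", vol, 8), ("Vmc", vol, 8), ("Vvc", vol, 8), ("Vvv", vol, 8),
    ]
    return ParameterRegistry(tuple(RegistryEntry(*s) for s in spec))


DEFAULT_REGISTRY = _make_default_registry()

#: Threshold at which an autocorrelation ray is considered decayed.
ACF_DECAY = 0.2
#: Number of 1-degree rays for the Sal/Str search.
N_RAYS = 360
#: Ray step in pixels.
RAY_STEP = 0.5
#: Fine material-ratio grid (percent) for bearing-curve crossings/integrals.
MR_FINE = np.linspace(0.0, 100.0, 2001)
#: Search grid (percent) for the left end of the 40 %-wide Sk chord.
SK_GRID = np.linspace(0.0, 60.0, 601)


@dataclass(frozen=True)
class SurfaceParameterVector:
    """Ordered name -> value map plus the window side it came from."""

    values: Dict[str, float]
    source_window_px: int

    def as_array(self, names: Optional[Sequence[str]] = None) -> np.ndarray:
        names = list(self.values) if names is None else list(names)
        return np.array([self.values[n] for n in names], dtype=float)


def level_mean(image: ChannelImage) -> ChannelImage:
    """Subtract the mean height; shape, pitch and units unchanged."""
    return image.with_values(image.values - image.values.mean())


def _bearing_height(zs_desc: np.ndarray, p):
    """Height at material ratio p (percent) by linear interpolation.

    The descending-sorted heights sit at material ratios i/(N-1)*100; the
    interpolation formula is fixed (index t = p*(N-1)/100) so windowed and
    whole-image paths agree bitwise.
    """
    n = zs_desc.size
    t = np.asarray(p, dtype=float) * (n - 1) / 100.0
    i0 = np.clip(np.floor(t).astype(int), 0, n - 2)
    frac = t - i0
    return zs_desc[i0] + frac * (zs_desc[i0 + 1] - zs_desc[i0])


class _Engine:
    """Computes every registry parameter on one mean-leveled window,
    sharing intermediates (sorted heights, autocorrelation, spectrum)."""

    def __init__(self, z: np.ndarray, pitch_nm: float):
        self.z = z - z.mean()
        self.pitch = float(pitch_nm)
        self.rows, self.cols = self.z.shape
        self.n = self.z.size
        self._cache: Dict[str, object] = {}

    # -- cached intermediates ------------------------------------------------

    def _sorted_desc(self) -> np.ndarray:
        if "sorted" not in self._cache:
            self._cache["sorted"] = np.sort(self.z.ravel())[::-1]
        return self._cache["sorted"]

    def _sq(self) -> float:
        if "sq" not in self._cache:
            self._cache["sq"] = float(np.sqrt(np.mean(self.z**2)))
        return self._cache["sq"]

    def _require_variance(self, name: str) -> float:
        sq = self._sq()
        if sq == 0.0:
            raise UndefinedParameterError(f"{name} undefined on a zero-variance surface")
        return sq

    def _acf_map(self) -> np.ndarray:
        # periodic autocorrelation, normalised, zero lag at (rows//2, cols//2)
        if "acf" not in self._cache:
            f = np.fft.fft2(self.z)
            acf = np.fft.ifft2(f * np.conj(f)).real / self.n
            acf = np.fft.fftshift(acf)
            self._cache["acf"] = acf / acf[self.rows // 2, self.cols // 2]
        return self._cache["acf"]

    def _decay_lengths(self) -> np.ndarray:
        """0.2-decay length (px) of the autocorrelation along 360 rays."""
        if "decay" in self._cache:
            return self._cache["decay"]
        self._require_variance("Sal")
        m = self._acf_map()
        cy, cx = self.rows // 2, self.cols // 2
        rmax = min(self.rows // 2, self.cols // 2) - 1
        nsteps = int(np.floor(rmax / RAY_STEP))
        radii = (np.arange(nsteps) + 1) * RAY_STEP
        theta = np.deg2rad(np.arange(N_RAYS))
        dx, dy = np.cos(theta), np.sin(theta)
        xs = cx + radii[None, :] * dx[:, None]
        ys = cy + radii[None, :] * dy[:, None]
        x0 = np.floor(xs).astype(int)
        y0 = np.floor(ys).astype(int)
        x1 = np.minimum(x0 + 1, self.cols - 1)
        y1 = np.minimum(y0 + 1, self.rows - 1)
        wx, wy = xs - x0, ys - y0
        vals = (1 - wy) * ((1 - wx) * m[y0, x0] + wx * m[y0, x1]) + wy * (
            (1 - wx) * m[y1, x0] + wx * m[y1, x1]
        )
        below = vals < ACF_DECAY
        decay = np.full(N_RAYS, radii[-1])
        hit = below.any(axis=1)
        j = np.argmax(below, axis=1)
        idx = np.arange(N_RAYS)[hit]
        jj = j[hit]
        cur = vals[idx, jj]
        prev = np.where(jj > 0, vals[idx, np.maximum(jj - 1, 0)], 1.0)
        rho_prev = np.where(jj > 0, radii[np.maximum(jj - 1, 0)], 0.0)
        decay[hit] = rho_prev + RAY_STEP * (prev - ACF_DECAY) / (prev - cur)
        self._cache["decay"] = decay
        return decay

    def _spectrum(self):
        """Half-plane power spectrum: (power, fy, fx) with DC removed."""
        if "spec" not in self._cache:
            p = np.abs(np.fft.fft2(self.z)) ** 2
            p = np.fft.fftshift(p)
            fy = np.arange(self.rows) - self.rows // 2
            fx = np.arange(self.cols) - self.cols // 2
            fxg, fyg = np.meshgrid(fx, fy)
            keep = (fyg > 0) | ((fyg == 0) & (fxg > 0))
            self._cache["spec"] = (p[keep], fyg[keep], fxg[keep])
        return self._cache["spec"]

    def _summit_mask(self) -> np.ndarray:
        # strict local maxima over the 8-neighbourhood, interior pixels only
        if "summits" not in self._cache:
            z = self.z
            c = z[1:-1, 1:-1]
            mask = np.ones_like(c, dtype=bool)
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    mask &= c > z[1 + di : z.shape[0] - 1 + di, 1 + dj : z.shape[1] - 1 + dj]
            self._cache["summits"] = mask
        return self._cache["summits"]

    def _pit_mask(self) -> np.ndarray:
        if "pits" not in self._cache:
            z = self.z
            c = z[1:-1, 1:-1]
            mask = np.ones_like(c, dtype=bool)
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    mask &= c < z[1 + di : z.shape[0] - 1 + di, 1 + dj : z.shape[1] - 1 + dj]
            self._cache["pits"] = mask
        return self._cache["pits"]

    # -- amplitude -----------------------------------------------------------

    def Sa(self):
        return float(np.mean(np.abs(self.z)))

    def Sq(self):
        return self._sq()

    def Ssk(self):
        sq = self._require_variance("Ssk")
        return float(np.mean(self.z**3) / sq**3)

    def Sku(self):
        sq = self._require_variance("Sku")
        return float(np.mean(self.z**4) / sq**4)

    def Sp(self):
        return float(self.z.max())

    def Sv(self):
        return float(-self.z.min())

    def Sz(self):
        return self.Sp() + self.Sv()

    def S10z(self):
        peaks = np.sort(self.z[1:-1, 1:-1][self._summit_mask()])[::-1]
        pits = np.sort(self.z[1:-1, 1:-1][self._pit_mask()])
        # mean of up to 5 highest peaks / deepest pits; fall back on the
        # global extreme when a small window has no interior extremum
        ph = float(np.mean(peaks[:5])) if peaks.size else self.Sp()
        pv = float(-np.mean(pits[:5])) if pits.size else self.Sv()
        return ph + pv

    # -- hybrid --------------------------------------------------------------

    def Sdq(self):
        gy, gx = np.gradient(self.z, self.pitch)
        return float(np.sqrt(np.mean(gx**2 + gy**2)))

    def Sdr(self):
        z, h = self.z, self.pitch
        dzx1 = z[:-1, 1:] - z[:-1, :-1]
        dzy1 = z[1:, :-1] - z[:-1, :-1]
        dzx2 = z[1:, :-1] - z[1:, 1:]
        dzy2 = z[:-1, 1:] - z[1:, 1:]
        a1 = 0.5 * h * np.sqrt(dzx1**2 + dzy1**2 + h**2)
        a2 = 0.5 * h * np.sqrt(dzx2**2 + dzy2**2 + h**2)
        projected = (self.rows - 1) * (self.cols - 1) * h**2
        return float(((a1.sum() + a2.sum()) / projected - 1.0) * 100.0)

    def Ssc(self):
        mask = self._summit_mask()
        if not mask.any():
            return 0.0
        z, h = self.z, self.pitch
        zxx = (z[1:-1, 2:] - 2 * z[1:-1, 1:-1] + z[1:-1, :-2]) / h**2
        zyy = (z[2:, 1:-1] - 2 * z[1:-1, 1:-1] + z[:-2, 1:-1]) / h**2
        return float(np.mean(-0.5 * (zxx + zyy)[mask]))

    def Sds(self):
        # density over the interior area where summits can be detected, so
        # the value is comparable across window sizes
        area_um2 = (self.rows - 2) * (self.cols - 2) * self.pitch**2 / 1e6
        return float(self._summit_mask().sum() / area_um2)

    # -- spatial -------------------------------------------------------------

    def Sal(self):
        return float(self._decay_lengths().min() * self.pitch)

    def Str(self):
        d = self._decay_lengths()
        return float(d.min() / d.max())

    def Std(self):
        self._require_variance("Std")
        p, fy, fx = self._spectrum()
        order = np.lexsort((fx, fy, -p))  # max power, ties to small fy then fx
        k = order[0]
        return float(np.degrees(np.arctan2(fy[k], fx[k])) % 180.0)

    def Srw(self):
        self._require_variance("Srw")
        p, fy, fx = self._spectrum()
        m = min(self.rows, self.cols)
        s = np.sqrt((fy / self.rows) ** 2 + (fx / self.cols) ** 2)
        ring = np.round(s * m).astype(int)
        power = np.bincount(ring, weights=p)
        power[0] = 0.0
        b = int(np.argmax(power))
        return float(self.pitch * m / b)

    def Stdi(self):
        self._require_variance("Stdi")
        p, fy, fx = self._spectrum()
        ang = np.degrees(np.arctan2(fy, fx)) % 180.0
        bins = np.minimum((ang // 5).astype(int), 35)
        a = np.bincount(bins, weights=p, minlength=36)
        occupied = np.bincount(bins, minlength=36) > 0
        return float(a[occupied].mean() / a[occupied].max())

    # -- functional (bearing curve) ------------------------------------------

    def _sk_line(self):
        """Levels (z at 0 % and 100 %) of the minimal-slope 40 %-chord secant."""
        if "skline" in self._cache:
            return self._cache["skline"]
        zs = self._sorted_desc()
        lo = _bearing_height(zs, SK_GRID)
        hi = _bearing_height(zs, SK_GRID + 40.0)
        slope = (hi - lo) / 40.0  # <= 0
        k = int(np.argmax(slope))  # flattest (closest to 0); ties -> smallest p
        p0 = SK_GRID[k]
        z0 = lo[k] + slope[k] * (0.0 - p0)
        z100 = lo[k] + slope[k] * (100.0 - p0)
        self._cache["skline"] = (z0, z100)
        return z0, z100

    def _crossing(self, level: float) -> float:
        """Smallest material ratio (%) where the bearing curve falls to `level`."""
        zs = self._sorted_desc()
        zeta = _bearing_height(zs, MR_FINE)
        below = zeta <= level
        if not below.any():
            return 100.0
        i = int(np.argmax(below))
        if i == 0:
            return 0.0
        denom = zeta[i - 1] - zeta[i]
        if denom <= 0:
            return float(MR_FINE[i])
        return float(MR_FINE[i - 1] + (zeta[i - 1] - level) / denom * (MR_FINE[i] - MR_FINE[i - 1]))

    def Sk(self):
        z0, z100 = self._sk_line()
        return float(z0 - z100)

    def Smr1(self):
        z0, _ = self._sk_line()
        return self._crossing(z0)

    def Smr2(self):
        _, z100 = self._sk_line()
        return self._crossing(z100)

    def Spk(self):
        z0, _ = self._sk_line()
        smr1 = self.Smr1()
        if smr1 <= 0.0:
            return 0.0
        zeta = _bearing_height(self._sorted_desc(), MR_FINE)
        a1 = np.trapezoid(np.clip(zeta - z0, 0.0, None), MR_FINE)
        return float(2.0 * a1 / smr1)

    def Svk(self):
        _, z100 = self._sk_line()
        smr2 = self.Smr2()
        if smr2 >= 100.0:
            return 0.0
        zeta = _bearing_height(self._sorted_desc(), MR_FINE)
        a2 = np.trapezoid(np.clip(z100 - zeta, 0.0, None), MR_FINE)
        return float(2.0 * a2 / (100.0 - smr2))

    def _vm(self, p: float) -> float:
        c = float(_bearing_height(self._sorted_desc(), p))
        return float(np.mean(np.clip(self.z - c, 0.0, None)))

    def _vv(self, p: float) -> float:
        c = float(_bearing_height(self._sorted_desc(), p))
        return float(np.mean(np.clip(c - self.z, 0.0, None)))

    def Sbi(self):
        sq = self._require_variance("Sbi")
        eta = float(_bearing_height(self._sorted_desc(), 5.0))
        if eta == 0.0:
            raise UndefinedParameterError("Sbi undefined: zero height at 5% bearing ratio")
        return float(sq / eta)

    def Sci(self):
        sq = self._require_variance("Sci")
        return float((self._vv(5.0) - self._vv(80.0)) / sq)

    def Svi(self):
        sq = self._require_variance("Svi")
        return float(self._vv(80.0) / sq)

    def Sxp(self):
        zs = self._sorted_desc()
        return float(_bearing_height(zs, 2.5) - _bearing_height(zs, 50.0))

    def Sdc(self):
        zs = self._sorted_desc()
        return float(_bearing_height(zs, 20.0) - _bearing_height(zs, 80.0))

    # -- volume --------------------------------------------------------------

    def Vmp(self):
        return self._vm(10.0)

    def Vmc(self):
        return self._vm(80.0) - self._vm(10.0)

    def Vvc(self):
        return self._vv(10.0) - self._vv(80.0)

    def Vvv(self):
        return self._vv(80.0)

    def compute(self, name: str) -> float:
        fn = getattr(self, name, None)
        if fn is None or name.startswith("_"):
            raise UnknownParameterError(name)
        return fn()


def compute_parameter(
    image: ChannelImage, name: str, registry: ParameterRegistry = DEFAULT_REGISTRY
) -> float:
    """Compute one registry parameter on the whole raster (leveled internally)."""
    entry = registry.entry(name)
    if min(image.shape) < entry.min_window_px:
        raise ScaleError(
            f"{name} needs a window of at least {entry.min_window_px} px, got {image.shape}"
        )
    return _Engine(image.values, image.pitch_nm).compute(name)


def compute_all(
    image: ChannelImage, registry: ParameterRegistry = DEFAULT_REGISTRY
) -> SurfaceParameterVector:
    """All registry parameters computable at this raster size, in registry order."""
    window = min(image.shape)
    eng = _Engine(image.values, image.pitch_nm)
    values = {}
    for e in registry.entries:
        if e.min_window_px > window:
            continue
        try:
            values[e.name] = eng.compute(e.name)
        except UndefinedParameterError as exc:
            raise UndefinedParameterError(f"{e.name}: {exc}") from None
    return SurfaceParameterVector(values, window)
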