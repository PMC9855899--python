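"""Sliding-window probability heatmaps: localise class-driving surface regions.

A trained classifier is rastered across the cell in overlapping square
windows (default 32×32 px, stride 1).  For each window position the selected
surface parameters are computed on the window per channel, standardised with
the classifier's training statistics, and P(high aggressiveness) is stored at
the window's centre pixel (for even windows the centre is the top-left pixel
of the central 2×2 block).  The border where no window fits is masked rather
than padded — padding would fabricate texture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
from scipy import ndimage
from skimage import measure

from .io import CellRecord, ChannelImage
from .model import AggressivenessGPResults
from .params import DEFAULT_REGISTRY, ParameterRegistry, _Engine


@dataclass
class ProbabilityHeatmap:
    """Per-pixel P(high) grid aligned with the source image."""

    probabilities: np.ndarray
    valid_mask: np.ndarray
    window_px: int
    stride_px: int
    pitch_nm: float
    positive_class: str = "high"

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        m = np.asarray(self.valid_mask, dtype=bool)
        if p.shape != m.shape:
            raise ValueError("probabilities and mask shapes differ")
        valid = p[m]
        if valid.size and (not np.all(np.isfinite(valid)) or valid.min() < 0 or valid.max() > 1):
            raise ValueError("valid probabilities must be finite and in [0, 1]")
        self.probabilities = p
        self.valid_mask = m

    @property
    def shape(self) -> tuple:
        return self.probabilities.shape

    def valid_values(self) -> np.ndarray:
        return self.probabilities[self.valid_mask]


def _center_offset(window_px: int) -> int:
    # even windows: top-left pixel of the central 2x2 block
    return window_px // 2 - 1 if window_px % 2 == 0 else window_px // 2


def compute_heatmap(
    cell: CellRecord,
    results: AggressivenessGPResults,
    window_px: int = 32,
    stride_px: int = 1,
    registry: ParameterRegistry = DEFAULT_REGISTRY,
) -> ProbabilityHeatmap:
    """Raster the classifier over all window positions of a cell.

    For stride > 1 only every stride-th window position is evaluated and the
    remaining valid-region pixels take the value of the nearest computed
    position.
    """
    w, s = int(window_px), int(stride_px)
    if s < 1:
        raise ValueError("stride_px must be >= 1")
    rows, cols = cell.shape
    if w > min(rows, cols):
        raise ValueError(f"window {w} exceeds image size {cell.shape}")
    # group required parameter names per channel, preserving feature order
    per_channel = {}
    for ch, par in results.features:
        per_channel.setdefault(ch, []).append(par)
    missing = [ch for ch in per_channel if ch not in cell.channels]
    if missing:
        raise ValueError(f"cell {cell.cell_id!r} lacks channels {missing} required by the model")
    too_small = [
        (ch, par)
        for ch, pars in per_channel.items()
        for par in pars
        if registry.entry(par).min_window_px > w
    ]
    if too_small:
        raise ValueError(f"window {w} too small for selected features: {too_small}")

    pos_i = list(range(0, rows - w + 1, s))
    pos_j = list(range(0, cols - w + 1, s))
    pitch = cell.pitch_nm
    feat_rows = np.empty((len(pos_i) * len(pos_j), len(results.features)))
    for a, i in enumerate(pos_i):
        for b, j in enumerate(pos_j):
            vals = {}
            for ch, pars in per_channel.items():
                eng = _Engine(cell.channels[ch].values[i : i + w, j : j + w], pitch)
                for par in pars:
                    vals[(ch, par)] = eng.compute(par)
            feat_rows[a * len(pos_j) + b] = [vals[k] for k in results.features]
    probs = results.predict_proba_matrix(feat_rows).reshape(len(pos_i), len(pos_j))

    off = _center_offset(w)
    grid = np.zeros((rows, cols))
    mask = np.zeros((rows, cols), dtype=bool)
    # valid region: centres of all stride-1 window positions
    r0, r1 = off, off + (rows - w)
    c0, c1 = off, off + (cols - w)
    if s == 1:
        grid[r0 : r1 + 1, c0 : c1 + 1] = probs
    else:
        rr = np.arange(r0, r1 + 1)
        cc = np.arange(c0, c1 + 1)
        ai = np.clip(np.round((rr - r0) / s).astype(int), 0, len(pos_i) - 1)
        bj = np.clip(np.round((cc - c0) / s).astype(int), 0, len(pos_j) - 1)
        grid[r0 : r1 + 1, c0 : c1 + 1] = probs[np.ix_(ai, bj)]
    mask[r0 : r1 + 1, c0 : c1 + 1] = True
    return ProbabilityHeatmap(grid, mask, w, s, pitch)


def window_probability(
    cell: CellRecord,
    results: AggressivenessGPResults,
    i: int,
    j: int,
    window_px: int = 32,
) -> float:
    """P(high) for the single window whose top-left corner is (i, j) —
    the no-raster reference path for spot checks."""
    w = int(window_px)
    vals = {}
    for ch, par in results.features:
        eng_vals = _Engine(cell.channels[ch].values[i : i + w, j : j + w], cell.pitch_nm)
        vals[(ch, par)] = eng_vals.compute(par)
    return results.predict_probability(vals)


def render_heatmap_png(heatmap: ProbabilityHeatmap, path) -> None:
    """8-bit PNG render: diverging colormap centred at P=0.5, masked pixels grey."""
    import matplotlib

    matplotlib.use("Agg")
    from matplotlib import cm, image as mpimage

    rgba = cm.coolwarm(np.clip(heatmap.probabilities, 0, 1))
    rgba[~heatmap.valid_mask] = (0.5, 0.5, 0.5, 1.0)
    mpimage.imsave(path, (rgba * 255).astype(np.uint8))


def overlay(
    heatmap: ProbabilityHeatmap,
    image: ChannelImage,
    alpha: float = 0.5,
    path=None,
) -> np.ndarray:
    """Alpha-blend the heatmap over a grayscale render of one channel.

    Returns an (rows, cols, 3) uint8 array; masked pixels show the channel
    only.  ``alpha=0`` is the pure channel, ``alpha=1`` the pure heatmap in
    the valid region.
    """
    if image.shape != heatmap.shape:
        raise ValueError(f"shape mismatch: heatmap {heatmap.shape} vs image {image.shape}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    import matplotlib

    matplotlib.use("Agg")
    from matplotlib import cm, image as mpimage

    v = image.values
    lo, hi = v.min(), v.max()
    gray = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
    base = np.stack([gray] * 3, axis=-1)
    heat = cm.coolwarm(np.clip(heatmap.probabilities, 0, 1))[..., :3]
    a = np.where(heatmap.valid_mask, alpha, 0.0)[..., None]
    blended = (1 - a) * base + a * heat
    out = (np.clip(blended, 0, 1) * 255).astype(np.uint8)
    if path is not None:
        mpimage.imsave(path, out)
    return out


@dataclass
class Region:
    """One 8-connected component of the thresholded heatmap."""

    label: str  # "low" | "high"
    pixels: np.ndarray  # (n, 2) array of (row, col) indices
    boundary_nm: np.ndarray  # (m, 2) polyline of (y_nm, x_nm) physical coords

    @property
    def area_px(self) -> int:
        return len(self.pixels)


@dataclass
class RegionSet:
    regions: List[Region]

    def by_label(self, label: str) -> List[Region]:
        return [r for r in self.regions if r.label == label]

    def to_json(self, path) -> None:
        import json

        payload = [
            {
                "label": r.label,
                "area_px": r.area_px,
                "boundary_nm": np.asarray(r.boundary_nm).tolist(),
            }
            for r in self.regions
        ]
        from pathlib import Path

        Path(path).write_text(json.dumps(payload))


_EIGHT = np.ones((3, 3), dtype=int)


def extract_regions(
    heatmap: ProbabilityHeatmap, low_cut: float = 0.5, min_area_px: int = 1
) -> RegionSet:
    """Connected components of {P < low_cut} (low) and {P >= low_cut} (high)
    inside the valid region; components smaller than ``min_area_px`` are
    dropped.  Boundaries are traced as sub-pixel contours in physical nm
    (pixel centre at (index + 0.5) * pitch)."""
    regions: List[Region] = []
    pitch = heatmap.pitch_nm
    for label, mask in (
        ("low", (heatmap.probabilities < low_cut) & heatmap.valid_mask),
        ("high", (heatmap.probabilities >= low_cut) & heatmap.valid_mask),
    ):
        lab, n = ndimage.label(mask, structure=_EIGHT)
        for idx in range(1, n + 1):
            comp = lab == idx
            area = int(comp.sum())
            if area < min_area_px:
                continue
            contours = measure.find_contours(comp.astype(float), 0.5)
            boundary = max(contours, key=len) if contours else np.empty((0, 2))
            boundary_nm = (np.asarray(boundary) + 0.5) * pitch
            pixels = np.argwhere(comp)
            regions.append(Region(label, pixels, boundary_nm))
    return RegionSet(regions)
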