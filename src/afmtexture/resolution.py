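"""Blur-scale sensitivity scan: find the feature scale carrying class signal.

Re-running the whole classification pipeline on progressively
moving-average-blurred copies of the images produces an accuracy-vs-kernel
curve; the kernel size where accuracy collapses localises the informative
spatial scale.  The window ("zoom") size for heatmaps is the largest kernel
that keeps accuracy above a threshold fraction X (default 80 %) of the
unblurred baseline, floored at 32 px because the surface parameters need a
minimum number of pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

from .io import CellRecord, ChannelImage


@dataclass(frozen=True)
class BlurAccuracyCurve:
    """(kernel_px, accuracy) points; kernel 1 is the unblurred baseline."""

    points: Tuple[Tuple[int, float], ...]

    def __post_init__(self):
        ks = [k for k, _ in self.points]
        if ks != sorted(set(ks)):
            raise ValueError("kernel sizes must be strictly increasing")
        if not ks or ks[0] != 1:
            raise ValueError("curve must contain the kernel-1 baseline")

    @property
    def baseline(self) -> float:
        return self.points[0][1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["kernel_px", "accuracy"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ZoomSelection:
    zoom_px: int
    threshold_X: float = 0.80
    min_zoom_px: int = 32
    rationale: str = ""

    def __post_init__(self):
        if self.zoom_px < self.min_zoom_px:
            raise ValueError("zoom_px must respect the floor")


#: Default kernel ladder (powers of two up to 64 px).
DEFAULT_KERNELS = (1, 2, 4, 8, 16, 32, 64)


def blur_average(image: ChannelImage, kernel_px: int) -> ChannelImage:
    """Moving average: pixel (i, j) becomes the mean of the k×k block anchored
    at its top-left corner, truncated at the bottom/right image edges.
    Kernel 1 is the identity."""
    k = int(kernel_px)
    if k < 1:
        raise ValueError("kernel_px must be >= 1")
    r, c = image.shape
    if k > min(r, c):
        raise ValueError(f"kernel {k} exceeds image size {image.shape}")
    if k == 1:
        return image.with_values(image.values.copy())
    v = image.values
    # integral image with a zero row/col prepended
    s = np.zeros((r + 1, c + 1))
    s[1:, 1:] = v.cumsum(axis=0).cumsum(axis=1)
    i = np.arange(r)
    j = np.arange(c)
    i2 = np.minimum(i + k, r)
    j2 = np.minimum(j + k, c)
    block = s[np.ix_(i2, j2)] - s[np.ix_(i, j2)] - s[np.ix_(i2, j)] + s[np.ix_(i, j)]
    area = (i2 - i)[:, None] * (j2 - j)[None, :]
    return image.with_values(block / area)


def blur_cell(cell: CellRecord, kernel_px: int) -> CellRecord:
    """Blur every channel of a cell with the same kernel."""
    return CellRecord(
        cell.cell_id,
        cell.label,
        {k: blur_average(im, kernel_px) for k, im in cell.channels.items()},
    )


def accuracy_vs_blur(
    cells: Sequence[CellRecord],
    kernels: Sequence[int] = DEFAULT_KERNELS,
    config=None,
) -> BlurAccuracyCurve:
    """Blur every channel at each kernel size and re-run the full step-1
    pipeline (features → Gini ranking → top-k → GP → test accuracy) with the
    seeds fixed by ``config`` (a :class:`afmtexture.pipeline.Step1Config`)."""
    from .pipeline import Step1Config, evaluate_step1

    if config is None:
        config = Step1Config()
    kernels = sorted(set(int(k) for k in kernels))
    points = []
    for k in kernels:
        blurred = cells if k == 1 else [blur_cell(c, k) for c in cells]
        try:
            outcome = evaluate_step1(blurred, config)
        except Exception as exc:
            raise RuntimeError(f"pipeline failed at blur kernel {k}: {exc}") from exc
        points.append((k, outcome.test_accuracy))
    return BlurAccuracyCurve(tuple(points))


def select_zoom(
    curve: BlurAccuracyCurve,
    threshold_X: float = 0.8,
    min_zoom_px: int = 32,
    relative: bool = True,
) -> ZoomSelection:
    """Largest kernel whose accuracy stays at or above the threshold, floored.

    ``relative=True`` (default) reads the threshold as a fraction of the
    kernel-1 baseline accuracy; ``relative=False`` applies it as an absolute
    accuracy level.
    """
    cut = threshold_X * curve.baseline if relative else threshold_X
    keep = [k for k, acc in curve.points if acc >= cut]
    raw = max(keep) if keep else 1
    zoom = max(raw, min_zoom_px)
    mode = "relative to baseline" if relative else "absolute"
    if raw < min_zoom_px:
        why = (
            f"accuracy fell below {threshold_X:.0%} ({mode}) already at kernel {raw}; "
            f"floored at {min_zoom_px} px — surface parameters need enough pixels"
        )
    else:
        why = f"largest kernel with accuracy >= {threshold_X:.0%} ({mode}) is {raw} px"
    return ZoomSelection(zoom, threshold_X, min_zoom_px, why)


def plot_curve(curve: BlurAccuracyCurve, path) -> None:
    """Accuracy-vs-kernel plot (log2 kernel axis)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ks, accs = zip(*curve.points)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(ks, accs, "o-")
    ax.set_xscale("log", base=2)
    ax.set_xlabel("averaging kernel (px)")
    ax.set_ylabel("classification accuracy")
    ax.set_ylim(0, 1.05)
    ax.axhline(0.8 * curve.baseline, ls="--", c="grey", lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
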