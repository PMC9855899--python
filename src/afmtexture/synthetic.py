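"""Two-class synthetic AFM-like cell surfaces for end-to-end testing.

The generator composes, per channel, three texture components that mirror the
scales the method is sensitive to:

* a large-scale Gaussian random field (correlation length ~1 µm) that is
  identical between classes — the cell-body undulation carrying no class
  signal;
* sub-micron Gaussian-profile bumps (~0.4 µm FWHM) at Poisson-distributed
  positions, emulating microvilli/microridges, whose surface density differs
  between classes;
* fine nano-granularity (a short-correlation random field at the 20–40 nm
  scale, i.e. 1–2 px at ~20 nm pitch), whose amplitude differs between
  classes.

Channels share latent noise mixed by ``cross_channel_corr`` and share bump
positions, so the multi-channel structure is co-registered as in real
recordings.  The default geometry is 512×512 px over 10×10 µm (pitch
19.53 nm).  Adhesion-like channels are offset to be non-negative, which is
cosmetic (every amplitude parameter is offset-invariant).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .io import CellRecord, ChannelImage, write_cell_record, read_cell_record


@dataclass(frozen=True)
class TextureSpec:
    """Per-class texture recipe for one channel (lengths nm, amplitudes in
    the channel's units).

    ``nano_style`` selects the fine-scale granularity model: ``gaussian`` is
    a short-correlation Gaussian random field; ``spiky`` is sparse shot
    noise (Poisson-distributed Gaussian-profile impulses) with the *same*
    power spectrum and RMS, differing only in higher-order structure.  A
    spiky texture is strongly non-Gaussian (large skew/kurtosis) but becomes
    Gaussian under spatial averaging, so style contrast is erased by
    blurring even though amplitude contrast would survive any linear filter.
    """

    field_corr_len_nm: float
    field_amp: float
    bump_density_per_um2: float
    bump_diam_nm: float
    bump_height: float
    nano_feature_size_nm: float
    nano_feature_amp: float
    nano_style: str = "gaussian"
    #: impulse density for the spiky style; None derives a density giving
    #: excess kurtosis ~20 for the granularity size
    nano_spike_density_per_um2: Optional[float] = None
    #: fraction of the nano variance carried by spikes in the spiky style;
    #: the rest stays a Gaussian ripple shared with the gaussian style
    nano_spike_fraction: float = 0.5

    def __post_init__(self):
        for name in ("field_corr_len_nm", "bump_diam_nm", "nano_feature_size_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.bump_density_per_um2 < 0:
            raise ValueError("bump density must be >= 0")
        if self.nano_style not in ("gaussian", "spiky"):
            raise ValueError(f"unknown nano_style {self.nano_style!r}")


@dataclass(frozen=True)
class ChannelSpec:
    kind: str
    units: str
    low: TextureSpec
    high: TextureSpec


@dataclass(frozen=True)
class SyntheticConfig:
    rows: int = 512
    cols: int = 512
    pitch_nm: float = 19.53
    channels: Tuple[ChannelSpec, ...] = ()
    cross_channel_corr: float = 0.5
    #: sd of the per-cell lognormal amplitude factor applied to each texture
    #: component (cell-to-cell biological variability; 0 disables it)
    amp_jitter_sd: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if not -1.0 <= self.cross_channel_corr <= 1.0:
            raise ValueError("cross_channel_corr must be in [-1, 1]")
        if self.amp_jitter_sd < 0:
            raise ValueError("amp_jitter_sd must be >= 0")
        if not self.channels:
            raise ValueError("config needs at least one channel spec")

    def spec_for(self, kind: str, label: str) -> TextureSpec:
        for ch in self.channels:
            if ch.kind == kind:
                return ch.low if label == "low" else ch.high
        raise KeyError(kind)


def _filtered_noise(white: np.ndarray, sigma_px: float) -> np.ndarray:
    """Convolve white noise with a periodic Gaussian kernel of std sigma_px
    (spectral multiplication); the result has a Gaussian autocovariance with
    1/e decay at 2*sigma_px."""
    if sigma_px <= 0:
        return white.copy()
    r, c = white.shape
    fy = np.fft.fftfreq(r)[:, None]
    fx = np.fft.fftfreq(c)[None, :]
    transfer = np.exp(-2.0 * np.pi**2 * sigma_px**2 * (fy**2 + fx**2))
    return np.fft.ifft2(np.fft.fft2(white) * transfer).real


def _rescale(field: np.ndarray, amp: float) -> np.ndarray:
    field = field - field.mean()
    rms = np.sqrt(np.mean(field**2))
    if rms == 0 or amp == 0:
        return np.zeros_like(field)
    return field * (amp / rms)


def gaussian_random_field(
    rows: int, cols: int, corr_len_px: float, amp: float, seed: int
) -> np.ndarray:
    """Stationary Gaussian random field with sample RMS exactly ``amp`` and
    autocorrelation 1/e-decay length ``corr_len_px`` (spectral synthesis,
    periodic)."""
    if corr_len_px <= 0:
        raise ValueError("corr_len_px must be > 0")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((rows, cols))
    return _rescale(_filtered_noise(white, corr_len_px / 2.0), amp)


def add_bumps(
    grid: np.ndarray,
    density_per_um2: float,
    diam_nm: float,
    height: float,
    pitch_nm: float,
    seed: int,
    centers: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Add Gaussian-profile bumps (FWHM = ``diam_nm``) at Poisson-distributed
    centres; expected count = density × imaged area.  Pre-drawn ``centers``
    (n×2, fractional pixel coords) override the random draw so channels can
    share bump positions."""
    out = np.asarray(grid, dtype=float).copy()
    r, c = out.shape
    if centers is None:
        rng = np.random.default_rng(seed)
        area_um2 = r * c * pitch_nm**2 / 1e6
        n = rng.poisson(density_per_um2 * area_um2)
        centers = np.column_stack([rng.uniform(0, r, n), rng.uniform(0, c, n)])
    sigma_px = diam_nm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / pitch_nm
    reach = max(1, int(np.ceil(4 * sigma_px)))
    for cy, cx in np.atleast_2d(centers) if len(centers) else []:
        i0, i1 = max(0, int(cy) - reach), min(r, int(cy) + reach + 1)
        j0, j1 = max(0, int(cx) - reach), min(c, int(cx) + reach + 1)
        yy = np.arange(i0, i1)[:, None] - cy
        xx = np.arange(j0, j1)[None, :] - cx
        out[i0:i1, j0:j1] += height * np.exp(-(yy**2 + xx**2) / (2 * sigma_px**2))
    return out


def draw_bump_centers(
    rows: int, cols: int, density_per_um2: float, pitch_nm: float, seed: int
) -> np.ndarray:
    """Poisson-distributed bump centres (n×2 fractional pixel coords)."""
    rng = np.random.default_rng(seed)
    area_um2 = rows * cols * pitch_nm**2 / 1e6
    n = rng.poisson(density_per_um2 * area_um2)
    return np.column_stack([rng.uniform(0, rows, n), rng.uniform(0, cols, n)])


def _channel_values(
    config: SyntheticConfig,
    spec: TextureSpec,
    shared_field_white: np.ndarray,
    shared_nano_white: np.ndarray,
    own_rng: np.random.Generator,
    centers: np.ndarray,
    spike_centers: np.ndarray,
    jitter: np.ndarray,
    non_negative: bool,
) -> np.ndarray:
    rho = config.cross_channel_corr
    mix = lambda shared, own: rho * shared + np.sqrt(1 - rho**2) * own  # noqa: E731
    field_white = mix(shared_field_white, own_rng.standard_normal(shared_field_white.shape))
    field = _rescale(
        _filtered_noise(field_white, spec.field_corr_len_nm / config.pitch_nm / 2.0),
        spec.field_amp * jitter[0],
    )
    nano_sigma = spec.nano_feature_size_nm / config.pitch_nm / 2.0
    nano_amp = spec.nano_feature_amp * jitter[1]
    nano_white = mix(shared_nano_white, own_rng.standard_normal(shared_nano_white.shape))
    ripple = _filtered_noise(nano_white, nano_sigma)
    if spec.nano_style == "spiky":
        # mixture: a Gaussian ripple backbone plus sparse shot noise carrying
        # nano_spike_fraction of the variance.  Impulses are shared across
        # channels (the same clusters appear in every channel) and have the
        # same Gaussian profile, hence the same spectrum, as the ripple.
        rows, cols = shared_field_white.shape
        impulses = np.zeros((rows, cols))
        if len(spike_centers):
            ii = np.clip(np.round(spike_centers[:, 0]).astype(int), 0, rows - 1)
            jj = np.clip(np.round(spike_centers[:, 1]).astype(int), 0, cols - 1)
            np.add.at(impulses, (ii, jj), 1.0)
        f = spec.nano_spike_fraction
        nano = _rescale(ripple, nano_amp * np.sqrt(1.0 - f)) + _rescale(
            _filtered_noise(impulses, nano_sigma), nano_amp * np.sqrt(f)
        )
    else:
        nano = _rescale(ripple, nano_amp)
    v = add_bumps(
        field + nano,
        spec.bump_density_per_um2,
        spec.bump_diam_nm,
        spec.bump_height * jitter[2],
        config.pitch_nm,
        seed=0,
        centers=centers,
    )
    if non_negative:
        v = v - v.min()
    return v


def generate_cell(
    config: SyntheticConfig, label: str, cell_id: str, seed: int
) -> CellRecord:
    """One synthetic cell with all configured channels, co-registered."""
    if label not in ("low", "high"):
        raise ValueError(f"label must be low/high, got {label!r}")
    ss = np.random.SeedSequence(seed)
    shared_ss, bump_ss, *channel_ss = ss.spawn(2 + len(config.channels))
    shared_rng = np.random.default_rng(shared_ss)
    shared_field_white = shared_rng.standard_normal((config.rows, config.cols))
    shared_nano_white = shared_rng.standard_normal((config.rows, config.cols))
    # one amplitude factor per texture component per cell, shared across
    # channels: cell-to-cell biological variability
    jitter = np.exp(config.amp_jitter_sd * shared_rng.standard_normal(3))
    # bump and spike positions shared across channels; densities depend only
    # on the class (first channel's spec sets the shared geometry)
    lead = config.channels[0].low if label == "low" else config.channels[0].high
    bump_rng = np.random.default_rng(bump_ss)
    centers = draw_bump_centers(
        config.rows, config.cols, lead.bump_density_per_um2, config.pitch_nm,
        int(bump_rng.integers(2**31)),
    )
    spike_centers = draw_bump_centers(
        config.rows, config.cols, _spike_density(lead, config.pitch_nm), config.pitch_nm,
        int(bump_rng.integers(2**31)),
    )
    channels = {}
    for ch, ch_ss in zip(config.channels, channel_ss):
        spec = ch.low if label == "low" else ch.high
        values = _channel_values(
            config,
            spec,
            shared_field_white,
            shared_nano_white,
            np.random.default_rng(ch_ss),
            centers,
            spike_centers,
            jitter,
            non_negative=(ch.units == "nN"),
        )
        channels[ch.kind] = ChannelImage(values, config.pitch_nm, ch.units, ch.kind)
    return CellRecord(cell_id, label, channels)


def _spike_density(spec: TextureSpec, pitch_nm: float) -> float:
    """Impulse density (per µm²) for the spiky nano style.  The default is
    set so the shot-noise excess kurtosis 1/(2π λ σ²) is ~20."""
    if spec.nano_style != "spiky":
        return 0.0
    if spec.nano_spike_density_per_um2 is not None:
        return spec.nano_spike_density_per_um2
    sigma_px = spec.nano_feature_size_nm / pitch_nm / 2.0
    lam_px = 1.0 / (2.0 * np.pi * sigma_px**2 * 20.0)
    return lam_px * 1e6 / pitch_nm**2


def generate_dataset(
    config: SyntheticConfig, n_per_class: int, base_seed: int
) -> List[CellRecord]:
    """2×n cells (low_000…, high_000…) with per-cell seeds derived from
    ``base_seed``."""
    seeds = np.random.SeedSequence(base_seed).generate_state(2 * n_per_class) % (2**31)
    cells = []
    k = 0
    for label in ("low", "high"):
        for i in range(n_per_class):
            cells.append(generate_cell(config, label, f"{label}_{i:03d}", int(seeds[k])))
            k += 1
    return cells


@dataclass
class CompositeCell:
    """A synthetic cell stitched from two class textures plus its ground-truth
    per-pixel class mask (True = high)."""

    record: CellRecord
    mask: np.ndarray

    def save(self, directory) -> None:
        directory = Path(directory)
        write_cell_record(self.record, directory)
        np.savetxt(directory / "class_mask.txt", self.mask.astype(int), fmt="%d")

    @staticmethod
    def load(directory) -> "CompositeCell":
        directory = Path(directory)
        record = read_cell_record(directory)
        mask = np.loadtxt(directory / "class_mask.txt").astype(bool)
        return CompositeCell(record, mask)


def generate_composite(
    config: SyntheticConfig, mask: np.ndarray, seed: int, cell_id: str = "composite"
) -> CompositeCell:
    """Per-pixel class mixture: pixels take their class's texture, blended
    across a transition band of at most ~4 px.

    Both class textures are generated from the same seed, so an all-low mask
    reproduces ``generate_cell(..., "low", seed)`` exactly.
    """
    from scipy.ndimage import gaussian_filter

    mask = np.asarray(mask).astype(bool)
    if mask.shape != (config.rows, config.cols):
        raise ValueError(f"mask shape {mask.shape} != config geometry")
    low = generate_cell(config, "low", cell_id, seed)
    high = generate_cell(config, "high", cell_id, seed)
    w = gaussian_filter(mask.astype(float), sigma=1.0)
    channels = {}
    for kind in low.channels:
        blended = (1 - w) * low.channels[kind].values + w * high.channels[kind].values
        channels[kind] = low.channels[kind].with_values(blended)
    # composite cells carry no single class label
    return CompositeCell(CellRecord(cell_id, None, channels), mask)


# ---------------------------------------------------------------------------
# Canonical study conditions

def default_config(rows: int = 512, cols: int = 512, seed: int = 0) -> SyntheticConfig:
    """Default two-class study conditions: the height channel plus three
    Ringing-mode channels, 512×512 px over 10×10 µm.

    Class contrast is structural at the two scales the method is sensitive
    to.  At the ~30 nm scale the high class's granularity is sparse spiky
    shot noise while the low class's is Gaussian, at equal RMS — the
    contrast lives in higher-order moments, not amplitude.  At the ~0.4 µm
    scale the low class has denser but shallower microvilli-like bumps with
    the bump RMS matched between classes (height ∝ 1/√density), so the
    contrast is again sparsity, not power.  The residual large-scale
    undulation (images are assumed flattened, so only a modest
    ~1 µm-correlation field remains) is identical between classes, and every
    component amplitude carries 15 % per-cell lognormal variability.  Matched
    second-order statistics are what make the blur scan meaningful: an
    amplitude ratio would survive any linear filter, whereas sparsity
    contrast is erased once averaging Gaussianizes the texture."""

    def specs(field_amp, bump_h, nano_amp):
        base = dict(
            field_corr_len_nm=1000.0,
            field_amp=field_amp,
            bump_diam_nm=250.0,
            nano_feature_size_nm=30.0,
            nano_feature_amp=nano_amp,
        )
        # bump RMS matched: height scales with 1/sqrt(density); densities are
        # high enough that a 32 px window holds a few bumps on average
        low = TextureSpec(
            bump_density_per_um2=8.0, bump_height=bump_h, nano_style="gaussian", **base
        )
        high = TextureSpec(
            bump_density_per_um2=4.0,
            bump_height=bump_h * np.sqrt(2.0),
            nano_style="spiky",
            **base,
        )
        return low, high

    channels = (
        ChannelSpec("height", "nm", *specs(2.5, 12.0, 4.0)),
        ChannelSpec("rm_adhesion", "nN", *specs(0.12, 0.5, 0.3)),
        ChannelSpec("rm_restored_adhesion", "nN", *specs(0.15, 0.6, 0.4)),
        ChannelSpec("rm_viscoelastic_adhesion", "nN", *specs(0.08, 0.3, 0.2)),
    )
    return SyntheticConfig(rows=rows, cols=cols, channels=channels, seed=seed)


def nano_contrast_config(rows: int = 128, cols: int = 128, seed: int = 0) -> SyntheticConfig:
    """Conditions where the classes differ ONLY at fine scale (~2 px): same
    large-scale field and identical bump statistics in both classes; the
    ~40 nm granularity has equal RMS and spectrum but Gaussian (low) versus
    spiky shot-noise (high) structure.  Averaging kernels larger than the
    granularity Gaussianize both textures and erase the only class signal,
    so the blur-accuracy curve collapses; the class-identical bumps provide
    the medium-scale texture that survives blurring."""

    def specs(field_amp, nano_amp):
        base = dict(
            field_corr_len_nm=1000.0,
            field_amp=field_amp,
            bump_density_per_um2=2.0,
            bump_diam_nm=400.0,
            bump_height=1.0,  # identical in both classes: no bump contrast
            nano_feature_size_nm=40.0,
            nano_feature_amp=nano_amp,
        )
        return (
            TextureSpec(nano_style="gaussian", **base),
            TextureSpec(nano_style="spiky", **base),
        )

    channels = (
        ChannelSpec("rm_restored_adhesion", "nN", *specs(0.5, 0.75)),
    )
    return SyntheticConfig(rows=rows, cols=cols, channels=channels, seed=seed)


def scaled_config(config: SyntheticConfig, rows: int, cols: int) -> SyntheticConfig:
    """Same texture recipe on a smaller raster (identical pitch, smaller
    field of view)."""
    return replace(config, rows=rows, cols=cols)


def write_dataset(cells: Sequence[CellRecord], directory, fmt: str = "txt") -> None:
    """Write cells as one directory each plus a manifest CSV."""
    import csv

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cell_id", "label"])
        for cell in cells:
            write_cell_record(cell, directory / cell.cell_id, fmt=fmt)
            writer.writerow([cell.cell_id, cell.label])


def read_dataset(directory) -> List[CellRecord]:
    import csv

    directory = Path(directory)
    cells = []
    with open(directory / "manifest.csv") as fh:
        for row in csv.DictReader(fh):
            cells.append(read_cell_record(directory / row["cell_id"]))
    return cells
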