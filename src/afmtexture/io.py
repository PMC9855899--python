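"""Reading and writing AFM channel rasters, cell records and probability heatmaps.

On-disk layout is one directory per cell, one raster file per channel
(plain-text whitespace-delimited matrix or single-plane 32-bit float TIFF),
with JSON sidecars carrying the physical metadata (pixel pitch in nm, value
units, channel kind).  Pixel (0, 0) is the top-left corner of the stored
raster; indices are row-major and the physical position of a pixel centre is
``(index + 0.5) * pitch_nm``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import tifffile

CHANNEL_KINDS = (
    "height",
    "adhesion",
    "peakforce_error",
    "rm_adhesion",
    "rm_restored_adhesion",
    "rm_viscoelastic_adhesion",
)

UNITS = ("nm", "nN", "a.u.")

LABELS = ("low", "high")


class FormatError(ValueError):
    """Malformed raster file or sidecar."""


class ConsistencyError(ValueError):
    """Channels of one cell disagree on geometry or metadata."""


@dataclass(frozen=True)
class ChannelImage:
    """A single 2D AFM raster with its physical metadata.

    Parameters
    ----------
    values : ndarray
        Rectangular (rows x cols) array of finite reals.
    pitch_nm : float
        Physical size of one pixel in nm (square pixels).
    units : str
        One of ``nm``, ``nN``, ``a.u.``.
    channel_kind : str
        One of :data:`CHANNEL_KINDS`.
    """

    values: np.ndarray
    pitch_nm: float
    units: str
    channel_kind: str

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise FormatError(f"channel values must be 2D, got {arr.ndim}D")
        if arr.shape[0] < 2 or arr.shape[1] < 2:
            raise FormatError(f"channel must be at least 2x2, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise FormatError("channel values contain non-finite entries")
        if not (self.pitch_nm > 0):
            raise FormatError(f"pitch_nm must be > 0, got {self.pitch_nm}")
        if self.units not in UNITS:
            raise FormatError(f"unknown units {self.units!r}; expected one of {UNITS}")
        if self.channel_kind not in CHANNEL_KINDS:
            raise FormatError(
                f"unknown channel_kind {self.channel_kind!r}; expected one of {CHANNEL_KINDS}"
            )
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def with_values(self, values: np.ndarray) -> "ChannelImage":
        """Copy of this image with new values (same metadata)."""
        return ChannelImage(values, self.pitch_nm, self.units, self.channel_kind)


@dataclass
class CellRecord:
    """A labelled cell: mapping channel kind -> co-registered ChannelImage."""

    cell_id: str
    label: Optional[str]  # "low", "high" or None (unlabelled)
    channels: Mapping[str, ChannelImage] = field(default_factory=dict)

    def __post_init__(self):
        if self.label is not None and self.label not in LABELS:
            raise ConsistencyError(f"label must be one of {LABELS} or None, got {self.label!r}")
        if not self.channels:
            raise ConsistencyError(f"cell {self.cell_id!r} has no channels")
        shapes = {k: im.shape for k, im in self.channels.items()}
        pitches = {k: im.pitch_nm for k, im in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ConsistencyError(f"cell {self.cell_id!r}: channel shapes disagree: {shapes}")
        if len(set(pitches.values())) > 1:
            raise ConsistencyError(f"cell {self.cell_id!r}: channel pitches disagree: {pitches}")

    @property
    def shape(self) -> tuple:
        return next(iter(self.channels.values())).shape

    @property
    def pitch_nm(self) -> float:
        return next(iter(self.channels.values())).pitch_nm


def _read_text_matrix(path: Path) -> np.ndarray:
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            try:
                row = [float(p) for p in parts]
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric entry on row {lineno}: {exc}") from None
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise FormatError(
                    f"{path}: ragged matrix — row {lineno} has {len(row)} entries, expected {width}"
                )
            rows.append(row)
    if not rows:
        raise FormatError(f"{path}: empty matrix file")
    return np.asarray(rows, dtype=float)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_channel_image(path, metadata=None) -> ChannelImage:
    """Read one channel raster (text matrix or single-plane TIFF) plus JSON sidecar.

    ``metadata`` may be an explicit sidecar path; by default ``<path>.json``
    is used.  The sidecar must carry ``pitch_nm``, ``units`` and
    ``channel_kind``.
    """
    path = Path(path)
    side = Path(metadata) if metadata is not None else _sidecar_path(path)
    if not side.exists():
        raise FormatError(f"missing metadata sidecar {side}")
    try:
        meta = json.loads(side.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{side}: invalid JSON: {exc}") from None
    for key in ("pitch_nm", "units", "channel_kind"):
        if key not in meta:
            raise FormatError(f"{side}: missing required field {key!r}")
    if path.suffix.lower() in (".tif", ".tiff"):
        values = tifffile.imread(path)
        if values.ndim != 2:
            raise FormatError(f"{path}: expected single-plane TIFF, got shape {values.shape}")
        values = np.asarray(values, dtype=float)
    else:
        values = _read_text_matrix(path)
    return ChannelImage(values, float(meta["pitch_nm"]), meta["units"], meta["channel_kind"])


def write_channel_image(image: ChannelImage, path) -> None:
    """Write a channel raster with JSON sidecar.

    ``.tif``/``.tiff`` paths get a 32-bit float TIFF; anything else a
    plain-text matrix (full double precision, whitespace-delimited).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.values.astype(np.float32))
    else:
        np.savetxt(path, image.values, fmt="%.17g")
    meta = {
        "pitch_nm": image.pitch_nm,
        "units": image.units,
        "channel_kind": image.channel_kind,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_cell_record(directory) -> CellRecord:
    """Read a cell directory: ``cell.json`` plus one raster file per channel."""
    directory = Path(directory)
    meta_path = directory / "cell.json"
    if not meta_path.exists():
        raise FormatError(f"missing cell-level metadata {meta_path}")
    meta = json.loads(meta_path.read_text())
    if "cell_id" not in meta or "channels" not in meta:
        raise FormatError(f"{meta_path}: needs 'cell_id' and 'channels' fields")
    channels = {}
    for kind in meta["channels"]:
        found = None
        for ext in (".txt", ".tif", ".tiff"):
            cand = directory / f"{kind}{ext}"
            if cand.exists():
                found = cand
                break
        if found is None:
            raise FormatError(f"cell {meta['cell_id']!r}: declared channel {kind!r} has no file in {directory}")
        channels[kind] = read_channel_image(found)
    return CellRecord(meta["cell_id"], meta.get("label"), channels)


def write_cell_record(cell: CellRecord, directory, fmt: str = "txt") -> None:
    """Write a cell directory in the layout :func:`read_cell_record` expects."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = ".tif" if fmt in ("tif", "tiff") else ".txt"
    for kind, image in cell.channels.items():
        write_channel_image(image, directory / f"{kind}{ext}")
    meta = {
        "cell_id": cell.cell_id,
        "label": cell.label,
        "channels": sorted(cell.channels),
    }
    (directory / "cell.json").write_text(json.dumps(meta, indent=1))


def write_heatmap(heatmap, path, render: bool = True) -> None:
    """Write a probability heatmap: text matrix (+ sidecar) and optional PNG.

    Masked (invalid-border) pixels are serialised as ``nan`` in the text
    matrix and rendered grey in the PNG.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mat = np.where(heatmap.valid_mask, heatmap.probabilities, np.nan)
    np.savetxt(path, mat, fmt="%.6f")
    meta = {
        "window_px": heatmap.window_px,
        "stride_px": heatmap.stride_px,
        "pitch_nm": heatmap.pitch_nm,
        "positive_class": "high",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    if render:
        from .heatmap import render_heatmap_png

        render_heatmap_png(heatmap, path.with_suffix(".png"))


def read_heatmap(path):
    """Read back a heatmap text matrix written by :func:`write_heatmap`."""
    from .heatmap import ProbabilityHeatmap

    path = Path(path)
    mat = np.loadtxt(path)
    meta = json.loads(_sidecar_path(path).read_text())
    mask = np.isfinite(mat)
    return ProbabilityHeatmap(
        probabilities=np.where(mask, mat, 0.0),
        valid_mask=mask,
        window_px=int(meta["window_px"]),
        stride_px=int(meta["stride_px"]),
        pitch_nm=float(meta["pitch_nm"]),
    )
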