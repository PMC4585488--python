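"""Render a cell table as a multichannel 8-bit fluorescence image.

Each cell is drawn per channel as a filled soma: a flat disk of radius
``soma_radius`` at the cell's channel intensity with a Gaussian edge falloff
of width ``blob_sigma`` (cell bodies are filled with fluorophore, so the
interior is flat; only the optical edge is soft).  Channels share the
spatial profile, so intensity ratios between channels — the quantity the
cell code is built from — are preserved everywhere in the blob.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile

from .cortex import ConfigurationError
from .decoding import bin_center, channel_columns

__all__ = ["RenderConfig", "render_image", "write_tiff", "OutOfFieldError"]


class OutOfFieldError(ValueError):
    """A cell centroid falls outside the image field."""

    def __init__(self, cell_ids):
        self.cell_ids = list(cell_ids)
        super().__init__(f"centroid(s) outside the field for cell ids {self.cell_ids}")


@dataclass(frozen=True)
class RenderConfig:
    """Rendering geometry and intensity scaling.

    ``pixel_size`` is μm per pixel; ``soma_radius`` (μm) is the flat blob
    core; ``blob_sigma`` (μm) the Gaussian edge width; ``background_level``
    a uniform additive offset, which must stay below the lowest non-zero
    quantization-bin center so background never masquerades as signal.
    Output is always 8-bit, channel-first (C, Y, X).
    """

    pixel_size: float = 1.0
    soma_radius: float = 5.0
    blob_sigma: float = 1.0
    background_level: int = 8

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be positive")
        if self.soma_radius < 0 or self.blob_sigma <= 0:
            raise ConfigurationError("soma_radius >= 0 and blob_sigma > 0 required")
        if not (0 <= self.background_level < bin_center(1)):
            raise ConfigurationError(
                f"background_level must be in [0, {bin_center(1)})"
            )


def _profile(d_px: np.ndarray, core_px: float, sigma_px: float) -> np.ndarray:
    edge = np.clip(d_px - core_px, 0.0, None)
    return np.exp(-(edge**2) / (2.0 * sigma_px**2))


def render_image(
    cells: pd.DataFrame,
    shape_um: tuple[float, float],
    cfg: RenderConfig = RenderConfig(),
) -> np.ndarray:
    """Render cells into a (C, H, W) uint8 image.

    ``shape_um`` is (depth extent, width extent) in μm; depth maps to image
    rows and the tangential coordinate to columns.  Raises
    :class:`OutOfFieldError` listing the offending cell ids if any centroid
    lies outside the field.
    """
    chans = channel_columns(cells)
    if not chans and len(cells):
        raise ValueError("cell table has no channel columns (ch1..chK)")
    n_ch = len(chans) if chans else 1
    H = int(np.ceil(shape_um[0] / cfg.pixel_size))
    W = int(np.ceil(shape_um[1] / cfg.pixel_size))
    canvas = np.zeros((n_ch, H, W), dtype=float)

    if len(cells):
        cols = cells["x_um"].to_numpy(float) / cfg.pixel_size
        rows = cells["y_um"].to_numpy(float) / cfg.pixel_size
        bad = (
            (cols < 0) | (cols > W - 0.5) | (rows < 0) | (rows > H - 0.5)
        )
        if bad.any():
            raise OutOfFieldError(cells["cell_id"].to_numpy()[bad])

        core_px = cfg.soma_radius / cfg.pixel_size
        sigma_px = cfg.blob_sigma / cfg.pixel_size
        r_ext = int(np.ceil(core_px + 4.0 * sigma_px)) + 1
        intens = cells[chans].to_numpy(float)
        for i in range(len(cells)):
            r0, c0 = rows[i], cols[i]
            rlo, rhi = max(int(r0) - r_ext, 0), min(int(r0) + r_ext + 1, H)
            clo, chi = max(int(c0) - r_ext, 0), min(int(c0) + r_ext + 1, W)
            rr, cc = np.mgrid[rlo:rhi, clo:chi]
            d = np.hypot(rr - r0, cc - c0)
            prof = _profile(d, core_px, sigma_px)
            for c in range(n_ch):
                canvas[c, rlo:rhi, clo:chi] += intens[i, c] * prof

    out = np.rint(np.clip(canvas + cfg.background_level, 0, 255))
    return out.astype(np.uint8)


def write_tiff(path, image: np.ndarray) -> None:
    """Write a channel-first multichannel 8-bit TIFF."""
    if image.dtype != np.uint8:
        raise ValueError("image must be uint8")
    tifffile.imwrite(path, image, photometric="minisblack", metadata={"axes": "CYX"})
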