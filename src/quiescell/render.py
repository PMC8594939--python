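"""Render ground-truth cell states into multi-channel 16-bit time lapses.

Channels, in order: ``phase`` (phase-contrast-like: bright cell bodies with
a dark lipid-droplet puncta), ``ex390`` and ``ex475`` (the two pHluorin
excitation channels, whose in-cell intensity ratio equals the forward
calibration model applied to the true pH), and ``marker`` (diffuse
cytoplasmic fluorescence plus a bright focus while the marker's foci state
is on, or the mitochondrial texture when rendering the mitochondrial
marker). Gaussian read noise is added last; with ``noise_sd = 0`` the
in-cell ratio round-trips exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line

from .calibration import DEFAULT_FORWARD_PARAMS, forward_ratio
from .config import SimulationConfig
from .lineage import R_MINUS

__all__ = ["ImageStack", "render_timelapse", "CHANNELS"]

CHANNELS = ("phase", "ex390", "ex475", "marker")

PHASE_AMPLITUDE = 600.0


@dataclass
class ImageStack:
    """A rendered 4-channel time lapse plus ground-truth label images.

    ``data`` has shape (channel, frame, height, width), dtype uint16, with
    channel order :data:`CHANNELS`; ``labels`` holds the true segmentation
    (cell_id per pixel, 0 = background); ``times`` are frame timestamps in
    hours.
    """

    data: np.ndarray
    times: np.ndarray
    labels: np.ndarray
    channel_names: tuple[str, ...] = CHANNELS
    pixel_size: float = 0.2

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_names.index(name)]


def _put(img: np.ndarray, rr: np.ndarray, cc: np.ndarray, value) -> None:
    img[rr, cc] = value


def _mito_texture(marker: np.ndarray, cx: float, cy: float, radius: float,
                  state: str, level: float, contrast: float,
                  cell_rng: np.random.Generator, shape) -> None:
    """Draw a crude mitochondrial morphology: a line (tubular), three small
    blobs (fragmented) or one bright blob (globular)."""
    if state == "tubular":
        r0 = int(round(cy - 0.6 * radius)); c0 = int(round(cx - 0.6 * radius))
        r1 = int(round(cy + 0.6 * radius)); c1 = int(round(cx + 0.6 * radius))
        h, w = shape
        r0, r1 = np.clip([r0, r1], 0, h - 1)
        c0, c1 = np.clip([c0, c1], 0, w - 1)
        rr, cc = draw_line(r0, c0, r1, c1)
        marker[rr, cc] += 0.4 * contrast
    elif state == "fragmented":
        for _ in range(3):
            ang = cell_rng.uniform(0, 2 * math.pi)
            rad = cell_rng.uniform(0.2, 0.7) * radius
            rr, cc = draw_disk((cy + rad * math.sin(ang), cx + rad * math.cos(ang)),
                               1.2, shape=shape)
            marker[rr, cc] += 0.5 * contrast
    else:  # globular
        rr, cc = draw_disk((cy, cx), max(1.8, 0.35 * radius), shape=shape)
        marker[rr, cc] += contrast


def render_timelapse(lineage: pd.DataFrame, series: pd.DataFrame,
                     config: SimulationConfig,
                     rng: np.random.Generator | None = None,
                     forward_params: tuple[float, float, float, float] = DEFAULT_FORWARD_PARAMS,
                     ) -> ImageStack:
    """Render a state series (from :mod:`quiescell.states`) into images.

    Deterministic given the rng / config seed. The number of drawn cells in
    each frame equals the number of lineage cells alive at that time.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 30)
    h, w = config.image_height, config.image_width
    times = config.frame_times
    n_frames = times.size
    shape = (h, w)

    data = np.zeros((len(CHANNELS), n_frames, h, w), dtype=np.uint16)
    labels = np.zeros((n_frames, h, w), dtype=np.uint16)

    marker_name = config.render_marker
    foci_col = f"foci_{marker_name}" if f"foci_{marker_name}" in series.columns else None
    render_mito = marker_name.lower() in ("ilv3", "mito")
    fates = dict(zip(lineage["cell_id"], lineage["fate"]))

    t_ds_end = config.phase_times[1]
    by_frame = series.groupby("frame", sort=True)

    for f in range(n_frames):
        phase = np.full(shape, config.background_level, dtype=float)
        ex390 = np.full(shape, config.background_level, dtype=float)
        ex475 = np.full(shape, config.background_level, dtype=float)
        marker = np.full(shape, config.background_level, dtype=float)
        lab = labels[f]

        try:
            frame_rows = by_frame.get_group(f)
        except KeyError:
            frame_rows = None

        if frame_rows is not None:
            for row in frame_rows.itertuples(index=False):
                radius = math.sqrt(row.area / math.pi)
                rr, cc = draw_disk((row.y, row.x), radius, shape=shape)
                lab[rr, cc] = row.cell_id

                decay = 1.0
                if (config.r_minus_fluorescence_decay
                        and fates[row.cell_id] == R_MINUS
                        and row.time > t_ds_end):
                    decay = math.exp(-(row.time - t_ds_end) / 10.0)

                phase[rr, cc] = config.background_level + PHASE_AMPLITUDE
                amp475 = config.ex475_amplitude * decay
                ratio = float(forward_ratio(row.ph_true, forward_params))
                ex475[rr, cc] = config.background_level + amp475
                ex390[rr, cc] = config.background_level + ratio * amp475
                marker[rr, cc] = config.background_level + config.marker_diffuse_level

                # dark lipid droplet on the phase image
                ld_rr, ld_cc = draw_disk((row.ld_y, row.ld_x), 1.5, shape=shape)
                phase[ld_rr, ld_cc] = (config.background_level
                                       + PHASE_AMPLITUDE * (1.0 - config.ld_depth))

                if render_mito:
                    cell_rng = np.random.default_rng(
                        (config.seed, 1000 + row.cell_id, f))
                    _mito_texture(marker, row.x, row.y, radius,
                                  str(row.mito_state), config.marker_diffuse_level,
                                  config.foci_contrast, cell_rng, shape)
                elif foci_col is not None and getattr(row, foci_col):
                    frr, fcc = draw_disk((row.ld_y, row.ld_x), 1.5, shape=shape)
                    marker[frr, fcc] += config.foci_contrast

        for ci, img in enumerate((phase, ex390, ex475, marker)):
            if config.noise_sd > 0:
                img = img + rng.normal(0.0, config.noise_sd, size=shape)
            np.clip(img, 0, 65535, out=img)
            data[ci, f] = np.round(img).astype(np.uint16)

    return ImageStack(data=data, times=times, labels=labels,
                      pixel_size=config.pixel_size)
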