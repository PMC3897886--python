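"""Render synthetic confocal-style images from per-nucleus profiles.

Produces one nuclear-counterstain channel (bright disks on a dim field)
and one image per expression channel in which each nucleus' disk is
painted with its tabulated intensity over the smooth background field.
Images are 16-bit grayscale and writable as TIFF.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import tifffile
from scipy.spatial import cKDTree
from skimage.draw import disk

from .core import ConfigurationError, EmbryoProfile
from .synthetic import CohortConfig, background_field

#: nuclear-channel paint values (16-bit a.u.)
NUCLEAR_FOREGROUND = 30000
NUCLEAR_BASELINE = 500


def render_images(
    embryo: EmbryoProfile,
    shape: tuple[int, int] = (400, 1000),
    nucleus_radius_px: int = 3,
    *,
    intensity_scale: float = 100.0,
    config: CohortConfig | None = None,
    overlap_tolerance: float = 0.01,
) -> tuple[np.ndarray, dict[str, np.ndarray], pd.DataFrame]:
    """Render ``embryo`` to (nuclear image, per-channel images, placement).

    The embryo's [0, 100]% coordinate box maps to the image minus a margin
    of one nucleus diameter.  ``placement`` records each nucleus' pixel
    centre for ground-truth matching.  Overlapping disks beyond
    ``overlap_tolerance`` (fraction of nuclei) trigger a warning only.
    """
    if nucleus_radius_px <= 0 or min(shape) <= 4 * nucleus_radius_px:
        raise ConfigurationError("resolution and nucleus radius must be positive and compatible")
    rows, cols = shape
    margin = 2 * nucleus_radius_px + 1
    r = margin + embryo.data["y"].to_numpy() / 100.0 * (rows - 1 - 2 * margin)
    c = margin + embryo.data["x"].to_numpy() / 100.0 * (cols - 1 - 2 * margin)

    if len(r) > 1:
        d_min = cKDTree(np.column_stack([r, c])).query(np.column_stack([r, c]), k=2)[0][:, 1]
        n_overlap = int(np.sum(d_min < 2 * nucleus_radius_px))
        if n_overlap > overlap_tolerance * len(r):
            warnings.warn(
                f"{n_overlap}/{len(r)} nuclei closer than one diameter; "
                "disks overlap in the rendered image",
                stacklevel=2,
            )

    nuclear = np.full(shape, NUCLEAR_BASELINE, dtype=np.uint16)
    channels: dict[str, np.ndarray] = {}
    for ch in embryo.channels:
        if config is not None:
            yy, xx = np.mgrid[0:rows, 0:cols]
            x_el = np.clip((xx - margin) / (cols - 1 - 2 * margin) * 100.0, 0, 100)
            y_el = np.clip((yy - margin) / (rows - 1 - 2 * margin) * 100.0, 0, 100)
            field = background_field(config, x_el, y_el) * intensity_scale
            channels[ch] = np.clip(field, 0, 65535).astype(np.uint16)
        else:
            channels[ch] = np.zeros(shape, dtype=np.uint16)

    for i, (ri, ci) in enumerate(zip(r, c)):
        rr, cc = disk((ri, ci), nucleus_radius_px + 0.5, shape=shape)
        nuclear[rr, cc] = NUCLEAR_FOREGROUND
        for ch in embryo.channels:
            value = embryo.data[f"I_{ch}"].iloc[i] * intensity_scale
            channels[ch][rr, cc] = np.uint16(np.clip(value, 0, 65535))

    placement = pd.DataFrame(
        {"nucleus_id": embryo.data["nucleus_id"].to_numpy(), "row": r, "col": c}
    )
    return nuclear, channels, placement


def write_tiff(path, image: np.ndarray) -> None:
    """Write a single-channel 16-bit grayscale TIFF."""
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.uint16))


def read_tiff(path) -> np.ndarray:
    return tifffile.imread(str(path))
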