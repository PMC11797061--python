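"""Count reporter-positive cells in single-channel fluorescence images.

Cells expressing the mKate2 reporter are segmented from the far-red channel
and counted when they pass two gates: occupied area within 150-800 um^2
(inclusive) and mean intensity >= 400 (inclusive, arbitrary instrument
units).  Segmentation is the simplest reproducible operator chain: optional
Gaussian smoothing, a global threshold (distinct from, and by default below,
the 400-unit intensity gate), and 8-connected components.  Mean intensity is
always measured on the unsmoothed image.  Flat-field correction is
approximated by optional division by a large-sigma Gaussian background
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure
from skimage.filters import gaussian

from .exceptions import ParameterError


@dataclass
class GateConfig:
    """Segmentation and counting gates.

    Defaults follow the reference high-content pipeline: area gate
    150-800 um^2, mean-intensity gate 400 (instrument units, configurable
    since intensity scales are instrument-specific).
    """

    pixel_size: float  # um / pixel
    intensity_threshold: float = 400.0
    area_min: float = 150.0  # um^2
    area_max: float = 800.0  # um^2
    background_sigma: float = 0.0  # smoothing for segmentation only, px
    segmentation_threshold: float = 200.0

    def __post_init__(self) -> None:
        if self.pixel_size is None or self.pixel_size <= 0:
            raise ParameterError("pixel_size (um/px) must be set and positive")
        if not self.area_min < self.area_max:
            raise ParameterError("area_min must be smaller than area_max")


def flatfield_correct(image: np.ndarray, sigma: float = 50.0) -> np.ndarray:
    """Divide by a large-sigma Gaussian background estimate (approximate
    flat-field correction), rescaled to preserve the mean intensity."""
    image = np.asarray(image, dtype=float)
    background = gaussian(image, sigma=sigma, preserve_range=True)
    background = np.maximum(background, 1e-9)
    corrected = image / background
    return corrected * image.mean() / max(corrected.mean(), 1e-9)


def count_positive_cells(
    image: np.ndarray, gates: GateConfig
) -> tuple[int, pd.DataFrame]:
    """Count gate-passing objects; returns (count, per-object table).

    The table has one row per segmented object with its area (um^2), mean
    intensity, centroid and the gate verdict; the count is the number of
    rows passing both gates.  An empty or all-background image yields
    count 0.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ParameterError("expected a single-channel 2-D image")
    seg_source = (
        gaussian(img, sigma=gates.background_sigma, preserve_range=True)
        if gates.background_sigma > 0
        else img
    )
    mask = seg_source > gates.segmentation_threshold
    labels = measure.label(mask, connectivity=2)  # 8-connectivity
    rows = []
    for region in measure.regionprops(labels, intensity_image=img):
        area_um2 = region.area * gates.pixel_size**2
        mean_intensity = float(region.intensity_mean)
        passed = (
            gates.area_min <= area_um2 <= gates.area_max
            and mean_intensity >= gates.intensity_threshold
        )
        rows.append(
            {
                "label": region.label,
                "area_um2": float(area_um2),
                "mean_intensity": mean_intensity,
                "centroid_row": float(region.centroid[0]),
                "centroid_col": float(region.centroid[1]),
                "passed": bool(passed),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "label", "area_um2", "mean_intensity",
            "centroid_row", "centroid_col", "passed",
        ],
    )
    return int(table["passed"].sum()) if len(table) else 0, table


def timecourse_counts(images, gates: GateConfig) -> pd.DataFrame:
    """Apply :func:`count_positive_cells` per frame of an image sequence."""
    images = list(images)
    if not images:
        return pd.DataFrame(columns=["frame", "count"])
    shape = np.asarray(images[0]).shape
    counts = []
    for i, frame in enumerate(images):
        frame = np.asarray(frame)
        if frame.shape != shape:
            raise ParameterError(
                f"frame {i} has shape {frame.shape}, expected {shape}"
            )
        count, _ = count_positive_cells(frame, gates)
        counts.append({"frame": i, "count": count})
    return pd.DataFrame(counts)
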