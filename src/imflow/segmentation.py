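"""Primary object identification: threshold, label, declump, gate, measure.

The binarization step is global minimum cross-entropy (Li) thresholding:
intensities are quantized to ``n_bins`` bin centers and the threshold is
the bin boundary minimizing the cross entropy between the image and its
two-level (foreground mean / background mean) reconstruction,

    cost(t) = - sum_{g<t} g h(g) ln mu_low(t) - sum_{g>=t} g h(g) ln mu_high(t)

with h the histogram over bin centers g.  Touching cells are optionally
split by a distance-transform watershed, objects are gated by equivalent
diameter (inclusive bounds, in micrometres), and each surviving cell gets
the arithmetic mean of all its pixels -- the whole cell region, no nuclear
compartmentalization and no background subtraction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure as skmeasure
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .config import SegmentationParams
from .io_formats import CELL_COLUMNS, FluorImage


def mce_threshold(image: np.ndarray | FluorImage, n_bins: int = 256) -> float:
    """Global minimum cross-entropy threshold of a grayscale image.

    Returns the threshold as an intensity on the image's own scale;
    foreground is ``pixels >= threshold``.  Ties are broken toward the
    smaller boundary.  Raises on a constant image (degenerate histogram).
    """
    pixels = image.pixels if isinstance(image, FluorImage) else np.asarray(image)
    values = pixels.ravel().astype(np.float64)
    lo, hi = float(values.min()), float(values.max())
    if not hi > lo:
        raise ValueError("degenerate histogram: image is constant")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")

    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    w = centers * counts  # first-moment mass per bin
    cum_n = np.cumsum(counts)
    cum_w = np.cumsum(w)
    total_n, total_w = cum_n[-1], cum_w[-1]

    # candidate boundaries k = 1..n_bins-1 split bins [0,k) vs [k,n_bins)
    n_low = cum_n[:-1]
    w_low = cum_w[:-1]
    n_high = total_n - n_low
    w_high = total_w - w_low

    with np.errstate(divide="ignore", invalid="ignore"):
        mu_low = np.where(n_low > 0, w_low / n_low, np.nan)
        mu_high = np.where(n_high > 0, w_high / n_high, np.nan)
        # a side with zero first moment contributes nothing to the cost
        term_low = np.where(w_low > 0, -w_low * np.log(mu_low), 0.0)
        term_high = np.where(w_high > 0, -w_high * np.log(mu_high), 0.0)
    cost = term_low + term_high
    valid = (n_low > 0) & (n_high > 0)
    if not valid.any():
        raise ValueError("degenerate histogram: no valid threshold candidate")
    cost = np.where(valid, cost, np.inf)
    best = int(np.argmin(cost))  # argmin returns the smallest tied index
    return float(edges[best + 1])


def binarize(image: FluorImage, params: SegmentationParams) -> np.ndarray:
    """Threshold an image (optionally pre-smoothed) into a foreground mask."""
    pixels = image.pixels
    if params.smooth_sigma_px > 0:
        pixels = ndi.gaussian_filter(pixels, params.smooth_sigma_px)
    thr = mce_threshold(pixels, params.n_bins)
    return pixels >= thr


def label_objects(
    binary_mask: np.ndarray,
    params: SegmentationParams,
    pitch_um_per_px: float | None = None,
) -> np.ndarray:
    """Connected-component labels, with optional watershed declumping.

    Declumping seeds are local maxima of the Gaussian-smoothed Euclidean
    distance transform, separated by at least ``declump_min_sep_um``; the
    watershed then runs on the negated distance transform inside the mask.
    Background is 0, labels are consecutive positive integers.
    """
    binary_mask = np.asarray(binary_mask, dtype=bool)
    connectivity = 2 if params.connectivity == 8 else 1
    if not binary_mask.any():
        return np.zeros(binary_mask.shape, dtype=np.int32)
    labels = skmeasure.label(binary_mask, connectivity=connectivity)
    if not params.declump:
        return labels.astype(np.int32)
    if pitch_um_per_px is None:
        raise ValueError("declumping needs the pixel pitch to set seed separation")

    distance = ndi.distance_transform_edt(binary_mask)
    smoothed = ndi.gaussian_filter(distance, sigma=2.0)
    min_sep_px = max(1, int(round(params.declump_min_sep_um / pitch_um_per_px)))
    coords = peak_local_max(
        smoothed,
        min_distance=min_sep_px,
        labels=labels,
        exclude_border=False,
    )
    markers = np.zeros(binary_mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    # components that got no seed (thin slivers) keep a fallback marker
    seeded = set(labels[markers > 0].tolist())
    next_id = len(coords) + 1
    for region in skmeasure.regionprops(labels):
        if region.label not in seeded:
            r, c = region.coords[len(region.coords) // 2]
            markers[r, c] = next_id
            next_id += 1
    split = watershed(-distance, markers=markers, mask=binary_mask)
    return _relabel(split)


def _relabel(mask: np.ndarray) -> np.ndarray:
    """Compact label ids to 1..n preserving order of first appearance."""
    ids = np.unique(mask)
    ids = ids[ids > 0]
    out = np.zeros_like(mask, dtype=np.int32)
    for new, old in enumerate(ids, start=1):
        out[mask == old] = new
    return out


def equivalent_diameter_um(area_px: np.ndarray | float, pitch_um_per_px: float) -> np.ndarray | float:
    """Diameter (um) of the circle with the same pixel area as the object."""
    return 2.0 * np.sqrt(np.asarray(area_px, dtype=np.float64) / np.pi) * pitch_um_per_px


def gate_by_diameter(
    label_mask: np.ndarray,
    pitch_um_per_px: float,
    d_min_um: float,
    d_max_um: float,
) -> tuple[np.ndarray, int]:
    """Keep objects whose equivalent diameter lies in [d_min_um, d_max_um].

    Returns (filtered mask with original label ids, number removed).
    """
    out = label_mask.copy()
    removed = 0
    for region in skmeasure.regionprops(label_mask):
        d_um = float(equivalent_diameter_um(region.area, pitch_um_per_px))
        if not d_min_um <= d_um <= d_max_um:
            out[out == region.label] = 0
            removed += 1
    return out, removed


def clear_border_objects(label_mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Drop objects touching the image border (partially imaged cells)."""
    border = np.unique(
        np.concatenate(
            [label_mask[0], label_mask[-1], label_mask[:, 0], label_mask[:, -1]]
        )
    )
    border = border[border > 0]
    out = label_mask.copy()
    for lab in border:
        out[out == lab] = 0
    return out, int(len(border))


def measure_cells(image: FluorImage, label_mask: np.ndarray) -> pd.DataFrame:
    """Whole-cell mean intensities for every labeled object.

    One row per label: pixel area, equivalent diameter (um), centroid, and
    the arithmetic mean of the normalized pixel values under the label --
    plus the same mean on the 8-bit scale (x255, no rounding).
    """
    if label_mask.shape != image.pixels.shape:
        raise ValueError("label mask and image shapes differ")
    rows = []
    for region in skmeasure.regionprops(label_mask, intensity_image=image.pixels):
        mean_norm = float(region.intensity_mean)
        rows.append(
            {
                "cell_id": int(region.label),
                "image_id": image.image_id,
                "area_px": int(region.area),
                "equivalent_diameter_um": float(
                    equivalent_diameter_um(region.area, image.pitch_um_per_px)
                ),
                "centroid_row": float(region.centroid[0]),
                "centroid_col": float(region.centroid[1]),
                "mean_intensity_norm": mean_norm,
                "mean_intensity_8bit": 255.0 * mean_norm,
            }
        )
    return pd.DataFrame(rows, columns=CELL_COLUMNS)


def segment_image(
    image: FluorImage, params: SegmentationParams
) -> tuple[pd.DataFrame, np.ndarray, dict[str, int]]:
    """Full primary-object-identification pass on one image.

    Threshold -> label (+declump) -> drop border objects -> diameter gate
    -> measure.  Returns (cell table, final label mask, stage counts).
    """
    mask = binarize(image, params)
    labels = label_objects(mask, params, image.pitch_um_per_px)
    n_initial = int(labels.max())
    n_border = 0
    if params.exclude_border:
        labels, n_border = clear_border_objects(labels)
    labels, n_gated_out = gate_by_diameter(
        labels, image.pitch_um_per_px, params.d_min_um, params.d_max_um
    )
    cells = measure_cells(image, labels)
    counts = {
        "objects_initial": n_initial,
        "removed_border": n_border,
        "removed_gate": n_gated_out,
        "cells_measured": int(len(cells)),
    }
    return cells, labels, counts
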