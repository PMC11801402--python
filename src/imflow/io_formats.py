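"""Readers and writers for every external artifact the pipeline touches.

Images come in as grayscale TIFF or PNG and are normalized to [0, 1] by the
dtype's full scale (255 for 8-bit, 65535 for 16-bit), never by the per-image
maximum: microscope gain and illumination are fixed across an experiment,
so cross-image intensity comparability must be preserved.

Tabular artifacts (cell tables, event tables, truth tables, histogram
summaries) are CSV with a frozen dialect -- comma separator, '.' decimal
mark, '\\n' line terminator -- so repeated runs are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .fcs import read_fcs

VALID_CHANNELS = ("glucose_like", "mmp_like", "other")

#: column orders frozen for reproducible CSV output
EVENT_COLUMNS = ["intensity_8bit", "modality", "group", "source_id"]
CELL_COLUMNS = [
    "cell_id",
    "image_id",
    "area_px",
    "equivalent_diameter_um",
    "centroid_row",
    "centroid_col",
    "mean_intensity_norm",
    "mean_intensity_8bit",
]
TRUTH_COLUMNS = [
    "cell_id",
    "image_id",
    "center_row",
    "center_col",
    "radius_px",
    "true_intensity",
    "group",
]


@dataclass
class FluorImage:
    """One grayscale fluorescence frame with its physical pixel pitch.

    ``pixels`` holds normalized intensity in [0, 1]; ``pitch_um_per_px`` is
    the physical size of one pixel in micrometres.
    """

    pixels: np.ndarray
    pitch_um_per_px: float
    channel: str = "other"
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("pixels must be a 2-D array with both dims >= 1")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("pixel values must lie in [0, 1]")
        if self.pitch_um_per_px <= 0:
            raise ValueError("pitch_um_per_px must be > 0")
        if self.channel not in VALID_CHANNELS:
            raise ValueError(f"channel must be one of {VALID_CHANNELS}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def read_image(
    path: str | Path, pitch_um_per_px: float, channel: str = "other"
) -> FluorImage:
    """Read a grayscale TIFF/PNG and normalize to [0, 1] by dtype full scale.

    Integer data is divided by the maximum representable value of its dtype
    (e.g. 32768 in a uint16 file becomes 32768/65535); float data is clipped
    to [0, 1].  Color images are rejected: channel extraction must happen
    upstream so that this reader stays unambiguous.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        raw = tifffile.imread(path)
    else:
        raw = iio.imread(path)
    raw = np.asarray(raw)
    if raw.ndim != 2:
        raise ValueError(
            f"{path.name}: expected a single-channel grayscale image, "
            f"got shape {raw.shape}; extract one channel before reading"
        )
    if np.issubdtype(raw.dtype, np.integer):
        full_scale = float(np.iinfo(raw.dtype).max)
        pixels = raw.astype(np.float64) / full_scale
    elif np.issubdtype(raw.dtype, np.floating):
        pixels = np.clip(raw.astype(np.float64), 0.0, 1.0)
    else:
        raise ValueError(f"{path.name}: unsupported pixel dtype {raw.dtype}")
    return FluorImage(
        pixels=pixels,
        pitch_um_per_px=pitch_um_per_px,
        channel=channel,
        image_id=path.stem,
    )


def write_image(image: FluorImage, path: str | Path, dtype: str = "uint16") -> None:
    """Write a normalized image as an integer TIFF at dtype full scale."""
    info = np.iinfo(np.dtype(dtype))
    scaled = np.round(image.pixels * info.max).astype(dtype)
    tifffile.imwrite(Path(path), scaled)


def write_label_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write an integer label mask as 16-bit TIFF (background = 0)."""
    if mask.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit")
    tifffile.imwrite(Path(path), mask.astype(np.uint16))


def read_label_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int64)


def make_event_table(
    intensities_8bit: np.ndarray,
    modality: str,
    group: str,
    source_id: str | np.ndarray,
) -> pd.DataFrame:
    """Assemble a validated event table (one row per cell or flow event)."""
    values = np.asarray(intensities_8bit, dtype=np.float64)
    if values.ndim != 1:
        raise ValueError("intensities must be 1-D")
    if values.size and (values.min() < 0 or values.max() > 255):
        raise ValueError("event intensities must lie in [0, 255]")
    if modality not in ("imaging", "flow"):
        raise ValueError("modality must be 'imaging' or 'flow'")
    if not group:
        raise ValueError("group must be non-empty")
    table = pd.DataFrame(
        {
            "intensity_8bit": values,
            "modality": modality,
            "group": group,
            "source_id": source_id,
        }
    )
    return table[EVENT_COLUMNS]


def read_flow_events(
    path: str | Path,
    channel_name: str,
    full_scale: float | None = None,
    group: str = "unspecified",
) -> pd.DataFrame:
    """Read flow-cytometry list-mode events from CSV or FCS 3.0/3.1.

    Raw channel values are rescaled linearly to the 8-bit analysis scale:
    value / full_scale * 255.  For CSV input ``full_scale`` defaults to 255
    (identity); for FCS it defaults to the channel's $PnR range keyword.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "rb") as fh:
        magic = fh.read(6)
    if magic in (b"FCS3.0", b"FCS3.1"):
        data, meta = read_fcs(path)
        if channel_name not in data.columns:
            raise KeyError(
                f"channel {channel_name!r} not in {list(data.columns)}"
            )
        values = data[channel_name].to_numpy(dtype=np.float64)
        if full_scale is None:
            full_scale = float(meta.get(f"range:{channel_name}", 255.0))
    else:
        frame = pd.read_csv(path)
        if channel_name not in frame.columns:
            raise KeyError(
                f"channel {channel_name!r} not in columns {list(frame.columns)}"
            )
        values = frame[channel_name].to_numpy(dtype=np.float64)
        if full_scale is None:
            full_scale = 255.0
    if full_scale <= 0:
        raise ValueError("full_scale must be > 0")
    scaled = values / full_scale * 255.0
    return make_event_table(scaled, "flow", group, path.stem)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write any pipeline table as CSV in the frozen dialect.

    Column order is preserved as given; an empty table is an error and no
    file is created.
    """
    if table.empty:
        raise ValueError("refusing to write an empty table")
    table.to_csv(Path(path), index=False, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
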