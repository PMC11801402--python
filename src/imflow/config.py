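"""Run configuration for the imaging-cytometry pipeline.

All tunable parameters live in small dataclasses that serialize to/from a
single YAML file, so a run is fully described by (config, master seed).
Defaults reproduce the published analysis settings: an 18-38 um equivalent-
diameter gate, 1000x750 px random crop windows, Silverman-bandwidth KDE,
and alpha = 0.05 for significance calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields, is_dataclass
from pathlib import Path
from typing import Any

import yaml

# Channel presets: mean per-cell intensity (normalized), microscopy SBR and
# flow SBR as reported for the glucose-uptake (2-NBDG-like) and
# mitochondrial-membrane-potential (TMRE-like) channels.
CHANNEL_PROFILES: dict[str, dict[str, float]] = {
    "glucose_like": {"mean_intensity": 0.25, "sbr_microscopy": 20.0, "sbr_flow": 10.0},
    "mmp_like": {"mean_intensity": 0.30, "sbr_microscopy": 80.0, "sbr_flow": 1000.0},
}


@dataclass
class SegmentationParams:
    """Settings for primary object identification.

    ``d_min_um``/``d_max_um`` are the inclusive equivalent-diameter gate
    bounds in micrometres.  Declumping splits touching cells by a
    distance-transform watershed seeded at local maxima separated by at
    least ``declump_min_sep_um`` (default: half the lower gate bound).
    """

    n_bins: int = 256
    connectivity: int = 8
    declump: bool = True
    declump_min_sep_um: float = 9.0
    d_min_um: float = 18.0
    d_max_um: float = 38.0
    smooth_sigma_px: float = 0.0
    exclude_border: bool = True

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if not self.d_min_um < self.d_max_um:
            raise ValueError("d_min_um must be < d_max_um")


@dataclass
class CropParams:
    """Random analysis-window cropping (1000x750 px windows by default)."""

    enabled: bool = True
    width_px: int = 1000
    height_px: int = 750

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("crop dimensions must be >= 1")


@dataclass
class KDEParams:
    """Kernel-density settings for the frequency plots.

    Bandwidth follows the normal-reference (Silverman) rule
    h = 1.06 * s * n**(-1/5); the density is evaluated on ``grid_size``
    equally spaced points spanning [min - 3h, max + 3h].
    """

    bandwidth_rule: str = "silverman"
    grid_size: int = 512

    def __post_init__(self) -> None:
        if self.grid_size < 64:
            raise ValueError("grid_size must be >= 64")
        if self.bandwidth_rule != "silverman":
            raise ValueError(f"unknown bandwidth rule {self.bandwidth_rule!r}")


@dataclass
class StatsParams:
    alpha: float = 0.05
    bonferroni: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class GeneratorParams:
    """Ground-truth synthetic experiment settings.

    Defaults emulate the published study conditions: ~1 um optical
    resolution at 2.7 px/um, 15 images per group (within the reported
    10-20), ~65 cells per frame (~1000 cells per condition), 20,000 flow
    events per group split across 4 tubes, and channel-specific
    signal-to-background ratios.  Per-cell intensities are lognormal
    (right-skewed, as fluorescence histograms are), truncated at
    ``max_intensity`` by redraw.
    """

    channel: str = "glucose_like"
    image_height_px: int = 900
    image_width_px: int = 1200
    pitch_um_per_px: float = 1.0 / 2.7
    n_images: int = 15
    cells_per_image: int = 65
    cell_diameter_um: tuple[float, float] = (19.0, 37.0)
    placement_margin_px: float = 6.0
    intensity_family: str = "lognormal"
    mean_intensity: float | None = None  # None -> channel profile value
    sigma_log: float = 0.22
    max_intensity: float = 0.95
    groups: dict[str, float] = field(
        default_factory=lambda: {"control": 1.0, "treated": 1.3}
    )
    sbr_microscopy: float | None = None  # None -> channel profile value
    sbr_flow: float | None = None
    psf_sigma_px: float = 0.5
    photons_full_scale: float = 5000.0
    read_noise_sigma: float = 0.002
    n_flow_events: int = 20000
    n_flow_samples: int = 4
    flow_noise_sigma: float = 0.05

    def __post_init__(self) -> None:
        if self.channel not in CHANNEL_PROFILES:
            raise ValueError(
                f"unknown channel {self.channel!r}; options: {sorted(CHANNEL_PROFILES)}"
            )
        profile = CHANNEL_PROFILES[self.channel]
        if self.mean_intensity is None:
            self.mean_intensity = profile["mean_intensity"]
        if self.sbr_microscopy is None:
            self.sbr_microscopy = profile["sbr_microscopy"]
        if self.sbr_flow is None:
            self.sbr_flow = profile["sbr_flow"]
        self.cell_diameter_um = tuple(self.cell_diameter_um)  # type: ignore[assignment]
        d_lo, d_hi = self.cell_diameter_um
        if not 0 < d_lo <= d_hi:
            raise ValueError("cell_diameter_um must satisfy 0 < lo <= hi")
        if self.mean_intensity <= 0 or self.mean_intensity > 1:
            raise ValueError("mean_intensity must be in (0, 1]")
        if self.sbr_microscopy < 1 or self.sbr_flow < 1:
            raise ValueError("signal-to-background ratios must be >= 1")
        if any(fc <= 0 for fc in self.groups.values()):
            raise ValueError("fold changes must be > 0")
        if self.intensity_family not in ("lognormal", "gaussian"):
            raise ValueError("intensity_family must be 'lognormal' or 'gaussian'")
        if self.n_flow_samples < 1:
            raise ValueError("n_flow_samples must be >= 1")


@dataclass
class PipelineConfig:
    """Top-level configuration: one section per pipeline stage."""

    generator: GeneratorParams = field(default_factory=GeneratorParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    crop: CropParams = field(default_factory=CropParams)
    kde: KDEParams = field(default_factory=KDEParams)
    stats: StatsParams = field(default_factory=StatsParams)
    control_group: str = "control"

    def __post_init__(self) -> None:
        if not self.generator.groups:
            raise ValueError("at least one experimental group is required")
        if self.control_group not in self.generator.groups:
            raise ValueError(
                f"control group {self.control_group!r} missing from generator groups"
            )

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def _build(cls: type, data: dict[str, Any]) -> Any:
    """Construct a (possibly nested) config dataclass from plain dicts."""
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(data)
    for name, value in list(kwargs.items()):
        section = _section_type(cls, name)
        if is_dataclass(section) and isinstance(value, dict):
            kwargs[name] = _build(section, value)
    return cls(**kwargs)


def _section_type(cls: type, name: str) -> type:
    mapping = {
        "generator": GeneratorParams,
        "segmentation": SegmentationParams,
        "crop": CropParams,
        "kde": KDEParams,
        "stats": StatsParams,
    }
    return mapping.get(name, str)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML configuration file into a validated PipelineConfig."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return _build(PipelineConfig, data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
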