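"""End-to-end orchestration: simulate -> segment -> histogram -> compare.

Each stage reads its inputs from, and writes its outputs to, a run
directory, so stages can be re-run individually and compose bit-for-bit
into the full pipeline.  One master seed fans out to per-stage child
streams through a fixed derivation (``SeedSequence([master, stage])``), so
every stage is independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, save_config
from .histograms import (
    random_crop,
    relative_changes,
    summaries_to_frame,
    summarize_histogram,
)
from .io_formats import (
    make_event_table,
    read_image,
    read_table,
    write_image,
    write_label_mask,
    write_table,
)
from .stats import (
    build_concordance,
    compare_groups,
    per_image_means,
    per_tube_means,
    tests_to_frame,
)
from .segmentation import segment_image
from .synthetic import generate_experiment

_STAGE_SEEDS = {"simulate": 0, "segment": 1, "histogram": 2, "compare": 3}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class RunManifest:
    """Machine-readable record of one pipeline run."""

    seed: int
    version: str
    config: dict
    outputs: dict[str, list[str]] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


def _stage_seed(master: int, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master), _STAGE_SEEDS[stage]])


def stage_simulate(
    config: PipelineConfig, outdir: Path, seed: int
) -> dict[str, int]:
    """Generate the synthetic experiment and write all its artifacts."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(exist_ok=True)
    experiment = generate_experiment(config.generator, _stage_seed(seed, "simulate"))
    index_rows = []
    for group, images in experiment.images.items():
        for image, mask in zip(images, experiment.label_masks[group]):
            write_image(image, outdir / "images" / f"{image.image_id}.tif")
            write_label_mask(mask, outdir / "masks" / f"{image.image_id}_mask.tif")
            index_rows.append(
                {
                    "image_id": image.image_id,
                    "group": group,
                    "filename": f"images/{image.image_id}.tif",
                }
            )
    index = pd.DataFrame(index_rows)
    write_table(index, outdir / "images_index.csv")
    write_table(experiment.truth, outdir / "truth.csv")
    write_table(experiment.flow_events, outdir / "flow_events.csv")
    meta = {
        "background": experiment.background,
        "flow_baseline": experiment.flow_baseline,
    }
    (outdir / "generator_meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    return {
        "images": len(index),
        "flow_events": int(len(experiment.flow_events)),
    }


def stage_segment(config: PipelineConfig, outdir: Path, seed: int) -> dict[str, int]:
    """Crop (optionally), segment and measure every image in the run dir."""
    outdir = Path(outdir)
    index_path = outdir / "images_index.csv"
    if not index_path.exists():
        raise StageError("segment: missing images_index.csv (run simulate first)")
    index = read_table(index_path).sort_values("image_id").reset_index(drop=True)
    crop_seeds = _stage_seed(seed, "segment").spawn(len(index))
    tables = []
    counts = {"objects_initial": 0, "removed_border": 0, "removed_gate": 0}
    for (_, row), cseed in zip(index.iterrows(), crop_seeds):
        image = read_image(
            outdir / row["filename"],
            pitch_um_per_px=config.generator.pitch_um_per_px,
            channel=config.generator.channel,
        )
        if config.crop.enabled:
            rng = np.random.default_rng(cseed)
            image = random_crop(
                image, rng, config.crop.width_px, config.crop.height_px
            )
        # keep the uncropped id so replicates group by source image
        image.image_id = row["image_id"]
        try:
            cells, _, image_counts = segment_image(image, config.segmentation)
        except Exception as exc:  # pragma: no cover - defensive
            raise StageError(f"segment: failed on {row['image_id']}: {exc}") from exc
        cells["group"] = row["group"]
        tables.append(cells)
        for key in counts:
            counts[key] += image_counts[key]
    cell_table = pd.concat(tables, ignore_index=True)
    if cell_table.empty:
        raise StageError("segment: no cells identified in any image")
    write_table(cell_table, outdir / "cells.csv")
    counts["cells_measured"] = int(len(cell_table))
    return counts


def stage_histogram(config: PipelineConfig, outdir: Path) -> dict[str, int]:
    """Summarize every group x modality intensity distribution."""
    outdir = Path(outdir)
    cells_path = outdir / "cells.csv"
    flow_path = outdir / "flow_events.csv"
    if not cells_path.exists():
        raise StageError("histogram: missing cells.csv (run segment first)")
    cells = read_table(cells_path)
    summaries = []
    from .histograms import kde_curve  # local to keep module import light

    def _summarize(values: np.ndarray, group: str, modality: str) -> None:
        summary = summarize_histogram(values, config.kde, group, modality)
        summaries.append(summary)
        grid, density = kde_curve(values, config.kde)
        write_table(
            pd.DataFrame({"intensity_8bit": grid, "density": density}),
            outdir / f"density_{group}_{modality}.csv",
        )

    for group, sub in cells.groupby("group"):
        _summarize(sub["mean_intensity_8bit"].to_numpy(), str(group), "imaging")
    if flow_path.exists():
        flow = read_table(flow_path)
        for group, sub in flow.groupby("group"):
            _summarize(sub["intensity_8bit"].to_numpy(), str(group), "flow")
    frame = summaries_to_frame(summaries)
    write_table(frame, outdir / "histogram_summaries.csv")
    return {"summaries": len(frame)}


def stage_compare(config: PipelineConfig, outdir: Path) -> dict[str, int]:
    """Relative changes, significance tests and the concordance report."""
    outdir = Path(outdir)
    summaries_path = outdir / "histogram_summaries.csv"
    if not summaries_path.exists():
        raise StageError("compare: missing histogram_summaries.csv")
    summaries = read_table(summaries_path)
    cells = read_table(outdir / "cells.csv")
    control = config.control_group
    alpha = config.stats.alpha

    rel_imaging = relative_changes(summaries, control, "imaging")
    write_table(rel_imaging, outdir / "rel_changes_imaging.csv")

    imaging_groups = {
        str(g): per_image_means(sub).to_numpy()
        for g, sub in cells.groupby("group")
    }
    tests: dict[str, object] = {}
    tests["imaging"] = compare_groups(imaging_groups, alpha)

    flow_path = outdir / "flow_events.csv"
    have_flow = flow_path.exists() and "flow" in set(summaries["modality"])
    if have_flow:
        flow = read_table(flow_path)
        rel_flow = relative_changes(summaries, control, "flow")
        write_table(rel_flow, outdir / "rel_changes_flow.csv")
        flow_groups = {
            str(g): per_tube_means(sub).to_numpy()
            for g, sub in flow.groupby("group")
        }
        tests["flow"] = compare_groups(flow_groups, alpha)
        concordance = build_concordance(
            rel_imaging, rel_flow, tests["imaging"], tests["flow"]
        )
        write_table(concordance, outdir / "concordance.csv")
    write_table(tests_to_frame(tests), outdir / "tests.csv")

    lines = [f"imflow run report (alpha={alpha})"]
    for modality, res in tests.items():
        lines.append(
            f"{modality}: {res.test} statistic={res.statistic:.4f} "
            f"p={res.p_value:.4g} significant={res.significant}"
        )
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
    return {"comparisons": len(rel_imaging)}


def run_all(config: PipelineConfig, outdir: str | Path, seed: int) -> RunManifest:
    """Execute every stage in order and write the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(config, outdir / "config_snapshot.yaml")
    manifest = RunManifest(seed=int(seed), version=__version__, config=config.to_dict())
    counts: dict[str, int] = {}
    counts.update(stage_simulate(config, outdir, seed))
    counts.update(stage_segment(config, outdir, seed))
    counts.update(stage_histogram(config, outdir))
    counts.update(stage_compare(config, outdir))
    manifest.counts = counts
    manifest.outputs = {
        "tables": sorted(str(p.name) for p in outdir.glob("*.csv")),
        "images": sorted(str(p.name) for p in (outdir / "images").glob("*.tif")),
    }
    manifest.write(outdir / "manifest.json")
    return manifest
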