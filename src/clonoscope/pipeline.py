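"""End-to-end pipeline: simulate → (render → segment) → decode → stats.

A :class:`PipelineConfig` holds one parameter block per stage; running it
writes every artifact (cell tables, optional TIFF, clone summary, dispersion
statistics) under ``output_dir`` plus a :class:`RunManifest` with checksums,
so identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cortex import CorticalModel, build_layer_model, mouse_s1_model
from .decoding import clone_size_histogram, encode_table, group_clones
from .io import (
    load_yaml_config,
    sha256_of,
    write_cell_table,
    write_json_atomic,
    write_params_echo,
)
from .render import RenderConfig, render_image, write_tiff
from .segmentation import DetectionConfig, detect_cells
from .simulate import SimulationParams, simulate_clones
from .stats import pair_distances, summarize_dispersion

__all__ = ["PipelineConfig", "RunManifest", "PipelineStageError", "run_pipeline"]

log = logging.getLogger("clonoscope")

_CONFIG_KEYS = {
    "seed", "output_dir", "input_table", "layers", "slab_width",
    "simulate", "render", "segment", "decode", "stats", "log_level",
}


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Stage parameter blocks plus paths and the master seed."""

    output_dir: str | Path = "clonoscope_out"
    seed: int = 0
    input_table: str | None = None
    layers: dict[str, tuple[float, float]] | None = None
    slab_width: float = 600.0
    simulate: dict | None = None
    render: dict | None = None
    segment: dict = field(default_factory=dict)
    decode: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = load_yaml_config(path, _CONFIG_KEYS)
        return cls(**data)

    def model(self) -> CorticalModel:
        if self.layers is None:
            return mouse_s1_model(slab_width=self.slab_width)
        spec = {k: tuple(v) for k, v in self.layers.items()}
        return build_layer_model(spec, slab_width=self.slab_width)


@dataclass
class RunManifest:
    """Record of one pipeline run: stages, artifact checksums, timestamps."""

    version: str
    seed: int
    config: dict
    stages_completed: list[str] = field(default_factory=list)
    artifacts: dict[str, str] = field(default_factory=dict)  # path -> sha256
    started_at: str = ""
    finished_at: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _register(manifest: RunManifest, path: Path) -> None:
    manifest.artifacts[path.name] = sha256_of(path)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the configured stages end to end and write a manifest.

    Stage order: ``simulate`` (optional) → ``segment`` (only when a rendered
    or supplied image is in play) → ``decode`` → ``stats``.  Any stage
    failure aborts with a stage-tagged :class:`PipelineStageError`; the
    manifest written so far marks the run as partial.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        seed=config.seed,
        config={
            k: v for k, v in dataclasses.asdict(config).items() if v is not None
        },
        started_at=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    manifest_path = out / "manifest.json"
    model = config.model()

    try:
        cells: pd.DataFrame | None = None
        # --- simulate ------------------------------------------------------
        if config.simulate is not None:
            stage = "simulate"
            try:
                params = SimulationParams(**{**config.simulate, "seed": config.seed})
                cells, truth = simulate_clones(model, params)
                write_cell_table(cells, out / "cells_truth.csv")
                truth.table.to_csv(out / "clone_truth.csv", index=False)
                write_params_echo(dataclasses.asdict(params), out / "simulate_params.txt")
                _register(manifest, out / "cells_truth.csv")
                _register(manifest, out / "clone_truth.csv")
                manifest.stages_completed.append(stage)
                log.info("simulated %d cells", len(cells))
            except Exception as exc:
                raise PipelineStageError(stage, exc) from exc
        elif config.input_table is not None:
            from .io import read_cell_table

            cells = read_cell_table(config.input_table)

        if cells is None:
            raise PipelineStageError("simulate", ValueError(
                "no input: provide a simulate block or input_table"))

        # --- render + segment ---------------------------------------------
        if config.render is not None:
            stage = "segment"
            try:
                rcfg = RenderConfig(**config.render)
                image = render_image(
                    cells, (model.cortical_thickness, model.slab_width), rcfg
                )
                write_tiff(out / "image.tiff", image)
                _register(manifest, out / "image.tiff")
                dcfg = DetectionConfig(
                    pixel_size=rcfg.pixel_size, **config.segment
                )
                detected, searches = detect_cells(image, dcfg)
                detected["layer"] = model.layer_of(detected["y_um"].to_numpy())
                write_cell_table(detected, out / "cells_detected.csv")
                curves = {
                    f"ch{i + 1}": {str(n): (None if p == float("inf") else p)
                                   for n, p in s.psnr_by_n.items()}
                    for i, s in enumerate(searches)
                }
                write_json_atomic(curves, out / "psnr_curves.json")
                _register(manifest, out / "cells_detected.csv")
                _register(manifest, out / "psnr_curves.json")
                manifest.stages_completed.append(stage)
                cells_for_decode = detected
                log.info("detected %d cells", len(detected))
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(stage, exc) from exc
        else:
            cells_for_decode = cells
            manifest.stages_completed.append("segment")  # pass-through

        # --- decode --------------------------------------------------------
        stage = "decode"
        try:
            coded = encode_table(cells_for_decode)
            groups = group_clones(coded, **config.decode)
            code_by_cell = {c: g.clone_id for g in groups for c in g.cell_ids}
            coded["clone_label"] = coded["cell_id"].map(code_by_cell)
            write_cell_table(coded, out / "cells_coded.csv")
            clones_df = pd.DataFrame(
                [
                    {
                        "clone_id": g.clone_id,
                        "code": "-".join(map(str, g.code)),
                        "size": g.size,
                        "extent_um": round(g.extent_um, 2),
                        "section": g.section,
                    }
                    for g in groups
                ]
            )
            clones_df.to_csv(out / "clones.csv", index=False)
            hist = clone_size_histogram(groups) if groups else None
            write_json_atomic(
                {
                    "bins": [list(b) for b in hist.bins] if hist else [],
                    "counts": list(hist.counts) if hist else [],
                    "missing_sizes": list(hist.missing_sizes) if hist else [],
                },
                out / "clone_size_histogram.json",
            )
            _register(manifest, out / "cells_coded.csv")
            _register(manifest, out / "clones.csv")
            _register(manifest, out / "clone_size_histogram.json")
            manifest.stages_completed.append(stage)
            log.info("grouped %d clones", len(groups))
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc

        # --- stats ---------------------------------------------------------
        stage = "stats"
        try:
            for_stats = coded.copy()
            for_stats["clone_id"] = for_stats["clone_label"]
            pairs = pair_distances(
                for_stats, seed=config.seed, **config.stats
            )
            if len(pairs):
                summary = summarize_dispersion(pairs)
                summary.table.reset_index().to_csv(
                    out / "dispersion_summary.csv", index=False
                )
                summary.tests.to_csv(out / "dispersion_tests.csv", index=False)
                _register(manifest, out / "dispersion_summary.csv")
                _register(manifest, out / "dispersion_tests.csv")
            manifest.stages_completed.append(stage)
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc
    finally:
        manifest.finished_at = datetime.datetime.now(
            datetime.timezone.utc
        ).isoformat()
        write_json_atomic(manifest.to_dict(), manifest_path)
    return manifest
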