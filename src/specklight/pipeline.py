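"""End-to-end runs: simulate or load a stack, process one modality,
compute tumour/control ROI statistics, and write maps, tables and a
provenance record.

A run is described by a :class:`RunConfig` (constructible from YAML). The
provenance JSON written next to the outputs snapshots the configuration,
seeds, package version and per-stage wall time, so identical config + seed
reproduces identical numerical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dcs import dcs_map
from .io import load_roi, load_stack, write_map, write_mask, write_stack
from .lsci import lsci_map
from .mldcs import FilterConfig, TrainedRegressor, mldcs_map
from .phantom import Lesion, NoiseSpec, PhantomSpec, simulate_stack
from .roi import ROIMask, compare_rois, mirror_roi

__all__ = ["RunConfig", "run_pipeline"]

_MODALITIES = ("dcs", "mldcs", "lsci")

#: Columns of the statistics table, mirroring the conventional comparison
#: layout (control mean/std, tumour mean/std, SNR_T, Welch t).
TABLE_COLUMNS = ["modality", "mu_C", "sigma_C", "mu_T", "sigma_T", "SNR_T", "t", "p"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Either ``stack_path`` (with optional ``fps``) or ``phantom`` must be
    given. The ROI may come from a file (mask TIFF / polygon JSON); for a
    simulated phantom it defaults to the ground-truth lesion mask. The
    control ROI is always the mirrored tumour ROI.
    """

    out_dir: str
    modality: str = "dcs"
    stack_path: str | None = None
    fps: float | None = None
    phantom: dict | None = None
    noise: dict | None = None
    roi_path: str | None = None
    model_path: str | None = None  # required for mldcs
    modality_params: dict = field(default_factory=dict)
    seed: int = 0
    overwrite: bool = False
    log_level: str = "INFO"

    def __post_init__(self):
        if self.modality not in _MODALITIES:
            raise ValueError(f"modality must be one of {_MODALITIES}")
        if self.stack_path is None and self.phantom is None:
            raise ValueError("either stack_path or phantom must be given")
        if self.modality == "mldcs" and self.model_path is None:
            raise ValueError("the mldcs modality needs model_path")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def validate_inputs(self) -> None:
        """Fail fast: every referenced file must exist before work starts."""
        for p in (self.stack_path, self.roi_path, self.model_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")


def _phantom_from_dict(d: dict, seed: int) -> PhantomSpec:
    d = dict(d)
    lesions = tuple(Lesion(**l) for l in d.pop("lesions", []))
    d.setdefault("seed", seed)
    return PhantomSpec(lesions=lesions, **d)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute simulate/load -> modality -> ROI statistics.

    Returns a result bundle with the map object, the statistics table and
    the paths written. Stage errors abort with a stage-tagged message; an
    ``INCOMPLETE`` marker file flags partially written output directories.
    """
    cfg.validate_inputs()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "INCOMPLETE"
    marker.write_text("run in progress")
    prov: dict = {
        "config": dataclasses.asdict(cfg),
        "version": __version__,
        "stages": {},
    }
    t_all = time.perf_counter()

    def _stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                prov["stages"][name] = round(time.perf_counter() - self.t0, 4)
                if exc is not None:
                    raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

        return _Timer()

    # -- acquire ---------------------------------------------------------
    gt = None
    with _stage("acquire"):
        if cfg.phantom is not None:
            spec = _phantom_from_dict(cfg.phantom, cfg.seed)
            noise = NoiseSpec(**cfg.noise) if cfg.noise else None
            stack, gt = simulate_stack(spec, noise)
            write_stack(stack, out / "stack.tif", spec=spec, overwrite=cfg.overwrite)
        else:
            stack = load_stack(cfg.stack_path, fps=cfg.fps)

    # -- process ---------------------------------------------------------
    with _stage(cfg.modality):
        if cfg.modality == "dcs":
            result_map = dcs_map(stack, **cfg.modality_params)
        elif cfg.modality == "lsci":
            result_map = lsci_map(stack, **cfg.modality_params)
        else:
            model = TrainedRegressor.load(cfg.model_path)
            fparams = cfg.modality_params.get("filter", None)
            fcfg = FilterConfig(**fparams) if fparams else FilterConfig()
            result_map = mldcs_map(stack, model, filter_cfg=fcfg)
        map_path = write_map(result_map, out / f"{cfg.modality}_map.tif", overwrite=cfg.overwrite)

    # -- statistics ------------------------------------------------------
    with _stage("stats"):
        if cfg.roi_path is not None:
            tumour = load_roi(cfg.roi_path, shape=(stack.height, stack.width))
        elif gt is not None and gt.lesion_mask.any():
            tumour = ROIMask(mask=gt.lesion_mask, label="tumour", provenance="phantom ground truth")
        else:
            raise ValueError("no ROI available: give roi_path or a phantom with a lesion")
        control = mirror_roi(tumour)
        write_mask(tumour.mask, out / "roi_tumour.tif", overwrite=cfg.overwrite)
        write_mask(control.mask, out / "roi_control.tif", overwrite=cfg.overwrite)
        row = compare_rois(result_map, tumour, control)
        table = pd.DataFrame(
            [{**{"modality": cfg.modality}, **{k: row[k] for k in TABLE_COLUMNS[1:]}}],
            columns=TABLE_COLUMNS,
        )
        table_path = out / "stats.csv"
        if table_path.exists() and not cfg.overwrite:
            raise FileExistsError(f"{table_path} exists; set overwrite")
        table.to_csv(table_path, index=False, float_format="%.10g")

    prov["wall_time_s"] = round(time.perf_counter() - t_all, 4)
    prov["seed"] = cfg.seed
    (out / "provenance.json").write_text(json.dumps(prov, indent=1, default=str))
    marker.unlink(missing_ok=True)
    return {
        "map": result_map,
        "table": table,
        "paths": {"map": str(map_path), "table": str(table_path)},
        "provenance": prov,
    }
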