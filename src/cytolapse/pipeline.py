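"""End-to-end pipeline: simulate -> perturb -> evaluate -> lifecycle -> report.

:func:`run_pipeline` wires the modules into one deterministic run over a
sham/irradiated pair of simulated samples and writes a bundle of plain-text
outputs (annotation files, per-frame evaluation CSV, count series, growth-fit
report, CGSF table, censuses, run log).  All randomness derives from the
single seed in :class:`RunConfig`.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotations import write_annotations
from .detection import DEFAULT_IOU_SWEEP, per_frame_report
from .lifecycle import (
    cgsf,
    cgsf_from_series,
    count_series,
    dead_cell_census,
    division_census,
    fit_growth,
)
from .simulate import (
    NoiseConfig,
    SimConfig,
    apply_detector_noise,
    irradiated_config,
    mild_noise,
    sham_config,
    simulate_population,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    out_dir: Path
    seed: int = 0
    sim_sham: SimConfig = field(default_factory=sham_config)
    sim_irr: SimConfig = field(default_factory=irradiated_config)
    noise: NoiseConfig = field(default_factory=mild_noise)
    annotation_format: str = "csv"
    iou_sweep: tuple[float, ...] = DEFAULT_IOU_SWEEP
    interpolation: str = "envelope"
    absent_class: str = "exclude"
    confidence_level: float = 0.63
    channel: str = "vital"
    eval_stride: int = 12
    cgsf_times_h: tuple[float, ...] = (24.0, 48.0)
    death_window_h: float = 24.0

    def resolved(self) -> "RunConfig":
        """Copy with all sub-seeds derived from the master seed."""
        return replace(
            self,
            sim_sham=replace(self.sim_sham, seed=self.seed),
            sim_irr=replace(self.sim_irr, seed=self.seed + 1),
            noise=replace(self.noise, seed=self.seed + 2),
        )

    def to_dict(self) -> dict:
        d = {
            "out_dir": str(self.out_dir),
            "seed": self.seed,
            "sim_sham": self.sim_sham.to_dict(),
            "sim_irr": self.sim_irr.to_dict(),
            "noise": {
                **{
                    k: v
                    for k, v in self.noise.__dict__.items()
                    if k not in ("confusion",)
                },
                "confusion": np.asarray(self.noise.confusion).tolist(),
            },
            "annotation_format": self.annotation_format,
            "iou_sweep": [float(x) for x in self.iou_sweep],
            "interpolation": self.interpolation,
            "absent_class": self.absent_class,
            "confidence_level": self.confidence_level,
            "channel": self.channel,
            "eval_stride": self.eval_stride,
            "cgsf_times_h": list(self.cgsf_times_h),
            "death_window_h": self.death_window_h,
        }
        return d

    @classmethod
    def from_yaml(cls, path, out_dir: Optional[Path] = None) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "sim_sham" in d:
            kwargs["sim_sham"] = SimConfig.from_dict(d.pop("sim_sham"))
        if "sim_irr" in d:
            kwargs["sim_irr"] = SimConfig.from_dict(d.pop("sim_irr"))
        if "noise" in d:
            nd = d.pop("noise")
            if "confusion" in nd:
                nd["confusion"] = np.asarray(nd["confusion"], dtype=float)
            if "tp_confidence" in nd:
                nd["tp_confidence"] = tuple(nd["tp_confidence"])
            if "fp_confidence" in nd:
                nd["fp_confidence"] = tuple(nd["fp_confidence"])
            kwargs["noise"] = NoiseConfig(**nd)
        for k in (
            "seed",
            "annotation_format",
            "interpolation",
            "absent_class",
            "confidence_level",
            "channel",
            "eval_stride",
            "death_window_h",
        ):
            if k in d:
                kwargs[k] = d[k]
        if "iou_sweep" in d:
            kwargs["iou_sweep"] = tuple(d["iou_sweep"])
        if "cgsf_times_h" in d:
            kwargs["cgsf_times_h"] = tuple(d["cgsf_times_h"])
        kwargs["out_dir"] = Path(out_dir if out_dir is not None else d.get("out_dir", "cytolapse_run"))
        return cls(**kwargs)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(name, exc) from exc

        return wrapped

    return deco


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis and return a mapping of artifact names to paths."""
    config = config.resolved()
    for name, sim in (("sim_sham", config.sim_sham), ("sim_irr", config.sim_irr)):
        sim.validate()
        # a fully frozen video is legal for the simulator alone, but the
        # growth fit downstream needs growth, so reject it up front
        if sim.arrest_h > sim.duration_h:
            raise PipelineError(
                "validate",
                ValueError(
                    f"{name}: arrest_h ({sim.arrest_h}) exceeds duration_h "
                    f"({sim.duration_h})"
                ),
            )
    config.noise.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = config.annotation_format
    ext = {"csv": "csv", "via": "json", "coco": "json"}[fmt]
    paths: dict[str, Path] = {}

    @_stage("simulate")
    def _simulate():
        results = {}
        for name, sim in (("sham", config.sim_sham), ("irradiated", config.sim_irr)):
            video, lineage = simulate_population(sim)
            results[name] = (video, lineage)
            p = out / f"truth_{name}.{ext}"
            write_annotations(video, p, fmt)
            paths[f"truth_{name}"] = p
        return results

    truths = _simulate()

    @_stage("perturb")
    def _perturb():
        results = {}
        for i, (name, (video, _)) in enumerate(truths.items()):
            noise = replace(config.noise, seed=config.noise.seed + i)
            pred = apply_detector_noise(video, noise)
            results[name] = pred
            p = out / f"pred_{name}.{ext}"
            write_annotations(pred, p, fmt)
            paths[f"pred_{name}"] = p
        return results

    preds = _perturb()

    @_stage("evaluate")
    def _evaluate():
        for name in truths:
            report = per_frame_report(
                truths[name][0],
                preds[name],
                iou_thresholds=config.iou_sweep,
                absent_class=config.absent_class,
                interpolation=config.interpolation,
                stride=config.eval_stride,
            )
            p = out / f"evaluation_{name}.csv"
            report.to_csv(p, index=False)
            paths[f"evaluation_{name}"] = p

    _evaluate()

    @_stage("lifecycle")
    def _lifecycle():
        series = {}
        fits = {}
        for name, (video, lineage) in truths.items():
            s = count_series(video)
            series[name] = s
            p = out / f"counts_{name}.csv"
            s.to_csv(p)
            paths[f"counts_{name}"] = p
            fits[name] = fit_growth(
                s, channel=config.channel, confidence_level=config.confidence_level
            )
            census = division_census(lineage)
            p = out / f"divisions_{name}.csv"
            census.histogram.to_csv(p)
            paths[f"divisions_{name}"] = p
            death = dead_cell_census(video, window_h=config.death_window_h)
            pd.DataFrame(
                [
                    {
                        "k_dead": death.k,
                        "N_tracked": death.N,
                        "fraction": death.fraction,
                        "poisson_sigma": death.poisson_sigma,
                        "window_h": config.death_window_h,
                    }
                ]
            ).to_csv(out / f"death_census_{name}.csv", index=False)
            paths[f"death_census_{name}"] = out / f"death_census_{name}.csv"
        fit_report = "\n\n".join(
            f"[{name}]\n{fit.summary()}" for name, fit in fits.items()
        )
        p = out / "growth_fits.txt"
        p.write_text(fit_report + "\n")
        paths["growth_fits"] = p
        rows = []
        for t_h in config.cgsf_times_h:
            v_fit, s_fit = cgsf(fits["irradiated"], fits["sham"], t_h)
            v_raw, s_raw = cgsf_from_series(
                series["irradiated"], series["sham"], t_h, channel=config.channel
            )
            rows.append(
                {
                    "t_h": t_h,
                    "cgsf_fit": v_fit,
                    "sigma_fit": s_fit,
                    "cgsf_raw": v_raw,
                    "sigma_raw": s_raw,
                }
            )
        p = out / "cgsf.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        paths["cgsf"] = p

    _lifecycle()

    @_stage("log")
    def _log():
        cfg = config.to_dict()
        blob = yaml.safe_dump(cfg, sort_keys=True).encode()
        log = {
            "cytolapse_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(blob).hexdigest(),
            "config": cfg,
        }
        p = out / "run_log.json"
        p.write_text(json.dumps(log, indent=1))
        paths["run_log"] = p

    _log()
    return paths
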