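"""Agent-based simulator of a cell population and a detector-noise emulator.

The simulator reproduces the qualitative lifecycle of an adherent epithelial
population (CHO-K1-like) imaged by phase contrast every few minutes for up to
two days.  Each agent cycles through the state machine

    liv -> round -> div -> two liv daughters,

can die from any vital state (exponential hazard; ``dead`` is absorbing and
the dead box stays visible for the rest of the video), and holds its state
during an initial growth-arrest window that models the handling stress after
mounting/irradiation.  Irradiation effects are expressed purely through the
configuration: longer arrest, a larger non-dividing fraction, slower cycling
and extra death hazard — no dose-response law is built in.

The detector emulator perturbs a ground-truth video the way an imperfect
object detector would: missed objects, corner jitter, class confusion
(typically round <-> liv), spurious boxes, confidence scores, non-maximum
suppression and a hard cap on detections per frame (100 by default, the
practical ceiling of region-proposal detectors pre-trained with a fixed
detection budget).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import yaml

from .annotations import (
    CLASS_ORDER,
    Box,
    CellClass,
    FrameAnnotation,
    LabelledObject,
    SampleMeta,
    VideoAnnotation,
)

__all__ = [
    "SimConfig",
    "NoiseConfig",
    "LineageRecord",
    "ConfigError",
    "simulate_population",
    "apply_detector_noise",
    "nms",
    "sham_config",
    "irradiated_config",
    "mild_noise",
]


class ConfigError(ValueError):
    """A simulator or noise configuration violates its invariants."""


#: Per-class box size statistics: (mean_w, sd_w, mean_h, sd_h) in pixels.
#: Attached cells are large and elongated; round/dead cells are compact.
DEFAULT_BOX_STATS: dict[CellClass, tuple[float, float, float, float]] = {
    CellClass.LIV: (36.0, 8.0, 30.0, 7.0),
    CellClass.ROUND: (22.0, 3.0, 22.0, 3.0),
    CellClass.DIV: (34.0, 5.0, 26.0, 4.0),
    CellClass.DEAD: (18.0, 3.0, 18.0, 3.0),
}


@dataclass
class SimConfig:
    """Study conditions for one simulated sample.

    Defaults describe a sham-handled population: ~56 cells in a 1388 x 1040 px
    field imaged every 5 min for 48 h, uniform cycle time 12-16 h, a ~5.7 h
    arrest after handling, a small death hazard and a small permanently
    non-dividing fraction.
    """

    n_initial: int = 56
    field_size: tuple[int, int] = (1388, 1040)
    frame_interval_min: float = 5.0
    duration_h: float = 48.0
    cycle_time_h: tuple[float, float] = (12.0, 16.0)
    arrest_h: float = 5.7
    death_hazard_per_h: float = 0.002
    frac_nondividing: float = 0.05
    round_duration_min: float = 30.0
    div_duration_min: float = 15.0
    box_size_stats: dict[CellClass, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOX_STATS)
    )
    motility_px_per_frame: float = 2.0
    seed: int = 0
    sample_id: str = "sim"
    dose_gy: float = 0.0
    irradiated: bool = False

    def validate(self) -> None:
        if self.n_initial < 1:
            raise ConfigError("n_initial must be >= 1")
        w, h = self.field_size
        if w < 8 or h < 8:
            raise ConfigError(f"field_size {self.field_size} too small")
        if self.n_initial > w * h:
            raise ConfigError(
                f"field {w}x{h} too small to place {self.n_initial} distinct boxes"
            )
        if self.frame_interval_min <= 0 or self.duration_h <= 0:
            raise ConfigError("frame_interval_min and duration_h must be > 0")
        lo, hi = self.cycle_time_h
        if not (0 < lo <= hi):
            raise ConfigError(f"cycle_time_h range must be positive, got {self.cycle_time_h}")
        if self.arrest_h < 0 or self.death_hazard_per_h < 0:
            raise ConfigError("arrest_h and death_hazard_per_h must be >= 0")
        if not (0.0 <= self.frac_nondividing <= 1.0):
            raise ConfigError("frac_nondividing must be in [0, 1]")
        if self.round_duration_min < 0 or self.div_duration_min < 0:
            raise ConfigError("dwell times must be >= 0")
        dwell_h = (self.round_duration_min + self.div_duration_min) / 60.0
        if dwell_h >= lo:
            raise ConfigError("round+div dwell must be shorter than the cycle time")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_h * 60.0 / self.frame_interval_min))

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["field_size"] = list(self.field_size)
        d["cycle_time_h"] = list(self.cycle_time_h)
        d["box_size_stats"] = {
            cls.value: list(v) for cls, v in self.box_size_stats.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "field_size" in d:
            d["field_size"] = tuple(d["field_size"])
        if "cycle_time_h" in d:
            d["cycle_time_h"] = tuple(d["cycle_time_h"])
        if "box_size_stats" in d:
            d["box_size_stats"] = {
                CellClass(k): tuple(v) for k, v in d["box_size_stats"].items()
            }
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def sham_config(seed: int = 0) -> SimConfig:
    """Sham-handled control sample: handling arrest only."""
    return SimConfig(seed=seed, sample_id="sham", irradiated=False)


def irradiated_config(seed: int = 1) -> SimConfig:
    """4 Gy-like sample: slightly longer arrest, slower cycling, a larger
    permanently arrested fraction and extra death hazard."""
    return SimConfig(
        n_initial=45,
        arrest_h=5.8,
        cycle_time_h=(13.0, 17.5),
        frac_nondividing=0.20,
        death_hazard_per_h=0.0025,
        seed=seed,
        sample_id="irradiated",
        dose_gy=4.0,
        irradiated=True,
    )


@dataclass(frozen=True)
class LineageRecord:
    """Birth, division and death bookkeeping of one simulated cell."""

    cell_id: int
    parent_id: Optional[int]
    birth_time_min: float
    death_time_min: Optional[float] = None
    division_times_min: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.death_time_min is not None and not (
            self.birth_time_min < self.death_time_min
        ):
            raise ValueError("birth must precede death")
        times = self.division_times_min
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("division times must be strictly increasing")


class _Agent:
    __slots__ = (
        "cell_id",
        "state",
        "cx",
        "cy",
        "w",
        "h",
        "cycle_h",
        "age_h",
        "nondividing",
        "birth_min",
        "death_min",
        "division_min",
        "parent_id",
    )

    def __init__(self, cell_id, parent_id, cx, cy, w, h, cycle_h, age_h, nondividing, birth_min):
        self.cell_id = cell_id
        self.parent_id = parent_id
        self.state = CellClass.LIV
        self.cx, self.cy, self.w, self.h = cx, cy, w, h
        self.cycle_h = cycle_h
        self.age_h = age_h
        self.nondividing = nondividing
        self.birth_min = birth_min
        self.death_min = None
        self.division_min = None


def _draw_size(rng: np.random.Generator, stats, cls: CellClass) -> tuple[float, float]:
    mw, sw, mh, sh = stats[cls]
    w = max(6.0, rng.normal(mw, sw))
    h = max(6.0, rng.normal(mh, sh))
    return w, h


def _agent_box(a: _Agent, field: tuple[int, int]) -> Box:
    W, H = field
    w = min(a.w, W)
    h = min(a.h, H)
    x0 = min(max(a.cx - w / 2.0, 0.0), W - w)
    y0 = min(max(a.cy - h / 2.0, 0.0), H - h)
    return Box(round(x0, 2), round(y0, 2), round(x0 + w, 2), round(y0 + h, 2))


def simulate_population(config: SimConfig) -> tuple[VideoAnnotation, list[LineageRecord]]:
    """Run the lifecycle simulation and return (video, lineage).

    Every live agent emits exactly one labelled box per frame whose class
    reflects its state.  No transition (cycling, division, death) occurs
    before ``arrest_h``; a division replaces one agent by two ``liv``
    daughters; dead boxes persist, immobile, until the end of the video.
    The lineage list is complete and consistent with the emitted frames.
    Identical configs (including the seed) give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    W, H = config.field_size
    dt_h = config.frame_interval_min / 60.0
    round_h = config.round_duration_min / 60.0
    div_h = config.div_duration_min / 60.0
    lo, hi = config.cycle_time_h

    agents: list[_Agent] = []
    finished: list[_Agent] = []  # divided parents (left the field)
    next_id = 1
    seen_positions: set[tuple[float, float]] = set()
    for _ in range(config.n_initial):
        while True:
            cx = rng.uniform(0, W)
            cy = rng.uniform(0, H)
            key = (round(cx, 2), round(cy, 2))
            if key not in seen_positions:  # cells crowd, but never coincide
                seen_positions.add(key)
                break
        cycle = rng.uniform(lo, hi)
        # Desynchronised start: anywhere in the attached part of the cycle.
        age = rng.uniform(0.0, max(cycle - round_h - div_h, 0.0))
        w, h = _draw_size(rng, config.box_size_stats, CellClass.LIV)
        agents.append(_Agent(next_id, None, cx, cy, w, h, cycle, age, rng.random() < config.frac_nondividing, 0.0))
        next_id += 1

    frames: list[FrameAnnotation] = []
    hazard_p = 1.0 - math.exp(-config.death_hazard_per_h * dt_h)

    for fi in range(1, config.n_frames + 1):
        t_min = fi * config.frame_interval_min
        t_h = t_min / 60.0
        in_arrest = t_h <= config.arrest_h

        new_agents: list[_Agent] = []
        for a in agents:
            if a.state is CellClass.DEAD:
                new_agents.append(a)
                continue
            # Motility: vital cells wander even during arrest.
            if config.motility_px_per_frame > 0:
                a.cx = float(np.clip(a.cx + rng.normal(0, config.motility_px_per_frame), 0, W))
                a.cy = float(np.clip(a.cy + rng.normal(0, config.motility_px_per_frame), 0, H))
            if in_arrest:
                new_agents.append(a)
                continue
            # Death from any vital state.
            if hazard_p > 0 and rng.random() < hazard_p:
                a.state = CellClass.DEAD
                a.death_min = t_min
                a.w, a.h = _draw_size(rng, config.box_size_stats, CellClass.DEAD)
                new_agents.append(a)
                continue
            a.age_h += dt_h
            if a.nondividing:
                new_agents.append(a)
                continue
            old_state = a.state
            if a.age_h >= a.cycle_h:
                # Division completed: replace by two liv daughters.
                a.division_min = t_min
                finished.append(a)
                for _ in range(2):
                    cycle = rng.uniform(lo, hi)
                    w, h = _draw_size(rng, config.box_size_stats, CellClass.LIV)
                    off = rng.normal(0, max(a.w, a.h) / 3.0, size=2)
                    d = _Agent(
                        next_id,
                        a.cell_id,
                        float(np.clip(a.cx + off[0], 0, W)),
                        float(np.clip(a.cy + off[1], 0, H)),
                        w,
                        h,
                        cycle,
                        0.0,
                        rng.random() < config.frac_nondividing,
                        t_min,
                    )
                    next_id += 1
                    new_agents.append(d)
                continue
            if a.age_h >= a.cycle_h - div_h:
                a.state = CellClass.DIV
            elif a.age_h >= a.cycle_h - div_h - round_h:
                a.state = CellClass.ROUND
            else:
                a.state = CellClass.LIV
            if a.state is not old_state:
                a.w, a.h = _draw_size(rng, config.box_size_stats, a.state)
            new_agents.append(a)
        agents = new_agents

        objects = [
            LabelledObject(
                box=_agent_box(a, config.field_size),
                cls=a.state,
                confidence=1.0,
                object_id=str(a.cell_id),
            )
            for a in agents
        ]
        frames.append(
            FrameAnnotation(
                frame_index=fi,
                time_min=t_min,
                objects=objects,
                image_size=config.field_size,
            )
        )

    video = VideoAnnotation(
        frames=frames,
        frame_interval_min=config.frame_interval_min,
        sample_meta=SampleMeta(
            sample_id=config.sample_id,
            dose_gy=config.dose_gy,
            irradiated=config.irradiated,
        ),
    )
    lineage = []
    for a in sorted(agents + finished, key=lambda x: x.cell_id):
        lineage.append(
            LineageRecord(
                cell_id=a.cell_id,
                parent_id=a.parent_id,
                birth_time_min=a.birth_min,
                death_time_min=a.death_min,
                division_times_min=(a.division_min,) if a.division_min is not None else (),
            )
        )
    return video, lineage


# ---------------------------------------------------------------------------
# Detector emulation


def _identity_confusion() -> np.ndarray:
    return np.eye(4)


@dataclass
class NoiseConfig:
    """Failure modes of an emulated detector.

    ``confusion`` is a 4x4 row-stochastic matrix in class order
    (liv, round, div, dead): entry (i, j) is the probability that a detected
    object of true class i is reported as class j.  ``tp_confidence`` /
    ``fp_confidence`` give uniform ranges for the confidence of kept truth
    objects and of spurious boxes.  ``max_detections`` caps the per-frame
    output at the ``max_detections`` highest-confidence boxes.
    """

    miss_prob: float = 0.02
    spurious_rate: float = 0.05
    jitter_sd_px: float = 0.5
    confusion: np.ndarray = field(default_factory=_identity_confusion)
    tp_confidence: tuple[float, float] = (0.7, 1.0)
    fp_confidence: tuple[float, float] = (0.1, 0.5)
    max_detections: int = 100
    nms_iou: float = 0.95
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.miss_prob <= 1.0):
            raise ConfigError("miss_prob must be in [0, 1]")
        if self.spurious_rate < 0 or self.jitter_sd_px < 0:
            raise ConfigError("spurious_rate and jitter_sd_px must be >= 0")
        c = np.asarray(self.confusion, dtype=float)
        if c.shape != (4, 4) or np.any(c < 0) or not np.allclose(c.sum(axis=1), 1.0):
            raise ConfigError("confusion must be a 4x4 row-stochastic matrix")
        if self.max_detections < 1:
            raise ConfigError("max_detections must be >= 1")
        if not (0.0 < self.nms_iou <= 1.0):
            raise ConfigError("nms_iou must be in (0, 1]")
        for rng_ in (self.tp_confidence, self.fp_confidence):
            if not (0.0 <= rng_[0] <= rng_[1] <= 1.0):
                raise ConfigError("confidence ranges must satisfy 0 <= lo <= hi <= 1")


def mild_noise(seed: int = 0) -> NoiseConfig:
    """The well-trained regime: sub-pixel jitter and confidence spread only.

    This profile emulates a detector operating below its capacity limit on
    frames it was trained for; misses, confusion and spurious boxes are
    exercised through the degraded defaults of :class:`NoiseConfig`.
    """
    return NoiseConfig(
        miss_prob=0.0,
        spurious_rate=0.0,
        jitter_sd_px=0.25,
        seed=seed,
    )


def _box_iou(a: Box, b: Box) -> float:
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def nms(objects: list[LabelledObject], iou_threshold: float) -> list[LabelledObject]:
    """Greedy class-agnostic non-maximum suppression.

    Boxes are visited in descending confidence (ties: input order); a box is
    kept only if its IoU with every already-kept box is strictly below
    ``iou_threshold``.
    """
    if not (0.0 < iou_threshold <= 1.0):
        raise ValueError(f"iou_threshold must be in (0, 1], got {iou_threshold}")
    order = sorted(range(len(objects)), key=lambda i: (-objects[i].confidence, i))
    kept: list[LabelledObject] = []
    for i in order:
        if all(_box_iou(objects[i].box, k.box) < iou_threshold for k in kept):
            kept.append(objects[i])
    return kept


def apply_detector_noise(truth: VideoAnnotation, noise: NoiseConfig) -> VideoAnnotation:
    """Produce an imperfect prediction video from a ground-truth video.

    Per frame: each truth object is dropped with ``miss_prob``, otherwise its
    corners are jittered, its class re-sampled from the confusion row and a
    confidence assigned; spurious boxes arrive at rate ``spurious_rate``
    (Poisson); NMS is applied; output is truncated to the
    ``max_detections`` highest-confidence objects.  Object ids are not
    propagated — a detector has no notion of identity.
    """
    noise.validate()
    rng = np.random.default_rng(noise.seed)
    confusion = np.asarray(noise.confusion, dtype=float)
    cum = np.cumsum(confusion, axis=1)
    class_index = {cls: i for i, cls in enumerate(CLASS_ORDER)}
    out_frames = []
    for f in truth.frames:
        W, H = f.image_size
        detections: list[LabelledObject] = []
        for obj in f.objects:
            if noise.miss_prob > 0 and rng.random() < noise.miss_prob:
                continue
            b = obj.box
            if noise.jitter_sd_px > 0:
                j = rng.normal(0.0, noise.jitter_sd_px, size=4)
                x0, y0 = b.x_min + j[0], b.y_min + j[1]
                x1, y1 = b.x_max + j[2], b.y_max + j[3]
                x0, y0 = max(0.0, min(x0, W - 1.0)), max(0.0, min(y0, H - 1.0))
                x1, y1 = min(float(W), max(x1, x0 + 1.0)), min(float(H), max(y1, y0 + 1.0))
                b = Box(x0, y0, x1, y1)
            row = cum[class_index[obj.cls]]
            cls = CLASS_ORDER[int(np.searchsorted(row, rng.random(), side="right"))]
            conf = float(rng.uniform(*noise.tp_confidence))
            detections.append(LabelledObject(box=b, cls=cls, confidence=conf))
        n_spurious = int(rng.poisson(noise.spurious_rate)) if noise.spurious_rate > 0 else 0
        for _ in range(n_spurious):
            w = max(6.0, rng.normal(25.0, 8.0))
            h = max(6.0, rng.normal(25.0, 8.0))
            x0 = rng.uniform(0, max(W - w, 1.0))
            y0 = rng.uniform(0, max(H - h, 1.0))
            detections.append(
                LabelledObject(
                    box=Box(x0, y0, min(x0 + w, W), min(y0 + h, H)),
                    cls=CLASS_ORDER[int(rng.integers(0, 4))],
                    confidence=float(rng.uniform(*noise.fp_confidence)),
                )
            )
        detections = nms(detections, noise.nms_iou)
        detections.sort(key=lambda o: -o.confidence)
        detections = detections[: noise.max_detections]
        out_frames.append(
            FrameAnnotation(
                frame_index=f.frame_index,
                time_min=f.time_min,
                objects=detections,
                image_size=f.image_size,
            )
        )
    return VideoAnnotation(
        frames=out_frames,
        frame_interval_min=truth.frame_interval_min,
        sample_meta=truth.sample_meta,
    )
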