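"""Biological endpoints from annotated time-lapse videos.

This module turns per-frame class counts into the growth and survival
quantities of a live-cell imaging experiment:

* :func:`count_series` — per-class counts over time, normalised by the
  initial population, with Poisson (sqrt-N) counting errors;
* :func:`fit_growth` — weighted least-squares fit of the offset-exponential
  growth model

      n(t) = 1                                 for t <= t0
      n(t) = (1 - A) + A * exp((t - t0) / tau)  for t >  t0

  where ``t0`` is the growth-arrest offset after handling, ``tau`` the
  growth constant and ``A`` the amplitude; the model is continuous with
  n(t0) = 1;
* :func:`cgsf` — the cell-growth-defined survival fraction, the ratio of the
  irradiated to the sham normalised vital-cell number at a time point;
* :func:`division_census` — divisions per founder (maximum generation depth
  reached) from simulation lineage records;
* :func:`dead_cell_census` — unique dead cells in a time window, linking
  dead boxes frame-to-frame so every dead cell is counted exactly once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .annotations import CLASS_ORDER, CellClass, VideoAnnotation
from .detection import iou
from .simulate import LineageRecord

__all__ = [
    "CountSeries",
    "count_series",
    "GrowthFit",
    "growth_model",
    "fit_growth",
    "FitError",
    "cgsf",
    "cgsf_from_series",
    "DivisionCensus",
    "division_census",
    "LineageError",
    "DeathCensus",
    "dead_cell_census",
]


class FitError(RuntimeError):
    """Growth fit failed to converge."""


class LineageError(ValueError):
    """Lineage records are internally inconsistent."""


@dataclass
class CountSeries:
    """Per-frame class counts and normalised values for one sample.

    ``counts`` has one row per frame (index: time in minutes) and columns
    liv, round, div, dead, vital, total.  ``normalized`` divides by the total
    at the first frame; ``sigma_norm`` carries the propagated sqrt-N Poisson
    error on each normalised value.
    """

    counts: pd.DataFrame
    normalized: pd.DataFrame
    sigma_norm: pd.DataFrame
    n0: int
    sample_id: str = "sample"

    @property
    def time_min(self) -> np.ndarray:
        return self.counts.index.to_numpy(dtype=float)

    def channel(self, name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(time_h, normalised values, sigma) of one channel."""
        if name not in self.counts.columns:
            raise KeyError(f"unknown channel {name!r}; have {list(self.counts.columns)}")
        t_h = self.time_min / 60.0
        y = self.normalized[name].to_numpy(dtype=float)
        s = self.sigma_norm[name].to_numpy(dtype=float)
        return t_h, y, s

    def to_csv(self, path) -> None:
        out = self.counts.add_prefix("N_").join(self.normalized.add_prefix("n_")).join(
            self.sigma_norm.add_prefix("sigma_n_")
        )
        out.index.name = "time_min"
        out.to_csv(path)


def count_series(video: VideoAnnotation) -> CountSeries:
    """Count objects per class and frame and normalise by the first frame."""
    if not video.frames:
        raise ValueError("video has no frames")
    rows = []
    for f in video.frames:
        row = {cls.value: f.count(cls) for cls in CLASS_ORDER}
        row["vital"] = row["liv"] + row["round"] + row["div"]
        row["total"] = row["vital"] + row["dead"]
        rows.append(row)
    counts = pd.DataFrame(rows, index=[f.time_min for f in video.frames])
    counts.index.name = "time_min"
    n0 = int(counts["total"].iloc[0])
    if n0 == 0:
        raise ValueError("first frame is empty; cannot normalise")
    normalized = counts / n0
    # sqrt(N) Poisson error; a zero count keeps a one-count floor so that
    # weighted fits never see an infinite weight.
    sigma = np.sqrt(counts.clip(lower=1)) / n0
    return CountSeries(
        counts=counts,
        normalized=normalized,
        sigma_norm=sigma,
        n0=n0,
        sample_id=video.sample_meta.sample_id,
    )


# ---------------------------------------------------------------------------
# Growth model


def growth_model(t, A: float, t0: float, tau: float):
    """Offset exponential, continuous at ``t0`` with n(t0) = 1."""
    t = np.asarray(t, dtype=float)
    out = np.ones_like(t)
    late = t > t0
    out[late] = (1.0 - A) + A * np.exp((t[late] - t0) / tau)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class GrowthFit:
    """Fitted growth parameters with covariance and goodness of fit.

    ``confidence_level`` (default 0.63, i.e. roughly a one-sigma band)
    scales the pointwise confidence band obtained by linear propagation of
    the parameter covariance.
    """

    A: float
    t0: float
    tau: float
    cov: np.ndarray
    chi2: float
    r2_cor: float
    n_points: int
    confidence_level: float = 0.63
    channel: str = "total"
    t_range: tuple[float, float] = (0.0, 48.0)
    flat: bool = False  # degenerate near-constant series

    @property
    def A_sigma(self) -> float:
        return float(np.sqrt(self.cov[0, 0]))

    @property
    def t0_sigma(self) -> float:
        return float(np.sqrt(self.cov[1, 1]))

    @property
    def tau_sigma(self) -> float:
        return float(np.sqrt(self.cov[2, 2]))

    def predict(self, t_h):
        return growth_model(t_h, self.A, self.t0, self.tau)

    def band(self, t_h, level: Optional[float] = None):
        """Half-width of the pointwise confidence band at ``level``."""
        level = self.confidence_level if level is None else level
        z = stats.norm.ppf(0.5 + level / 2.0)
        t = np.atleast_1d(np.asarray(t_h, dtype=float))
        grad = np.zeros((t.size, 3))
        late = t > self.t0
        e = np.exp((t[late] - self.t0) / self.tau)
        grad[late, 0] = e - 1.0  # d/dA
        grad[late, 1] = -self.A * e / self.tau  # d/dt0
        grad[late, 2] = -self.A * e * (t[late] - self.t0) / self.tau**2  # d/dtau
        var = np.einsum("ij,jk,ik->i", grad, self.cov, grad)
        width = z * np.sqrt(np.maximum(var, 0.0))
        return width if np.asarray(t_h).ndim else float(width[0])

    def summary(self) -> str:
        lines = [
            f"offset-exponential growth fit ({self.channel} channel, "
            f"{self.n_points} points)",
            f"  A   = {self.A:.4g} +/- {self.A_sigma:.2g}",
            f"  t0  = {self.t0:.4g} +/- {self.t0_sigma:.2g} h",
            f"  tau = {self.tau:.4g} +/- {self.tau_sigma:.2g} h",
            f"  chi2 = {self.chi2:.4g}, corrected R^2 = {self.r2_cor:.5g}",
            f"  confidence band level: {self.confidence_level:.0%}",
        ]
        if self.flat:
            lines.append("  note: near-constant series; t0/tau poorly constrained")
        return "\n".join(lines)


def fit_growth(
    series: CountSeries,
    channel: str = "total",
    confidence_level: float = 0.63,
    absolute_sigma: bool = False,
) -> GrowthFit:
    """Weighted least-squares fit of the offset-exponential growth model.

    Pre-arrest points are fitted against the constant branch (n = 1), so
    they inform the arrest offset ``t0``.  Weights are the inverse squared
    Poisson errors of the normalised counts.
    """
    t, y, sigma = series.channel(channel)
    if t.size < 6:
        raise FitError(f"need at least 6 time points, got {t.size}")
    t_max = float(t.max())
    if np.ptp(y) < 1e-12:
        # Degenerate constant series: the exponential branch is never
        # expressed, so A pins to 0 and t0/tau are unconstrained.
        chi2 = float(np.sum(((y - 1.0) / sigma) ** 2))
        return GrowthFit(
            A=0.0,
            t0=t_max,
            tau=t_max,  # irrelevant at A = 0; kept finite for the band
            cov=np.diag([float(np.mean(sigma) ** 2), 1e12, 1e12]),
            chi2=chi2,
            r2_cor=np.nan,
            n_points=t.size,
            confidence_level=confidence_level,
            channel=channel,
            t_range=(float(t.min()), t_max),
            flat=True,
        )
    # Initial guesses: arrest near the last time the series is ~1, growth
    # constant from the log-slope of the tail.
    above = np.where(y > 1.05)[0]
    t0_guess = float(t[above[0]]) if above.size else min(5.0, t_max / 4)
    y_end = max(float(y[-1]), 1.05)
    tau_guess = max((t_max - t0_guess) / max(np.log(y_end), 0.05), 1.0)
    p0 = (max(y_end - 1.0, 0.1) / max(np.exp((t_max - t0_guess) / tau_guess) - 1, 0.5), t0_guess, tau_guess)
    try:
        popt, pcov = optimize.curve_fit(
            growth_model,
            t,
            y,
            p0=p0,
            sigma=sigma,
            absolute_sigma=absolute_sigma,
            bounds=([0.0, 0.0, 1e-3], [np.inf, t_max, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"growth fit did not converge: {exc}") from exc
    A, t0, tau = (float(v) for v in popt)
    resid = (y - growth_model(t, *popt)) / sigma
    chi2 = float(np.sum(resid**2))
    ss_res = float(np.sum((y - growth_model(t, *popt)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    n, p = t.size, 3
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
        r2_cor = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    else:
        r2_cor = np.nan
    flat = A < 1e-3 or ss_tot < 1e-12
    return GrowthFit(
        A=A,
        t0=t0,
        tau=tau,
        cov=np.asarray(pcov, dtype=float),
        chi2=chi2,
        r2_cor=r2_cor,
        n_points=n,
        confidence_level=confidence_level,
        channel=channel,
        t_range=(float(t.min()), t_max),
        flat=flat,
    )


def cgsf(fit_irr: GrowthFit, fit_sham: GrowthFit, t_h: float) -> tuple[float, float]:
    """Growth-curve survival fraction at ``t_h`` hours, with its uncertainty.

    CGSF(t) = n_irr(t) / n_sham(t) evaluated on the two fitted curves; the
    uncertainty propagates the two pointwise confidence bands assuming the
    samples are independent (separate wells).  Evaluation beyond twice the
    fitted time range triggers a warning.
    """
    for f in (fit_irr, fit_sham):
        if t_h > 2.0 * f.t_range[1]:
            warnings.warn(
                f"CGSF evaluated at {t_h} h, beyond 2x the fitted range "
                f"(up to {f.t_range[1]} h); extrapolation",
                stacklevel=2,
            )
    n_i = float(fit_irr.predict(t_h))
    n_s = float(fit_sham.predict(t_h))
    value = n_i / n_s
    b_i = float(fit_irr.band(t_h))
    b_s = float(fit_sham.band(t_h))
    sigma = value * float(np.hypot(b_i / n_i, b_s / n_s))
    return value, sigma


def cgsf_from_series(
    series_irr: CountSeries,
    series_sham: CountSeries,
    t_h: float,
    channel: str = "vital",
) -> tuple[float, float]:
    """CGSF from the raw normalised series at the frame nearest ``t_h``.

    Poisson errors of the two counts propagate into the ratio.
    """
    out = []
    for s in (series_irr, series_sham):
        t, y, sig = s.channel(channel)
        k = int(np.argmin(np.abs(t - t_h)))
        out.append((y[k], sig[k]))
    (y_i, s_i), (y_s, s_s) = out
    if y_s == 0:
        raise ValueError("sham channel is zero at the requested time")
    value = y_i / y_s
    sigma = value * float(np.hypot(s_i / max(y_i, 1e-12), s_s / y_s))
    return value, sigma


# ---------------------------------------------------------------------------
# Division census


@dataclass
class DivisionCensus:
    """Divisions per founder and total division events in a window."""

    per_founder: dict[int, int]
    histogram: pd.Series
    total_events: int
    window_h: Optional[float]


def division_census(
    lineage: Sequence[LineageRecord], window_h: Optional[float] = None
) -> DivisionCensus:
    """Maximum generation depth reached per founder within a time window.

    A founder at depth 4 has at least one descendant of the fifth
    generation.  ``total_events`` counts every division event (of founders
    and descendants) inside the window.
    """
    by_id = {r.cell_id: r for r in lineage}
    children: dict[int, list[int]] = {}
    for r in lineage:
        if r.parent_id is not None:
            if r.parent_id not in by_id:
                raise LineageError(
                    f"cell {r.cell_id} references unknown parent {r.parent_id}"
                )
            children.setdefault(r.parent_id, []).append(r.cell_id)
    limit_min = None if window_h is None else window_h * 60.0

    def divided_in_window(r: LineageRecord) -> bool:
        if not r.division_times_min:
            return False
        return limit_min is None or r.division_times_min[0] <= limit_min

    def depth(cid: int) -> int:
        r = by_id[cid]
        if not divided_in_window(r):
            return 0
        kids = children.get(cid, [])
        return 1 + max((depth(k) for k in kids), default=0)

    founders = [r.cell_id for r in lineage if r.parent_id is None]
    per_founder = {cid: depth(cid) for cid in founders}
    total_events = sum(1 for r in lineage if divided_in_window(r))
    hist = pd.Series(per_founder).value_counts().sort_index()
    hist.name = "n_founders"
    hist.index.name = "divisions"
    return DivisionCensus(
        per_founder=per_founder,
        histogram=hist,
        total_events=total_events,
        window_h=window_h,
    )


# ---------------------------------------------------------------------------
# Dead-cell census


@dataclass
class DeathCensus:
    """Unique dead cells (k) among tracked cells (N) in a window.

    The fraction carries the sqrt(k)/N Poisson counting error of rare
    independent death events.
    """

    k: int
    N: int
    window_h: Optional[float] = None

    def __post_init__(self) -> None:
        if self.k < 0 or self.N < 0 or (self.N > 0 and self.k > self.N):
            raise ValueError(f"need 0 <= k <= N, got k={self.k}, N={self.N}")

    @property
    def fraction(self) -> float:
        return self.k / self.N if self.N else 0.0

    @property
    def poisson_sigma(self) -> float:
        return float(np.sqrt(self.k)) / self.N if self.N else 0.0


def dead_cell_census(
    video: VideoAnnotation, window_h: float = 24.0, link_iou: float = 0.3
) -> DeathCensus:
    """Count every dead cell exactly once within the first ``window_h`` hours.

    Dead boxes are linked frame-to-frame: two dead boxes on consecutive
    analysed frames are the same cell when they share an ``object_id`` or
    overlap with IoU >= ``link_iou``.  ``k`` is the number of distinct dead
    tracks seen in the window.  ``N`` is the number of distinct cells in the
    window: the count of distinct object ids when ids are present, otherwise
    the initial population plus the divisions inferred from increments of
    the total count (an approximation documented in the methods note).
    """
    if not (0.0 < link_iou <= 1.0):
        raise ValueError(f"link_iou must be in (0, 1], got {link_iou}")
    window_min = window_h * 60.0
    frames = [f for f in video.frames if f.time_min <= window_min]
    if not frames:
        return DeathCensus(0, 0, window_h)

    k = 0
    prev: list = []  # (box, object_id) of dead objects on the previous frame
    for f in frames:
        dead = [(o.box, o.object_id) for o in f.objects if o.cls is CellClass.DEAD]
        taken = [False] * len(prev)
        for box, oid in dead:
            linked = False
            if oid is not None:
                # an id is authoritative: no IoU fallback that could steal
                # a neighbouring track's box
                for j, (pb, pid) in enumerate(prev):
                    if not taken[j] and pid == oid:
                        taken[j] = linked = True
                        break
            else:
                best_j, best_iou = -1, 0.0
                for j, (pb, pid) in enumerate(prev):
                    if taken[j]:
                        continue
                    v = iou(pb, box)
                    if v >= link_iou and v > best_iou:
                        best_j, best_iou = j, v
                if best_j >= 0:
                    taken[best_j] = linked = True
            if not linked:
                k += 1  # a new dead track starts here
        prev = dead

    ids: set[str] = set()
    all_have_ids = True
    for f in frames:
        for o in f.objects:
            if o.object_id is None:
                all_have_ids = False
                break
            ids.add(o.object_id)
        if not all_have_ids:
            break
    if all_have_ids and ids:
        N = len(ids)
    else:
        totals = np.array([len(f.objects) for f in frames])
        increments = np.diff(totals)
        N = int(totals[0] + increments[increments > 0].sum())
    return DeathCensus(k=k, N=N, window_h=window_h)
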