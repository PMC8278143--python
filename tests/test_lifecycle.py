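"""Lifecycle endpoints: count series, growth fit, CGSF, censuses."""

import numpy as np
import pytest

from cytolapse.annotations import (
    Box,
    CellClass,
    FrameAnnotation,
    LabelledObject,
    VideoAnnotation,
)
from cytolapse.lifecycle import (
    DeathCensus,
    GrowthFit,
    LineageError,
    cgsf,
    cgsf_from_series,
    count_series,
    dead_cell_census,
    division_census,
    fit_growth,
    growth_model,
)
from cytolapse.simulate import LineageRecord, SimConfig, simulate_population


def _obj(x0, y0, cls, oid=None, size=10):
    return LabelledObject(Box(x0, y0, x0 + size, y0 + size), cls, 1.0, oid)


def video_from_counts(counts_per_frame, interval=5.0):
    """Frames holding the requested number of objects per class."""
    frames = []
    for fi, spec in enumerate(counts_per_frame, start=1):
        objects = []
        k = 0
        for cls, n in spec.items():
            for _ in range(n):
                objects.append(_obj(12.0 * k, 0, cls, oid=None))
                k += 1
        frames.append(FrameAnnotation(fi, fi * interval, objects))
    return VideoAnnotation(frames=frames, frame_interval_min=interval)


def series_from_model(A, t0, tau, n0=56, noise=0.0, seed=0, duration_h=48.0):
    """CountSeries-like object generated directly from the growth model."""
    from cytolapse.lifecycle import CountSeries
    import pandas as pd

    rng = np.random.default_rng(seed)
    t_min = np.arange(5.0, duration_h * 60.0 + 1, 5.0)
    n = growth_model(t_min / 60.0, A, t0, tau)
    if noise:
        n = n * (1.0 + rng.normal(0.0, noise, size=n.size))
    N = np.maximum(np.rint(n * n0), 1)
    counts = pd.DataFrame(
        {"liv": N.astype(int), "round": 0, "div": 0, "dead": 0,
         "vital": N.astype(int), "total": N.astype(int)},
        index=t_min,
    )
    counts.index.name = "time_min"
    return CountSeries(
        counts=counts,
        normalized=counts / n0,
        sigma_norm=np.sqrt(counts.clip(lower=1)) / n0,
        n0=n0,
    )


class TestCountSeries:
    def test_initial_frame_composition(self):
        video = video_from_counts(
            [{CellClass.LIV: 36, CellClass.ROUND: 19, CellClass.DEAD: 1}]
        )
        s = count_series(video)
        row = s.counts.iloc[0]
        assert (row["liv"], row["round"], row["div"], row["dead"]) == (36, 19, 0, 1)
        assert row["total"] == 56
        assert s.normalized["liv"].iloc[0] == pytest.approx(36 / 56)
        assert s.normalized["total"].iloc[0] == 1.0

    def test_constant_video_constant_normals(self):
        spec = {CellClass.LIV: 10, CellClass.DEAD: 2}
        s = count_series(video_from_counts([spec] * 4))
        assert (s.normalized.nunique() == 1).all()

    def test_vital_aggregate(self):
        video = video_from_counts(
            [{CellClass.LIV: 3, CellClass.ROUND: 2, CellClass.DIV: 1, CellClass.DEAD: 4}]
        )
        s = count_series(video)
        assert s.counts["vital"].iloc[0] == 6

    def test_empty_first_frame_rejected(self):
        video = video_from_counts([{}, {CellClass.LIV: 3}])
        with pytest.raises(ValueError, match="empty"):
            count_series(video)

    def test_totals_match_simulator_lineage(self):
        cfg = SimConfig(n_initial=25, field_size=(600, 500), duration_h=20.0,
                        arrest_h=2.0, seed=13)
        video, lineage = simulate_population(cfg)
        s = count_series(video)
        n_div = sum(1 for r in lineage if r.division_times_min)
        assert s.counts["total"].iloc[-1] == cfg.n_initial + n_div


class TestGrowthFit:
    def test_model_continuous_at_t0(self):
        assert growth_model(5.8, 0.37, 5.8, 17.0) == pytest.approx(1.0)
        assert growth_model(5.8 - 1e-9, 0.37, 5.8, 17.0) == 1.0

    def test_parameter_recovery_at_low_noise(self):
        s = series_from_model(A=0.37, t0=5.8, tau=17.0, noise=0.02, seed=1)
        fit = fit_growth(s, channel="total")
        for value, target, sigma in [
            (fit.A, 0.37, fit.A_sigma),
            (fit.t0, 5.8, fit.t0_sigma),
            (fit.tau, 17.0, fit.tau_sigma),
        ]:
            assert abs(value - target) < 3 * sigma + 1e-9

    def test_flat_series_fits_zero_amplitude(self):
        s = series_from_model(A=0.0, t0=5.0, tau=15.0, noise=0.0)
        fit = fit_growth(s, channel="total")
        assert fit.A == pytest.approx(0.0, abs=1e-6)
        assert fit.flat
        assert fit.predict(30.0) == pytest.approx(1.0, abs=1e-5)

    def test_too_few_points_rejected(self):
        s = series_from_model(A=0.37, t0=5.8, tau=17.0, duration_h=0.4)
        from cytolapse.lifecycle import FitError

        with pytest.raises(FitError, match="6 time points"):
            fit_growth(s)

    def test_band_shrinks_with_level(self):
        s = series_from_model(A=0.37, t0=5.8, tau=17.0, noise=0.02, seed=2)
        fit = fit_growth(s)
        assert fit.band(30.0, level=0.2) < fit.band(30.0, level=0.9)


class TestCGSF:
    def _fit(self, A, t0, tau, sigma=1e-3):
        cov = np.diag([sigma**2] * 3)
        return GrowthFit(A=A, t0=t0, tau=tau, cov=cov, chi2=0.0, r2_cor=1.0,
                         n_points=100, t_range=(0.0, 48.0))

    def test_identical_fits_give_unity(self):
        f = self._fit(0.37, 5.8, 17.0)
        for t in (10.0, 24.0, 48.0):
            value, sigma = cgsf(f, f, t)
            assert value == pytest.approx(1.0)
            assert sigma < 0.01

    def test_reference_parameter_evaluation(self):
        # Irradiated (A=0.37, t0=5.8 h, tau=17 h) over sham (A=0.37,
        # t0=5.7 h, tau=15.3 h) at 24 h: ratio ~ 0.92.
        f_irr = self._fit(0.37, 5.8, 17.0)
        f_sham = self._fit(0.37, 5.7, 15.3)
        value, _ = cgsf(f_irr, f_sham, 24.0)
        assert value == pytest.approx(0.922, abs=0.005)

    def test_faster_sham_monotone_decreasing(self):
        f_irr = self._fit(0.37, 5.8, 17.0)
        f_sham = self._fit(0.37, 5.8, 14.0)
        ts = np.linspace(6.0, 48.0, 200)
        values = [cgsf(f_irr, f_sham, float(t))[0] for t in ts]
        assert all(b < a for a, b in zip(values, values[1:]))

    def test_extrapolation_warns(self):
        f = self._fit(0.37, 5.8, 17.0)
        with pytest.warns(UserWarning, match="extrapolation"):
            cgsf(f, f, 120.0)

    def test_raw_series_ratio(self):
        s_irr = series_from_model(A=0.37, t0=5.8, tau=17.0, n0=100)
        s_sham = series_from_model(A=0.37, t0=5.7, tau=15.3, n0=100)
        value, sigma = cgsf_from_series(s_irr, s_sham, 24.0, channel="total")
        assert value == pytest.approx(0.92, abs=0.02)
        assert sigma > 0


class TestDivisionCensus:
    def _rec(self, cid, parent=None, birth=0.0, divisions=()):
        return LineageRecord(cid, parent, birth, None, tuple(divisions))

    def test_chain_depth_four(self):
        records = [self._rec(1, None, 0.0, (720.0,))]
        cid = 2
        parent, birth = 1, 720.0
        for depth in range(3):
            records.append(self._rec(cid, parent, birth, (birth + 720.0,)))
            records.append(self._rec(cid + 1, parent, birth))
            parent, birth = cid, birth + 720.0
            cid += 2
        records.append(self._rec(cid, parent, birth))
        records.append(self._rec(cid + 1, parent, birth))
        census = division_census(records)
        assert census.per_founder[1] == 4

    def test_no_divisions(self):
        census = division_census([self._rec(1), self._rec(2)])
        assert census.per_founder == {1: 0, 2: 0}
        assert census.total_events == 0

    def test_three_founder_hand_enumeration(self):
        records = [
            # founder 1: divides at 10 h, one daughter divides at 25 h
            self._rec(1, None, 0.0, (600.0,)),
            self._rec(10, 1, 600.0, (1500.0,)),
            self._rec(11, 1, 600.0),
            self._rec(12, 10, 1500.0),
            self._rec(13, 10, 1500.0),
            # founder 2: never divides
            self._rec(2),
            # founder 3: divides at 30 h
            self._rec(3, None, 0.0, (1800.0,)),
            self._rec(14, 3, 1800.0),
            self._rec(15, 3, 1800.0),
        ]
        census = division_census(records)
        assert census.per_founder == {1: 2, 2: 0, 3: 1}
        assert census.total_events == 3
        assert census.histogram.to_dict() == {0: 1, 1: 1, 2: 1}
        # restricting the window to 24 h drops the late events
        census24 = division_census(records, window_h=24.0)
        assert census24.per_founder == {1: 1, 2: 0, 3: 0}
        assert census24.total_events == 1

    def test_orphan_parent_rejected(self):
        with pytest.raises(LineageError, match="unknown parent"):
            division_census([self._rec(2, parent=99, birth=5.0)])


class TestDeadCellCensus:
    def test_poisson_fraction_arithmetic(self):
        census = DeathCensus(k=5, N=108)
        assert 100 * census.fraction == pytest.approx(4.6, abs=0.05)
        assert 100 * census.poisson_sigma == pytest.approx(2.1, abs=0.05)

    def test_no_dead_boxes(self):
        video = video_from_counts([{CellClass.LIV: 5}] * 3)
        census = dead_cell_census(video)
        assert census.k == 0 and census.fraction == 0.0 and census.poisson_sigma == 0.0

    def test_persistent_dead_cell_counted_once(self):
        frames = [
            FrameAnnotation(fi, fi * 5.0, [_obj(50, 50, CellClass.DEAD)])
            for fi in range(1, 101)
        ]
        video = VideoAnnotation(frames=frames)
        assert dead_cell_census(video).k == 1

    def test_simulator_census_uses_ids(self):
        cfg = SimConfig(n_initial=30, field_size=(700, 600), duration_h=24.0,
                        arrest_h=2.0, death_hazard_per_h=0.01, seed=6)
        video, lineage = simulate_population(cfg)
        census = dead_cell_census(video, window_h=24.0)
        n_deaths = sum(
            1 for r in lineage
            if r.death_time_min is not None and r.death_time_min <= 24 * 60
        )
        assert census.k == n_deaths
        assert census.N == len(lineage)

    def test_idempotent_and_subsample_invariant(self):
        cfg = SimConfig(n_initial=30, field_size=(700, 600), duration_h=12.0,
                        arrest_h=1.0, death_hazard_per_h=0.02, seed=9)
        video, _ = simulate_population(cfg)
        # strip ids to exercise IoU linking
        frames = [
            FrameAnnotation(
                f.frame_index, f.time_min,
                [LabelledObject(o.box, o.cls, o.confidence, None) for o in f.objects],
                f.image_size,
            )
            for f in video.frames
        ]
        anon = VideoAnnotation(frames=frames, frame_interval_min=5.0)
        c1 = dead_cell_census(anon, window_h=12.0)
        c2 = dead_cell_census(anon, window_h=12.0)
        assert (c1.k, c1.N) == (c2.k, c2.N)
        sub = VideoAnnotation(
            frames=[f for f in frames if f.frame_index % 2 == 0],
            frame_interval_min=5.0,
        )
        assert dead_cell_census(sub, window_h=12.0).k == c1.k

    def test_link_iou_range(self):
        video = video_from_counts([{CellClass.LIV: 1}])
        with pytest.raises(ValueError):
            dead_cell_census(video, link_iou=0.0)
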