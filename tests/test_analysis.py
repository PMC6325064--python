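"""MSD series, D_rel curves, diffusion fits and anomaly classification."""

import numpy as np
import pandas as pd
import pytest

from memtopo import analysis
from memtopo.analysis import (
    DrelCurve,
    MSDSeries,
    classify_anomaly,
    drel,
    fit_diffusion,
    flat_baseline_msd,
    msd_time_course,
    occupied_node_count,
    population_msd,
    probability_by_distance,
)
from memtopo.distances import compute_distance_maps
from memtopo.errors import ContractError
from memtopo.surfaces import build_flat, build_ridges, insert_defect
from memtopo.walk import propagate


@pytest.fixture(scope="module")
def flat_run():
    surface = build_flat(81, 81)
    start = (40, 40, 0)
    maps = compute_distance_maps(surface, start)
    fields = propagate(surface, start, 40, record_every=1)
    return surface, start, maps, fields


class TestPopulationMSD:
    def test_first_iteration_msd_is_half_for_all_metrics(self, flat_run):
        _, _, maps, fields = flat_run
        series = population_msd(fields, maps)
        assert series.msd_2d[1] == pytest.approx(0.5)
        assert series.msd_3d[1] == pytest.approx(0.5)
        assert series.msd_swsd[1] == pytest.approx(0.5)
        assert series.msd_2d[0] == 0.0

    def test_flat_euclidean_msd_is_half_t(self, flat_run):
        _, _, maps, fields = flat_run
        series = population_msd(fields, maps)
        assert np.allclose(series.msd_2d, 0.5 * series.iterations, atol=1e-9)

    def test_metric_ordering_holds(self, flat_run):
        _, _, maps, fields = flat_run
        series = population_msd(fields, maps)
        assert (series.msd_swsd >= series.msd_3d - 1e-12).all()
        assert (series.msd_3d >= series.msd_2d - 1e-12).all()

    def test_snapshot_and_time_course_paths_agree(self, flat_run):
        surface, start, maps, fields = flat_run
        series_a = population_msd(fields, maps)
        series_b = msd_time_course(surface, start, 40, maps=maps)
        assert np.allclose(series_a.msd_swsd, series_b.msd_swsd, atol=1e-12)

    def test_mismatched_start_rejected(self, flat_run):
        surface, _, _, fields = flat_run
        other = compute_distance_maps(surface, (0, 0, 0))
        with pytest.raises(ContractError):
            population_msd(fields, other)


class TestDrel:
    def test_identity_when_test_equals_baseline(self, flat_run):
        surface, start, maps, _ = flat_run
        series = msd_time_course(surface, start, 40, maps=maps)
        curve = drel(series, series)
        assert np.allclose(curve.drel_2d, 1.0)
        assert np.allclose(curve.drel_swsd, 1.0)
        assert curve.iterations[0] == 1  # t = 0 excluded

    def test_grid_mismatch_rejected(self, flat_run):
        surface, start, maps, _ = flat_run
        a = msd_time_course(surface, start, 40, maps=maps)
        b = msd_time_course(surface, start, 39, maps=maps)
        with pytest.raises(ContractError):
            drel(a, b)

    def test_baseline_halfwidth_default_is_boundary_safe(self):
        series = flat_baseline_msd(64)
        assert series.provenance["halfwidth"] >= 4 * 8
        assert np.allclose(series.msd_2d, 0.5 * series.iterations, atol=1e-9)


class TestDiffusionFit:
    def test_exact_line_recovers_slope(self):
        t = np.arange(0, 101)
        series = MSDSeries(t, 0.5 * t, 0.5 * t, 0.8 * t)
        for window in [None, (10, 60), (0, 100)]:
            fit = fit_diffusion(series, "2d", window)
            assert fit.slope == pytest.approx(0.5, abs=1e-12)
            assert fit.r_squared == pytest.approx(1.0)

    def test_simulated_flat_slope_is_half(self):
        series = flat_baseline_msd(400)
        fit = fit_diffusion(series, "2d", window=(100, 400))
        assert fit.slope == pytest.approx(0.5, abs=1e-6)

    def test_saturating_series_has_smaller_late_slope(self):
        t = np.arange(0, 201)
        y = 100 * (1 - np.exp(-t / 50.0))
        series = MSDSeries(t, y, y, y)
        early = fit_diffusion(series, "2d", (0, 50)).slope
        late = fit_diffusion(series, "2d", (150, 200)).slope
        assert early > late

    def test_degenerate_window_rejected(self):
        t = np.arange(0, 20)
        series = MSDSeries(t, 0.5 * t, 0.5 * t, 0.8 * t)
        with pytest.raises(ContractError):
            fit_diffusion(series, "2d", (15, 15))


class TestAnomalyClassification:
    def _curve(self, values):
        t = np.arange(1, len(values) + 1)
        v = np.asarray(values, dtype=float)
        return DrelCurve(t, v, v, v)

    def test_flat_curve_is_all_normal(self):
        summary = classify_anomaly(self._curve(np.ones(50)), "swsd")
        assert (summary.labels == "normal").all()
        assert summary.return_iteration is None

    def test_peak_and_crossing_landmarks(self):
        v = np.concatenate([np.linspace(1.0, 1.1, 20), np.linspace(1.1, 0.9, 41)[1:]])
        summary = classify_anomaly(self._curve(v), "swsd", tolerance=0.02)
        assert summary.argmax_iteration == 20
        assert v[summary.return_iteration - 1] <= 1.0
        assert v[summary.return_iteration - 2] > 1.0
        assert summary.labels[0] == "normal"
        assert summary.labels[10] == "super"
        assert summary.labels[-1] == "sub"

    def test_ties_break_to_earliest_iteration(self):
        v = np.array([1.0, 1.2, 1.2, 0.8, 0.8])
        summary = classify_anomaly(self._curve(v), "swsd")
        assert summary.argmax_iteration == 2
        assert summary.argmin_iteration == 4


class TestOccupiedNodes:
    def test_flat_counts_start_at_one_then_five(self, flat_run):
        surface, start, _, fields = flat_run
        df = occupied_node_count(fields)
        assert df.occupied.iloc[0] == 1
        assert df.occupied.iloc[1] == 5
        assert (np.diff(df.occupied) >= 0).all()

    def test_slot_opens_more_nodes_than_intact_ridges(self):
        intact = build_ridges((63, 41), 7, 3, 9)
        phase = intact.metadata["phase"]
        slotted = insert_defect(intact, "slot", (phase + 24, 20))
        start = (phase + 24 - 5, 20, 0)
        t = 60
        occ_i = occupied_node_count(propagate(intact, start, t, record_every=5))
        occ_s = occupied_node_count(propagate(slotted, start, t, record_every=5))
        assert (occ_s.occupied >= occ_i.occupied).all()
        assert occ_s.occupied.iloc[-1] > occ_i.occupied.iloc[-1]


class TestProbabilityByDistance:
    def test_all_mass_in_shell_zero_at_t0(self, flat_run):
        _, _, maps, fields = flat_run
        shells = probability_by_distance(fields[0], maps, "swsd")
        assert shells.iloc[0] == pytest.approx(1.0)
        assert shells.sum() == pytest.approx(1.0)

    def test_flat_t1_swsd_shells(self, flat_run):
        _, _, maps, fields = flat_run
        shells = probability_by_distance(fields[1], maps, "swsd")
        assert shells.iloc[0] == pytest.approx(0.5)
        assert shells.iloc[1] == pytest.approx(0.5)

    def test_shells_partition_mass_for_euclidean_metric(self, flat_run):
        _, _, maps, fields = flat_run
        shells = probability_by_distance(fields[-1], maps, "2d")
        assert shells.sum() == pytest.approx(1.0, abs=1e-9)


class TestFlatAsymptotics:
    def test_swsd_to_euclidean_ratio_approaches_one_plus_two_over_pi(self):
        series = flat_baseline_msd(500)
        ratio = series.msd_swsd[-1] / series.msd_2d[-1]
        assert ratio == pytest.approx(1 + 2 / np.pi, rel=0.01)
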