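"""Tests for the two-state walker simulator and crossing detection."""

import numpy as np
import pandas as pd
import pytest

from tortmove import (
    AbundanceModel,
    PlotRegion,
    ResistanceRaster,
    ScenarioConfig,
    WalkerParams,
    build_scenario,
    detect_crossings,
    draw_abundance,
    expected_crossings,
    init_walkers,
    plot_regions,
    run_scenarios,
    simulate_replicate,
)
from tortmove.landscape import culvert_id_grid

SMALL = dict(height_m=600.0, highway_length_km=2.0, band_depth_m=9.0, validate_design=False)


def open_raster(side_m=600.0, resistance=0.0):
    n = int(side_m / 0.6)
    return ResistanceRaster(np.full((n, n), resistance, dtype=np.float32),
                            cell=0.6, x_origin=0.0, y_top=side_m)


def no_culverts(raster):
    return np.full(raster.values.shape, -1, dtype=np.int32)


class TestAbundance:
    def test_moments(self):
        rng = np.random.default_rng(0)
        model = AbundanceModel()
        draws = np.array([draw_abundance(model, rng) for _ in range(100_000)])
        assert draws.mean() == pytest.approx(70.0, rel=0.01)
        # NB variance = mean + mean^2/size = 70 + 70^2/13.08
        assert draws.var() == pytest.approx(70 + 70**2 / 13.08, rel=0.05)
        assert (draws >= 0).all()

    def test_poisson_limit(self):
        rng = np.random.default_rng(1)
        draws = np.array([draw_abundance(AbundanceModel(70, 1e6), rng) for _ in range(100_000)])
        assert draws.var() == pytest.approx(draws.mean(), rel=0.05)

    def test_invalid_model(self):
        with pytest.raises(ValueError):
            AbundanceModel(mean=-1)


class TestInitWalkers:
    def test_containment_and_stationary_state(self):
        raster, culverts = build_scenario(ScenarioConfig(2, 0.61, **SMALL))
        plots = plot_regions(culverts, raster, radius_m=200.0)
        xs, ys, hd, st = init_walkers(50_000, plots, raster, 42)
        y_lo, y_hi = raster.band_y
        assert ((ys <= y_lo) | (ys >= y_hi)).all()  # never on the highway band
        assert all(any(p.contains(x, y) for p in plots) for x, y in zip(xs[:500], ys[:500]))
        # stationary traveling fraction 0.098/(0.098+0.228) ~ 0.3006
        assert st.mean() == pytest.approx(0.098 / (0.098 + 0.228), abs=0.01)

    def test_determinism(self):
        raster, culverts = build_scenario(ScenarioConfig(2, 0.61, **SMALL))
        plots = plot_regions(culverts, raster, radius_m=200.0)
        a = init_walkers(100, plots, raster, 7)
        b = init_walkers(100, plots, raster, 7)
        for u, v in zip(a, b):
            assert np.array_equal(u, v)

    def test_empty_plots_rejected(self):
        with pytest.raises(ValueError):
            init_walkers(5, [], open_raster(60.0), 0)


class TestStepping:
    def test_resting_displacement_one_cell_open_terrain(self):
        """On zero-resistance terrain a resting step moves exactly one cell."""
        raster = open_raster(120.0)
        n = 200
        rng = np.random.default_rng(3)
        params = WalkerParams(p_rest_to_travel=1e-9, p_travel_to_rest=1 - 1e-9)
        rep = simulate_replicate(
            raster, no_culverts(raster),
            rng.uniform(40, 80, n), rng.uniform(40, 80, n),
            rng.uniform(-np.pi, np.pi, n), np.zeros(n, dtype=np.int8),
            params, n_steps=5, seed=1, record_trajectories=True,
        )
        tr = rep.trajectories
        for w, grp in tr.groupby("walker_id"):
            d = np.hypot(np.diff(grp["x"]), np.diff(grp["y"]))
            assert np.allclose(d, 0.6, atol=1e-9)

    def test_traveling_turn_correlation(self):
        """Empirical mean cos(heading change) matches the stated 0.707."""
        raster = open_raster(1500.0)
        n = 300
        rng = np.random.default_rng(4)
        params = WalkerParams(p_rest_to_travel=1 - 1e-9, p_travel_to_rest=1e-9,
                              travel_step_mean_m=5.0)
        rep = simulate_replicate(
            raster, no_culverts(raster),
            rng.uniform(600, 900, n), rng.uniform(600, 900, n),
            rng.uniform(-np.pi, np.pi, n), np.ones(n, dtype=np.int8),
            params, n_steps=400, seed=2, record_trajectories=True,
        )
        tr = rep.trajectories
        cosines = []
        for w, grp in tr.groupby("walker_id"):
            dx, dy = np.diff(grp["x"]), np.diff(grp["y"])
            head = np.arctan2(dy, dx)
            cosines.append(np.cos(np.diff(head)))
        cosines = np.concatenate(cosines)
        assert len(cosines) > 100_000
        assert cosines.mean() == pytest.approx(0.707, abs=0.02)

    def test_wall_truncation(self):
        """A resistance-1 wall ahead is never entered; a boxed-in walker stays."""
        raster = open_raster(120.0, resistance=0.0)
        raster.values[:, 100:] = 1.0  # wall east of x = 60 m
        params = WalkerParams(fixed_travel_step=True)
        rep = simulate_replicate(
            raster, no_culverts(raster),
            [55.0] * 50, list(np.linspace(20, 100, 50)),
            [0.0] * 50, np.ones(50, dtype=np.int8),
            params, n_steps=40, seed=3, record_trajectories=True,
        )
        assert (rep.trajectories["x"] < 60.0).all()

        # fully enclosed walker never leaves its single passable cell
        boxed = open_raster(12.0, resistance=1.0)
        boxed.values[10, 10] = 0.0
        rep = simulate_replicate(
            boxed, no_culverts(boxed), [6.3], [5.7], [0.0],
            np.ones(1, dtype=np.int8), WalkerParams(), n_steps=10,
            seed=4, record_trajectories=True,
        )
        cells = {boxed.world_to_cell(x, y) for x, y in
                 zip(rep.trajectories["x"], rep.trajectories["y"])}
        assert cells == {(10, 10)}

    def test_stationary_travel_occupancy(self):
        """Long-run traveling fraction approaches 0.098/(0.098+0.228)."""
        raster = open_raster(2000.0, resistance=0.2)
        n = 50
        rng = np.random.default_rng(5)
        rep = simulate_replicate(
            raster, no_culverts(raster),
            rng.uniform(900, 1100, n), rng.uniform(900, 1100, n),
            rng.uniform(-np.pi, np.pi, n),
            (rng.random(n) < 0.3006).astype(np.int8),
            WalkerParams(), n_steps=4000, seed=6,
        )
        assert rep.travel_fraction == pytest.approx(0.098 / (0.098 + 0.228), abs=0.01)


class TestCrossings:
    def test_all_north_no_events(self):
        raster, culverts = build_scenario(ScenarioConfig(2, 1.83, **SMALL))
        traj = pd.DataFrame({"walker_id": 0, "step": range(5),
                             "x": np.linspace(100, 200, 5),
                             "y": np.full(5, 500.0)})
        assert len(detect_crossings(traj, raster, culverts)) == 0

    def test_threaded_path_two_events_same_culvert(self):
        """Through a culvert and back: two events, same culvert, opposite
        directions (the observed field behaviour)."""
        raster, culverts = build_scenario(ScenarioConfig(2, 1.83, **SMALL))
        cx = culverts[0].center_x
        y_n, y_s = raster.band_y[1] + 5, raster.band_y[0] - 5
        traj = pd.DataFrame({"walker_id": 0, "step": range(4),
                             "x": [cx, cx, cx, cx],
                             "y": [y_n, y_s, y_s, y_n]})
        ev = detect_crossings(traj, raster, culverts)
        assert len(ev) == 2
        assert ev["culvert_id"].nunique() == 1
        assert set(ev["direction"]) == {1, -1}

    def test_crossing_outside_culvert_is_leak(self):
        raster, culverts = build_scenario(ScenarioConfig(2, 1.83, **SMALL))
        traj = pd.DataFrame({"walker_id": 0, "step": [0, 1],
                             "x": [40.0, 40.0],
                             "y": [raster.band_y[1] + 5, raster.band_y[0] - 5]})
        with pytest.raises(RuntimeError, match="leak"):
            detect_crossings(traj, raster, culverts)

    def test_engine_agrees_with_detector(self):
        """Crossings counted inside the kernel match the trajectory-based
        detector on a recorded run."""
        raster, culverts = build_scenario(ScenarioConfig(4, 1.83, **SMALL))
        culv = culvert_id_grid(raster, culverts)
        plots = plot_regions(culverts, raster, radius_m=100.0)
        xs, ys, hd, st = init_walkers(60, plots, raster, 11)
        rep = simulate_replicate(raster, culv, xs, ys, hd, st, WalkerParams(),
                                 n_steps=2000, seed=12, record_trajectories=True)
        ev = detect_crossings(rep.trajectories, raster, culverts)
        assert len(ev) == rep.n_events
        if len(ev):
            assert set(ev["culvert_id"]) == set(rep.events["culvert_id"])


class TestRunScenarios:
    def test_summary_structure_and_determinism(self):
        scen = [ScenarioConfig(2, 0.61, **SMALL), ScenarioConfig(2, 1.83, **SMALL)]
        kw = dict(abundance=AbundanceModel(8, 13.08), n_replicates=3,
                  seed=9, n_days=2, plot_radius_m=100.0)
        a = run_scenarios(scen, WalkerParams(), **kw)
        b = run_scenarios(scen, WalkerParams(), **kw)
        assert list(a.columns) == ["scenario", "n_culverts", "width_m", "placement",
                                   "mean_rate_pct", "min_rate_pct", "max_rate_pct", "n_reps"]
        assert len(a) == 2
        assert (a["n_reps"] == 3).all()
        assert (a["min_rate_pct"] <= a["mean_rate_pct"]).all()
        assert (a["mean_rate_pct"] <= a["max_rate_pct"]).all()
        pd.testing.assert_frame_equal(a, b)  # bit-identical given the seed


class TestExpectedCrossings:
    def test_worked_example(self):
        raw, rounded = expected_crossings(2_451_644, 0.005)
        assert raw == pytest.approx(122.58, abs=0.01)
        assert rounded == 123

    def test_zero_rate(self):
        assert expected_crossings(10_000, 0.0) == (0.0, 0)

    def test_definition(self):
        raw, _ = expected_crossings(100, 1.0)
        assert raw == pytest.approx(1.0)
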