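"""Moving-window estimator: placement, class means, filters, summaries."""

import numpy as np
import pytest

from forestcloud.grid import GridField
from forestcloud.surface import SurfaceClass, buffer_water_mask
from forestcloud.windows import (
    LossSample, Rejection, WindowSample, WindowSpec, actual_effect,
    aggregate_to_display, diurnal_max_hour, elevation_filter,
    latitudinal_profile, place_windows, potential_effects,
    seasonal_max_month, sign_fractions, window_effect,
)


def field(values, variable="field", mask=None, resolution=0.05):
    values = np.asarray(values, dtype=float)
    n_lat, n_lon = values.shape
    return GridField(values=values,
                     lat=resolution * (np.arange(n_lat) + 0.5),
                     lon=resolution * (np.arange(n_lon) + 0.5),
                     resolution=resolution, mask=mask, variable=variable)


class FakeClassMap:
    """Hand-built class map for deterministic window tests."""

    def __init__(self, labels, change=None, change_threshold=0.05):
        self.labels = field(labels, "surface_class")
        self._change = (np.asarray(change, dtype=float) if change is not None
                        else np.ones(self.labels.shape))
        from forestcloud.surface import ClassifierConfig
        self.config = ClassifierConfig(change_threshold=change_threshold)

    def where(self, cls):
        return self.labels.values == int(cls)

    def change_magnitude(self):
        return self._change


def checkerboard_labels(n):
    """Half forest, half non-forest, alternating rows."""
    labels = np.full((n, n), int(SurfaceClass.UNCHANGED_NONFOREST))
    labels[::2] = int(SurfaceClass.UNCHANGED_FOREST)
    return labels


class TestPlaceWindows:
    def test_exactly_one_window_on_matching_grid(self):
        cmap = FakeClassMap(checkerboard_labels(9))
        wins = place_windows(cmap, WindowSpec(size=9, step=5))
        assert len(wins) == 1
        assert (wins[0].row0, wins[0].col0) == (0, 0)

    def test_adjacent_centers_step_apart(self):
        cmap = FakeClassMap(checkerboard_labels(20))
        wins = place_windows(cmap, WindowSpec(size=9, step=5))
        rows = sorted({w.row0 + 4 for w in wins})
        assert np.all(np.diff(rows) == 5)

    def test_grid_smaller_than_window_empty(self):
        cmap = FakeClassMap(checkerboard_labels(5))
        assert place_windows(cmap, WindowSpec(size=9, step=5)) == []

    def test_trigger_matches_brute_force_scan(self):
        rng = np.random.default_rng(21)
        change = np.zeros((20, 20))
        change[7, 13] = 1.0  # single changed pixel
        cmap = FakeClassMap(checkerboard_labels(20), change=change)
        spec = WindowSpec(size=9, step=5)
        wins = place_windows(cmap, spec)
        # brute-force oracle over the full center lattice
        expected = []
        for r in range(4, 16, 5):
            for c in range(4, 16, 5):
                block = change[r - 4:r + 5, c - 4:c + 5]
                if (block > 0.05).any():
                    expected.append((r - 4, c - 4))
        assert [(w.row0, w.col0) for w in wins] == expected
        assert len(wins) > 0


class TestWindowEffect:
    def _window(self, size=9):
        from forestcloud.windows import Window
        return Window(0, 0, size, 0.0, 0.0)

    def test_constant_classes(self):
        labels = checkerboard_labels(9)
        cloud = np.where(labels == int(SurfaceClass.UNCHANGED_FOREST), 0.6, 0.5)
        cmap = FakeClassMap(labels)
        s = window_effect(self._window(), cmap, field(cloud), spec=WindowSpec())
        assert s.delta == pytest.approx(0.1, abs=1e-12)

    def test_identical_values_zero_delta(self):
        cmap = FakeClassMap(checkerboard_labels(9))
        s = window_effect(self._window(), cmap, field(np.full((9, 9), 0.42)))
        assert s.delta == pytest.approx(0.0, abs=1e-15)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(22)
        labels = rng.choice([1, 2, 3, 4], size=(9, 9))
        cloud = rng.random((9, 9))
        water = rng.random((9, 9)) < 0.1
        cmap = FakeClassMap(labels)
        buf = buffer_water_mask(field(water.astype(float), "water_mask"))
        s = window_effect(self._window(), cmap, field(cloud), buf,
                          WindowSpec(min_count_forest=1, min_count_nonforest=1))
        exc = buf.values.astype(bool)
        forest_vals = [cloud[i, j] for i in range(9) for j in range(9)
                       if labels[i, j] == 1 and not exc[i, j]]
        nonforest_vals = [cloud[i, j] for i in range(9) for j in range(9)
                          if labels[i, j] == 2 and not exc[i, j]]
        assert s.mean_forest == pytest.approx(np.mean(forest_vals), abs=1e-12)
        assert s.delta == pytest.approx(
            np.mean(forest_vals) - np.mean(nonforest_vals), abs=1e-12)

    def test_min_count_rejection(self):
        labels = np.full((9, 9), int(SurfaceClass.UNCHANGED_FOREST))
        labels[0, 0] = int(SurfaceClass.UNCHANGED_NONFOREST)
        cmap = FakeClassMap(labels)
        res = window_effect(self._window(), cmap, field(np.ones((9, 9)) * 0.5),
                            spec=WindowSpec(min_count_nonforest=3))
        assert isinstance(res, Rejection)
        assert res.reason == "min_count_nonforest"

    def test_antisymmetry_under_label_swap(self):
        rng = np.random.default_rng(23)
        labels = checkerboard_labels(9)
        cloud = rng.random((9, 9))
        swapped = np.where(labels == 1, 2, np.where(labels == 2, 1, labels))
        a = window_effect(self._window(), FakeClassMap(labels), field(cloud))
        b = window_effect(self._window(), FakeClassMap(swapped), field(cloud))
        assert a.delta == pytest.approx(-b.delta, abs=1e-15)

    def test_actual_effect_loss_vs_forest(self):
        labels = np.full((9, 9), int(SurfaceClass.UNCHANGED_FOREST))
        labels[:3, :3] = int(SurfaceClass.FOREST_LOSS)
        cloud = np.where(labels == int(SurfaceClass.FOREST_LOSS), 0.55, 0.50)
        s = actual_effect(self._window(), FakeClassMap(labels), field(cloud))
        assert isinstance(s, LossSample)
        assert s.delta_loss == pytest.approx(0.05, abs=1e-12)

    def test_actual_effect_no_loss_rejection(self):
        labels = checkerboard_labels(9)
        res = actual_effect(self._window(), FakeClassMap(labels),
                            field(np.ones((9, 9)) * 0.5))
        assert isinstance(res, Rejection) and res.reason == "min_count_loss"


class TestElevationFilter:
    def _window(self):
        from forestcloud.windows import Window
        return Window(0, 0, 9, 0.0, 0.0)

    def test_flat_terrain_passes(self):
        assert elevation_filter(self._window(), field(np.full((9, 9), 200.0)))

    def test_large_sd_fails(self):
        rng = np.random.default_rng(24)
        elev = rng.normal(0, 150, size=(9, 9))
        elev = elev / elev.std() * 150  # force sd = 150 m
        assert not elevation_filter(self._window(), field(elev))

    def test_sd_matches_two_pass_oracle(self):
        rng = np.random.default_rng(25)
        elev = rng.normal(300, 60, size=(9, 9))
        mask = rng.random((9, 9)) < 0.2
        fld = field(elev, mask=mask)
        vals = elev[~mask]
        oracle_sd = np.sqrt(np.mean((vals - vals.mean()) ** 2))
        expected_pass = oracle_sd <= 100.0
        assert elevation_filter(self._window(), fld) == expected_pass

    def test_all_nodata_fails(self):
        fld = field(np.zeros((9, 9)), mask=np.ones((9, 9), bool))
        assert not elevation_filter(self._window(), fld)

    def test_rejection_reason_in_pipeline(self, scene, classmap):
        rough = scene.elevation.like(
            np.random.default_rng(1).normal(0, 500, scene.elevation.shape))
        _, rejections = potential_effects(classmap, scene.cloud_yearly.mean(),
                                          rough)
        assert rejections and all(r.reason == "elevation_sd"
                                  for r in rejections)


class TestDisplayAggregation:
    def test_single_sample_single_cell(self):
        s = WindowSample(0.2, 0.3, 0.6, 0.5, 0.1, 5, 5)
        emap = aggregate_to_display([s], 0.5)
        assert emap.delta.values[0, 0] == pytest.approx(0.1)
        assert emap.count[0, 0] == 1

    def test_two_samples_mean(self):
        a = WindowSample(0.2, 0.3, 0, 0, -0.01, 5, 5)
        b = WindowSample(0.25, 0.35, 0, 0, 0.03, 5, 5)
        emap = aggregate_to_display([a, b], 0.5)
        assert emap.delta.values[0, 0] == pytest.approx(0.01, abs=1e-12)

    def test_matches_binning_oracle(self):
        rng = np.random.default_rng(26)
        samples = [WindowSample(float(rng.uniform(0, 2)),
                                float(rng.uniform(0, 2)), 0, 0,
                                float(rng.normal()), 5, 5)
                   for _ in range(100)]
        emap = aggregate_to_display(samples, 0.5)
        g = emap.delta
        for i in range(g.shape[0]):
            for j in range(g.shape[1]):
                cell = [s.delta for s in samples
                        if g.lat[i] - 0.25 <= s.center_lat < g.lat[i] + 0.25
                        and g.lon[j] - 0.25 <= s.center_lon < g.lon[j] + 0.25]
                if cell:
                    assert g.values[i, j] == pytest.approx(np.mean(cell),
                                                           abs=1e-12)
                    assert emap.count[i, j] == len(cell)
                else:
                    assert emap.delta.mask[i, j]


class TestSummaries:
    def _map_from(self, deltas):
        samples = [WindowSample(0.1 + 0.5 * k, 0.1, 0, 0, d, 5, 5)
                   for k, d in enumerate(deltas)]
        return aggregate_to_display(samples, 0.5)

    def test_sign_fractions_all_positive(self):
        enh, inh = sign_fractions(self._map_from([0.1, 0.2, 0.3]))
        assert (enh, inh) == (100.0, 0.0)

    def test_sign_fractions_half_half(self):
        enh, inh = sign_fractions(self._map_from([0.1, -0.2, 0.3, -0.4]))
        assert enh == pytest.approx(50.0) and inh == pytest.approx(50.0)

    def test_sign_fractions_sum_100_and_zero_positive(self):
        emap = self._map_from([0.0, -0.1])
        enh, inh = sign_fractions(emap)
        assert enh + inh == pytest.approx(100.0)
        assert enh == pytest.approx(50.0)  # zero counted as enhancement

    def test_sign_fractions_matches_counting_oracle(self):
        rng = np.random.default_rng(27)
        deltas = list(rng.normal(size=60))
        emap = self._map_from(deltas)
        enh, _ = sign_fractions(emap)
        vals = emap.delta.values[emap.valid]
        assert enh == pytest.approx(100.0 * np.mean(vals >= 0))

    def test_latitudinal_profile_positive_only(self):
        prof = latitudinal_profile(self._map_from([0.1, 0.2]), 1.0)
        assert prof["inhibition"].isna().all()
        assert (prof["n_enhancement"] > 0).any()

    def test_latitudinal_profile_matches_groupby_oracle(self):
        rng = np.random.default_rng(28)
        samples = [WindowSample(float(rng.uniform(0, 4)), 0.2, 0, 0,
                                float(rng.normal()), 5, 5)
                   for _ in range(80)]
        emap = aggregate_to_display(samples, 0.5)
        prof = latitudinal_profile(emap, 1.0)
        g = emap.delta
        for band in prof.index:
            sel = [(i, j) for i in range(g.shape[0]) for j in range(g.shape[1])
                   if not g.mask[i, j] and band <= g.lat[i] < band + 1.0]
            pos = [g.values[i, j] for i, j in sel if g.values[i, j] >= 0]
            if pos:
                assert prof.loc[band, "enhancement"] == pytest.approx(
                    np.mean(pos), abs=1e-12)


class TestTiming:
    def test_seasonal_peak_month(self):
        series = [0.01] * 12
        series[8] = 0.08  # September
        assert seasonal_max_month(series) == 9

    def test_seasonal_snow_month_excluded(self):
        series = [0.01] * 12
        series[0] = 0.09   # January peak, but snow-covered
        series[6] = 0.05
        assert seasonal_max_month(series, snowfree_months=range(4, 11)) == 7

    def test_seasonal_matches_argmax_oracle(self):
        rng = np.random.default_rng(29)
        series = list(rng.normal(size=12))
        allowed = [m for m in range(1, 13) if m % 2]
        got = seasonal_max_month(series, allowed)
        oracle = max(allowed, key=lambda m: (abs(series[m - 1]), -m))
        assert got == oracle

    def test_diurnal_shift_to_local_time(self):
        series = [0.0] * 24
        series[12] = 0.1  # UTC noon peak
        assert diurnal_max_hour(series, 30.0) == 14  # +2 h offset

    def test_diurnal_flat_series_earliest_hour(self):
        assert diurnal_max_hour([0.05] * 24, 0.0) == 0

    def test_diurnal_matches_shift_argmax_oracle(self):
        rng = np.random.default_rng(30)
        series = list(rng.normal(size=24))
        lon = -97.0
        got = diurnal_max_hour(series, lon)
        shift = round(lon / 15.0)
        local = {(h + shift) % 24: series[h] for h in range(24)}
        oracle = max(sorted(local), key=lambda h: (abs(local[h]), -h))
        assert got == oracle


class TestScenePipeline:
    def test_noise_free_signal_recovery(self, noisefree_scene,
                                        noisefree_classmap):
        """Each retained window's ΔCloud equals the generative linear
        combination of its tree and elevation differences."""
        scene = noisefree_scene
        cfg = scene.truth
        spec = WindowSpec()
        cloud = scene.cloud_yearly.mean()
        tree = scene.tree_multiyear_mean()
        wins = place_windows(noisefree_classmap, spec)
        checked = 0
        for w in wins:
            sc = window_effect(w, noisefree_classmap, cloud, spec=spec)
            if isinstance(sc, Rejection):
                continue
            st = window_effect(w, noisefree_classmap, tree, spec=spec)
            se = window_effect(w, noisefree_classmap, scene.elevation,
                               spec=spec)
            expected = cfg.S_tree_true * st.delta + cfg.S_ele_true * se.delta
            assert sc.delta == pytest.approx(expected, abs=1e-10)
            checked += 1
        assert checked > 5

    def test_window_size_robustness(self, scene, classmap):
        """Sign splits with window sizes 9, 11, 21 agree within 10 points."""
        enh = []
        for size in (9, 11, 21):
            samples, _ = potential_effects(
                classmap, scene.cloud_yearly.mean(), scene.elevation,
                scene.water_mask, WindowSpec(size=size, step=5))
            emap = aggregate_to_display(samples, 0.5)
            enh.append(sign_fractions(emap)[0])
        assert max(enh) - min(enh) <= 10.0
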