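"""Heatmap binning, normalization, bias subtraction, correlation, accumulation."""

import numpy as np
import pytest
from scipy import stats

from styletax import (
    FixationRecord,
    GazeBehaviorModel,
    HeatmapGrid,
    ImageRect,
    StyleSet,
    accumulate_style_heatmaps,
    average_correlations,
    bin_fixations,
    compare_trees,
    correlate_styles_for_image,
    density_map,
    gaze_pipeline,
    grand_bias,
    make_gaze_design,
    normalize_heatmap,
    simulate_fixations,
    subtract_bias,
)
from styletax.gaze import StyleCorrelation

RECT = ImageRect(x0=100.0, y0=50.0, width=824.0, height=824.0)


def fx(x, y, subject="s", motif="m", style="A"):
    return FixationRecord(subject=subject, motif=motif, style=style, x=x, y=y)


def grid(mass, state="bias_subtracted", motif="m", style="A"):
    mass = np.asarray(mass, dtype=float)
    n_fix = int(mass.sum()) if state == "raw_counts" else 0
    return HeatmapGrid(motif=motif, style=style, mass=mass, n_fixations=n_fix, state=state)


class TestBinning:
    def test_cell_width_is_image_over_grid(self):
        # 824 px image at G = 10 -> 82.4 px cells: a fixation at 82.4 px into
        # the image falls in the second cell (half-open intervals)
        h = bin_fixations([fx(100.0 + 82.4, 50.0)], RECT, 10)
        assert h.mass[0, 1] == 1
        h2 = bin_fixations([fx(100.0 + 82.3999, 50.0)], RECT, 10)
        assert h2.mass[0, 0] == 1

    def test_single_center_fixation_single_cell(self):
        h = bin_fixations([fx(100 + 412, 50 + 412)], RECT, 10)
        assert h.mass.sum() == 1
        assert h.mass[5, 5] == 1

    def test_last_bin_closed_at_image_edge(self):
        h = bin_fixations([fx(100.0 + 824.0, 50.0 + 824.0)], RECT, 10)
        assert h.mass[9, 9] == 1
        assert h.n_discarded == 0

    def test_hand_enumeration_of_seven_fixations(self):
        pts = [(0, 0), (41, 41), (82.4, 0), (411, 411), (823, 823), (82.39, 82.39), (700, 100)]
        h = bin_fixations([fx(100 + x, 50 + y) for x, y in pts], RECT, 10)
        expected = np.zeros((10, 10))
        for x, y in pts:
            expected[min(int(y // 82.4), 9), min(int(x // 82.4), 9)] += 1
        assert np.array_equal(h.mass, expected)
        assert h.n_fixations == 7

    def test_outside_fixations_discarded_and_counted(self):
        h = bin_fixations([fx(0, 0), fx(100 + 412, 50 + 412), fx(2000, 2000)], RECT, 10)
        assert h.n_fixations == 1
        assert h.n_discarded == 2

    def test_degenerate_rect_rejected(self):
        with pytest.raises(ValueError, match="empty image rectangle"):
            ImageRect(x0=0, y0=0, width=0, height=10)


class TestStateMachine:
    def test_normalized_map_sums_to_one(self):
        h = bin_fixations([fx(100 + i * 80, 50 + i * 80) for i in range(5)], RECT, 10)
        n = normalize_heatmap(h)
        assert n.mass.sum() == pytest.approx(1.0, abs=1e-9)
        assert n.state == "normalized"

    def test_normalize_requires_raw_counts(self):
        n = normalize_heatmap(bin_fixations([fx(200, 200)], RECT, 10))
        with pytest.raises(ValueError, match="raw_counts"):
            normalize_heatmap(n)

    def test_normalize_zero_fixations_rejected(self):
        h = bin_fixations([], RECT, 10)
        with pytest.raises(ValueError, match="no fixations"):
            normalize_heatmap(h)

    def test_correlation_rejects_undebias_maps(self):
        styles = StyleSet(("A", "B"))
        n = normalize_heatmap(bin_fixations([fx(200, 200)], RECT, 10))
        with pytest.raises(ValueError, match="bias_subtracted"):
            correlate_styles_for_image({"A": n, "B": n}, styles)

    def test_uniform_counts_normalize_to_uniform_mass(self):
        h = grid(np.ones((10, 10)), state="raw_counts")
        assert np.allclose(normalize_heatmap(h).mass, 0.01)


class TestBias:
    def test_bias_of_identical_maps_is_that_map_and_subtraction_zeroes(self):
        m = normalize_heatmap(grid(np.arange(16).reshape(4, 4) + 1, state="raw_counts"))
        bias = grand_bias([m, m, m])
        assert np.allclose(bias, m.mass)
        assert np.allclose(subtract_bias(m, bias).mass, 0)

    def test_two_map_bias_is_cellwise_midpoint(self):
        a = normalize_heatmap(grid([[3, 1], [0, 0]], state="raw_counts"))
        b = normalize_heatmap(grid([[0, 0], [1, 1]], state="raw_counts"))
        bias = grand_bias([a, b])
        assert np.allclose(bias, (a.mass + b.mass) / 2)

    def test_subtracted_maps_sum_to_zero(self):
        rng = np.random.default_rng(0)
        maps = [
            normalize_heatmap(grid(rng.integers(0, 9, size=(10, 10)) + 1, state="raw_counts"))
            for _ in range(6)
        ]
        bias = grand_bias(maps)
        for m in maps:
            assert subtract_bias(m, bias).mass.sum() == pytest.approx(0.0, abs=1e-9)

    def test_hand_example_2x2_subtraction(self):
        h = grid([[0.5, 0.25], [0.25, 0.0]], state="normalized")
        out = subtract_bias(h, np.array([[0.25, 0.25], [0.25, 0.25]]))
        assert np.allclose(out.mass, [[0.25, 0.0], [0.0, -0.25]])

    def test_grid_mismatch_rejected(self):
        h = grid(np.full((4, 4), 1 / 16.0), state="normalized")
        with pytest.raises(ValueError, match="shape"):
            subtract_bias(h, np.zeros((5, 5)))

    def test_center_weighted_simulation_biases_center(self, planted):
        model = GazeBehaviorModel(weight_content=0, weight_style=0, weight_center=1, seed=9)
        design = make_gaze_design(planted.styles, 1, seed=9, n_subjects=8)
        fixations = simulate_fixations(design, planted, model)
        rect = ImageRect.centered(model.screen_size, model.image_size)
        by_img: dict[tuple[str, str], list] = {}
        for f in fixations:
            by_img.setdefault((f.motif, f.style), []).append(f)
        maps = [
            normalize_heatmap(bin_fixations(v, rect, 10, motif=k[0], style=k[1]))
            for k, v in by_img.items()
        ]
        bias = grand_bias(maps)
        peak = np.unravel_index(np.argmax(bias), bias.shape)
        # ~1000 fixations: the argmax lands somewhere in the central block
        assert peak[0] in (3, 4, 5, 6) and peak[1] in (3, 4, 5, 6)


class TestCorrelation:
    def test_identical_maps_r_one_negation_r_minus_one(self):
        styles = StyleSet(("A", "B"))
        rng = np.random.default_rng(1)
        m = rng.normal(size=(10, 10))
        m -= m.mean()
        same = correlate_styles_for_image({"A": grid(m), "B": grid(m, style="B")}, styles)
        assert same.r[0, 1] == pytest.approx(1.0)
        neg = correlate_styles_for_image({"A": grid(m), "B": grid(-m, style="B")}, styles)
        assert neg.r[0, 1] == pytest.approx(-1.0)

    def test_product_moment_formula_oracle(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=100), rng.normal(size=100)
        expected = ((a - a.mean()) * (b - b.mean())).sum() / (
            np.sqrt(((a - a.mean()) ** 2).sum()) * np.sqrt(((b - b.mean()) ** 2).sum())
        )
        styles = StyleSet(("A", "B"))
        got = correlate_styles_for_image(
            {"A": grid(a.reshape(10, 10)), "B": grid(b.reshape(10, 10), style="B")}, styles
        )
        assert got.r[0, 1] == pytest.approx(expected, abs=1e-12)
        assert 0 <= got.p[0, 1] <= 1

    def test_symmetric_unit_diagonal(self):
        styles = StyleSet(("A", "B", "C"))
        rng = np.random.default_rng(3)
        maps = {s: grid(rng.normal(size=(10, 10)), style=s) for s in styles.labels}
        c = correlate_styles_for_image(maps, styles)
        assert np.allclose(c.r, c.r.T)
        assert np.allclose(np.diag(c.r), 1.0)
        off = c.r[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) <= 1)

    def test_zero_variance_map_warns_and_stays_nan(self):
        styles = StyleSet(("A", "B"))
        flat = grid(np.zeros((10, 10)))
        other = grid(np.random.default_rng(4).normal(size=(10, 10)), style="B")
        with pytest.warns(UserWarning, match="zero-variance"):
            c = correlate_styles_for_image({"A": flat, "B": other}, styles)
        assert np.isnan(c.r[0, 1])


class TestAveraging:
    def mat(self, r01, styles):
        r = np.array([[1.0, r01], [r01, 1.0]])
        return StyleCorrelation(styles=styles, r=r, p=np.full((2, 2), np.nan),
                                n_images=np.ones((2, 2)))

    def test_single_matrix_identity(self):
        styles = StyleSet(("A", "B"))
        avg = average_correlations([self.mat(0.4, styles)])
        assert avg.r[0, 1] == pytest.approx(0.4)

    def test_opposite_halves_average_to_zero(self):
        styles = StyleSet(("A", "B"))
        mats = [self.mat(1.0, styles)] * 3 + [self.mat(-1.0, styles)] * 3
        avg = average_correlations(mats)
        assert avg.r[0, 1] == pytest.approx(0.0)
        assert avg.n_images[0, 1] == 6

    def test_three_matrix_cellwise_mean(self):
        styles = StyleSet(("A", "B"))
        avg = average_correlations([self.mat(v, styles) for v in (0.1, 0.5, 0.9)])
        assert avg.r[0, 1] == pytest.approx(0.5)

    def test_nan_cells_averaged_over_defined_images_only(self):
        styles = StyleSet(("A", "B"))
        m1, m2 = self.mat(0.8, styles), self.mat(np.nan, styles)
        avg = average_correlations([m1, m2])
        assert avg.r[0, 1] == pytest.approx(0.8)
        assert avg.n_images[0, 1] == 1


class TestAccumulation:
    def test_single_image_dataset_accumulates_to_zero(self):
        styles = StyleSet(("A", "B"))
        m = normalize_heatmap(grid([[3, 1], [0, 4]], state="raw_counts"))
        bias = grand_bias([m])
        acc = accumulate_style_heatmaps([m], styles, bias)
        assert np.allclose(acc["A"].mass, 0)

    def test_accumulated_maps_sum_to_zero(self, small_gaze, styles8):
        fixations, rect, _ = small_gaze
        res = gaze_pipeline(fixations, styles8, image_rect=rect)
        for h in res.style_heatmaps.values():
            assert h.mass.sum() == pytest.approx(0.0, abs=1e-9)
            assert h.state == "bias_subtracted"

    def test_distinct_style_fields_separate_accumulations(self, small_gaze, styles8):
        fixations, rect, _ = small_gaze
        res = gaze_pipeline(fixations, styles8, image_rect=rect)
        a, b = res.style_heatmaps["EI"], res.style_heatmaps["P"]
        assert not np.allclose(a.mass, b.mass)


class TestDensityMap:
    def test_single_fixation_peaks_there(self):
        dm = density_map([fx(300, 400)], screen_size=(1280, 1024))
        assert dm.peak_xy == (300.0, 400.0)

    def test_density_integrates_to_one(self, small_gaze):
        fixations, _, model = small_gaze
        dm = density_map(fixations[:2000], screen_size=model.screen_size)
        dx = dm.x_coords[1] - dm.x_coords[0]
        dy = dm.y_coords[1] - dm.y_coords[0]
        assert dm.density.sum() * dx * dy == pytest.approx(1.0, abs=0.05)

    def test_center_biased_simulation_peaks_near_center(self, planted):
        model = GazeBehaviorModel(weight_content=0, weight_style=0, weight_center=1, seed=12)
        design = make_gaze_design(planted.styles, 1, seed=12, n_subjects=8)
        fixations = simulate_fixations(design, planted, model)
        dm = density_map(fixations, screen_size=model.screen_size)
        cx, cy = dm.screen_center
        assert abs(dm.peak_xy[0] - cx) < 0.1 * model.image_size
        assert abs(dm.peak_xy[1] - cy) < 0.1 * model.image_size


class TestPipeline:
    def test_small_scale_recovery_orders_correlations_by_distance(self, small_gaze, styles8, planted):
        fixations, rect, _ = small_gaze
        res = gaze_pipeline(fixations, styles8, image_rect=rect)
        iu = np.triu_indices(8, 1)
        d = np.array([[planted.distance(a, b) for b in styles8.labels] for a in styles8.labels])
        rho = stats.spearmanr(res.averaged.r[iu], d[iu]).statistic
        assert rho < -0.6  # correlations decrease with planted distance

    def test_deterministic_on_fixed_input(self, small_gaze, styles8):
        fixations, rect, _ = small_gaze
        r1 = gaze_pipeline(fixations, styles8, image_rect=rect)
        r2 = gaze_pipeline(fixations, styles8, image_rect=rect)
        assert np.array_equal(r1.averaged.r, r2.averaged.r)
        assert r1.tree == r2.tree

    def test_empty_log_rejected(self, styles8):
        with pytest.raises(ValueError, match="empty"):
            gaze_pipeline([], styles8, image_rect=RECT)

    def test_unknown_style_rejected(self, styles8):
        with pytest.raises(KeyError, match="Z"):
            gaze_pipeline([fx(200, 200, style="Z")], styles8, image_rect=RECT)
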