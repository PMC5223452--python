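"""Wright map, box-plot KIDMAP and ICC-overlay builders plus rendering."""

import json

import numpy as np
import pytest

import raschcir as rc


@pytest.fixture(scope="module")
def aberrant_fit():
    """A cohort with one deliberately contrary respondent: their responses
    run against the item-difficulty ordering everyone else follows."""
    spec = rc.SimulationSpec(40, 6, noise_mode="beta", beta_precision=12,
                             seed=5, delta_values=np.linspace(-2.0, 2.0, 6))
    matrix, _ = rc.simulate_matrix(spec)
    values = matrix.values.copy()
    values[0] = [0.02, 0.05, 0.4, 0.6, 0.95, 0.98]  # easy items low, hard high
    m = rc.ResponseMatrix(matrix.person_ids, matrix.item_ids, values, 0, 1)
    result = rc.fit(m)
    stats = rc.compute_fit_statistics(result)
    return result, stats


class TestWrightMap:
    def test_item_points_cover_all_non_extreme_items(self, beta_fit):
        _, _, result, stats = beta_fit
        data = rc.build_wright_map(result, stats)
        assert len(data.item_points) == (~result.extreme_item_flags).sum()
        lo, hi = data.shared_axis
        for _, d, _, _ in data.item_points:
            assert lo <= d <= hi

    def test_bin_total_equals_non_extreme_person_count(self, beta_fit):
        _, _, result, stats = beta_fit
        for width in (0.25, 0.4, 1.0):
            data = rc.build_wright_map(result, stats, bin_width=width)
            assert sum(data.person_bins) == (~result.extreme_person_flags).sum()

    def test_identical_measures_occupy_one_bin(self):
        m = rc.ResponseMatrix(["a", "b"], ["x", "y"],
                              [[1.0, 0.0], [0.0, 1.0]], 0, 1)
        result = rc.fit(m)
        stats = rc.compute_fit_statistics(result)
        data = rc.build_wright_map(result, stats)
        assert sum(1 for c in data.person_bins if c > 0) == 1

    def test_single_construct_annotation_tracks_infit_rule(self, beta_fit):
        _, _, result, stats = beta_fit
        data = rc.build_wright_map(result, stats)
        expected = bool(np.all(stats.item_infit[~result.extreme_item_flags] < 1.5))
        assert data.single_construct == expected
        for _, _, infit, ok in data.item_points:
            assert ok == (infit < 1.5)


class TestKidmap:
    def test_contrary_respondent_is_flagged_misfit(self, aberrant_fit):
        result, stats = aberrant_fit
        data = rc.build_kidmap(result, stats, result.person_ids[0])
        assert data.outfit >= 2.0 and data.misfit
        assert len(data.per_item) == len(result.item_ids)
        assert data.strengths and data.weaknesses

    def test_classification_matches_cell_z_flags(self, aberrant_fit):
        result, stats = aberrant_fit
        n = 0
        data = rc.build_kidmap(result, stats, result.person_ids[n])
        for j, item in enumerate(result.item_ids):
            z = result.residuals.Z[n, j]
            assert (item in data.strengths) == (z >= 2.0)
            assert (item in data.weaknesses) == (z <= -2.0)
        assert not set(data.strengths) & set(data.weaknesses)

    def test_model_conforming_person_has_no_flags(self):
        spec = rc.SimulationSpec(25, 5, noise_mode="exact", seed=9)
        matrix, _ = rc.simulate_matrix(spec)
        result = rc.fit(matrix, rc.RunConfig(change_tol=1e-8))
        stats = rc.compute_fit_statistics(result)
        data = rc.build_kidmap(result, stats, "P1")
        assert data.strengths == [] and data.weaknesses == []

    def test_unknown_person_rejected(self, beta_fit):
        _, _, result, stats = beta_fit
        with pytest.raises(KeyError, match="unknown person"):
            rc.build_kidmap(result, stats, "nobody")

    def test_cohort_boxes_are_ordered_five_number_summaries(self, beta_fit):
        _, _, result, stats = beta_fit
        data = rc.build_kidmap(result, stats, result.person_ids[3])
        for entry in data.per_item:
            c = entry["cohort"]
            assert c["min"] <= c["q1"] <= c["median"] <= c["q3"] <= c["max"]


class TestICCOverlay:
    def test_curve_passes_through_half_at_zero(self, beta_fit):
        _, _, result, stats = beta_fit
        data = rc.build_icc_overlay(result, stats)
        x = np.asarray(data.curve_x)
        p = np.asarray(data.curve_p)
        assert np.interp(0.0, x, p) == pytest.approx(0.5, abs=1e-4)

    def test_curve_strictly_increasing(self, beta_fit):
        _, _, result, stats = beta_fit
        data = rc.build_icc_overlay(result, stats)
        assert np.all(np.diff(data.curve_p) > 0)

    def test_points_above_flag_line_are_the_flagged_persons(self, aberrant_fit):
        result, stats = aberrant_fit
        data = rc.build_icc_overlay(result, stats)
        above = {p for p, _, o, _ in data.person_points if o >= data.flag_line}
        flagged = {p for p, _, _, f in data.person_points if f}
        assert above == flagged


class TestRender:
    def test_json_roundtrip_is_exact_and_deterministic(self, tmp_path,
                                                       beta_fit):
        _, _, result, stats = beta_fit
        data = rc.build_wright_map(result, stats)
        p1 = rc.render(data, tmp_path / "w1.json")
        p2 = rc.render(data, tmp_path / "w2.json")
        assert p1.read_bytes() == p2.read_bytes()
        payload = json.loads(p1.read_text())
        assert payload["kind"] == "WrightMapData"
        assert payload["data"]["person_bins"] == data.person_bins
        assert payload["data"]["bin_edges"] == data.bin_edges

    def test_builders_are_pure(self, beta_fit):
        _, _, result, stats = beta_fit
        a = rc.build_kidmap(result, stats, result.person_ids[0])
        b = rc.build_kidmap(result, stats, result.person_ids[0])
        assert a == b

    @pytest.mark.parametrize("fmt", ["svg", "png"])
    def test_figures_are_written(self, tmp_path, beta_fit, fmt):
        _, _, result, stats = beta_fit
        for build, name in [
            (lambda: rc.build_wright_map(result, stats), "wright"),
            (lambda: rc.build_kidmap(result, stats, result.person_ids[0]),
             "kidmap"),
            (lambda: rc.build_icc_overlay(result, stats), "icc"),
        ]:
            out = rc.render(build(), tmp_path / f"{name}.{fmt}")
            assert out.stat().st_size > 0

    def test_unknown_format_rejected(self, tmp_path, beta_fit):
        _, _, result, stats = beta_fit
        data = rc.build_wright_map(result, stats)
        with pytest.raises(ValueError, match="unknown render format"):
            rc.render(data, tmp_path / "w.bmp")
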