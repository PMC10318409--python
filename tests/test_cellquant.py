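"""Single-cell measurement, tracking, generations and population metrics."""

import numpy as np
import pytest

from flimox.cellquant import (
    CellRecord,
    LabelMaskFrame,
    LineageForest,
    PopulationSeries,
    assign_generations,
    border_filter,
    cell_intensities,
    fold_change,
    generation_correlation,
    growth_rate,
    intensity_slope,
    intensity_vs_generation,
    population_series,
    track_cells,
)


def mask_frame(labels, pixel_size=0.065, frame=0, t=0.0):
    return LabelMaskFrame(
        labels=np.asarray(labels, dtype=np.int32),
        pixel_size_um=pixel_size,
        frame_index=frame,
        timestamp_s=t,
    )


class TestBorderFilter:
    def test_zero_margin_is_identity(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[0:3, 0:3] = 1
        out, removed = border_filter(mask_frame(labels), margin_um=0.0)
        assert removed == []
        assert np.array_equal(out.labels, labels)

    def test_edge_touching_cell_removed_interior_kept(self):
        # 0.5 μm at 0.065 μm/px -> pixels 0..7 count as border
        labels = np.zeros((40, 40), dtype=np.int32)
        labels[10:14, 0:4] = 1      # touches left edge
        labels[15:19, 15:19] = 2    # interior
        labels[25:29, 20:24] = 3    # interior (border band is 8 px wide)
        out, removed = border_filter(mask_frame(labels), margin_um=0.5)
        assert removed == [1]
        assert set(np.unique(out.labels)) == {0, 2, 3}

    def test_centered_cell_survives_default_margin(self):
        labels = np.zeros((40, 40), dtype=np.int32)
        labels[18:22, 18:22] = 1
        _, removed = border_filter(mask_frame(labels), margin_um=0.5)
        assert removed == []

    def test_count_monotone_in_margin(self):
        rng = np.random.default_rng(1)
        labels = np.zeros((50, 50), dtype=np.int32)
        for k in range(1, 11):
            r, c = rng.integers(0, 46, size=2)
            labels[r:r + 4, c:c + 4] = k
        counts = []
        for margin in [0.0, 0.2, 0.5, 1.0, 1.5]:
            out, _ = border_filter(mask_frame(labels), margin_um=margin)
            counts.append(len(out.cell_labels()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_oversized_margin_removes_everything_with_warning(self):
        labels = np.ones((10, 10), dtype=np.int32)
        with pytest.warns(UserWarning, match="margin"):
            out, _ = border_filter(mask_frame(labels), margin_um=10.0)
        assert out.cell_labels().size == 0


class TestCellIntensities:
    def test_uniform_fluorescence(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[2:4, 2:4] = 1
        labels[6:9, 6:9] = 2
        records = cell_intensities(mask_frame(labels), np.full((10, 10), 42.0))
        assert [r.mean_intensity for r in records] == [42.0, 42.0]

    def test_hand_computed_mean(self):
        labels = np.zeros((4, 4), dtype=np.int32)
        labels[1:3, 1:3] = 1
        fluor = np.zeros((4, 4))
        fluor[1:3, 1:3] = [[10.0, 20.0], [30.0, 40.0]]
        (rec,) = cell_intensities(mask_frame(labels), fluor)
        assert rec.mean_intensity == 25.0  # exact
        assert rec.area_um2 == pytest.approx(4 * 0.065**2)
        assert rec.centroid == (1.5, 1.5)

    def test_background_only_mask_gives_empty_list(self):
        assert cell_intensities(mask_frame(np.zeros((5, 5), int)), np.ones((5, 5))) == []

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            cell_intensities(mask_frame(np.zeros((5, 5), int)), np.ones((6, 6)))


def two_cell_mask():
    labels = np.zeros((20, 20), dtype=np.int32)
    labels[5:9, 2:8] = 1
    labels[12:16, 10:16] = 2
    return labels


class TestTracking:
    def test_static_masks_give_chains_without_divisions(self):
        frames = [mask_frame(two_cell_mask(), frame=i) for i in range(5)]
        forest = track_cells(frames)
        assert len(forest.roots) == 2
        assert forest.n_divisions() == 0
        assert all(
            forest.generation(n) == 0 for n in forest.graph.nodes
        )

    def test_split_into_halves_detected_as_division(self):
        parent = np.zeros((20, 20), dtype=np.int32)
        parent[8:12, 4:16] = 1
        daughters = np.zeros((20, 20), dtype=np.int32)
        daughters[8:12, 4:10] = 1
        daughters[8:12, 10:16] = 2
        forest = track_cells(
            [mask_frame(parent, frame=0), mask_frame(daughters, frame=1)]
        )
        assert forest.n_divisions() == 1
        assert forest.generation((1, 1)) == 1
        assert forest.generation((1, 2)) == 1

    def test_empty_frame_restarts_lineages_as_roots(self):
        empty = np.zeros((20, 20), dtype=np.int32)
        frames = [
            mask_frame(two_cell_mask(), frame=0),
            mask_frame(empty, frame=1),
            mask_frame(two_cell_mask(), frame=2),
        ]
        forest = track_cells(frames)
        assert len(forest.roots) == 4

    def test_simulator_lineage_recovered_from_rendered_masks(self, rendered_colony):
        """Greedy IoU tracking reproduces ≥95% of ground-truth links."""
        r = rendered_colony
        frames = [
            LabelMaskFrame(
                labels=r.masks[i], pixel_size_um=r.pixel_size_um,
                frame_index=i, timestamp_s=float(r.frame_times_s[i]),
            )
            for i in range(len(r.masks))
        ]
        forest = track_cells(frames)
        truth = set(map(tuple, r.forest.edges_frame().to_numpy().tolist()))
        got = set(map(tuple, forest.edges_frame().to_numpy().tolist()))
        assert len(truth & got) / len(truth) >= 0.95

    def test_roots_plus_divisions_balance_final_count(self, small_colony):
        """With no disappearances, roots + divisions = final cell count."""
        assert small_colony.n_exited == 0  # 6 h colony never reaches the ends
        forest = small_colony.forest
        assert (
            len(forest.roots) + forest.n_divisions() == len(small_colony.cells[-1])
        )


class TestGenerations:
    def test_perfect_binary_tree_three_rounds(self):
        forest = LineageForest()
        # frame f holds 2^f cells, all dividing every frame
        for f in range(4):
            for c in range(2**f):
                forest.add_node(f, c)
        for f in range(3):
            for c in range(2**f):
                forest.add_edge((f, c), (f + 1, 2 * c))
                forest.add_edge((f, c), (f + 1, 2 * c + 1))
        assign_generations(forest)
        gens = forest.generations_at_frame(3)
        assert len(gens) == 8
        assert set(gens.values()) == {3}

    def test_single_division_then_one_daughter_divides(self):
        forest = LineageForest()
        forest.add_node(0, 1)
        for c in (1, 2):
            forest.add_node(1, c)
        for c in (1, 2, 3):
            forest.add_node(2, c)
        forest.add_edge((0, 1), (1, 1))
        forest.add_edge((0, 1), (1, 2))
        forest.add_edge((1, 1), (2, 1))  # continues
        forest.add_edge((1, 2), (2, 2))  # divides again
        forest.add_edge((1, 2), (2, 3))
        assign_generations(forest)
        assert forest.generations_at_frame(1) == {1: 1, 2: 1}
        assert forest.generations_at_frame(2) == {1: 1, 2: 2, 3: 2}

    def test_generation_bound_two_to_the_g(self, small_colony):
        """At most 2^g cells of generation g can descend from one founder."""
        table = small_colony.cells[-1]
        n_roots = len(small_colony.cells[0])
        for g, count in table.groupby("generation").size().items():
            assert count <= n_roots * 2**g


class TestPopulationMetrics:
    def test_population_series_counts_and_means(self):
        records = [
            [
                CellRecord(0, i, (0, 0), 1.0, v, timestamp_s=0.0)
                for i, v in enumerate([10.0, 20.0, 30.0])
            ],
            [],
        ]
        series = population_series(records, timestamps_s=[0.0, 300.0])
        assert series.n_population.tolist() == [3, 0]
        assert series.i_population[0] == 20.0
        assert np.isnan(series.i_population[1])

    @pytest.mark.parametrize("mu", [0.3, 0.52, 0.55, 0.7])
    def test_growth_rate_recovered_from_rounded_exponential(self, mu):
        t = np.arange(0, 9.0 + 1e-9, 5 / 60)
        n = np.round(2.0 * np.exp(mu * t)).astype(int)
        series = PopulationSeries(
            timestamps_s=t * 3600, n_population=n, i_population=np.full_like(t, 1.0)
        )
        fit_mu, se = growth_rate(series)
        assert fit_mu == pytest.approx(mu, abs=0.01)

    def test_constant_population_zero_growth(self):
        t = np.arange(10.0)
        series = PopulationSeries(t * 3600, np.full(10, 7), np.ones(10))
        assert growth_rate(series)[0] == pytest.approx(0.0, abs=1e-12)

    def test_hourly_doubling_gives_ln2(self):
        t = np.arange(8.0)
        series = PopulationSeries(t * 3600, 2 ** np.arange(8), np.ones(8))
        assert growth_rate(series)[0] == pytest.approx(np.log(2), abs=1e-9)

    def test_intensity_slope_exact_on_linear_input(self):
        t = np.arange(0, 9.0, 5 / 60)
        series = PopulationSeries(t * 3600, np.ones_like(t, int), 5 + 23 * t)
        slope, se, r2 = intensity_slope(series)
        assert slope == pytest.approx(23.0, abs=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_intensity_slope_zero_on_constant(self):
        t = np.arange(10.0)
        series = PopulationSeries(t * 3600, np.ones(10, int), np.full(10, 3.0))
        assert intensity_slope(series)[0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "post, pre, ratio, fold",
        [(165.0, 23.0, 7.17, 7), (10.0, 10.0, 1.0, 1), (-5.0, 10.0, -0.5, 0)],
    )
    def test_fold_change(self, post, pre, ratio, fold):
        got_ratio, got_fold = fold_change(post, pre)
        assert got_ratio == pytest.approx(ratio, abs=0.005)
        assert got_fold == fold

    def test_fold_change_rejects_zero_reference(self):
        with pytest.raises(ValueError):
            fold_change(10.0, 0.0)


class TestIntensityVsGeneration:
    def test_two_cells_perfectly_anticorrelated(self):
        forest = LineageForest()
        forest.add_node(0, 1, generation=1)
        forest.add_node(0, 2, generation=3)
        records = [
            CellRecord(0, 1, (0, 0), 1.0, 50.0),
            CellRecord(0, 2, (0, 0), 1.0, 20.0),
        ]
        table = intensity_vs_generation(records, forest)
        assert len(table) == 2
        assert generation_correlation(table) == pytest.approx(-1.0)

    def test_single_generation_forms_one_group(self):
        forest = LineageForest()
        for c in (1, 2, 3):
            forest.add_node(0, c, generation=0)
        records = [CellRecord(0, c, (0, 0), 1.0, float(c)) for c in (1, 2, 3)]
        table = intensity_vs_generation(records, forest)
        assert set(table["generation"]) == {0}

    def test_dilution_makes_generation_anticorrelated_after_switch(
        self, switch_experiment
    ):
        """Fast-dividing lineages dilute the released GFP backlog."""
        anaerobic, _ = switch_experiment
        ds = anaerobic.datasets[0]
        last = len(ds.cells) - 1
        table = intensity_vs_generation(ds.truth_records(last), ds.forest, last)
        assert generation_correlation(table) < 0
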