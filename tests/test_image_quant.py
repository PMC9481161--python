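"""Polar cluster detection, fluorescence partitioning, omega and binning."""
import numpy as np
import pytest

from polarquant import image_quant as iq
from polarquant import synthetic as syn
from conftest import checkerboard_fluor, make_rod_scene


class TestExtractCells:
    def test_single_rod_poles_on_medial_axis(self, rod_scene):
        labels, _ = rod_scene
        cells = iq.extract_cells(labels)
        assert len(cells) == 1
        (cell,) = cells
        rows, cols = cell.pixels[:, 0], cell.pixels[:, 1]
        # poles at the column extremes, on the central rows
        assert cell.pole_a[1] == cols.min() and cell.pole_b[1] == cols.max()
        mid = (rows.min() + rows.max()) / 2
        assert abs(cell.pole_a[0] - mid) <= 1 and abs(cell.pole_b[0] - mid) <= 1
        assert not cell.touches_border

    def test_empty_mask_gives_empty_list(self):
        assert iq.extract_cells(np.zeros((20, 20), dtype=int)) == []

    def test_two_disjoint_labels_give_disjoint_cells(self):
        labels = np.zeros((40, 40), dtype=int)
        labels[5:9, 5:25] = 1
        labels[20:24, 5:25] = 2
        cells = iq.extract_cells(labels)
        assert [c.cell_id for c in cells] == [1, 2]
        s1 = {tuple(p) for p in cells[0].pixels}
        s2 = {tuple(p) for p in cells[1].pixels}
        assert not s1 & s2

    def test_border_cell_flagged(self):
        labels = np.zeros((20, 30), dtype=int)
        labels[0:4, 5:25] = 1
        (cell,) = iq.extract_cells(labels)
        assert cell.touches_border


class TestPoleRegions:
    def test_fraction_spans_expected_axis_length(self, rod_scene):
        labels, _ = rod_scene
        (cell,) = iq.extract_cells(labels)
        ra, rb = iq.identify_pole_regions(cell, pole_fraction=0.2)
        length = cell.axis_length
        cols_a = cell.pixels[ra][:, 1]
        assert cols_a.max() - cell.pole_a[1] <= 0.2 * length
        assert not (ra & rb).any()

    def test_fraction_half_partitions_cell(self, rod_scene):
        labels, _ = rod_scene
        (cell,) = iq.extract_cells(labels)
        ra, rb = iq.identify_pole_regions(cell, pole_fraction=0.5)
        assert (ra | rb).all() and not (ra & rb).any()

    def test_symmetric_rod_gives_equal_regions(self, rod_scene):
        labels, _ = rod_scene
        (cell,) = iq.extract_cells(labels)
        ra, rb = iq.identify_pole_regions(cell, pole_fraction=0.2)
        assert abs(int(ra.sum()) - int(rb.sum())) <= 1

    def test_invalid_fraction_rejected(self, rod_scene):
        labels, _ = rod_scene
        (cell,) = iq.extract_cells(labels)
        with pytest.raises(ValueError):
            iq.identify_pole_regions(cell, pole_fraction=0.6)


class TestClusterDetection:
    """Cytoplasm painted as a 90/110 checkerboard: mu ~= 100, sigma ~= 10,
    so the pixel threshold mu + 2*sigma sits just above 120."""

    def _scene_with_pole_patch(self, value, size, low=90.0, high=110.0):
        labels, _ = make_rod_scene()
        fluor = checkerboard_fluor(labels, low=low, high=high)
        (cell,) = iq.extract_cells(labels, fluor)
        ra, _ = iq.identify_pole_regions(cell)
        pix = cell.pixels[ra]
        d = np.hypot(pix[:, 0] - cell.pole_a[0], pix[:, 1] - cell.pole_a[1])
        chosen = pix[np.argsort(d)[:size]]
        fluor[chosen[:, 0], chosen[:, 1]] = value
        return cell, fluor

    def test_bright_patch_above_threshold_accepted(self):
        cell, fluor = self._scene_with_pole_patch(130.0, 5)
        clusters = iq.detect_polar_clusters(cell, fluor, mode="snapshot")
        assert len(clusters) == 1
        assert clusters[0].size_px >= 5
        assert clusters[0].pole_label == "a"

    def test_two_pixel_patch_rejected_by_size(self):
        cell, fluor = self._scene_with_pole_patch(130.0, 2)
        assert iq.detect_polar_clusters(cell, fluor, mode="snapshot") == []

    def test_timelapse_requires_twofold_over_cytoplasm(self):
        # sigma ~= 5 -> 150 passes mu+2*sigma but fails the 2*mu rule
        cell, fluor = self._scene_with_pole_patch(150.0, 5, low=95.0, high=105.0)
        assert iq.detect_polar_clusters(cell, fluor, mode="snapshot")
        assert iq.detect_polar_clusters(cell, fluor, mode="timelapse") == []

    def test_sparse_cytoplasm_unquantifiable(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[4:6, 2:8] = 1  # 12 px cell, almost all inside pole regions
        fluor = np.full(labels.shape, 100.0)
        (cell,) = iq.extract_cells(labels, fluor)
        with pytest.raises(iq.UnquantifiableCellError):
            iq.detect_polar_clusters(cell, fluor)

    def test_affine_intensity_transform_preserves_decisions(self):
        spec = syn.SnapshotPopulationSpec(
            n_cells=30, pattern_mixture={"unipolar": 0.4, "bipolar_symmetric": 0.3,
                                         "diffuse": 0.3},
            noise_sd=2.0, seed=13)
        labels, fluor, _ = syn.gen_snapshot_scene(spec)
        base, _ = iq.quantify_scene(labels, fluor, mode="snapshot")
        for transform in (lambda x: 3.0 * x + 50.0, lambda x: 0.25 * x):
            moved, _ = iq.quantify_scene(labels, transform(fluor), mode="snapshot")
            assert [r.pattern for r in moved] == [r.pattern for r in base]

    def test_multiplicative_transform_preserves_timelapse_decisions(self):
        spec = syn.SnapshotPopulationSpec(
            n_cells=20, pattern_mixture={"unipolar": 0.5, "diffuse": 0.5},
            noise_sd=2.0, seed=14)
        labels, fluor, _ = syn.gen_snapshot_scene(spec)
        base, _ = iq.quantify_scene(labels, fluor, mode="timelapse")
        scaled, _ = iq.quantify_scene(labels, 2.5 * fluor, mode="timelapse")
        assert [r.pattern for r in scaled] == [r.pattern for r in base]


class TestLocalization:
    def _record(self, f1, f2, total=1000.0):
        """Cell whose image totals `total`, with cluster sums f1 and f2."""
        labels, _ = make_rod_scene()
        fluor = np.zeros(labels.shape)
        (cell,) = iq.extract_cells(labels)
        n = len(cell.pixels)
        fluor[cell.pixels[:, 0], cell.pixels[:, 1]] = (total - f1 - f2) / n
        clusters = []
        if f1 > 0:
            clusters.append(iq.PolarCluster(1, "a", cell.pixels[:3], f1 / 3, f1))
            fluor[cell.pixels[:3, 0], cell.pixels[:3, 1]] += f1 / 3
        if f2 > 0:
            clusters.append(iq.PolarCluster(1, "b", cell.pixels[-3:], f2 / 3, f2))
            fluor[cell.pixels[-3:, 0], cell.pixels[-3:, 1]] += f2 / 3
        return iq.compute_localization(cell, clusters, fluor)

    def test_omega_from_cluster_totals(self):
        rec = self._record(75.0, 25.0)
        assert rec.omega == pytest.approx(0.5)
        assert rec.pattern == "bipolar_asymmetric"

    def test_equal_poles_give_zero_omega(self):
        rec = self._record(50.0, 50.0)
        assert rec.omega == pytest.approx(0.0)
        assert rec.pattern == "bipolar_symmetric"

    def test_single_cluster_gives_omega_one(self):
        rec = self._record(80.0, 0.0)
        assert rec.omega == pytest.approx(1.0)
        assert rec.pattern == "unipolar"

    def test_no_cluster_is_diffuse_with_zero_pole_fractions(self):
        rec = self._record(0.0, 0.0)
        assert rec.omega is None and rec.pattern == "diffuse"
        assert rec.f_pole1 == rec.f_pole2 == 0.0

    def test_fractions_sum_to_one(self):
        rec = self._record(75.0, 25.0)
        assert rec.f_pole1 + rec.f_pole2 + rec.f_cyto == pytest.approx(1.0, abs=1e-9)
        assert rec.f_pole1 >= rec.f_pole2 >= 0

    def test_zero_total_fluorescence_invalid(self, rod_scene):
        labels, _ = rod_scene
        (cell,) = iq.extract_cells(labels)
        with pytest.raises(ValueError):
            iq.compute_localization(cell, [], np.zeros(labels.shape))


class TestClassifyPattern:
    @pytest.mark.parametrize("omega,expected", [
        (0.95, "unipolar"),
        (0.9, "bipolar_asymmetric"),   # boundary to the less extreme class
        (0.5, "bipolar_asymmetric"),
        (0.2, "bipolar_symmetric"),
        (0.05, "bipolar_symmetric"),
        (None, "diffuse"),
    ])
    def test_binning(self, omega, expected):
        assert iq.classify_pattern(omega) == expected

    def test_partition_is_total_on_random_scene(self):
        spec = syn.SnapshotPopulationSpec(
            n_cells=60, pattern_mixture={"unipolar": 0.3, "bipolar_asymmetric": 0.3,
                                         "bipolar_symmetric": 0.2, "diffuse": 0.2},
            noise_sd=3.0, seed=21)
        labels, fluor, _ = syn.gen_snapshot_scene(spec)
        records, skipped = iq.quantify_scene(labels, fluor)
        assert len(records) + len(skipped) == 60
        for r in records:
            assert r.pattern in iq.PATTERNS
            if r.omega is not None:
                assert 0.0 <= r.omega <= 1.0


class TestSummarize:
    def test_all_diffuse_population(self):
        recs = [iq.LocalizationRecord(i, 0, 0, 1.0, None, "diffuse")
                for i in range(10)]
        s = iq.summarize_population(recs)
        assert s.percent["diffuse"] == 100.0
        assert sum(s.percent.values()) == pytest.approx(100.0, abs=1e-6)

    def test_mean_cytoplasmic_percentage(self):
        recs = [iq.LocalizationRecord(i, 0.3, 0.1, 0.6, 0.5, "bipolar_asymmetric")
                for i in range(5)]
        s = iq.summarize_population(recs)
        assert s.mean_percent_cytoplasm == pytest.approx(60.0)
        assert len(s.scatter) == 5

    def test_mixture_recovered_within_binomial_error(self):
        mix = {"unipolar": 0.5, "diffuse": 0.5}
        spec = syn.SnapshotPopulationSpec(n_cells=200, pattern_mixture=mix,
                                          noise_sd=1.0, seed=22)
        labels, fluor, _ = syn.gen_snapshot_scene(spec)
        records, _ = iq.quantify_scene(labels, fluor)
        s = iq.summarize_population(records)
        se = 100 * np.sqrt(0.25 / 200)
        assert abs(s.percent["unipolar"] - 50.0) < 3 * se + 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            iq.summarize_population([])


class TestGroundTruthRecovery:
    def test_perfect_agreement_without_noise(self):
        mix = {"unipolar": 0.4, "bipolar_asymmetric": 0.3,
               "bipolar_symmetric": 0.15, "diffuse": 0.15}
        spec = syn.SnapshotPopulationSpec(n_cells=100, pattern_mixture=mix,
                                          cytoplasm_sd=0.0, noise_sd=0.0, seed=31)
        labels, fluor, truth = syn.gen_snapshot_scene(spec)
        records, skipped = iq.quantify_scene(labels, fluor)
        assert not skipped
        truth_map = dict(zip(truth["cell_id"], truth["pattern"]))
        assert all(truth_map[r.cell_id] == r.pattern for r in records)

    def test_agreement_degrades_monotonically_with_noise(self):
        mix = {"unipolar": 0.4, "bipolar_asymmetric": 0.3,
               "bipolar_symmetric": 0.15, "diffuse": 0.15}
        agreements = []
        for noise in (0.0, 2.0, 30.0):
            spec = syn.SnapshotPopulationSpec(n_cells=80, pattern_mixture=mix,
                                              cytoplasm_sd=0.0, noise_sd=noise,
                                              seed=32)
            labels, fluor, truth = syn.gen_snapshot_scene(spec)
            records, _ = iq.quantify_scene(labels, fluor)
            truth_map = dict(zip(truth["cell_id"], truth["pattern"]))
            agreements.append(
                np.mean([truth_map[r.cell_id] == r.pattern for r in records]))
        assert agreements[0] == 1.0
        assert agreements[0] >= agreements[1] >= agreements[2]
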