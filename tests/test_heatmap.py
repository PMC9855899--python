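import numpy as np
import pytest

from afmtexture import (
    CellRecord,
    Step1Config,
    SplitSpec,
    compute_heatmap,
    evaluate_step1,
    extract_regions,
    overlay,
    window_probability,
)
from afmtexture.heatmap import ProbabilityHeatmap
from afmtexture import nano_contrast_config, generate_dataset, generate_cell


@pytest.fixture(scope="module")
def tiny_results():
    """Classifier over 5 features trained on 20 small single-channel cells."""
    cells = generate_dataset(nano_contrast_config(64, 64), 10, 5)
    outcome = evaluate_step1(cells, Step1Config(k=5, split=SplitSpec(seed=5)))
    return outcome.results


@pytest.fixture(scope="module")
def sample_cell():
    return generate_cell(nano_contrast_config(64, 64), "high", "sample", 99)


class TestComputeHeatmap:
    def test_valid_region_arithmetic(self, tiny_results, sample_cell):
        hm = compute_heatmap(sample_cell, tiny_results, window_px=32, stride_px=1)
        assert hm.valid_mask.sum() == (64 - 32 + 1) ** 2
        # even window: centre is the top-left pixel of the central 2x2 block
        rows, cols = np.where(hm.valid_mask)
        assert rows.min() == cols.min() == 15
        assert rows.max() == cols.max() == 15 + 32

    def test_matches_single_window_oracle_at_random_positions(
        self, tiny_results, sample_cell
    ):
        hm = compute_heatmap(sample_cell, tiny_results, window_px=32)
        rng = np.random.default_rng(0)
        for _ in range(10):
            i, j = rng.integers(0, 64 - 32 + 1, size=2)
            expected = window_probability(sample_cell, tiny_results, i, j, 32)
            assert hm.probabilities[i + 15, j + 15] == pytest.approx(
                expected, abs=1e-10
            )

    def test_translation_consistency(self, tiny_results, sample_cell):
        dr, dc = 4, 6
        big = sample_cell.channels["rm_restored_adhesion"].values
        shifted = CellRecord(
            "shifted",
            None,
            {
                "rm_restored_adhesion": sample_cell.channels[
                    "rm_restored_adhesion"
                ].with_values(np.roll(np.roll(big, dr, axis=0), dc, axis=1))
            },
        )
        h0 = compute_heatmap(sample_cell, tiny_results, 32)
        h1 = compute_heatmap(shifted, tiny_results, 32)
        # overlap of the two valid regions after the shift
        a = h0.probabilities[15 : 48 - dr, 15 : 48 - dc]
        b = h1.probabilities[15 + dr : 48, 15 + dc : 48]
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_stride_fills_with_nearest_computed_value(self, tiny_results, sample_cell):
        h1 = compute_heatmap(sample_cell, tiny_results, 32, stride_px=1)
        h4 = compute_heatmap(sample_cell, tiny_results, 32, stride_px=4)
        np.testing.assert_array_equal(h1.valid_mask, h4.valid_mask)
        # computed positions agree exactly with the stride-1 map
        np.testing.assert_allclose(
            h4.probabilities[15::4, 15::4], h1.probabilities[15::4, 15::4], atol=0
        )
        # intermediate pixels replicate the nearest computed position
        assert h4.probabilities[16, 16] == h4.probabilities[15 + 4 * round(1 / 4), 15]

    def test_deterministic_rerun_bit_identical(self, tiny_results, sample_cell):
        h1 = compute_heatmap(sample_cell, tiny_results, 32)
        h2 = compute_heatmap(sample_cell, tiny_results, 32)
        np.testing.assert_array_equal(h1.probabilities, h2.probabilities)

    def test_window_too_small_for_selected_features_is_rejected(
        self, tiny_results, sample_cell
    ):
        spatial = [(c, p) for c, p in tiny_results.features]
        if not any(p in ("Sal", "Str", "Sk", "Vvv", "Smr1", "Spk") for _, p in spatial):
            pytest.skip("no >=8px feature selected")
        with pytest.raises(ValueError, match="too small"):
            compute_heatmap(sample_cell, tiny_results, window_px=4)

    def test_missing_channel_rejected(self, tiny_results):
        cells = generate_dataset(nano_contrast_config(64, 64), 2, 1)
        stripped = CellRecord(
            "x",
            None,
            {
                "height": cells[0]
                .channels["rm_restored_adhesion"]
                .with_values(cells[0].channels["rm_restored_adhesion"].values)
            },
        )
        # rebuild with a kind the classifier does not use
        from afmtexture import ChannelImage

        stripped = CellRecord(
            "x",
            None,
            {"height": ChannelImage(np.zeros((64, 64)) + np.eye(64), 19.53, "nm", "height")},
        )
        with pytest.raises(ValueError, match="lacks channels"):
            compute_heatmap(stripped, tiny_results, 32)


class TestProbabilityHeatmapType:
    def test_rejects_out_of_range_probabilities(self):
        p = np.full((6, 6), 1.5)
        m = np.ones((6, 6), dtype=bool)
        with pytest.raises(ValueError):
            ProbabilityHeatmap(p, m, 3, 1, 19.53)

    def test_masked_entries_may_be_anything(self):
        p = np.full((6, 6), 99.0)
        m = np.zeros((6, 6), dtype=bool)
        ProbabilityHeatmap(p, m, 3, 1, 19.53)  # no error


class TestOverlay:
    def _pair(self):
        rng = np.random.default_rng(1)
        from afmtexture import ChannelImage

        img = ChannelImage(rng.standard_normal((20, 20)), 19.53, "nN", "rm_adhesion")
        p = rng.uniform(size=(20, 20))
        m = np.zeros((20, 20), dtype=bool)
        m[5:15, 5:15] = True
        return ProbabilityHeatmap(p, m, 5, 1, 19.53), img

    def test_alpha_zero_is_the_pure_channel_render(self):
        hm, img = self._pair()
        out = overlay(hm, img, alpha=0.0)
        v = img.values
        gray = np.uint8(np.clip((v - v.min()) / (v.max() - v.min()), 0, 1) * 255)
        np.testing.assert_array_equal(out[..., 0], gray)
        np.testing.assert_array_equal(out[..., 0], out[..., 1])

    def test_alpha_one_shows_pure_heatmap_in_valid_region(self):
        hm, img = self._pair()
        out1 = overlay(hm, img, alpha=1.0)
        from matplotlib import cm

        heat = np.uint8(np.clip(cm.coolwarm(hm.probabilities)[..., :3], 0, 1) * 255)
        np.testing.assert_array_equal(out1[hm.valid_mask], heat[hm.valid_mask])

    def test_deterministic_bytes_and_shape_checks(self):
        hm, img = self._pair()
        np.testing.assert_array_equal(overlay(hm, img, 0.5), overlay(hm, img, 0.5))
        from afmtexture import ChannelImage

        small = ChannelImage(np.zeros((5, 5)) + np.eye(5), 19.53, "nm", "height")
        with pytest.raises(ValueError, match="mismatch"):
            overlay(hm, small)


class TestExtractRegions:
    def _uniform(self, value, n=20, window=5):
        p = np.full((n, n), value)
        m = np.zeros((n, n), dtype=bool)
        m[2 : n - 2, 2 : n - 2] = True
        return ProbabilityHeatmap(p, m, window, 1, 19.53)

    def test_uniform_high_map_is_one_high_region(self):
        regions = extract_regions(self._uniform(0.9), min_area_px=1)
        assert len(regions.by_label("high")) == 1
        assert len(regions.by_label("low")) == 0
        assert regions.by_label("high")[0].area_px == 16 * 16

    def test_embedded_low_block_found_with_exact_area(self):
        hm = self._uniform(0.9)
        hm.probabilities[5:15, 5:15] = 0.1
        regions = extract_regions(hm, min_area_px=4)
        low = regions.by_label("low")
        assert len(low) == 1 and low[0].area_px == 100
        assert len(low[0].boundary_nm) > 0

    def test_min_area_filters_small_components(self):
        hm = self._uniform(0.9)
        hm.probabilities[5, 5] = 0.1
        assert extract_regions(hm, min_area_px=4).by_label("low") == []

    def test_boundary_in_physical_nm(self):
        hm = self._uniform(0.9)
        regions = extract_regions(hm, min_area_px=1)
        b = regions.by_label("high")[0].boundary_nm
        assert b.max() <= 20 * 19.53 and b.min() >= 0

    def test_regions_json(self, tmp_path):
        regions = extract_regions(self._uniform(0.2), min_area_px=1)
        regions.to_json(tmp_path / "r.json")
        import json

        data = json.loads((tmp_path / "r.json").read_text())
        assert data[0]["label"] == "low" and data[0]["area_px"] == 256
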