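import numpy as np
import pytest

from afmtexture import compute_parameter, default_config, nano_contrast_config
from afmtexture.synthetic import (
    ChannelSpec,
    CompositeCell,
    SyntheticConfig,
    TextureSpec,
    add_bumps,
    gaussian_random_field,
    generate_cell,
    generate_composite,
    generate_dataset,
    read_dataset,
    write_dataset,
)


def _plain_spec(field_amp=1.0, **kw):
    base = dict(
        field_corr_len_nm=160.0,
        field_amp=field_amp,
        bump_density_per_um2=0.0,
        bump_diam_nm=400.0,
        bump_height=0.0,
        nano_feature_size_nm=40.0,
        nano_feature_amp=0.0,
    )
    base.update(kw)
    return TextureSpec(**base)


def _config(low, high, n=64, **kw):
    kw.setdefault("amp_jitter_sd", 0.0)
    return SyntheticConfig(
        rows=n,
        cols=n,
        channels=(ChannelSpec("height", "nm", low, high),),
        **kw,
    )


class TestGaussianRandomField:
    def test_zero_amplitude_gives_zero_grid(self):
        assert np.all(gaussian_random_field(32, 32, 4.0, 0.0, 0) == 0)

    def test_sample_rms_is_exact(self):
        g = gaussian_random_field(128, 128, 8.0, 2.5, 3)
        assert np.sqrt(np.mean(g**2)) == pytest.approx(2.5, abs=1e-9)
        assert g.mean() == pytest.approx(0.0, abs=1e-12)

    def test_autocorrelation_decay_length_matches_request(self):
        """1/e-decay of the autocorrelation ~ the requested correlation
        length, averaged over 10 seeds."""
        target = 8.0
        estimates = []
        for seed in range(10):
            g = gaussian_random_field(256, 256, target, 1.0, seed)
            f = np.fft.fft2(g)
            acf = np.fft.ifft2(f * np.conj(f)).real
            acf /= acf[0, 0]
            profile = acf[0, :32]
            k = np.argmax(profile < np.exp(-1))
            # linear interpolation of the 1/e crossing
            p0, p1 = profile[k - 1], profile[k]
            estimates.append(k - 1 + (p0 - np.exp(-1)) / (p0 - p1))
        assert np.mean(estimates) == pytest.approx(target, rel=0.25)

    def test_seed_determinism(self):
        a = gaussian_random_field(64, 64, 4.0, 1.0, 11)
        b = gaussian_random_field(64, 64, 4.0, 1.0, 11)
        np.testing.assert_array_equal(a, b)


class TestAddBumps:
    def test_zero_density_leaves_grid_unchanged(self):
        grid = np.random.default_rng(0).standard_normal((64, 64))
        out = add_bumps(grid, 0.0, 400.0, 1.0, 19.53, seed=1)
        np.testing.assert_array_equal(out, grid)

    def test_single_bump_peaks_at_its_centre(self):
        grid = np.zeros((64, 64))
        out = add_bumps(
            grid, 0.0, 400.0, 2.0, 19.53, seed=0, centers=np.array([[32.0, 32.0]])
        )
        assert out[32, 32] == pytest.approx(2.0, rel=0.01)
        assert out.max() == out[32, 32]

    def test_bump_count_is_poisson_with_expected_rate(self):
        # 2 bumps/um^2 on ~6.25 um^2 -> lambda = 12.5 per grid
        counts = []
        pitch, n = 19.53, 128
        lam = 2.0 * n * n * pitch**2 / 1e6
        for seed in range(40):
            grid = add_bumps(np.zeros((n, n)), 2.0, 100.0, 1.0, pitch, seed=seed)
            # count local maxima above half height as a bump proxy is fragile;
            # instead count via total added volume / single-bump volume
            single = add_bumps(
                np.zeros((n, n)), 0.0, 100.0, 1.0, pitch, 0, centers=np.array([[64.0, 64.0]])
            ).sum()
            counts.append(grid.sum() / single)
        mean = np.mean(counts)
        assert abs(mean - lam) < 3 * np.sqrt(lam / len(counts))


class TestGenerateCell:
    def test_same_seed_reproduces_the_record(self):
        cfg = default_config(64, 64)
        a = generate_cell(cfg, "low", "c", 5)
        b = generate_cell(cfg, "low", "c", 5)
        for k in a.channels:
            np.testing.assert_array_equal(a.channels[k].values, b.channels[k].values)

    def test_sq_ratio_follows_configured_field_amplitudes(self):
        cfg = _config(_plain_spec(1.0), _plain_spec(2.0))
        low = generate_cell(cfg, "low", "c", 7)
        high = generate_cell(cfg, "high", "c", 7)
        sq_low = compute_parameter(low.channels["height"], "Sq")
        sq_high = compute_parameter(high.channels["height"], "Sq")
        assert sq_high / sq_low == pytest.approx(2.0, rel=0.10)

    def test_default_config_has_four_coregistered_channels(self):
        cell = generate_cell(default_config(64, 64), "high", "c", 1)
        assert len(cell.channels) == 4
        assert cell.shape == (64, 64)
        assert {im.units for im in cell.channels.values()} == {"nm", "nN"}

    def test_adhesion_channels_are_non_negative(self):
        cell = generate_cell(default_config(64, 64), "low", "c", 2)
        for kind, im in cell.channels.items():
            if im.units == "nN":
                assert im.values.min() >= 0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            generate_cell(default_config(64, 64), "medium", "c", 0)


class TestGenerateDataset:
    def test_balance_determinism_and_distinctness(self):
        cfg = default_config(64, 64)
        cells = generate_dataset(cfg, 3, 9)
        assert [c.label for c in cells] == ["low"] * 3 + ["high"] * 3
        again = generate_dataset(cfg, 3, 9)
        np.testing.assert_array_equal(
            cells[0].channels["height"].values, again[0].channels["height"].values
        )
        assert not np.array_equal(
            cells[0].channels["height"].values, cells[1].channels["height"].values
        )

    def test_round_trip_through_disk_layout(self, tmp_path):
        cells = generate_dataset(default_config(64, 64), 2, 1)
        write_dataset(cells, tmp_path / "ds")
        back = read_dataset(tmp_path / "ds")
        assert [c.cell_id for c in back] == [c.cell_id for c in cells]
        np.testing.assert_allclose(
            back[0].channels["height"].values,
            cells[0].channels["height"].values,
            rtol=1e-15,
        )


class TestGenerateComposite:
    def test_all_low_mask_reproduces_the_low_cell(self):
        cfg = nano_contrast_config(64, 64)
        mask = np.zeros((64, 64), dtype=bool)
        comp = generate_composite(cfg, mask, 13)
        pure = generate_cell(cfg, "low", "composite", 13)
        for k in pure.channels:
            np.testing.assert_allclose(
                comp.record.channels[k].values, pure.channels[k].values, atol=1e-12
            )

    def test_half_mask_gives_half_class_statistics(self):
        cfg = _config(_plain_spec(1.0), _plain_spec(3.0), n=128)
        mask = np.zeros((128, 128), dtype=bool)
        mask[:, 64:] = True
        comp = generate_composite(cfg, mask, 21)
        v = comp.record.channels["height"].values
        sq_left = np.sqrt(np.mean((v[:, :56] - v[:, :56].mean()) ** 2))
        sq_right = np.sqrt(np.mean((v[:, 72:] - v[:, 72:].mean()) ** 2))
        lo = generate_cell(cfg, "low", "composite", 21).channels["height"].values
        hi = generate_cell(cfg, "high", "composite", 21).channels["height"].values
        sq_lo = np.sqrt(np.mean((lo[:, :56] - lo[:, :56].mean()) ** 2))
        sq_hi = np.sqrt(np.mean((hi[:, 72:] - hi[:, 72:].mean()) ** 2))
        assert sq_left == pytest.approx(sq_lo, rel=0.10)
        assert sq_right == pytest.approx(sq_hi, rel=0.10)

    def test_mask_round_trips_with_the_record(self, tmp_path):
        cfg = nano_contrast_config(64, 64)
        mask = np.zeros((64, 64), dtype=bool)
        mask[10:30, 20:50] = True
        comp = generate_composite(cfg, mask, 3)
        comp.save(tmp_path / "comp")
        back = CompositeCell.load(tmp_path / "comp")
        np.testing.assert_array_equal(back.mask, mask)
        assert back.record.cell_id == comp.record.cell_id

    def test_wrong_mask_shape_rejected(self):
        with pytest.raises(ValueError):
            generate_composite(nano_contrast_config(64, 64), np.zeros((32, 32)), 0)


class TestSpecValidation:
    def test_bad_texture_and_config_values(self):
        with pytest.raises(ValueError):
            _plain_spec(field_corr_len_nm=-1.0)
        with pytest.raises(ValueError):
            _plain_spec(bump_density_per_um2=-0.1)
        with pytest.raises(ValueError):
            _plain_spec(nano_style="fractal")
        with pytest.raises(ValueError):
            _config(_plain_spec(), _plain_spec(), cross_channel_corr=1.5)
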