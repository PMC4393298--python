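"""Simulator contracts: cluster statistics, rendering physics, determinism."""

import numpy as np
import pytest

from longtemplate.flowcell_sim import (
    BASES,
    ClusterGroundTruth,
    SimConfig,
    generate_clusters,
    ground_truth_frame,
    read_cycle_tiffs,
    read_ground_truth,
    render_cycle,
    simulate_run,
    write_cycle_tiffs,
    write_run,
)


class TestGenerateClusters:
    def test_zero_density_gives_no_clusters(self):
        cfg = SimConfig(optimal_density=0.0, seed=1)
        assert generate_clusters(cfg) == []

    def test_poisson_count_near_expectation(self):
        # E[count]=2000 on a 512x512 tile; 3 sigma band of a Poisson draw
        cfg = SimConfig(
            optimal_density=2000 / 512**2, density_fraction=1.0, seed=42
        )
        n = len(generate_clusters(cfg))
        assert abs(n - 2000) <= 3 * np.sqrt(2000)

    def test_full_lowdiv_fraction_forces_prefix(self):
        cfg = SimConfig(
            tile_width_px=128,
            tile_height_px=128,
            n_cycles=14,
            lowdiv_fraction=1.0,
            seed=3,
        )
        clusters = generate_clusters(cfg)
        assert clusters
        for c in clusters:
            assert any(
                c.sequence.startswith(p[: cfg.n_cycles]) for p in cfg.prefix_sequences
            )
            assert len(c.sequence) == cfg.n_cycles
            assert 0 <= c.x_px < cfg.tile_width_px
            assert 0 <= c.y_px < cfg.tile_height_px

    def test_lowdiv_fraction_mixture_share(self):
        cfg = SimConfig(n_cycles=12, lowdiv_fraction=0.3, seed=5)
        clusters = generate_clusters(cfg)
        share = np.mean([c.sample_label == "lowdiv" for c in clusters])
        assert share == pytest.approx(0.3, abs=0.03)

    def test_exclusion_radius_enforces_spacing(self):
        from scipy.spatial import cKDTree

        cfg = SimConfig(
            tile_width_px=256, tile_height_px=256, exclusion_radius_px=1.5, seed=9
        )
        clusters = generate_clusters(cfg)
        xy = np.array([[c.x_px, c.y_px] for c in clusters])
        assert not cKDTree(xy).query_pairs(1.5)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(density_fraction=-0.1)
        with pytest.raises(ValueError):
            SimConfig(lowdiv_fraction=1.2)
        with pytest.raises(ValueError):
            SimConfig(prefix_sequences=("TCGAX",))
        with pytest.raises(ValueError):
            SimConfig(crosstalk=((1.0, 0.5, 0, 0),) * 4)


class TestRenderCycle:
    def _noiseless(self, **kw):
        defaults = dict(
            tile_width_px=96,
            tile_height_px=96,
            n_cycles=1,
            background_level=0.0,
            read_noise_sd=0.0,
            seed=0,
        )
        defaults.update(kw)
        return SimConfig(**defaults)

    def test_single_channel_signal_when_all_share_base(self):
        cfg = self._noiseless()
        clusters = [
            ClusterGroundTruth(i, 20.0 + 10 * i, 48.0, "T", 3000.0) for i in range(5)
        ]
        ims = render_cycle(clusters, 1, cfg)
        total = sum(im.sum() for im in ims.channel_images.values())
        assert ims.channel_images["T"].sum() / total >= 0.99

    def test_no_clusters_zero_background_gives_zero_images(self):
        cfg = self._noiseless()
        ims = render_cycle([], 1, cfg)
        for b in BASES:
            assert not ims.channel_images[b].any()

    def test_spot_integrates_to_amplitude(self):
        cfg = self._noiseless()
        ims = render_cycle([ClusterGroundTruth(0, 47.3, 51.8, "C", 5000.0)], 1, cfg)
        total = sum(im.sum() for im in ims.channel_images.values())
        assert total == pytest.approx(5000.0, rel=0.01)

    def test_linearity_in_amplitude(self):
        cfg = self._noiseless(seed=4)
        base = [
            ClusterGroundTruth(i, 10 + 17.3 * i, 30 + 11.1 * i, "ACGT"[i % 4], 2000.0)
            for i in range(4)
        ]
        doubled = [
            ClusterGroundTruth(c.id, c.x_px, c.y_px, c.sequence, 2 * c.amplitude)
            for c in base
        ]
        im1 = render_cycle(base, 1, cfg)
        im2 = render_cycle(doubled, 1, cfg)
        for b in BASES:
            assert np.array_equal(2 * im1.channel_images[b], im2.channel_images[b])

    def test_composition_tracks_base_frequencies(self):
        # the per-cycle pie-chart property: channel share of total signal
        # equals the amplitude-weighted base composition at that cycle
        cfg = SimConfig(
            tile_width_px=256,
            tile_height_px=256,
            n_cycles=4,
            background_level=0.0,
            read_noise_sd=0.0,
            seed=7,
        )
        clusters = generate_clusters(cfg)
        ims = render_cycle(clusters, 2, cfg)
        total = sum(im.sum() for im in ims.channel_images.values())
        amp_total = sum(c.amplitude for c in clusters)
        for b in BASES:
            channel_share = ims.channel_images[b].sum() / total
            comp_share = (
                sum(c.amplitude for c in clusters if c.sequence[1] == b) / amp_total
            )
            assert channel_share == pytest.approx(comp_share, abs=0.02)

    def test_crosstalk_mixes_channels(self):
        m = ((0.9, 0.1, 0, 0), (0, 1.0, 0, 0), (0, 0, 1.0, 0), (0, 0, 0, 1.0))
        cfg = self._noiseless(crosstalk=m)
        ims = render_cycle([ClusterGroundTruth(0, 48, 48, "A", 1000.0)], 1, cfg)
        total = sum(im.sum() for im in ims.channel_images.values())
        assert ims.channel_images["C"].sum() / total == pytest.approx(0.1, abs=0.01)

    def test_cycle_out_of_range_rejected(self):
        cfg = self._noiseless()
        with pytest.raises(ValueError):
            render_cycle([], 2, cfg)


class TestSimulateRun:
    def test_one_image_set_per_cycle_and_offsets(self):
        cfg = SimConfig(tile_width_px=96, tile_height_px=96, n_cycles=3, seed=2)
        image_sets, _ = simulate_run(cfg)
        assert [ims.cycle for ims in image_sets] == [1, 2, 3]
        assert image_sets[0].applied_offset == (0.0, 0.0)
        for ims in image_sets[1:]:
            assert all(abs(v) <= cfg.drift_px for v in ims.applied_offset)

    def test_drift_disabled_keeps_all_offsets_zero(self):
        cfg = SimConfig(tile_width_px=96, tile_height_px=96, n_cycles=4, drift_px=0, seed=2)
        image_sets, _ = simulate_run(cfg)
        assert all(ims.applied_offset == (0.0, 0.0) for ims in image_sets)

    def test_same_seed_reproduces_run_exactly(self):
        cfg = SimConfig(tile_width_px=128, tile_height_px=128, n_cycles=2, seed=17)
        ims_a, cl_a = simulate_run(cfg)
        ims_b, cl_b = simulate_run(cfg)
        assert [c.sequence for c in cl_a] == [c.sequence for c in cl_b]
        for a, b in zip(ims_a, ims_b):
            for base in BASES:
                assert np.array_equal(a.channel_images[base], b.channel_images[base])


class TestRoundTrips:
    def test_tiff_round_trip_is_quantized_image(self, tmp_path):
        cfg = SimConfig(tile_width_px=64, tile_height_px=64, n_cycles=1, seed=8)
        ims, _ = simulate_run(cfg)
        write_cycle_tiffs(ims[0], tmp_path)
        back = read_cycle_tiffs(1, tmp_path)
        for b in BASES:
            assert np.array_equal(
                back.channel_images[b], np.round(ims[0].channel_images[b])
            )

    def test_run_manifest_and_ground_truth_round_trip(self, tmp_path):
        cfg = SimConfig(tile_width_px=64, tile_height_px=64, n_cycles=2, seed=8)
        ims, clusters = simulate_run(cfg)
        write_run(ims, clusters, cfg, tmp_path)
        assert (tmp_path / "run.yaml").exists()
        back = read_ground_truth(tmp_path / "ground_truth.tsv")
        assert len(back) == len(clusters)
        assert back[0].sequence == clusters[0].sequence
        assert back[-1].x_px == pytest.approx(clusters[-1].x_px)
        assert set(ground_truth_frame(clusters).columns) >= {
            "id", "x", "y", "sequence", "amplitude", "sample_label",
        }
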