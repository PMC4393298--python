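"""Template generation: spot detection, golden/silver ranking, registration,
the low-diversity failure mode, and the memory model."""

import numpy as np
import pytest

from longtemplate.flowcell_sim import ClusterGroundTruth, SimConfig, generate_clusters, render_cycle, simulate_run
from longtemplate.template_engine import (
    MemoryModel,
    Template,
    TemplateConfig,
    build_template,
    detect_spots,
    estimate_template_memory,
    max_template_length,
    rank_cycles,
    register_offset,
    template_recovery,
)
from conftest import true_positions_in_template_frame


def _noiseless_cfg(**kw):
    defaults = dict(
        tile_width_px=96,
        tile_height_px=96,
        n_cycles=1,
        background_level=100.0,
        read_noise_sd=2.0,
        seed=0,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestDetectSpots:
    def test_well_separated_spots_found_accurately(self):
        cfg = _noiseless_cfg()
        truth = [(30.0, 40.0), (30.0 + 6 * cfg.psf_sigma_px, 40.0)]
        clusters = [
            ClusterGroundTruth(i, x, y, "A", 4000.0) for i, (x, y) in enumerate(truth)
        ]
        spots = detect_spots(
            render_cycle(clusters, 1, cfg), TemplateConfig(detection_threshold_sd=6)
        )
        assert len(spots) == 2
        for x, y in truth:
            d = np.hypot(spots[:, 0] - x, spots[:, 1] - y).min()
            assert d <= 0.5

    def test_sub_sigma_pair_merges_to_one_spot(self):
        # two equal spots 0.8 sigma apart in the same channel have a single
        # summed-Gaussian maximum, hence one detected cluster
        cfg = _noiseless_cfg()
        s = 0.8 * cfg.psf_sigma_px
        clusters = [
            ClusterGroundTruth(0, 40.0, 40.0, "A", 4000.0),
            ClusterGroundTruth(1, 40.0 + s, 40.0, "A", 4000.0),
        ]
        spots = detect_spots(
            render_cycle(clusters, 1, cfg), TemplateConfig(detection_threshold_sd=6)
        )
        assert len(spots) == 1

    def test_empty_image_detects_nothing(self):
        cfg = _noiseless_cfg(read_noise_sd=0.0, background_level=0.0)
        spots = detect_spots(render_cycle([], 1, cfg), TemplateConfig())
        assert len(spots) == 0

    def test_oracle_on_well_separated_field(self):
        # spacing >= 4 sigma and high SNR: every cluster found, <=0.5 px error
        cfg = _noiseless_cfg(
            tile_width_px=256, tile_height_px=256, exclusion_radius_px=5.0, seed=13
        )
        clusters = generate_clusters(cfg)
        spots = detect_spots(
            render_cycle(clusters, 1, cfg), TemplateConfig(detection_threshold_sd=6)
        )
        assert len(spots) == len(clusters)
        errs = [
            np.hypot(spots[:, 0] - c.x_px, spots[:, 1] - c.y_px).min() for c in clusters
        ]
        assert np.mean(errs) <= 0.5


class TestRankCycles:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([100, 120, 90, 110], (2, 4)),
            ([50, 50], (1, 2)),  # tie: earlier cycle wins
            ([5, 9, 9], (2, 3)),
        ],
    )
    def test_golden_and_silver_selection(self, counts, expected):
        assert rank_cycles(counts) == expected

    def test_single_cycle_rejected(self):
        with pytest.raises(ValueError):
            rank_cycles([7])

    def test_lowdiv_run_picks_diverse_cycles(self, lowdiv_run):
        # with a 5 nt shared prefix and a 7-cycle template, the two
        # diverse cycles (6, 7) detect the most clusters
        _, image_sets, _ = lowdiv_run
        template = build_template(image_sets, TemplateConfig(template_cycle_count=7))
        assert {template.golden_cycle, template.silver_cycle} == {6, 7}


@pytest.fixture(scope="module")
def scene():
    cfg = SimConfig(n_cycles=4, seed=5, drift_px=0, tile_width_px=256, tile_height_px=256)
    clusters = generate_clusters(cfg)
    template = build_template(
        [render_cycle(clusters, c, cfg, (0, 0)) for c in (1, 2)],
        TemplateConfig(template_cycle_count=2),
    )
    return cfg, clusters, template


class TestRegisterOffset:

    @pytest.mark.parametrize(
        "applied,tol",
        [((0.0, 0.0), 0.25), ((2.0, -1.0), 0.25), ((1.5, 0.5), 0.25), ((-3.0, 2.0), 0.25)],
    )
    def test_known_offsets_recovered(self, scene, applied, tol):
        cfg, clusters, template = scene
        ims = render_cycle(clusters, 3, cfg, applied)
        dx, dy = register_offset(ims, template, TemplateConfig())
        assert dx == pytest.approx(applied[0], abs=tol)
        assert dy == pytest.approx(applied[1], abs=tol)

    def test_integer_offsets_exact_at_integer_resolution(self, scene):
        cfg, clusters, template = scene
        ims = render_cycle(clusters, 4, cfg, (2.0, -1.0))
        dx, dy = register_offset(ims, template, TemplateConfig())
        assert (round(dx), round(dy)) == (2, -1)

    def test_empty_template_rejected(self, scene):
        cfg, clusters, _ = scene
        ims = render_cycle(clusters, 1, cfg, (0, 0))
        with pytest.raises(ValueError):
            register_offset(ims, np.empty((0, 2)), TemplateConfig())


class TestBuildTemplate:
    def test_diverse_template_count_close_to_truth(self):
        # well-separated diverse clusters: template count within 2% of truth
        cfg = SimConfig(n_cycles=4, seed=31, exclusion_radius_px=4.0)
        image_sets, clusters = simulate_run(cfg)
        template = build_template(image_sets, TemplateConfig())
        assert abs(len(template) - len(clusters)) <= 0.02 * len(clusters)

    def test_lowdiv_short_template_fails_long_template_recovers(self, lowdiv_run):
        _, image_sets, clusters = lowdiv_run
        short = build_template(image_sets, TemplateConfig(template_cycle_count=4))
        long = build_template(image_sets, TemplateConfig(template_cycle_count=7))
        rec_short = template_recovery(
            short, true_positions_in_template_frame(image_sets, short, clusters)
        )
        rec_long = template_recovery(
            long, true_positions_in_template_frame(image_sets, long, clusters)
        )
        assert rec_short < 0.80
        assert rec_long >= 0.95

    def test_recovery_monotone_in_template_length(self, lowdiv_run):
        _, image_sets, clusters = lowdiv_run
        recs = []
        for k in (4, 5, 6, 7):
            t = build_template(image_sets, TemplateConfig(template_cycle_count=k))
            recs.append(
                template_recovery(
                    t, true_positions_in_template_frame(image_sets, t, clusters)
                )
            )
        # non-decreasing up to barcode length + 2, small seed-level slack
        assert all(b >= a - 0.005 for a, b in zip(recs, recs[1:]))
        assert recs[-1] > recs[0]

    def test_template_is_immutable(self, lowdiv_run):
        _, image_sets, _ = lowdiv_run
        template = build_template(image_sets, TemplateConfig(template_cycle_count=4))
        with pytest.raises((AttributeError, TypeError)):
            template.positions = ()
        with pytest.raises(TypeError):
            template.positions[0] = (0.0, 0.0)

    def test_missing_cycles_rejected(self, lowdiv_run):
        _, image_sets, _ = lowdiv_run
        with pytest.raises(ValueError):
            build_template(image_sets[:3], TemplateConfig(template_cycle_count=5))


class TestMemoryModel:
    def test_hiseq_tile_memory_per_cycle(self):
        model = MemoryModel()
        _, gb = estimate_template_memory(model, 1)
        assert gb == pytest.approx(2.6, abs=0.05)

    @pytest.mark.parametrize("cycles,expected_gb", [(4, 10.4), (20, 52.0)])
    def test_memory_scales_linearly_to_published_values(self, cycles, expected_gb):
        model = MemoryModel()
        _, gb = estimate_template_memory(model, cycles)
        assert gb == pytest.approx(expected_gb, rel=0.01)

    def test_exact_linearity(self):
        model = MemoryModel(image_width_px=1000, image_height_px=777)
        b1, _ = estimate_template_memory(model, 1)
        for length in (2, 5, 13):
            bl, _ = estimate_template_memory(model, length)
            assert bl == length * b1

    @pytest.mark.parametrize(
        "ram,per_cycle,expected", [(48, 4, 12), (192, 4, 48), (4, 4, 1), (7.9, 4, 1)]
    )
    def test_max_template_length(self, ram, per_cycle, expected):
        assert max_template_length(ram, per_cycle) == expected
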