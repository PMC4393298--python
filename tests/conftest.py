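import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from longtemplate import SimConfig, TemplateConfig, simulate_run, build_template


@pytest.fixture(scope="session")
def small_diverse_run():
    """A small fully diverse tile run with drift, shared across tests."""
    config = SimConfig(
        tile_width_px=256, tile_height_px=256, n_cycles=8, seed=11
    )
    image_sets, clusters = simulate_run(config)
    return config, image_sets, clusters


@pytest.fixture(scope="session")
def lowdiv_run():
    """A 100% low-diversity run (5 nt shared prefix) at normal density."""
    config = SimConfig(
        n_cycles=9, seed=21, lowdiv_fraction=1.0, prefix_sequences=("TCGAG",)
    )
    image_sets, clusters = simulate_run(config)
    return config, image_sets, clusters


def true_positions_in_template_frame(image_sets, template, clusters):
    off = image_sets[template.golden_cycle - 1].applied_offset
    return np.array([[c.x_px + off[0], c.y_px + off[1]] for c in clusters])
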