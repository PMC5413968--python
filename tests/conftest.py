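"""Shared fixtures: synthetic screens are expensive, so they are built once
per session and reused across the statistical, event and acceptance tests."""

import numpy as np
import pytest

from densdelta import stat_model as sm
from densdelta.grid_io import DensityMap
from densdelta.synthetic import EventSpec, SyntheticConfig, simulate_screen

SCREEN_SEED = 1


@pytest.fixture(scope="session")
def screen():
    """Default study conditions: 40 hit-free crystals plus five bound states
    at occupancies 0.3–0.7, all at one resolution so every dataset shares a
    characterization set."""
    cfg = SyntheticConfig(
        n_ground=40,
        events=[EventSpec(occupancy=o, residue_index=i % 3)
                for i, o in enumerate([0.3, 0.4, 0.5, 0.6, 0.7])],
        resolution_range=(2.0, 2.0),
        seed=SCREEN_SEED,
    )
    datasets, truth = simulate_screen(cfg)
    return cfg, datasets, truth


@pytest.fixture(scope="session")
def screen_model(screen):
    """Ensemble statistics fitted on the full default screen (hits included,
    the default characterization policy)."""
    _, datasets, _ = screen
    return sm.fit_model([d.map for d in datasets], [d.id for d in datasets])


@pytest.fixture(scope="session")
def occupancy_series():
    """One screen with three bound datasets at the same pocket, occupancies
    0.2/0.4/0.6, and a ground-only model — for background-correction trend
    checks at fixed noise."""
    cfg = SyntheticConfig(
        n_ground=40,
        events=[EventSpec(occupancy=o, residue_index=0) for o in (0.2, 0.4, 0.6)],
        resolution_range=(2.0, 2.0),
        seed=SCREEN_SEED,
    )
    datasets, truth = simulate_screen(cfg)
    model = sm.fit_model([d.map for d in datasets[:40]],
                         [d.id for d in datasets[:40]])
    return datasets, truth, model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_map(values, spacing=0.5, origin=(0.0, 0.0, 0.0)):
    return DensityMap(np.asarray(values, dtype=float), spacing,
                      np.asarray(origin, dtype=float))


def masked_corr(a, b, mask):
    x, y = a[mask], b[mask]
    x = x - x.mean()
    y = y - y.mean()
    return float((x * y).sum() / np.sqrt((x * x).sum() * (y * y).sum()))
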