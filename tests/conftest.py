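"""Shared fixtures: all data is generated by the bundled simulator at test
time; the heavier artifacts (pre-trained encoder, labelled window pools) are
session-scoped so the reconstruction, recovery and transfer tests share them.
"""

import numpy as np
import pytest

import larvaction as la


@pytest.fixture(scope="session")
def window_cfg():
    return la.WindowingConfig()


@pytest.fixture(scope="session")
def pretrain_windows(window_cfg):
    """2000 posture windows from mixed-action tracks (unlabelled pool)."""
    rng = np.random.default_rng(0)
    windows = []
    while len(windows) < 2000:
        steps = [(str(a), float(rng.uniform(2, 4)))
                 for a in rng.choice(la.ACTIONS, size=4)]
        track, _ = la.simulate_track(
            la.SimScript(steps=steps, seed=int(rng.integers(2**31))))
        windows.extend(la.extract_windows(track, window_cfg)[::2])
    return windows[:2000]


@pytest.fixture(scope="session")
def pretrained_model(pretrain_windows):
    """Encoder pre-trained for 200 epochs on the unlabelled pool."""
    return la.pretrain(pretrain_windows, la.TrainConfig(epochs=200, seed=0))


@pytest.fixture(scope="session")
def labelled_pool(window_cfg):
    """500 labelled windows per action class (training pool)."""
    windows, names = la.make_labelled_windows(window_cfg, 500, seed=1)
    return list(zip(windows, names))


@pytest.fixture(scope="session")
def test_pool(window_cfg):
    """100 labelled windows per action class (held-out test set)."""
    windows, names = la.make_labelled_windows(window_cfg, 100, seed=2)
    return list(zip(windows, names))


@pytest.fixture(scope="session")
def trained_tagger(pretrained_model, labelled_pool):
    return la.train_tagger(pretrained_model, labelled_pool,
                           la.TrainConfig(epochs=150, seed=0))
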