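"""Shared fixtures: simulated genomes, datasets and a trained model.

The expensive fixtures (small simulated dataset, trained reduced-width
model) are session-scoped and shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

import resplice as rs


TRAIN_SEED = 1  # pipeline seed for the shared trained model


@pytest.fixture(scope="session")
def tiny_sim():
    """A tiny simulated genome with ground truth (written to disk)."""
    return rs.simulate_genome(rs.SimulatorConfig.tiny(seed=3))


@pytest.fixture(scope="session")
def tiny_sim_paths(tiny_sim, tmp_path_factory):
    out = tmp_path_factory.mktemp("tiny_sim")
    return tiny_sim.write(out / "sim")


@pytest.fixture(scope="session")
def tiny_splits():
    splits, manifest = rs.make_fixture("tiny", "donor", seed=3)
    return splits, manifest


@pytest.fixture(scope="session")
def small_donor_encoded():
    """Encoded small donor dataset (the main training fixture)."""
    splits, _ = rs.make_fixture("small", "donor", seed=TRAIN_SEED)
    return rs.encode_splits(splits)


@pytest.fixture(scope="session")
def trained_small(small_donor_encoded):
    """Reduced-width network trained on the small donor fixture under the
    standard protocol (shared by the end-to-end and interpretation tests)."""
    config = rs.TrainingConfig(epochs=10, repeats=1, seed=TRAIN_SEED)
    result = rs.fit(rs.NetworkSpec.reduced(), small_donor_encoded, config)
    return result


@pytest.fixture(scope="session")
def attribution_small(trained_small, small_donor_encoded):
    """Expected-gradients attribution for 100 positive test windows of the
    trained model (shared: attribution is the slow interpretation step)."""
    X, Y = small_donor_encoded["test"]
    Xp = X[Y[:, 0] == 1][:100]
    return rs.attribute(trained_small.network, Xp,
                        n_references=8, n_steps=16, seed=0)


@pytest.fixture(scope="session")
def toy_spec():
    """A miniature spec for fast forward/backward tests."""
    return rs.NetworkSpec(
        window_length=24,
        stem=rs.StageConfig(n=4, k=3),
        stages=(
            rs.StageConfig(4, 3, 1),
            rs.StageConfig(6, 3, 2),
            rs.StageConfig(6, 3, 2),
            rs.StageConfig(8, 3, 2),
        ),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
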