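import numpy as np
import pytest

from treerow import PromptConfig, SceneConfig, build_prompts, generate_batch, generate_scene


@pytest.fixture(scope="session")
def scene():
    """One default 3-tree scene with truth."""
    cfg = SceneConfig(seed=42)
    image, truth = generate_scene(cfg)
    return cfg, image, truth


@pytest.fixture(scope="session")
def batch100():
    """The 100-scene seeded batch used by the statistical checks."""
    return generate_batch(100, seed=2024)


@pytest.fixture(scope="session")
def batch20():
    return generate_batch(20, seed=7)


def true_heights(truth):
    return {rec.label: rec.height_px for rec in truth.per_tree}


def supervised_prompts(truth):
    """Prompts from trunk truth with per-tree true heights."""
    return build_prompts(
        truth.trunk_instances,
        PromptConfig(mode="supervised", height_px=1.0),
        height_px=true_heights(truth),
    )
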