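import numpy as np
import pytest

from cellvstain.core import DatasetDescriptor, seeded_rng
from cellvstain import synthdata as sd


@pytest.fixture(scope="session")
def round_scene():
    """A deterministic 3-cell round-style scene with ground truth."""
    return sd.generate_scene(3, "round", (64, 64), rng=seeded_rng(7))


@pytest.fixture(scope="session")
def protrusive_scene():
    return sd.generate_scene(3, "protrusive", (96, 96), rng=seeded_rng(5),
                             size_scale=1.3)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 12-pair round dataset on disk (manifest + TIFFs + truth)."""
    root = tmp_path_factory.mktemp("ds")
    desc = DatasetDescriptor(dataset_id="round_small")
    man = sd.make_dataset(desc, 12, "round", seeded_rng(3), root,
                          size=(64, 64), n_slices=3, n_test=3)
    return man


@pytest.fixture(scope="session")
def demo_summary(tmp_path_factory):
    """One full tiny-preset pipeline run shared by the acceptance suite."""
    from cellvstain.workbench import RunRecipe, run_recipe

    out = tmp_path_factory.mktemp("demo")
    return run_recipe(RunRecipe(seed=1, out_root=out))
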