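import numpy as np
import pytest

from circuitbench.examples import desk_scale_tree, load_example_tree


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def example_workdir(tmp_path_factory):
    """Materialized example configuration, full scale, resolved."""
    workdir = tmp_path_factory.mktemp("example")
    tree = load_example_tree(workdir)
    return workdir, tree


@pytest.fixture(scope="session")
def desk_model(example_workdir):
    """A small (~200 cortical neurons) push-pull model, built once."""
    from circuitbench.model import build_push_pull_model

    workdir, tree = example_workdir
    small = desk_scale_tree(tree)
    model = build_push_pull_model(small, np.random.default_rng(7), base_dir=workdir)
    return model, small
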