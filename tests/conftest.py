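import numpy as np
import pandas as pd
import pytest

from cernet import SimulationConfig, generate_bundle
from cernet.diffexpr import IntensityPanel
from cernet.io import fixtures_to_network_inputs, read_fixture_tables


def make_panel(foreground, background=None, flags=None, rna_class="mRNA",
               n_per_group=None):
    """Build a two-group IntensityPanel from a feature x sample array."""
    fg = np.atleast_2d(np.asarray(foreground, dtype=float))
    n, s = fg.shape
    assert s % 2 == 0
    half = s // 2
    samples = [f"dep_{i+1}" for i in range(half)] + \
              [f"hc_{i+1}" for i in range(half)]
    design = {x: ("depression" if x.startswith("dep") else "healthy")
              for x in samples}
    index = pd.Index([f"f{i}" for i in range(n)], name="feature_id")
    bg = (np.zeros_like(fg) if background is None
          else np.atleast_2d(np.asarray(background, dtype=float)))
    fl = (np.full(fg.shape, "P") if flags is None
          else np.atleast_2d(np.asarray(flags, dtype=object)))
    return IntensityPanel(
        rna_class=rna_class,
        foreground=pd.DataFrame(fg, index=index, columns=samples),
        background=pd.DataFrame(bg, index=index, columns=samples),
        flags=pd.DataFrame(fl, index=index, columns=samples),
        design=design,
    )


@pytest.fixture(scope="session")
def fixture_tables():
    return read_fixture_tables()


@pytest.fixture(scope="session")
def fixture_network_inputs(fixture_tables):
    return fixtures_to_network_inputs(fixture_tables)


@pytest.fixture(scope="session")
def small_bundle():
    config = SimulationConfig(n_mrna=300, n_lncrna=60, n_mirna=40, seed=11)
    bundle, truth = generate_bundle(config)
    return config, bundle, truth
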