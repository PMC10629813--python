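import pandas as pd
import pytest

from tadreg import SimulationConfig, simulate_bundle
from tadreg.pipeline import _load_tracks
from tadreg.intervals import read_intervals


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The default synthetic bundle (seed 1), generated once per session."""
    out = tmp_path_factory.mktemp("bundle")
    return simulate_bundle(SimulationConfig(seed=1), out)


@pytest.fixture(scope="session")
def bundle_tracks(default_bundle):
    return _load_tracks(default_bundle.paths["tracks_yaml"])


@pytest.fixture(scope="session")
def bundle_peaks(default_bundle):
    return read_intervals(default_bundle.paths["peaks"], "narrowPeak")


@pytest.fixture(scope="session")
def archetype_truth(default_bundle) -> pd.Series:
    return pd.read_csv(default_bundle.paths["truth_archetypes"],
                       sep="\t").set_index("peak_id")["archetype"]
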