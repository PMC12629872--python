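import numpy as np
import pytest

from cd9flow.listmode_io import EventTable, PanelConfig
from cd9flow.pipeline import run_sample
from cd9flow.synthetic import CHANNELS, generate_sample, make_fmo, preset


@pytest.fixture(scope="session")
def normal_spec():
    return preset("normal_marrow", seed=42)


@pytest.fixture(scope="session")
def normal_sample(normal_spec):
    """One 50k-event normal-marrow sample with truth labels."""
    return generate_sample(normal_spec)


@pytest.fixture(scope="session")
def normal_fmo_table(normal_spec):
    table, _ = generate_sample(make_fmo(normal_spec))
    return table


@pytest.fixture(scope="session")
def normal_result(normal_sample, normal_fmo_table):
    """Full pipeline result on the normal-marrow sample (FMO-calibrated)."""
    table, _ = normal_sample
    return run_sample(table, normal_fmo_table)


@pytest.fixture
def make_events():
    """Factory for tiny hand-constructed event tables.

    Rows are dicts of marker -> linear intensity; unspecified markers
    default to dim values (scatter set to a mid-size intact singlet).
    """

    defaults = {
        "FSC_A": 100_000.0, "FSC_H": 100_000.0, "SSC": 10_000.0,
        "CD45": 5_000.0, "CD9": 300.0, "CD10": 300.0, "CD19": 300.0,
        "CD20": 300.0, "CD22": 300.0, "CD24": 300.0, "CD34": 300.0,
        "CD38": 300.0, "CD58": 300.0,
    }

    def build(rows, sample_id="constructed"):
        data = np.array(
            [[{**defaults, **row}[ch] for ch in CHANNELS] for row in rows]
        )
        return EventTable(
            sample_id=sample_id,
            data=data.reshape(-1, len(CHANNELS)),
            channel_names=list(CHANNELS),
            marker_map=PanelConfig().resolve(list(CHANNELS)),
        )

    return build
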