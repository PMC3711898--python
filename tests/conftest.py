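import pandas as pd
import pytest

import crabtree as ct

PRESETS = ["strong_positive", "intermediate", "negative"]


@pytest.fixture(scope="session")
def noiseless_runs():
    """Noiseless simulation + extracted metrics per phenotype preset."""
    runs = {}
    for preset in PRESETS:
        params = ct.make_preset(preset)
        ts = ct.simulate_batch(params, seed=0)
        metrics = ct.extract_metrics(ts)
        runs[preset] = (params, ts, metrics)
    return runs


@pytest.fixture(scope="session")
def reference_records():
    return ct.load_reference_table()


@pytest.fixture(scope="session")
def analysis_set(reference_records):
    return ct.build_analysis_set(reference_records)


def make_timeseries(time_h, **columns) -> ct.CultureTimeSeries:
    """Small hand-built trajectory; unspecified channels default to 0."""
    n = len(time_h)
    data = {"time_h": time_h}
    for col in ct.simulator.TIMESERIES_COLUMNS[1:]:
        data[col] = columns.get(col, [0.0] * n)
    return ct.CultureTimeSeries(pd.DataFrame(data))
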