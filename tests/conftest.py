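import pytest

import hydrorat as hr


@pytest.fixture(scope="session")
def params() -> hr.ModelParams:
    return hr.ModelParams()


@pytest.fixture(scope="session")
def baseline(params) -> hr.BodyState:
    return hr.init_state(params)


@pytest.fixture(scope="session")
def control_run_20d(params) -> hr.TimeSeries:
    """One 20-day control simulation shared by the long-run tests."""
    return hr.simulate(params, hr.control(), days=20, seed=11)
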