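import pytest

import uhcpack as u


@pytest.fixture(scope="session")
def fixture_records():
    return u.builtin_fixture()


@pytest.fixture(scope="session")
def base_config():
    return u.AnalysisConfig()


@pytest.fixture(scope="session")
def calibration(fixture_records, base_config):
    """Calibrated 2000 Int$ -> 2015 US$ factor (structural landmark)."""
    return u.calibrate_conversion(fixture_records, base_config)


@pytest.fixture(scope="session")
def calibrated_solutions(fixture_records, base_config, calibration):
    """All three scenario solutions at the calibrated conversion factor."""
    cfg = base_config.with_(conversion_factor=calibration.factor)
    return {
        name: u.solve_scenario(fixture_records, cfg.with_(scenario=name))
        for name in ("variable_coverage", "equity_weighted", "all_or_nothing")
    }
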