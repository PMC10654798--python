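import pytest

from crcscreen import default_parameter_set, run_all_strategies

# published base-case (cost, life-years) pairs used as worked-example input
TABLE2_PAIRS = [
    ("Natural history", 6284.0, 35.574),
    ("FIT", 8223.0, 35.624),
    ("Colonoscopy", 9037.0, 35.672),
    ("Stool DNA", 11583.0, 35.641),
    ("Colonoscopy-LB", 12006.0, 35.680),
    ("LB", 15562.0, 35.581),
]


@pytest.fixture(scope="session")
def params():
    """Calibrated base-case parameter set (calibration run once per session)."""
    return default_parameter_set()


@pytest.fixture(scope="session")
def base_outcomes(params):
    """Base-case outcomes for all six strategies."""
    return run_all_strategies(params)


@pytest.fixture()
def table2_pairs():
    return list(TABLE2_PAIRS)
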