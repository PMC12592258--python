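import pytest

from lazdose.analysis import run_scenarios
from lazdose.calibration import calibrate, load_targets

SEED = 2025


@pytest.fixture(scope="session")
def targets():
    return load_targets()


@pytest.fixture(scope="session")
def calibrated(targets):
    """Model calibrated once per session to the packaged exposure table."""
    return calibrate(targets, seed=SEED)


@pytest.fixture(scope="session")
def study_report(calibrated, targets):
    """The four-scenario Monte Carlo study at n=10,000 per arm."""
    return run_scenarios(
        calibrated.typical,
        n=10000,
        seed=SEED,
        threshold=targets.threshold_mg_per_l,
        price_per_dosing_day=targets.price_per_dosing_day_usd,
    )
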