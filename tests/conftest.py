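import numpy as np
import pytest

from cropflux import FluxPartitionModel, chamber
from cropflux.synthetic import SeasonConfig, generate_closures, generate_season


@pytest.fixture(scope="session")
def noiseless_config():
    """Short zero-noise season for exact round-trip checks."""
    return SeasonConfig(
        start_doy=100,
        end_doy=160,
        lai_peak_doy=140,
        weather_noise=0.0,
        conc_noise_sd=0.0,
        refl_noise_sd=0.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def noiseless_truth(noiseless_config):
    return generate_season(noiseless_config)


def closures_to_records(truth, config, seed=99, discard_initial_s=10.0):
    """Process every campaign day's closures into QC'd flux records."""
    rng = np.random.default_rng(seed)
    records, dates = [], []
    for day in truth.campaign_days:
        for cl in generate_closures(day, truth, config, rng=rng):
            records.append(chamber.process_closure(cl, discard_initial_s))
            dates.append(day)
    return chamber.qc_filter(records), dates


@pytest.fixture(scope="session")
def noiseless_results(noiseless_truth, noiseless_config):
    records, dates = closures_to_records(noiseless_truth, noiseless_config)
    model = FluxPartitionModel(
        records,
        noiseless_truth.drivers,
        latitude=noiseless_config.latitude,
        record_dates=dates,
    )
    return model.fit()
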