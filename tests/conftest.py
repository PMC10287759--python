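import numpy as np
import pytest

from planksync import MonitoringSeries, SimSpec, generate_dataset


def make_series(values, variable="phytoplankton", start=(2001, 5), lake="testlake",
                gap_after=None):
    """Build a series of consecutive months, optionally with a winter gap.

    ``gap_after`` restarts the calendar at the same start month of the next
    year after that many samples, mimicking the unsampled cold period.
    """
    values = np.asarray(values, dtype=float)
    years, months = [], []
    y, m = start
    for i in range(values.size):
        if gap_after is not None and i > 0 and i % gap_after == 0:
            y += 1
            m = start[1]
        years.append(y + (m - 1) // 12)
        months.append((m - 1) % 12 + 1)
        m += 1
    return MonitoringSeries(lake=lake, variable=variable,
                            years=np.array(years), months=np.array(months),
                            values=values)


@pytest.fixture(scope="session")
def coupled_sim():
    """One simulated campaign under the default (temperature-coupled) conditions."""
    return generate_dataset(SimSpec(seed=11))


@pytest.fixture(scope="session")
def uncoupled_sim():
    """Matched campaign whose growth signal carries no seasonal phase."""
    return generate_dataset(SimSpec(seed=11, growth_amplitude=0.0,
                                    growth_noise_sd=0.15))
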