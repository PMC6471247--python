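import numpy as np
import pytest
from hypothesis import settings

from fermkin import TimeCourse, fractional_conversion

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

#: Nine-point sampling grid of a 48-h batch fermentation.
GRID = np.array([0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 24.0, 30.0, 48.0])


@pytest.fixture
def grid():
    return GRID.copy()


def make_curve(C0, Cinf, K, times=GRID, donor="O1", matrix="Mnc",
               replicate=1, analyte="acetate", corrected=True):
    """Noiseless fractional-conversion time course on the standard grid."""
    conc = fractional_conversion(C0, Cinf, K, times)
    return TimeCourse(donor, matrix, replicate, analyte,
                      np.asarray(times, float), conc, corrected=corrected)


@pytest.fixture
def curve_factory():
    return make_curve
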