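import numpy as np
import pandas as pd
import pytest

from ventbloom.config import CalibrationSpec, PipelineConfig
from ventbloom.profiles import FloatProfile


@pytest.fixture
def cfg():
    c = PipelineConfig()
    c.validate()
    return c


@pytest.fixture
def cal():
    return CalibrationSpec(dark=30.0, slope=0.01, f490=0.3)


def make_profile(pres, temp=None, psal=None, fluo=None, bbp=None, *,
                 day=True, time="2014-12-01T12:00", lat=-50.0, lon=30.0,
                 float_id="T1", cycle=1):
    """Convenience builder for small hand-made casts."""
    pres = np.asarray(pres, dtype=float)
    n = pres.size
    return FloatProfile(
        float_id=float_id, cycle=cycle, time=pd.Timestamp(time),
        lat=lat, lon=lon, day_flag=day,
        pres=pres,
        temp=np.full(n, 5.0) if temp is None else np.asarray(temp, float),
        psal=np.full(n, 34.0) if psal is None else np.asarray(psal, float),
        fluo=np.zeros(n) if fluo is None else np.asarray(fluo, float),
        bbp700=np.full(n, 5e-4) if bbp is None else np.asarray(bbp, float))


@pytest.fixture
def profile_builder():
    return make_profile
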