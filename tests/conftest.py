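import numpy as np
import pytest

from heliwork.campaign import FTIRecord
from heliwork.synthetic import CampaignConfig, iter_maneuvers

FS = 64.0


def make_fti(duration=30.0, ng=None, collective=None, theta=None, height=None,
             trigger=None, fs=FS):
    """Minimal hand-built FTI record; unspecified channels are benign constants."""
    n = int(duration * fs)
    t = np.arange(n) / fs
    zeros = np.zeros(n)

    def chan(x, default):
        if x is None:
            return np.full(n, default)
        return np.asarray(x, dtype=float)

    return FTIRecord(
        time=t,
        controls={
            "collective": chan(collective, 55.0),
            "lateral": np.full(n, 50.0),
            "longitudinal": np.full(n, 50.0),
            "pedal": np.full(n, 50.0),
        },
        fuel_lever=np.full(n, 80.0),
        ng=chan(ng, 85.0),
        nr=np.full(n, 390.0),
        tq=np.full(n, 50.0),
        theta=chan(theta, 3.0),
        phi=zeros, psi=zeros, p=zeros, q=zeros, r=zeros,
        height=chan(height, 500.0),
        airspeed=np.full(n, 70.0),
        trigger=chan(trigger, 0.0),
        sample_rate=fs,
    )


@pytest.fixture(scope="session")
def small_campaign():
    """Six-pilot campaign with all channels, reused across tests."""
    cfg = CampaignConfig(seed=11, pilots_per_group=(2, 2, 2), maneuvers_per_pilot=4)
    return cfg, list(iter_maneuvers(cfg))


@pytest.fixture(scope="session")
def fti_only_campaign():
    """Larger campaign without physiology, for event/reaction statistics."""
    cfg = CampaignConfig(seed=5, pilots_per_group=(2, 3, 3), maneuvers_per_pilot=10,
                         include_eda=False, include_ekg=False)
    return cfg, list(iter_maneuvers(cfg))
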