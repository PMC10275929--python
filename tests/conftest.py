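import numpy as np
import pytest

from physioaffect.cohort import SubjectParams, default_protocol, simulate_subject
from physioaffect.io import ChannelSignal, Recording, SelfReport, StimulusEvent
from physioaffect.study import subject_feature_table


@pytest.fixture
def small_recording() -> Recording:
    """A tiny hand-built 3-channel recording with two stimulus events."""
    rng = np.random.default_rng(0)
    dur = 80.0
    channels = {
        "gsr": ChannelSignal("gsr", "uS", 51.2, 5.0 + 0.01 * rng.standard_normal(int(dur * 51.2))),
        "ecg": ChannelSignal("ecg", "mV", 250.0, 0.02 * rng.standard_normal(int(dur * 250))),
        "resp_rate": ChannelSignal("resp_rate", "breaths/min", 25.0,
                                   15.0 + 0.05 * rng.standard_normal(int(dur * 25))),
    }
    events = [
        StimulusEvent("imgA", 7.0, 7.5, onset_s=40.0, cluster_quadrant="HAHV"),
        StimulusEvent("imgB", 2.5, 2.0, onset_s=60.0, cluster_quadrant="LALV"),
    ]
    reports = [
        SelfReport("imgA", 8, 7, 5.0),
        SelfReport("imgB", 2, 3, 6.0),
    ]
    return Recording("P00", channels, baseline_interval=(0.0, 35.0),
                     events=events, self_reports=reports)


@pytest.fixture(scope="session")
def sim_subject():
    """One full simulated session under the default protocol and effects."""
    params = SubjectParams.draw("P00", 42)
    return simulate_subject(params, default_protocol(1), seed=7)


@pytest.fixture(scope="session")
def sim_table(sim_subject):
    return subject_feature_table(sim_subject)
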