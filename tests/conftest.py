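import numpy as np
import pytest

from popsync.io_model import Session, SpikeTrain, StimulusEvent, UnitMeta


def make_train(unit_id, times, t_stop):
    return SpikeTrain(unit_id, np.asarray(times, dtype=float), t_stop)


def make_session(trains, depths=None, events=(), session_id="s"):
    depths = depths or [100.0] * len(trains)
    units = [(tr, UnitMeta(tr.unit_id, d, channel=i))
             for i, (tr, d) in enumerate(zip(trains, depths))]
    return Session(session_id, units, list(events))


@pytest.fixture
def indentation_events():
    """Ten 500 ms steps at 10 mN with 1.5 s baselines, 2.5 s apart."""
    return [StimulusEvent("indentation", 1.5 + 2.5 * k, 2.0 + 2.5 * k, k,
                          force_mN=10.0) for k in range(10)]


@pytest.fixture
def periodic_session(indentation_events):
    """Two regular-spiking units spanning the event block."""
    t_stop = 30.0
    a = make_train("a", np.arange(0.1, t_stop - 0.1, 0.05), t_stop)
    b = make_train("b", np.arange(0.11, t_stop - 0.1, 0.07), t_stop)
    return make_session([a, b], events=indentation_events)
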