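import numpy as np
import pytest

from termfret.qc import FretSeries
from termfret.synthetic import EmissionModel, KineticScheme, StatePath


def two_state_scheme(k01=1.0, k10=1.0, e=(0.5, 0.7), sd=(0.0, 0.0),
                     init=None, dark=()):
    if init is None:
        tot = k01 + k10
        init = (k10 / tot, k01 / tot) if tot > 0 else (1.0, 0.0)
    return KineticScheme(
        state_ids=("a", "b"),
        fret_mean=tuple(e),
        fret_sd=tuple(sd),
        rates=np.array([[0.0, k01], [k10, 0.0]]),
        initial_probs=tuple(init),
        dark_states=frozenset(dark),
    )


def noiseless_emission(beta=0.0, bleach=0.0):
    return EmissionModel(total_intensity=1000.0, noise_sd_donor=0.0,
                         noise_sd_acceptor=0.0, bleedthrough_beta=beta,
                         bleach_rate_donor=bleach, bleach_rate_acceptor=bleach)


def single_state_path(state="b", duration=10.0, **bleach):
    return StatePath(states=[state], t_start=np.array([0.0]),
                     t_end=np.array([duration]), **bleach)


def make_series(values, frame_rate=30.0, mask=None, trace_id=0):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones_like(values, dtype=bool)
    return FretSeries(values=values, mask=np.asarray(mask, dtype=bool),
                      frame_rate=frame_rate, trace_id=trace_id)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
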