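import numpy as np
import pytest

import polbind as pb


@pytest.fixture(scope="session")
def aaf_scheme():
    return pb.make_preset("aaf_n1")


@pytest.fixture(scope="session")
def aaf_fret_dataset():
    """Moderate AAF n+1 FRET dataset shared by the idealization tests."""
    return pb.generate_dataset("aaf_n1", n_traces=60, duration=80.0, seed=2024, channel="fret")


@pytest.fixture(scope="session")
def aaf_fret_values(aaf_fret_dataset):
    return [
        np.nan_to_num(pb.apparent_fret(tr.donor, tr.acceptor), nan=0.0)
        for tr in aaf_fret_dataset.traces
    ]


@pytest.fixture(scope="session")
def aaf_hmm_fit(aaf_fret_values):
    return pb.fit_hmm(aaf_fret_values, n_states=3, seed=1, n_restarts=3, tol=1e-7)


@pytest.fixture(scope="session")
def aaf_idealized(aaf_hmm_fit, aaf_fret_values, aaf_fret_dataset):
    dt = aaf_fret_dataset.traces[0].frame_time
    return pb.viterbi(aaf_hmm_fit, aaf_fret_values, dt)


def two_state_scheme(k_ab: float, k_ba: float, fret=(0.1, 0.6)) -> pb.KineticScheme:
    rates = np.array([[0.0, k_ab], [k_ba, 0.0]])
    return pb.KineticScheme(("A", "B"), fret, (1.0, 1.5), rates, initial_state="A")
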