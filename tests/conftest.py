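"""Shared fixtures: small synthetic recordings reused across test modules."""

import numpy as np
import pytest

import nf1eeg as nf
from nf1eeg.synthetic_eeg import ArtifactSpec, SynthConfig


NO_ARTIFACTS = ArtifactSpec(blink_rate_hz=0.0, saccade_rate_hz=0.0)


@pytest.fixture(scope="session")
def montage():
    return nf.Montage.standard()


@pytest.fixture(scope="session")
def small_cfg():
    """Short session: 40 s rest per condition, two 20-trial n-back blocks."""
    return SynthConfig(
        seed=7,
        rest_open_s=40.0,
        rest_closed_s=40.0,
        blocks=("1back", "2back"),
        trials_per_block=20,
        targets_per_block=5,
        artifacts=NO_ARTIFACTS,
    )


@pytest.fixture(scope="session")
def small_recording(small_cfg):
    return nf.generate_recording(small_cfg)


@pytest.fixture(scope="session")
def rest_epochs(small_recording):
    """Clean rest epochs after the full chain minus ICA (no artifacts injected)."""
    rr = nf.rereference(small_recording, "averaged-mastoids")
    filt = nf.filter_chain(rr, "rest")
    ep = nf.make_epochs(filt, "rest-arbitrary")
    ep = nf.reject_and_repair(ep, 200.0)
    return nf.rereference(ep, "common-average")


@pytest.fixture(scope="session")
def task_epochs(small_recording):
    rr = nf.rereference(small_recording, "averaged-mastoids")
    filt = nf.filter_chain(rr, "task")
    ep = nf.make_epochs(filt, "task")
    ep = nf.reject_and_repair(ep, 120.0)
    return nf.rereference(ep, "common-average")


def sinusoid_epochs(freq_hz, amp_uv=1.0, n_epochs=3, rate=256.0, phase=0.0):
    """Epochs holding a pure sinusoid on a minimal two-channel montage."""
    m = nf.Montage(
        ("chx", "chy"),
        np.array([[0.0, 1.0, 0.0], [0.0, -1.0, 0.0]]),
        np.array([True, True]),
    )
    n_samp = nf.window_n_samples(0.0, 1900.0, rate)
    t = np.arange(n_samp) / rate
    sig = amp_uv * np.cos(2 * np.pi * freq_hz * t + phase)
    data = np.tile(sig, (n_epochs, 2, 1))
    return nf.Epochs(
        data=data,
        rate=rate,
        window_ms=(0.0, 1900.0),
        conditions=np.array(["eyes_open"] * n_epochs, dtype=object),
        montage=m,
    )
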