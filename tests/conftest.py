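import numpy as np
import pytest

import emodec as em


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_recording():
    """4-channel, 256 Hz, 10-s deterministic recording with three events."""
    gen = np.random.default_rng(7)
    data = gen.standard_normal((2560, 4)) * 10.0
    events = [
        em.Event(5.0, "joy"),
        em.Event(2.0, "anger"),
        em.Event(0.5, "sadness"),  # too close to the start for a 2-s window
    ]
    return em.Recording(
        data=data, fs=256.0, channel_labels=["A", "B", "C", "D"], subject_id="sub-t1", events=events
    )


@pytest.fixture()
def small_segments():
    """Tiny SegmentSet: 12 segments, 64 samples, 5 channels, both classes."""
    gen = np.random.default_rng(11)
    tensor = gen.standard_normal((12, 64, 5))
    labels = np.array([0, 1] * 6)
    return em.SegmentSet(
        tensor=tensor,
        labels=labels,
        subject_ids=np.array(["sub-t1"] * 12, dtype=object),
        fs=32.0,
        channel_labels=[f"c{i}" for i in range(5)],
    )


@pytest.fixture(scope="session")
def default_gamma_segments():
    """Default synthetic subject, gamma-filtered and segmented (shared: slow)."""
    cfg = em.SynthConfig(seed=1)
    rec = em.generate_recording(cfg, 0)
    filtered = em.bandpass(rec, "gamma")
    return em.segment(filtered, 2.0, em.default_label_scheme("valence"), band="gamma")
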