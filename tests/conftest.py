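import numpy as np
import pytest

from swimassay import Track, Visit, VisitSequence, get_arena


@pytest.fixture(scope="session")
def spm_arena():
    return get_arena("spm")


@pytest.fixture(scope="session")
def ot_arena():
    return get_arena("ot")


def track_from_labels(label_spec, frame_rate=10.0, positions=None,
                      subject_id="s1", session_id="sess1"):
    """Build a dummy track whose frames spell out given zone-label runs.

    ``label_spec`` is a list of (label, duration_s); positions are
    irrelevant for label-driven tests and default to the origin.
    """
    labels = []
    for lab, dur in label_spec:
        labels.extend([lab] * int(round(dur * frame_rate)))
    n = len(labels)
    t = np.arange(n) / frame_rate
    if positions is None:
        x = np.zeros(n)
        y = np.zeros(n)
    else:
        x, y = positions
    return Track(subject_id, session_id, t, x, y, frame_rate=frame_rate), labels


@pytest.fixture
def make_visits():
    def _make(spec, session_length=None, subject_id="s1", session_id="sess1"):
        visits = [Visit(z, t0, t1) for z, t0, t1 in spec]
        if session_length is None:
            session_length = spec[-1][2] if spec else 0.0
        return VisitSequence(subject_id, session_id, visits, session_length)

    return _make
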