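import numpy as np
import pandas as pd
import pytest

import photothreat as pt


@pytest.fixture
def single_event_log():
    """One instantaneous loom event at t = 12 s."""
    return pt.EventLog(
        pd.DataFrame(
            {
                "label": ["loom"],
                "onset_s": [12.0],
                "offset_s": [np.nan],
                "trial_index": [0],
            }
        )
    )


def make_single_transient_session(
    amplitude: float,
    noise_sd: float,
    seed: int,
    onset_s: float = 12.0,
    duration_s: float = 24.0,
    **session_kw,
):
    """A session holding exactly one transient at ``onset_s``."""
    spec = pt.SessionSpec(
        duration_s=duration_s, noise_sd=noise_sd, seed=seed, **session_kw
    )
    return pt.generate_photometry_session(
        spec, [pt.TransientSpec(onset_s=onset_s, amplitude=amplitude)]
    )


@pytest.fixture
def transient_session_factory():
    return make_single_transient_session
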