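import numpy as np
import pandas as pd
import pytest

from visearch import pipeline


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_classified_frame(rows):
    """Build a minimal classified-fixation frame for pipeline/inference tests.

    ``rows`` is a list of dicts; missing columns get sensible defaults for a
    correct target-absent search trial.
    """
    defaults = dict(
        participant="p00", trial=0, phase="search", block=1,
        condition="split_half", configuration="hard_up", target_present=False,
        target_half="absent", target_col=None, target_row=None,
        response="absent", correct=True, rt_ms=1000.0, stim_seed=0,
        fix_index=2, x_px=0.0, y_px=0.0, dur_ms=250.0,
        label=pipeline.LABEL_HET,
    )
    return pd.DataFrame([dict(defaults, **r) for r in rows])


@pytest.fixture
def classified_frame_factory():
    return make_classified_frame
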