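import numpy as np
import pandas as pd
import pytest

from stopcsp import (
    CSPConfig,
    ParticipantBehaviorModel,
    SessionDesign,
    SyntheticEMGParams,
)
from stopcsp.synthetic_data import TRIAL_COLUMNS


@pytest.fixture
def design():
    return SessionDesign()


@pytest.fixture
def behavior():
    return ParticipantBehaviorModel()


@pytest.fixture
def emg_params():
    return SyntheticEMGParams()


@pytest.fixture
def csp_config():
    return CSPConfig()


def make_trial_table(go_rts, stop_trials, go_correct=None, participant_id="P00"):
    """Hand-built experimental trial table.

    go_rts: list of RT values (None = omission); stop_trials: list of
    (ssd, rt_or_None); go_correct: optional per-go-trial booleans.
    """
    rows = []
    go_correct = go_correct or [True] * len(go_rts)
    for i, (rt, ok) in enumerate(zip(go_rts, go_correct)):
        responded = rt is not None
        rows.append(
            dict(
                participant_id=participant_id,
                block=1,
                trial=i,
                phase="experimental",
                trial_type="go",
                direction="left",
                ssd_ms=np.nan,
                response=("left" if ok else "right") if responded else "none",
                rt_ms=rt if responded else np.nan,
                correct=int(responded and ok),
            )
        )
    for j, (ssd, rt) in enumerate(stop_trials):
        responded = rt is not None
        rows.append(
            dict(
                participant_id=participant_id,
                block=1,
                trial=len(go_rts) + j,
                phase="experimental",
                trial_type="stop",
                direction="right",
                ssd_ms=ssd,
                response="right" if responded else "none",
                rt_ms=rt if responded else np.nan,
                correct=int(not responded),
            )
        )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


@pytest.fixture
def trial_table_factory():
    return make_trial_table
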