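import numpy as np
import pandas as pd
import pytest

from permsplit.data_model import TrialTable
from permsplit.scoring import ScoreSpec


def make_table(rows, factors=("stimulus_type", "direction")):
    """Build a TrialTable from (participant, stimulus, type, direction, rt)
    tuples, presentation indices assigned in listed order per participant."""
    df = pd.DataFrame(rows, columns=["participant", "stimulus", *factors, "rt"])
    df["presentation"] = df.groupby("participant").cumcount() + 1
    return TrialTable(df, tuple(factors))


@pytest.fixture
def aat_spec():
    """Double-difference AAT score: (avoid - approach) for targets minus the
    same contrast for controls."""
    return ScoreSpec(
        "mean",
        ("stimulus_type", "direction"),
        {"stimulus_type": "target", "direction": "avoid"},
    )


@pytest.fixture
def toy_aat():
    """Six participants, 2 stimuli per category, 1 trial per cell; trial
    order interleaves stimuli so that the odd and the even presentation half
    each contain every condition cell (with a different stimulus)."""
    rows = []
    rng = np.random.default_rng(42)
    for p in ("p1", "p2", "p3", "p4", "p5", "p6"):
        for cat in ("target", "control"):
            for direction in ("avoid", "approach"):
                for s in (1, 2):
                    rows.append(
                        (p, f"{cat}_s{s}", cat, direction, float(rng.integers(400, 900)))
                    )
    return make_table(rows)
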