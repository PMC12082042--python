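import numpy as np
import pandas as pd
import pytest

REARR_DEFAULTS = dict(
    participant_id="P1",
    v_call="IGHV1-1*01",
    j_call="IGHJ4",
    c_call="IGHM",
    mutation_count=0,
    duplicate_count=1,
)


def make_rearrangements(rows: list[dict]) -> pd.DataFrame:
    """Build a rearrangement table from partial row dicts.

    ``junction_length`` is filled from the junction unless given explicitly
    (tests of the length invariant pass it on purpose).
    """
    full = []
    for i, row in enumerate(rows):
        r = dict(REARR_DEFAULTS, sequence_id=f"S{i:03d}", **row)
        r.setdefault("junction_length", len(r["junction"]))
        full.append(r)
    return pd.DataFrame(full)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
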