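import numpy as np
import pandas as pd
import pytest

from seroprofile import (
    CutoffRule,
    call_reactivity,
    nmad_transform,
    simulate_bead_cohort,
)


@pytest.fixture(scope="session")
def bead_cohort():
    """Default simulated cohort: 55 cases, 52 controls, 246 antigens."""
    return simulate_bead_cohort(seed=1)


@pytest.fixture(scope="session")
def called_cohort(bead_cohort):
    """The default cohort carried through normalization and calling."""
    matrix, metadata, panel, truth = bead_cohort
    calls = call_reactivity(nmad_transform(matrix), CutoffRule())
    labels = pd.Series({r.sample_id: r.group for r in metadata})
    return calls, metadata, panel, truth, labels


def make_binary_frame(rows, sample_prefix="s", columns=None):
    """Small binary call DataFrame from a list of 0/1 rows."""
    rows = np.asarray(rows, dtype=int)
    index = [f"{sample_prefix}{i + 1}" for i in range(rows.shape[0])]
    columns = columns or [f"t{j + 1}" for j in range(rows.shape[1])]
    return pd.DataFrame(rows, index=index, columns=columns)
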