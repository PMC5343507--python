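"""Small builders shared across test modules."""

import numpy as np
import pandas as pd

from timscan.fitness import LANDSCAPE_COLUMNS, FitnessLandscape


def landscape_from_values(values) -> FitnessLandscape:
    """A minimal one-library landscape holding the given s values."""
    values = list(values)
    rows = [
        ("X", 1, i + 1, "A", "V", v, v, "") for i, v in enumerate(values)
    ]
    return FitnessLandscape(table=pd.DataFrame(rows, columns=LANDSCAPE_COLUMNS))
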