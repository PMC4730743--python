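import numpy as np
import pandas as pd
import pytest

from clonofit.dataio import SF_COLUMNS, SurvivalDataset
from clonofit.synthetic import paper_like_panel


def make_dataset(rows):
    """Build a SurvivalDataset from (line, rep, dose, sf) tuples."""
    return SurvivalDataset(pd.DataFrame(rows, columns=list(SF_COLUMNS)))


def lq_dataset(alpha, beta, doses=(0, 1, 2, 4, 6, 8, 10), reps=1,
               sigma=0.0, seed=0, line="A"):
    """Panel of one line generated from the LQ truth on the log scale."""
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(1, reps + 1):
        for d in doses:
            eps = rng.normal(0.0, sigma) if (sigma > 0 and d > 0) else 0.0
            sf = float(np.exp(alpha * d + beta * d**2 + eps)) if d > 0 else 1.0
            rows.append((line, f"R{r}", float(d), sf))
    return make_dataset(rows)


@pytest.fixture(scope="session")
def panel():
    """Default-seed study-design panel (9 lines, two groups)."""
    return paper_like_panel(0)
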