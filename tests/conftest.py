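import numpy as np
import pytest
from hypothesis import settings

from maekin import reference
from maekin.synthetic import PAPER_SCHEDULE_MIN

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def schedule():
    """The study's 11-point sampling schedule (minutes)."""
    return np.asarray(PAPER_SCHEDULE_MIN, dtype=float)


@pytest.fixture(scope="session")
def tp_profile_pairs():
    """Published (power W, first-order k1) pairs for total phenolics."""
    return reference.first_order_k_profile("TP")


@pytest.fixture(scope="session")
def published_param_sets():
    """Published per-power parameter records for every model family,
    pooled over both responses — a realistic grid for evaluator checks."""
    sets = []
    for rows in (reference.table_y_rows(), reference.table_tp_rows()):
        for row in rows:
            sets.append((row.model_id, dict(row.params)))
    return sets
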