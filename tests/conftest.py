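import numpy as np
import pandas as pd
import pytest

from orgloc.core_io import AMINO_ACIDS, GOLD_CLASSES, ProteinRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def random_records(rng):
    """200 random sequences (all starting with M, no partials)."""
    def make(n=200, min_len=20, max_len=120):
        records = []
        for i in range(n):
            length = int(rng.integers(min_len, max_len, endpoint=True))
            seq = "M" + "".join(rng.choice(list(AMINO_ACIDS), size=length - 1))
            records.append(ProteinRecord(id=f"r{i:04d}", sequence=seq))
        return records
    return make


@pytest.fixture
def random_calls_table(rng):
    """Random calls table over a set of tools and native labels."""
    def make(n=200, tools=("toolA", "toolB")):
        natives = ["cTP", "mTP", "SP", "none"]
        rows = []
        for i in range(n):
            rows.append({
                "protein_id": f"p{i:04d}",
                "tool_id": tools[i % len(tools)],
                "native_label": str(rng.choice(natives)),
            })
        return pd.DataFrame(rows)
    return make


@pytest.fixture
def random_labels(rng):
    def make(n=100):
        return pd.DataFrame({
            "protein_id": [f"p{i:04d}" for i in range(n)],
            "true_class": rng.choice(list(GOLD_CLASSES), size=n),
        })
    return make
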