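import numpy as np
import pandas as pd
import pytest


def make_fc_table(rows):
    """Long-format fold-change table from (gene, line, log2_fc, q, status) tuples."""
    return pd.DataFrame(rows, columns=["gene_id", "line", "log2_fc", "q_value", "status"])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_line_fc():
    """Three genes across two lines: one shared up, one conflicting, one null."""
    return make_fc_table(
        [
            ("gA", "L1", 1.5, 0.001, "measured"),
            ("gA", "L2", 1.2, 0.002, "measured"),
            ("gB", "L1", 2.0, 0.003, "measured"),
            ("gB", "L2", -1.8, 0.004, "measured"),
            ("gC", "L1", 0.1, 0.8, "measured"),
            ("gC", "L2", -0.1, 0.9, "measured"),
        ]
    )
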