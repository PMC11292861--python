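"""Shared fixtures: compact builders for summary-stat tables and harmonized frames."""

import numpy as np
import pandas as pd
import pytest

from medmr import SummaryStatsTable

ROW_FIELDS = ("variant_id", "chrom", "pos", "effect_allele", "other_allele",
              "eaf", "beta", "se", "pval", "n")


def make_table(rows, label="trait", trait_type="quantitative"):
    """Build a SummaryStatsTable from (vid, chrom, pos, ea, oa, eaf, beta, se, pval, n) tuples."""
    df = pd.DataFrame([dict(zip(ROW_FIELDS, r)) for r in rows])
    df["eaf"] = df["eaf"].astype(float)
    df["n"] = df["n"].astype(float)
    return SummaryStatsTable(df, trait_label=label, trait_type=trait_type)


def harmonized_frame(bx, sx, by, sy, ids=None):
    """A minimal harmonized frame accepted by every MR estimator."""
    bx = np.asarray(bx, dtype=float)
    n = len(bx)
    return pd.DataFrame(
        {
            "variant_id": ids if ids is not None else [f"rs{i + 1}" for i in range(n)],
            "beta_exp": bx,
            "se_exp": np.broadcast_to(np.asarray(sx, dtype=float), (n,)).copy(),
            "beta_out": np.asarray(by, dtype=float),
            "se_out": np.broadcast_to(np.asarray(sy, dtype=float), (n,)).copy(),
            "action": "kept",
        }
    )


@pytest.fixture
def simple_pair():
    """A 3-variant exposure/outcome pair on identical allele frames."""
    exposure = make_table(
        [
            ("rs1", "1", 1000, "A", "G", 0.3, 0.10, 0.01, 1e-8, 10000),
            ("rs2", "1", 2000, "C", "T", 0.4, 0.15, 0.01, 1e-10, 10000),
            ("rs3", "2", 3000, "G", "A", 0.2, 0.20, 0.02, 1e-9, 10000),
        ],
        label="exposure",
    )
    outcome = make_table(
        [
            ("rs1", "1", 1000, "A", "G", 0.3, 0.02, 0.01, 0.05, 20000),
            ("rs2", "1", 2000, "C", "T", 0.4, 0.04, 0.01, 0.01, 20000),
            ("rs3", "2", 3000, "G", "A", 0.2, 0.05, 0.01, 0.002, 20000),
        ],
        label="outcome",
        trait_type="binary",
    )
    return exposure, outcome
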