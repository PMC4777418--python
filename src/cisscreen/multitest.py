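"""Multiple-testing corrections shared across pipeline stages.

The screen stage adjusts per-gene p-values with the Benjamini-Hochberg
step-up (FDR control); the validation stages (clonogenic assays, yeast
fitness) use the Holm step-down (FWER control).  Both are thin, order-
preserving wrappers around :func:`statsmodels.stats.multitest.multipletests`.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def _check(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-d array")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("pvalues must lie in [0, 1]")
    return p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Equivalent to ``min_{j >= i} p_(j) * m / j`` in sorted order, capped at
    1; output keeps the input order.
    """
    p = _check(pvalues)
    return multipletests(p, method="fdr_bh")[1]


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down (Holm-Bonferroni) adjusted p-values.

    Sorted ascending, ``p_(i) * (m - i + 1)`` with running-maximum
    monotonicity, capped at 1; output keeps the input order.
    """
    p = _check(pvalues)
    return multipletests(p, method="holm")[1]


def pairwise_welch_holm(groups: dict) -> "pd.DataFrame":
    """All pairwise Welch t-tests between named groups, Holm-adjusted.

    Used for clonogenic plating-efficiency comparisons, where each group is
    the replicate PE values of one treatment condition.
    """
    import itertools

    import pandas as pd

    names = sorted(groups)
    rows = []
    for a, b in itertools.combinations(names, 2):
        t, p = stats.ttest_ind(groups[a], groups[b], equal_var=False)
        rows.append({"group_a": a, "group_b": b, "t": t, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_holm"] = holm_adjust(out["p"].to_numpy())
    return out
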