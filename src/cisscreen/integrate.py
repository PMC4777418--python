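"""Integration of the expression shortlist with screen ranks, enrichment
tests, and clonogenic plating efficiency.

Differentially expressed genes are joined to the screen summary by
case-normalized symbol, narrowed by a strict Gene Score rank filter
(default rank < 2000), and the overlap between any two gene lists is
tested with a two-sided Fisher exact test.  Gene-set enrichment against
user-supplied collections (GMT format) uses the upper-tail hypergeometric
test with an optional BH column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from cisscreen.multitest import bh_adjust

CANDIDATE_COLUMNS = [
    "gene",
    "lfc",
    "pct_survival_cddp",
    "survival_index",
    "potentiation",
    "gene_score",
    "whole_genome_rank",
]


def _norm(symbols) -> pd.Series:
    return pd.Series(symbols, dtype=str).str.strip().str.upper()


def join_screen_expression(de_list: pd.DataFrame, screen_table: pd.DataFrame):
    """Inner-join DE genes to screen summaries on case-normalized symbol.

    ``de_list`` needs columns ``gene`` and ``lfc``; ``screen_table`` is a
    gene summary (with ``rank``, reported as ``whole_genome_rank``).
    Returns ``(candidates, unmatched)`` — DE genes absent from the screen
    are reported, never silently dropped.
    """
    if len(de_list) == 0:
        return pd.DataFrame(columns=CANDIDATE_COLUMNS), []
    de = de_list.copy()
    de["_key"] = _norm(de["gene"])
    sc = screen_table.copy()
    sc["_key"] = _norm(sc["gene"])
    sc = sc.rename(columns={"rank": "whole_genome_rank"})

    merged = de.merge(
        sc.drop(columns=["gene"]), on="_key", how="left", suffixes=("", "_screen")
    )
    matched = merged[~merged["whole_genome_rank"].isna()].copy()
    unmatched = sorted(merged.loc[merged["whole_genome_rank"].isna(), "gene"])
    matched["whole_genome_rank"] = matched["whole_genome_rank"].astype(int)
    return matched[CANDIDATE_COLUMNS].reset_index(drop=True), unmatched


def rank_filter(candidates: pd.DataFrame, rank_max: int = 2000) -> pd.DataFrame:
    """Keep candidates with whole-genome Gene Score rank strictly below
    ``rank_max``."""
    if "whole_genome_rank" not in candidates.columns:
        raise ValueError("candidates need a whole_genome_rank column")
    keep = candidates["whole_genome_rank"] < rank_max
    return candidates[keep].reset_index(drop=True)


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Computed by enumerating the hypergeometric support at fixed margins
    and summing the probabilities of tables no more likely than the one
    observed (the conventional two-sided definition).
    """
    (a, b), (c, d) = np.asarray(table, dtype=int)
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    n = a + b + c + d
    r1, c1 = a + b, a + c
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    probs = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = stats.hypergeom.pmf(a, n, c1, r1)
    # relative tie tolerance: exact rational ties computed via gammaln can
    # differ in the last floating bits
    return float(min(probs[probs <= p_obs * (1 + 1e-7)].sum(), 1.0))


def overlap_fisher(list_a, list_b, universe_size: int) -> float:
    """Two-sided Fisher test of the overlap between two gene lists.

    The 2x2 table partitions a universe of ``universe_size`` genes by
    membership in each list.
    """
    a, b = set(_norm(list(list_a))), set(_norm(list(list_b)))
    if max(len(a), len(b)) > universe_size:
        raise ValueError("lists cannot exceed the universe")
    k = len(a & b)
    table = [
        [k, len(a) - k],
        [len(b) - k, universe_size - len(a) - len(b) + k],
    ]
    if table[1][1] < 0:
        raise ValueError("universe too small for the given lists")
    return fisher_two_sided(table)


def read_gmt(path: str | Path) -> dict:
    """Parse a GMT gene-set file: name, description, symbols per line."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = sorted(set(parts[2:]) - {""})
    return sets


def hypergeom_enrichment(
    gene_list,
    sets: dict,
    universe_size: int,
    adjust: bool = True,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a gene list in named sets.

    For each set, the p-value is the probability of drawing at least the
    observed overlap when ``len(gene_list)`` genes are sampled without
    replacement from the universe.  Overlapping genes are listed; a BH
    column is added when ``adjust`` is true.
    """
    query = set(_norm(list(gene_list)))
    if len(query) > universe_size:
        raise ValueError("gene list larger than the universe")
    rows = []
    for name in sorted(sets):
        members = set(_norm(list(sets[name])))
        if not members:
            raise ValueError(f"gene set {name!r} is empty")
        overlap = sorted(query & members)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, universe_size, len(members), len(query)))
        rows.append(
            {
                "set": name,
                "set_size": len(members),
                "overlap": k,
                "p": min(p, 1.0),
                "genes": ";".join(overlap),
            }
        )
    out = pd.DataFrame(rows)
    if adjust and len(out):
        out["p_bh"] = bh_adjust(out["p"].to_numpy())
    return out


def plating_efficiency(colonies: float, seeded: float) -> float:
    """Clonogenic plating efficiency: colonies formed per 100 cells seeded."""
    if seeded <= 0:
        raise ValueError("seeded cell count must be positive")
    if colonies < 0:
        raise ValueError("colony count must be non-negative")
    return 100.0 * colonies / seeded
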