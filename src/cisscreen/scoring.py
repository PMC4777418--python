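"""Per-gene scoring of drug-sensitization screens.

The screen statistic is built from per-well nuclei counts in two arms
(untreated and low-dose cisplatin).  For each gene:

* **Survival Index (SI)** — the untreated median count as a percentage of
  the transfection-reagent (RNAiMAX) control median; lethality of the
  knockdown on its own.
* **% survival with CDDP** — the cisplatin-arm median count as a
  percentage of the same no-drug reference.
* **Difference (sensitization)** — SI minus % survival with CDDP.
* **Potentiation** — the Difference as a percentage of the Difference
  measured for the BRCA2 positive-control wells on the same plates.
* **Gene Score** — ``(100 - |SI - 100|) * Potentiation``: large when the
  knockdown is tolerated on its own (SI near 100) yet strongly sensitizes
  the cells to the drug.

Medians rather than means are used throughout so that a single failed
replicate well (e.g. a transfection failure) cannot dominate a gene.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from cisscreen.tables import GENE_TABLE_COLUMNS, gene_symbol, is_gene_role


def median_gene_count(wells) -> float:
    """Median count over a gene's replicate wells in one arm.

    Robust to a single failed well among triplicates; for an even number
    of wells the mean of the central pair is returned.
    """
    wells = np.asarray(wells, dtype=float)
    if wells.size == 0:
        raise ValueError("no wells to aggregate")
    return float(np.median(wells))


def survival_index(gene_untreated_median: float, ref_untreated_median: float) -> float:
    """Untreated viability as % of the transfection-reagent control."""
    if ref_untreated_median <= 0:
        raise ValueError("degenerate reference: control median must be positive")
    return 100.0 * gene_untreated_median / ref_untreated_median


def potentiation(gene_diff: float, brca2_diff: float) -> float:
    """Sensitization as % of the BRCA2 positive-control sensitization.

    Negative values indicate protection (more cells survive the drug after
    knockdown than without it).
    """
    if brca2_diff <= 0:
        raise ValueError("positive control failed: BRCA2 difference must be positive")
    return 100.0 * gene_diff / brca2_diff


def gene_score(si: float, pot: float) -> float:
    """``(100 - |SI - 100|) * Potentiation``, applied literally.

    No clamping: an SI above 200 makes the first term negative and sinks
    the gene in the ranking, which matches the statistic's intent.  The
    score is symmetric in SI about 100.
    """
    return (100.0 - abs(si - 100.0)) * pot


def rank_genes(scores: pd.Series) -> pd.Series:
    """Rank genes by score, rank 1 = highest.

    Ties are broken by gene symbol ascending so the ranking is a
    deterministic permutation of 1..n.
    """
    if len(scores) == 0:
        raise ValueError("no scores to rank")
    order = sorted(scores.index, key=lambda g: (-scores[g], str(g)))
    return pd.Series(np.arange(1, len(order) + 1), index=order, name="rank").loc[
        scores.index
    ]


def classify_lethal(si: float, cutoff: float = 30.0) -> bool:
    """A knockdown is lethal when it alone loses >= (100-cutoff)% viability.

    The boundary is inclusive: SI exactly at the cutoff counts as lethal.
    """
    return si <= cutoff


def select_hit_set(
    summaries: pd.DataFrame,
    diff_pctl: float = 90.0,
    si_pctl: float = 75.0,
) -> set:
    """High-confidence non-lethal sensitizer set.

    Genes whose Difference reaches its ``diff_pctl``-th percentile AND
    whose Survival Index reaches its ``si_pctl``-th percentile across the
    screen.  Percentiles are linearly interpolated between order
    statistics; a degenerate constant column passes every gene.
    """
    if len(summaries) == 0:
        raise ValueError("no summaries")
    d_cut = np.percentile(summaries["difference"], diff_pctl)
    s_cut = np.percentile(summaries["survival_index"], si_pctl)
    keep = (summaries["difference"] >= d_cut) & (summaries["survival_index"] >= s_cut)
    return set(summaries.loc[keep, "gene"])


def fraction_affected(viable_treated: float, viable_untreated: float) -> float:
    """Fraction affected: 0 = no effect, 1 = total kill; clipped to [0, 1]."""
    if viable_untreated <= 0:
        raise ValueError("untreated viable count must be positive")
    return float(np.clip(1.0 - viable_treated / viable_untreated, 0.0, 1.0))


def estimate_noel(doses, fa, target_fa: float = 0.1) -> float:
    """Dose giving the target fraction affected (the IC10 / NOEL).

    Linear interpolation of Fa on log10 dose between the first pair of
    observed doses bracketing the target.
    """
    doses = np.asarray(doses, dtype=float)
    fa = np.asarray(fa, dtype=float)
    if doses.ndim != 1 or doses.shape != fa.shape or doses.size < 2:
        raise ValueError("need matching 1-d dose and Fa arrays with >= 2 points")
    if np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be strictly increasing")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive for log-scale interpolation")
    fa = np.clip(fa, 0.0, 1.0)

    exact = np.nonzero(fa == target_fa)[0]
    if exact.size:
        return float(doses[exact[0]])
    for i in range(doses.size - 1):
        lo, hi = fa[i], fa[i + 1]
        if lo < target_fa < hi:
            frac = (target_fa - lo) / (hi - lo)
            logd = math.log10(doses[i]) + frac * (
                math.log10(doses[i + 1]) - math.log10(doses[i])
            )
            return float(10.0**logd)
    raise ValueError("no bracketing doses: target Fa outside observed range")


def _control_median(plate_df: pd.DataFrame, role: str, arm: str) -> float:
    sel = plate_df[(plate_df["role"] == role) & (plate_df["arm"] == arm)]
    if len(sel) == 0:
        raise ValueError(f"no {role} wells in {arm} arm")
    return float(np.median(sel["count"]))


def score_screen(
    plates: pd.DataFrame,
    ref_control: str = "rnaimax",
    pos_control: str = "brca2",
    difference_scale: str = "percent",
    include_controls: bool = False,
) -> pd.DataFrame:
    """Score a whole screen into a per-gene summary table.

    For each gene, counts are aggregated by median per arm; the reference
    is the ``ref_control`` untreated-arm median pooled over the plates
    hosting that gene, and the Potentiation normalizer is the
    ``pos_control`` sensitization on the same plates.

    ``difference_scale`` selects the sensitization scale: ``"percent"``
    (SI minus % survival with CDDP; plate-comparable, the default) or
    ``"count"`` (raw untreated-minus-treated median counts, with the
    positive-control difference computed the same way).

    With ``include_controls`` the control classes themselves are scored as
    pseudo-genes (useful for QC: the reference class scores SI = 100 and
    the positive control scores Potentiation = 100 by construction).
    """
    if difference_scale not in ("percent", "count"):
        raise ValueError("difference_scale must be 'percent' or 'count'")

    gene_rows = plates[plates["role"].map(is_gene_role)]
    work = [(gene_symbol(r), grp) for r, grp in gene_rows.groupby("role")]
    if include_controls:
        for role in (ref_control, pos_control, "scramble"):
            grp = plates[plates["role"] == role]
            if len(grp):
                work.append((role, grp))

    records = []
    for gene, grp in sorted(work):
        host = plates[plates["plate_id"].isin(grp["plate_id"].unique())]
        ref_u = _control_median(host, ref_control, "untreated")
        if ref_u <= 0:
            raise ValueError(f"degenerate reference on plates hosting {gene}")

        med_u = median_gene_count(grp.loc[grp["arm"] == "untreated", "count"])
        med_c = median_gene_count(grp.loc[grp["arm"] == "cisplatin", "count"])
        si = survival_index(med_u, ref_u)
        pct_cddp = 100.0 * med_c / ref_u

        b_u = _control_median(host, pos_control, "untreated")
        b_c = _control_median(host, pos_control, "cisplatin")
        if difference_scale == "percent":
            diff = si - pct_cddp
            b_diff = 100.0 * (b_u - b_c) / ref_u
        else:
            diff = med_u - med_c
            b_diff = b_u - b_c
        pot = potentiation(diff, b_diff)
        records.append(
            {
                "gene": gene,
                "survival_index": si,
                "pct_survival_cddp": pct_cddp,
                "difference": diff,
                "potentiation": pot,
                "gene_score": gene_score(si, pot),
            }
        )

    out = pd.DataFrame(records)
    scores = out.set_index("gene")["gene_score"]
    out["rank"] = rank_genes(scores).loc[out["gene"]].to_numpy()
    out["lethal"] = out["survival_index"].map(classify_lethal)
    return out[GENE_TABLE_COLUMNS + ["lethal"]]
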