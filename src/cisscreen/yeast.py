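"""Growth-curve fitness and the multiplicative drug-gene interaction model.

Fitness of a yeast strain under a condition is the baseline-subtracted
area under its OD600 growth curve, expressed as a proportion of the mean
wild-type untreated area.  Under the multiplicative (product) null model
the expected fitness of a mutant under drug is the product of the
mutation fitness and the drug fitness in the wild type; observed
replicate fitnesses are compared to this expectation with a one-sample
t-test and Holm correction across strains.  A strain significantly below
its expectation carries a synthetic-sick (sub-multiplicative) drug-gene
interaction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from cisscreen.multitest import holm_adjust


def auc_growth(time_h, od600) -> float:
    """Trapezoidal area (OD*h) over the full horizon after subtracting the
    initial OD (the inoculation density), so a no-growth curve scores 0."""
    t = np.asarray(time_h, dtype=float)
    od = np.asarray(od600, dtype=float)
    if t.size < 2 or t.shape != od.shape:
        raise ValueError("need matching time and OD arrays with >= 2 points")
    steps = np.diff(t)
    if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
        raise ValueError("time grid must be uniform and increasing")
    return float(np.trapezoid(od - od[0], t))


def fitness(auc_sample: float, auc_wt_untreated: float) -> float:
    """AUC as a proportion of the wild-type untreated AUC."""
    if auc_wt_untreated <= 0:
        raise ValueError("wild-type untreated AUC must be positive")
    return auc_sample / auc_wt_untreated


def expected_fitness(f_mutation: float, f_drug_wt: float) -> float:
    """Multiplicative-model expectation for mutant-plus-drug fitness."""
    if f_mutation < 0 or f_drug_wt < 0:
        raise ValueError("fitness proportions must be non-negative")
    return f_mutation * f_drug_wt


def compare_fitness(observed_reps, expected: float) -> float:
    """Two-sided one-sample t-test of replicate fitnesses vs the expected
    constant.  Replicates all exactly at the expectation give p = 1."""
    obs = np.asarray(observed_reps, dtype=float)
    if obs.size < 2:
        raise ValueError("insufficient replicates: need at least 2")
    if np.ptp(obs) == 0:
        return 1.0 if np.isclose(obs[0], expected, rtol=1e-9, atol=1e-12) else 0.0
    return float(stats.ttest_1samp(obs, expected).pvalue)


def analyze_fitness(
    curves: pd.DataFrame,
    wt_strain: str = "WT",
    drug_condition: str = "cisplatin",
) -> pd.DataFrame:
    """Full fitness analysis of a long-form growth-curve table.

    Expects columns ``strain, condition, replicate, time_h, od600`` with
    an untreated and a drug condition per strain and a wild-type strain.
    Per (strain, condition, replicate) the AUC is computed and divided by
    the mean wild-type untreated AUC; for each mutant under drug the
    multiplicative expectation (mean mutation fitness times mean wild-type
    drug fitness) is tested against the observed replicate fitnesses, and
    the p-values are Holm-adjusted across strains.
    """
    auc = (
        curves.sort_values("time_h")
        .groupby(["strain", "condition", "replicate"])
        .apply(
            lambda g: auc_growth(g["time_h"].to_numpy(), g["od600"].to_numpy()),
            include_groups=False,
        )
        .rename("auc")
        .reset_index()
    )
    wt_unt = auc.query("strain == @wt_strain and condition == 'untreated'")["auc"]
    if len(wt_unt) == 0:
        raise ValueError(f"no untreated curves for wild-type strain {wt_strain!r}")
    ref = wt_unt.mean()
    auc["fitness"] = auc["auc"] / ref

    mean_fit = auc.groupby(["strain", "condition"])["fitness"].agg(["mean", "sem"])
    f_drug_wt = mean_fit.loc[(wt_strain, drug_condition), "mean"]

    records = []
    for (strain, condition), grp in auc.groupby(["strain", "condition"]):
        obs = grp["fitness"].to_numpy()
        rec = {
            "strain": strain,
            "condition": condition,
            "n": obs.size,
            "observed_fitness": obs.mean(),
            "sem": stats.sem(obs) if obs.size > 1 else np.nan,
        }
        if condition == drug_condition and strain != wt_strain:
            f_mut = mean_fit.loc[(strain, "untreated"), "mean"]
            exp = expected_fitness(f_mut, f_drug_wt)
            rec["expected_fitness"] = exp
            rec["p"] = compare_fitness(obs, exp)
        else:
            rec["expected_fitness"] = np.nan
            rec["p"] = np.nan
        records.append(rec)
    out = pd.DataFrame(records)
    tested = ~out["p"].isna()
    out["p_holm"] = np.nan
    if tested.any():
        out.loc[tested, "p_holm"] = holm_adjust(out.loc[tested, "p"].to_numpy())
    return out


def plot_fitness(records: pd.DataFrame, ax=None, alpha: float = 0.05):
    """Observed-vs-expected fitness bar plot with SEM error bars.

    White bars show the wild type; mutant bars under drug are annotated
    with their raw p-value and starred when the Holm-adjusted p is below
    ``alpha``.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.8 * len(records), 4))
    x = np.arange(len(records))
    colors = [
        "white" if s == records["strain"].iloc[0] else "0.6"
        for s in records["strain"]
    ]
    ax.bar(
        x,
        records["observed_fitness"],
        yerr=records["sem"],
        color=colors,
        edgecolor="black",
        capsize=3,
    )
    has_exp = ~records["expected_fitness"].isna()
    ax.scatter(
        x[has_exp],
        records.loc[has_exp, "expected_fitness"],
        marker="_",
        s=300,
        color="red",
        label="expected (product model)",
    )
    for xi, rec in zip(x, records.itertuples(index=False)):
        if not np.isnan(rec.p):
            star = "*" if rec.p_holm < alpha else ""
            ax.text(
                xi,
                rec.observed_fitness + (rec.sem or 0) + 0.02,
                f"p={rec.p:.3g}{star}",
                ha="center",
                fontsize=7,
            )
    ax.set_xticks(x)
    ax.set_xticklabels(
        [f"{r.strain}\n{r.condition}" for r in records.itertuples(index=False)],
        fontsize=7,
    )
    ax.set_ylabel("fitness (proportion of WT untreated)")
    ax.legend(loc="upper right", fontsize=7)
    return ax
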