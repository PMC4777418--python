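"""Robust estimation and removal of plate and well-position artifacts.

High-content screens show systematic count depression at plate edges,
fixed reagent-dispensing patterns along rows/columns, and plate-to-plate
batch differences.  These are modeled multiplicatively (additively on log
counts): ``count ~ plate * row * column * gene``.  Row and column factors
are fitted by iterative median polish on log counts after removing each
plate/arm level — the robust B-score approach standard in screen
analysis — and plate factors come from the reference-control wells.  A
true mixed-model fit can be substituted via the ``fitter`` hook.

All factor families are constrained to geometric mean 1 for
identifiability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PlateEffectModel:
    """Multiplicative plate/row/column factors plus a residual scale."""

    plate_factors: pd.Series
    row_factors: pd.Series
    col_factors: pd.Series
    residual_scale: float
    flagged_plates: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for kind, series in (
            ("plate", self.plate_factors),
            ("row", self.row_factors),
            ("col", self.col_factors),
        ):
            rows.extend(
                {"factor_type": kind, "label": str(k), "factor": v}
                for k, v in series.items()
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PlateEffectModel":
        def grab(kind, as_int=False):
            sel = df[df["factor_type"] == kind]
            idx = sel["label"].astype(int) if as_int else sel["label"]
            return pd.Series(sel["factor"].to_numpy(), index=idx)

        return cls(grab("plate"), grab("row"), grab("col", as_int=True), float("nan"))


def _median_polish_rows_cols(resid, rows, cols, n_iter=25, tol=1e-10):
    """Alternating row/column median sweep on residual log counts."""
    row_eff = pd.Series(0.0, index=sorted(set(rows)))
    col_eff = pd.Series(0.0, index=sorted(set(cols)))
    resid = resid.copy()
    for _ in range(n_iter):
        r_step = resid.groupby(rows).median()
        row_eff = row_eff.add(r_step, fill_value=0.0)
        resid = resid - r_step.reindex(rows).to_numpy()
        c_step = resid.groupby(cols).median()
        col_eff = col_eff.add(c_step, fill_value=0.0)
        resid = resid - c_step.reindex(cols).to_numpy()
        if max(r_step.abs().max(), c_step.abs().max()) < tol:
            break
    return row_eff, col_eff, resid


def fit_plate_effects(
    plates: pd.DataFrame,
    ref_control: str = "rnaimax",
    fitter=None,
) -> PlateEffectModel:
    """Fit plate, row and column factors from a well-count table.

    Known-effect control wells (the near-empty transfection-efficiency
    class, and the sensitization positive control in the drug arm) and
    zero counts are excluded from the fit, since their planted effects
    would otherwise leak into the factors of the columns that host them;
    plates whose counts are all zero are flagged
    and excluded (their factor is set to 1).  ``fitter``, if given, is
    called with the prepared log-count frame and must return
    ``(plate_log, row_log, col_log, resid)`` — the hook for substituting
    e.g. a REML mixed-model fit.
    """
    totals = plates.groupby("plate_id")["count"].sum()
    flagged = sorted(totals.index[totals == 0])
    work = plates[~plates["plate_id"].isin(flagged)]
    # drop known-effect control wells: near-empty transfection-efficiency
    # wells everywhere, and the sensitization positive control under drug
    # (both sit in the control columns and would bias their factors)
    known_effect = (work["role"] == "plk1") | (
        (work["role"] == "brca2") & (work["arm"] == "cisplatin")
    )
    work = work[~known_effect & (work["count"] > 0)].reset_index(drop=True)
    if work.empty:
        raise ValueError("no usable wells to fit plate effects")
    if work.groupby("plate_id").apply(
        lambda g: g["row"].nunique() < 2 or g["col"].nunique() < 2, include_groups=False
    ).any():
        raise ValueError("each plate needs at least 2 occupied rows and columns")

    logc = np.log(work["count"].to_numpy(dtype=float))
    logc = pd.Series(logc, index=work.index)

    if fitter is not None:
        plate_log, row_log, col_log, resid = fitter(work.assign(log_count=logc))
    else:
        # remove each plate/arm level first: absorbs batch and treatment
        # effects so the positional sweep sees only row/column structure
        level = logc.groupby([work["plate_id"], work["arm"]]).transform("median")
        resid = logc - level
        row_log, col_log, resid = _median_polish_rows_cols(
            resid, work["row"], work["col"]
        )
        row_log -= row_log.mean()
        col_log -= col_log.mean()

        ref = work[(work["role"] == ref_control) & (work["arm"] == "untreated")]
        if ref.empty:
            raise ValueError(f"no untreated {ref_control} wells for plate factors")
        adj = (
            logc.loc[ref.index]
            - row_log.reindex(ref["row"]).to_numpy()
            - col_log.reindex(ref["col"]).to_numpy()
        )
        plate_log = adj.groupby(ref["plate_id"].to_numpy()).median()
        plate_log -= plate_log.mean()

    scale = float(stats.median_abs_deviation(resid, scale="normal"))
    plate_factors = np.exp(plate_log)
    for pid in flagged:
        plate_factors[pid] = 1.0
    return PlateEffectModel(
        plate_factors=plate_factors.sort_index(),
        row_factors=np.exp(row_log),
        col_factors=np.exp(col_log),
        residual_scale=scale,
        flagged_plates=flagged,
    )


def correct_counts(plates: pd.DataFrame, model: PlateEffectModel) -> pd.DataFrame:
    """Divide counts by the fitted plate, row and column factors.

    Corrected counts are non-negative floats; unknown labels (e.g. a plate
    not seen during fitting) default to factor 1.
    """
    out = plates.copy()
    f = (
        model.plate_factors.reindex(out["plate_id"]).fillna(1.0).to_numpy()
        * model.row_factors.reindex(out["row"]).fillna(1.0).to_numpy()
        * model.col_factors.reindex(out["col"]).fillna(1.0).to_numpy()
    )
    out["count"] = out["count"].to_numpy(dtype=float) / f
    return out


def gene_pvalues(plates: pd.DataFrame, min_replicates: int = 2) -> pd.DataFrame:
    """Per-gene Welch t-test of cisplatin vs untreated log counts.

    Returns a frame with the raw two-sided p, its BH adjustment, and a
    flag for genes with fewer than ``min_replicates`` wells in either arm
    (their p is left missing).
    """
    from cisscreen.multitest import bh_adjust
    from cisscreen.tables import gene_symbol, is_gene_role

    rows = []
    gene_rows = plates[plates["role"].map(is_gene_role)]
    for role, grp in sorted(gene_rows.groupby("role"), key=lambda kv: kv[0]):
        u = np.log1p(grp.loc[grp["arm"] == "untreated", "count"].to_numpy(dtype=float))
        c = np.log1p(grp.loc[grp["arm"] == "cisplatin", "count"].to_numpy(dtype=float))
        rec = {"gene": gene_symbol(role), "n_untreated": u.size, "n_cisplatin": c.size}
        if u.size < min_replicates or c.size < min_replicates:
            rec.update(p=np.nan, flagged=True)
        else:
            if np.ptp(u) == 0 and np.ptp(c) == 0:
                p = 1.0 if u.mean() == c.mean() else 0.0
            else:
                p = float(stats.ttest_ind(c, u, equal_var=False).pvalue)
            rec.update(p=max(p, np.finfo(float).tiny), flagged=False)
        rows.append(rec)
    out = pd.DataFrame(rows)
    ok = ~out["p"].isna()
    out["p_bh"] = np.nan
    if ok.any():
        out.loc[ok, "p_bh"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out
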