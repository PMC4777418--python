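"""Expression-matrix processing: normalization, QC, moderated-t DE, ddCt.

The stage ingests a gene-level log2 intensity matrix (summarization of
raw arrays is upstream of this package), quantile-normalizes it, screens
samples for outliers by classical multidimensional scaling, and contrasts
treated against untreated samples with an empirical-Bayes moderated
t-statistic.  Genes passing a strict p < alpha cutoff (default 0.005)
form the differential-expression shortlist, split by direction.

For validation qPCR data, relative quantities are computed with the ddCt
method against an endogenous control gene and a calibrator sample.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize, special, stats


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the same empirical distribution.

    The target distribution is the row-wise mean of the column-sorted
    matrix; tied values receive the interpolated target value at their
    average rank.  Idempotent, and all output columns have identical
    sorted values by construction.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    vals = matrix.to_numpy(dtype=float)
    ref = np.sort(vals, axis=0).mean(axis=1)
    positions = np.arange(1, vals.shape[0] + 1, dtype=float)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        ranks = stats.rankdata(vals[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, ref)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def mds_qc(matrix: pd.DataFrame, k: int = 2, z_cut: float = 3.0) -> pd.DataFrame:
    """Classical MDS of samples with robust-z outlier flagging.

    Samples are embedded by eigendecomposition of the double-centered
    squared Euclidean distance matrix; a sample is flagged when its
    distance from the coordinate centroid exceeds ``z_cut`` robust
    z-scores (median/MAD).  Returns one row per sample with coordinates,
    centroid distance, robust z and the outlier flag.
    """
    n = matrix.shape[1]
    if n < 3:
        raise ValueError("MDS QC needs at least 3 samples")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of samples ({n})")

    x = matrix.to_numpy(dtype=float).T  # samples x genes
    sq = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ sq @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:k]
    lam = np.clip(evals[order], 0.0, None)
    coords = evecs[:, order] * np.sqrt(lam)

    centroid = coords.mean(axis=0)
    dist = np.linalg.norm(coords - centroid, axis=1)
    med = np.median(dist)
    scale = stats.median_abs_deviation(dist, scale="normal")
    if scale > 0:
        z = (dist - med) / scale
        outlier = z > z_cut
    else:
        z = np.zeros(n)
        outlier = dist > med
    out = pd.DataFrame(
        coords, index=matrix.columns, columns=[f"mds{i + 1}" for i in range(k)]
    )
    out.insert(0, "sample", matrix.columns)
    out["dist"] = dist
    out["z"] = z
    out["outlier"] = outlier
    return out.reset_index(drop=True)


def _trigamma_inv(y: float) -> float:
    """Solve ``polygamma(1, x) = y`` for x > 0 (trigamma is decreasing)."""
    return optimize.brentq(lambda x: special.polygamma(1, x) - y, 1e-8, 1e8)


def moderated_t(
    matrix: pd.DataFrame,
    arms,
    treated: str = "cisplatin",
    shrink: bool = True,
) -> pd.DataFrame:
    """Per-gene treated-vs-untreated contrast with variance shrinkage.

    The log fold-change is the difference of arm means.  Pooled per-gene
    variances (df = n1 + n2 - 2) are shrunk toward a common prior whose
    scale ``s0^2`` and degrees of freedom ``d0`` are estimated by moment
    matching on the log sample variances (mean and variance of ``log s^2``
    against the digamma/trigamma moments of a scaled chi-square).  The
    moderated statistic uses the posterior variance
    ``(d0 s0^2 + df s^2) / (d0 + df)`` on ``df + d0`` degrees of freedom.

    With ``shrink=False`` (or when the prior is degenerate) the statistic
    is exactly the ordinary equal-variance two-sample t.  Genes with zero
    sample variance and no shrinkage get p = 0 for a nonzero fold-change
    and p = 1 otherwise.
    """
    arms = np.asarray(arms)
    if arms.shape[0] != matrix.shape[1]:
        raise ValueError("arms must label every sample column")
    t_mask = arms == treated
    u_mask = ~t_mask
    n1, n2 = int(t_mask.sum()), int(u_mask.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per arm")

    vals = matrix.to_numpy(dtype=float)
    xt, xu = vals[:, t_mask], vals[:, u_mask]
    lfc = xt.mean(axis=1) - xu.mean(axis=1)
    df = n1 + n2 - 2
    s2 = ((xt.var(axis=1, ddof=1) * (n1 - 1)) + (xu.var(axis=1, ddof=1) * (n2 - 1))) / df

    d0 = 0.0
    s02 = np.nan
    if shrink:
        pos = s2 > 0
        if pos.sum() >= 2:
            z = np.log(s2[pos])
            var_z = z.var(ddof=1)
            excess = var_z - special.polygamma(1, df / 2.0)
            if excess > 0:
                d0 = 2.0 * _trigamma_inv(excess)
                s02 = np.exp(
                    z.mean()
                    - special.digamma(df / 2.0)
                    + np.log(df / 2.0)
                    + special.digamma(d0 / 2.0)
                    - np.log(d0 / 2.0)
                )
            else:
                d0 = np.inf
                s02 = np.exp(z.mean() - special.digamma(df / 2.0) + np.log(df / 2.0))

    if d0 == 0.0:
        post = s2
        df_total = float(df)
    elif np.isinf(d0):
        post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        post = (d0 * s02 + df * s2) / (d0 + df)
        df_total = df + d0

    se = np.sqrt(post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = lfc / se
    degenerate = se == 0
    tstat[degenerate] = np.sign(lfc[degenerate]) * np.inf
    tstat[degenerate & (lfc == 0)] = 0.0
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    p = np.where(np.isinf(tstat), 0.0, p)
    p = np.clip(p, 0.0, 1.0)

    return pd.DataFrame(
        {
            "gene": matrix.index,
            "lfc": lfc,
            "t": tstat,
            "p": p,
            "direction": np.where(lfc >= 0, "up", "down"),
        }
    ).reset_index(drop=True)


class DEShortlist(NamedTuple):
    up: list
    down: list

    @property
    def n_up(self) -> int:
        return len(self.up)

    @property
    def n_down(self) -> int:
        return len(self.down)


def de_shortlist(degenes: pd.DataFrame, alpha: float = 0.005) -> DEShortlist:
    """Genes with p strictly below ``alpha``, split by fold-change sign."""
    if len(degenes) == 0:
        return DEShortlist([], [])
    sig = degenes[degenes["p"] < alpha]
    return DEShortlist(
        up=sorted(sig.loc[sig["direction"] == "up", "gene"]),
        down=sorted(sig.loc[sig["direction"] == "down", "gene"]),
    )


def ddct(
    ct: pd.DataFrame,
    control_gene: str = "GAPDH",
    calibrator: str | None = None,
) -> pd.DataFrame:
    """Relative mRNA quantities by the ddCt method.

    ``RQ = 2^(-ddCt)`` where ``ddCt = (Ct_target - Ct_control)_sample -
    (Ct_target - Ct_control)_calibrator``.  The endogenous control gene
    must be measured in every sample; the calibrator defaults to the
    first sample in the table.
    """
    wide = ct.pivot_table(index="sample", columns="gene", values="ct")
    if control_gene not in wide.columns or wide[control_gene].isna().any():
        raise ValueError(f"control gene {control_gene!r} missing in some samples")
    if calibrator is None:
        calibrator = ct["sample"].iloc[0]
    if calibrator not in wide.index:
        raise ValueError(f"calibrator sample {calibrator!r} not found")

    dct = wide.drop(columns=control_gene).sub(wide[control_gene], axis=0)
    dd = dct - dct.loc[calibrator]
    rq = np.power(2.0, -dd)
    out = rq.reset_index().melt(id_vars="sample", var_name="gene", value_name="rq")
    return out.dropna(subset=["rq"]).reset_index(drop=True)
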