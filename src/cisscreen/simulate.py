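"""Synthetic screens, expression matrices and growth curves with known truth.

Every generator emits both the dataset (in the same schema the readers in
:mod:`cisscreen.tables` accept) and a :class:`SyntheticTruth` record of the
planted effects, so that each downstream stage can be tested as a
planted-parameter recovery problem without any external data.

The screen generator emulates a genome-wide sensitization screen in
384-well plates: four control classes randomly spotted in the first four
columns of each plate (24 transfection-reagent wells, 16 lethal
transfection-efficiency controls, 8 non-targeting wells, 16 positive
sensitization controls), triplicate gene wells in paired untreated /
cisplatin arms, a low drug dose at the no-observed-effect level (default
fraction affected 0.1), multiplicative plate batch factors, row/column
positional factors with an extra border depression, and lognormal
well-to-well count noise (counts of order 10^3 are dominated by
multiplicative variation, not shot noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cisscreen.tables import (
    ARMS,
    CONTROL_LAYOUT_COUNTS,
    PLATE_COLS,
    PLATE_ROWS,
    validate_plate_table,
)

#: Per-arm split of each control class within a plate (sums to the
#: per-plate layout counts 24/16/8/16).
_CONTROL_ARM_SPLIT = {role: n // 2 for role, n in CONTROL_LAYOUT_COUNTS.items()}

_CONTROL_COLS = (1, 2, 3, 4)


@dataclass
class ScreenSimConfig:
    """Study conditions for the simulated sensitization screen.

    Effects are on the viability percentage scale used by the scoring
    stage: ``sensitizer_effect`` is the mean extra viability loss (in
    %-points) a sensitizer gene adds under cisplatin, ``lethal_si`` the
    mean Survival Index of lethal genes, and ``drug_fa`` the baseline
    fraction affected of the drug alone (0.1 = the IC10 dose the screen is
    run at).  ``brca2_effect`` is the planted sensitization of the
    positive-control wells.
    """

    n_genes: int
    frac_sensitizers: float = 0.05
    frac_lethal: float = 0.05
    sensitizer_effect: float = 30.0
    sensitizer_effect_sd: float = 5.0
    sensitizer_effect_dist: str = "normal"
    lethal_si: float = 20.0
    lethal_si_sd: float = 5.0
    edge_effect: float = 0.0
    plate_sd: float = 0.0
    count_noise_cv: float = 0.1
    replicates: int = 3
    drug_fa: float = 0.1
    brca2_effect: float = 50.0
    base_count: float = 2000.0
    row_factors: dict = field(default_factory=dict)
    col_factors: dict = field(default_factory=dict)
    max_plates: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_sensitizers", "frac_lethal", "drug_fa"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.count_noise_cv < 0:
            raise ValueError("count_noise_cv must be >= 0")
        if self.sensitizer_effect_dist not in ("normal", "uniform"):
            raise ValueError("sensitizer_effect_dist must be 'normal' or 'uniform'")
        if not 0 <= self.edge_effect < 1:
            raise ValueError("edge_effect must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside every simulated dataset."""

    genes: pd.DataFrame | None = None
    plates: pd.DataFrame | None = None
    positions: pd.DataFrame | None = None
    expression: pd.DataFrame | None = None
    strains: pd.DataFrame | None = None

    def write(self, stem: str | Path) -> None:
        """Write each populated truth table as ``<stem>.<part>.truth.csv``."""
        stem = str(stem)
        for part in ("genes", "plates", "positions", "expression", "strains"):
            tab = getattr(self, part)
            if tab is not None:
                tab.to_csv(f"{stem}.{part}.truth.csv", index=False)


def _lognormal_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Unit-mean multiplicative noise with the given coefficient of variation."""
    z = rng.standard_normal(n)
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log1p(cv**2))
    return np.exp(z * sigma - sigma**2 / 2.0)


def _positional_factor(cfg: ScreenSimConfig, row: str, col: int) -> float:
    f = cfg.row_factors.get(row, 1.0) * cfg.col_factors.get(col, 1.0)
    if row in ("A", "P") or col in (1, 24):
        f *= 1.0 - cfg.edge_effect
    return f


def _draw_gene_truth(cfg: ScreenSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_genes
    genes = [f"G{i:05d}" for i in range(1, n + 1)]
    n_sens = int(round(cfg.frac_sensitizers * n))
    n_leth = int(round(cfg.frac_lethal * n))
    if n_sens + n_leth > n:
        raise ValueError("sensitizer and lethal fractions exceed the gene count")
    labels = np.array(["null"] * n, dtype=object)
    perm = rng.permutation(n)
    labels[perm[:n_sens]] = "sensitizer"
    labels[perm[n_sens : n_sens + n_leth]] = "lethal"

    si = np.full(n, 100.0)
    extra = np.zeros(n)
    leth = labels == "lethal"
    sens = labels == "sensitizer"
    si[leth] = np.clip(
        cfg.lethal_si + cfg.lethal_si_sd * rng.standard_normal(leth.sum()), 1.0, 50.0
    )
    if cfg.sensitizer_effect_dist == "uniform":
        # titration design: effects spread evenly over mean +/- sqrt(3)*sd
        half = math.sqrt(3.0) * cfg.sensitizer_effect_sd
        draws = rng.uniform(
            cfg.sensitizer_effect - half, cfg.sensitizer_effect + half, sens.sum()
        )
    else:
        draws = cfg.sensitizer_effect + cfg.sensitizer_effect_sd * rng.standard_normal(
            sens.sum()
        )
    extra[sens] = np.clip(draws, 0.0, 95.0)
    pct_cddp = np.clip(si * (1.0 - cfg.drug_fa) - extra, 0.0, None)
    return pd.DataFrame(
        {
            "gene": genes,
            "label": labels,
            "true_si": si,
            "true_pct_cddp": pct_cddp,
            "true_sensitization": si - pct_cddp,
        }
    )


def _plate_layout(cfg: ScreenSimConfig, rng: np.random.Generator, genes: list[str]):
    """Assign control and gene wells for one plate; returns per-well tuples."""
    control_wells = [(r, c) for c in _CONTROL_COLS for r in PLATE_ROWS]
    rng.shuffle(control_wells)
    assignments = []
    i = 0
    for role in ("rnaimax", "plk1", "scramble", "brca2"):
        for arm_i, arm in enumerate(ARMS):
            for _ in range(_CONTROL_ARM_SPLIT[role]):
                r, c = control_wells[i]
                assignments.append((r, c, role, arm))
                i += 1

    gene_wells = [(r, c) for c in PLATE_COLS if c not in _CONTROL_COLS for r in PLATE_ROWS]
    rng.shuffle(gene_wells)
    j = 0
    for g in genes:
        for arm in ARMS:
            for _ in range(cfg.replicates):
                r, c = gene_wells[j]
                assignments.append((r, c, f"gene:{g}", arm))
                j += 1
    return assignments


def simulate_screen(cfg: ScreenSimConfig):
    """Simulate a full screen; returns ``(plate_table, truth)``.

    Counts follow ``base * plate_factor * positional_factor * viability *
    lognormal_noise`` rounded to integers, where viability is the planted
    per-gene survival fraction of the well's arm.  The positive-control
    wells carry a fixed planted sensitization so that Potentiation is
    defined; the transfection-efficiency control wells are near-empty.

    Independent random substreams drive truth labels, well placement,
    plate factors and count noise, so two configurations differing only in
    effect sizes share identical noise realizations for a given seed.
    """
    ss = np.random.SeedSequence(cfg.seed)
    truth_rng, layout_rng, plate_rng, noise_rng = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    gene_truth = _draw_gene_truth(cfg, truth_rng)
    surv_u = dict(zip(gene_truth["gene"], gene_truth["true_si"] / 100.0))
    surv_c = dict(zip(gene_truth["gene"], gene_truth["true_pct_cddp"] / 100.0))
    # control viabilities per arm
    ctrl_u = {"rnaimax": 1.0, "scramble": 1.0, "brca2": 1.0, "plk1": 0.01}
    ctrl_c = {
        "rnaimax": 1.0 - cfg.drug_fa,
        "scramble": 1.0 - cfg.drug_fa,
        "brca2": max((100.0 * (1.0 - cfg.drug_fa) - cfg.brca2_effect) / 100.0, 0.0),
        "plk1": 0.01,
    }

    n_gene_wells = 16 * 20
    genes_per_plate = n_gene_wells // (2 * cfg.replicates)
    if genes_per_plate == 0:
        raise ValueError("replicates too high to fit a single gene on a plate")
    n_plates = math.ceil(cfg.n_genes / genes_per_plate)
    if cfg.max_plates is not None and n_plates > cfg.max_plates:
        raise ValueError(
            f"cannot schedule {cfg.n_genes} genes into {cfg.max_plates} plates; "
            f"{n_plates} plates required"
        )

    plate_z = plate_rng.standard_normal(n_plates)
    plate_factors = np.exp(cfg.plate_sd * plate_z)

    all_genes = list(gene_truth["gene"])
    records = []
    for p in range(n_plates):
        plate_id = f"P{p + 1:03d}"
        plate_genes = all_genes[p * genes_per_plate : (p + 1) * genes_per_plate]
        for row, col, role, arm in _plate_layout(cfg, layout_rng, plate_genes):
            if role.startswith("gene:"):
                g = role.split(":", 1)[1]
                viability = surv_u[g] if arm == "untreated" else surv_c[g]
            else:
                viability = (ctrl_u if arm == "untreated" else ctrl_c)[role]
            mean = (
                cfg.base_count
                * plate_factors[p]
                * _positional_factor(cfg, row, col)
                * viability
            )
            records.append((plate_id, row, col, role, arm, mean))

    df = pd.DataFrame(
        records, columns=["plate_id", "row", "col", "role", "arm", "count"]
    )
    noise = _lognormal_factors(noise_rng, len(df), cfg.count_noise_cv)
    df["count"] = np.rint(df["count"].to_numpy() * noise).astype(int)
    validate_plate_table(df)

    truth = SyntheticTruth(
        genes=gene_truth,
        plates=pd.DataFrame(
            {"plate_id": [f"P{p + 1:03d}" for p in range(n_plates)],
             "factor": plate_factors}
        ),
        positions=pd.DataFrame(
            [
                {"row": r, "col": c, "factor": _positional_factor(cfg, r, c)}
                for r in PLATE_ROWS
                for c in PLATE_COLS
            ]
        ),
    )
    return df, truth


def simulate_expression(
    n_genes: int,
    n_de_up: int,
    n_de_down: int,
    lfc_mean: float = 1.0,
    replicates: int = 3,
    timepoints: int = 2,
    noise_sd: float = 0.3,
    seed: int = 0,
):
    """Simulate a treated-vs-untreated log2 expression experiment.

    Baseline log2 intensities are uniform on [6, 12]; treated samples of
    the planted genes are shifted by ``+lfc_mean`` (up-regulated) or
    ``-lfc_mean`` (down-regulated); Gaussian noise of scale ``noise_sd``
    is added to every measurement.  Returns ``(matrix, metadata, truth)``.
    """
    if n_de_up + n_de_down > n_genes:
        raise ValueError("more DE genes requested than genes")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    genes = [f"E{i:05d}" for i in range(1, n_genes + 1)]
    lfc = np.zeros(n_genes)
    idx = rng.permutation(n_genes)
    lfc[idx[:n_de_up]] = lfc_mean
    lfc[idx[n_de_up : n_de_up + n_de_down]] = -lfc_mean

    tps = [f"{24 * (t + 1)}h" for t in range(timepoints)]
    meta = pd.DataFrame(
        [
            {"sample": f"{arm}_{tp}_r{r + 1}", "arm": arm, "timepoint": tp,
             "replicate": r + 1}
            for arm in ARMS
            for tp in tps
            for r in range(replicates)
        ]
    )
    base = rng.uniform(6.0, 12.0, n_genes)
    cols = {}
    for rec in meta.itertuples(index=False):
        shift = lfc if rec.arm == "cisplatin" else 0.0
        cols[rec.sample] = base + shift + noise_sd * rng.standard_normal(n_genes)
    matrix = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))

    truth = SyntheticTruth(
        expression=pd.DataFrame({"gene": genes, "true_lfc": lfc})
    )
    return matrix, meta, truth


def simulate_growth_curves(
    strains: dict,
    drug_effect_wt: float = 0.6,
    dt: float = 0.5,
    horizon: float = 24.0,
    od0: float = 0.07,
    noise_sd: float = 0.0,
    replicates: int = 6,
    seed: int = 0,
    interactions: dict | None = None,
):
    """Simulate OD600 growth curves under a multiplicative fitness model.

    ``strains`` maps strain name to its mutation fitness multiplier in
    (0, 1]; the wild type ("WT", multiplier 1.0) is added if absent.
    Curves are a common logistic-shaped growth increment scaled by the
    strain/condition fitness and offset by the inoculation density
    ``od0``, so the baseline-subtracted AUC ratio to WT-untreated equals
    the planted multiplier exactly at zero noise.  Under drug, fitness is
    ``mutation * drug_effect_wt * interaction`` (interaction defaults to
    1.0, i.e. purely multiplicative; values below 1 plant a synthetic
    sub-multiplicative drug-gene interaction).

    Readings every ``dt`` hours over ``horizon`` hours (49 timepoints at
    the defaults).  Returns ``(curves, truth)`` with curves in long form.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_steps = horizon / dt
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("horizon must be a whole multiple of dt")
    if not 0 < drug_effect_wt <= 1:
        raise ValueError("drug_effect_wt must be in (0, 1]")
    strains = dict(strains)
    strains.setdefault("WT", 1.0)
    for s, m in strains.items():
        if not 0 < m <= 1:
            raise ValueError(f"fitness multiplier for {s} must be in (0, 1]")
    interactions = dict(interactions or {})

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    t = np.arange(round(n_steps) + 1) * dt
    # logistic growth shape, re-zeroed at t=0 (carrying capacity 1.0 OD,
    # rate 0.6/h, midpoint 8 h: saturates comfortably within 24 h)
    shape = 1.0 / (1.0 + np.exp(-0.6 * (t - 8.0)))
    shape = shape - shape[0]

    rows = []
    truth_rows = []
    for strain in sorted(strains):
        mut = strains[strain]
        inter = interactions.get(strain, 1.0)
        for condition in ("untreated", "cisplatin"):
            f = mut if condition == "untreated" else mut * drug_effect_wt * inter
            truth_rows.append(
                {"strain": strain, "condition": condition,
                 "mutation_multiplier": mut, "interaction": inter,
                 "true_fitness": f}
            )
            for rep in range(1, replicates + 1):
                od = od0 + f * shape + noise_sd * rng.standard_normal(t.size)
                od = np.clip(od, 0.0, None)
                rows.extend(
                    {
                        "strain": strain,
                        "condition": condition,
                        "replicate": rep,
                        "time_h": tt,
                        "od600": oo,
                    }
                    for tt, oo in zip(t, od)
                )
    curves = pd.DataFrame(rows)
    truth = SyntheticTruth(strains=pd.DataFrame(truth_rows))
    return curves, truth
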