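import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cisscreen.multitest import bh_adjust, holm_adjust
from cisscreen.plate_effects import (
    PlateEffectModel,
    correct_counts,
    fit_plate_effects,
    gene_pvalues,
)
from cisscreen.scoring import score_screen
from cisscreen.simulate import ScreenSimConfig, simulate_screen


def _clean_cfg(**kw):
    base = dict(
        n_genes=106,
        frac_sensitizers=0.0,
        frac_lethal=0.0,
        count_noise_cv=0.0,
        drug_fa=0.0,
        seed=17,
    )
    base.update(kw)
    return ScreenSimConfig(**base)


class TestFitPlateEffects:
    def test_injected_row_factor_recovered(self):
        plates, _ = simulate_screen(_clean_cfg(row_factors={"A": 0.8}))
        model = fit_plate_effects(plates)
        # identifiability: factors renormalized to geometric mean 1
        gm = np.exp(np.log([0.8] + [1.0] * 15).mean())
        assert model.row_factors["A"] == pytest.approx(0.8 / gm, abs=1e-6)
        assert model.row_factors["B"] == pytest.approx(1.0 / gm, abs=1e-6)

    def test_no_effects_gives_unit_factors(self):
        plates, _ = simulate_screen(_clean_cfg())
        model = fit_plate_effects(plates)
        assert np.allclose(model.row_factors, 1.0, atol=1e-9)
        assert np.allclose(model.col_factors, 1.0, atol=1e-9)
        assert np.allclose(model.plate_factors, 1.0, atol=1e-9)

    def test_plate_factors_recovered_up_to_constraint(self):
        plates, _ = simulate_screen(_clean_cfg())  # exactly 2 plates
        scale = plates["plate_id"].map({"P001": 0.9, "P002": 1.1})
        plates = plates.assign(count=np.rint(plates["count"] * scale).astype(int))
        model = fit_plate_effects(plates)
        gm = np.sqrt(0.9 * 1.1)
        assert model.plate_factors["P001"] == pytest.approx(0.9 / gm, abs=1e-3)
        assert model.plate_factors["P002"] == pytest.approx(1.1 / gm, abs=1e-3)

    def test_all_zero_plate_flagged_and_excluded(self):
        plates, _ = simulate_screen(_clean_cfg())
        plates.loc[plates["plate_id"] == "P002", "count"] = 0
        model = fit_plate_effects(plates)
        assert model.flagged_plates == ["P002"]
        assert model.plate_factors["P002"] == 1.0

    def test_identifiability_constraints_hold(self):
        plates, _ = simulate_screen(
            _clean_cfg(edge_effect=0.2, plate_sd=0.1, count_noise_cv=0.1)
        )
        model = fit_plate_effects(plates)
        for f in (model.row_factors, model.col_factors, model.plate_factors):
            assert np.exp(np.log(f).mean()) == pytest.approx(1.0, abs=1e-9)

    def test_model_round_trips_through_frame(self):
        plates, _ = simulate_screen(_clean_cfg(edge_effect=0.1))
        model = fit_plate_effects(plates)
        back = PlateEffectModel.from_frame(model.to_frame())
        assert np.allclose(back.row_factors, model.row_factors)
        assert np.allclose(back.col_factors, model.col_factors)
        assert np.allclose(back.plate_factors, model.plate_factors)


class TestCorrectCounts:
    def test_null_model_is_identity(self, null_screen):
        plates, _ = null_screen
        model = fit_plate_effects(plates)
        corrected = correct_counts(plates, model)
        assert np.allclose(corrected["count"], plates["count"], rtol=1e-9)

    def test_correction_leaves_si_unbiased(self):
        cfg = _clean_cfg(
            n_genes=500,
            count_noise_cv=0.05,
            edge_effect=0.15,
            plate_sd=0.1,
            drug_fa=0.1,
            seed=23,
        )
        plates, _ = simulate_screen(cfg)
        model = fit_plate_effects(plates)
        s = score_screen(correct_counts(plates, model))
        assert abs(s["survival_index"].mean() - 100.0) < 0.5

    def test_refit_on_corrected_data_is_near_identity(self):
        plates, _ = simulate_screen(
            _clean_cfg(edge_effect=0.2, plate_sd=0.1,
                       row_factors={"C": 0.85}, col_factors={7: 1.2})
        )
        model = fit_plate_effects(plates)
        refit = fit_plate_effects(correct_counts(plates, model))
        # integer rounding of simulated counts leaves ~1e-4 residual factors
        for f in (refit.row_factors, refit.col_factors, refit.plate_factors):
            assert np.abs(np.log(f)).max() < 1e-3


class TestGenePvalues:
    def test_identical_arms_give_p_one(self, null_screen):
        plates, _ = null_screen
        pv = gene_pvalues(plates)
        assert (pv["p"] == 1.0).all()

    def test_power_on_planted_kill(self):
        cfg = ScreenSimConfig(
            n_genes=200,
            frac_sensitizers=1.0,
            frac_lethal=0.0,
            sensitizer_effect=50.0,
            sensitizer_effect_sd=0.0,
            count_noise_cv=0.05,
            drug_fa=0.0,
            seed=31,
        )
        plates, _ = simulate_screen(cfg)
        pv = gene_pvalues(plates)
        assert (pv["p"] < 0.05).mean() >= 0.95

    def test_single_replicate_flagged_missing(self):
        plates, _ = simulate_screen(_clean_cfg(n_genes=160, replicates=1))
        pv = gene_pvalues(plates)
        assert pv["flagged"].all()
        assert pv["p"].isna().all()


def _bh_oracle(p):
    m = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        js = np.arange(rank_i, m + 1)
        out[idx] = min(1.0, (p[order[js - 1]] * m / js).min())
    return out


class TestBHAdjust:
    def test_hand_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        assert bh_adjust([0.2])[0] == 0.2

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(derandomize=True, max_examples=200)
    def test_matches_bruteforce_definition(self, p):
        p = np.asarray(p)
        assert np.allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)

    def test_order_invariant(self, rng):
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_dominated_by_holm(self, rng):
        p = rng.uniform(size=25)
        assert (holm_adjust(p) >= bh_adjust(p) - 1e-12).all()
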