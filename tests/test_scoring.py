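import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cisscreen import scoring
from cisscreen.datasets import load_reference_gene_table


class TestMedianGeneCount:
    @pytest.mark.parametrize(
        "wells, expected",
        [
            ([1000, 1200, 50], 1000),  # one failed well cannot drag the gene
            ([100, 100, 100], 100),
            ([2, 4], 3),
        ],
    )
    def test_examples(self, wells, expected):
        assert scoring.median_gene_count(wells) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            scoring.median_gene_count([])


class TestSurvivalIndex:
    @pytest.mark.parametrize(
        "gene, ref, expected",
        [(948.2, 1000, 94.82), (1000, 1000, 100.0), (0, 1000, 0.0)],
    )
    def test_examples(self, gene, ref, expected):
        assert scoring.survival_index(gene, ref) == pytest.approx(expected)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="degenerate reference"):
            scoring.survival_index(500, 0)


class TestPotentiation:
    def test_self_normalization_and_sign(self):
        assert scoring.potentiation(40.0, 40.0) == 100.0
        assert scoring.potentiation(0.0, 40.0) == 0.0
        # protection: knockdown shields cells from the drug
        assert scoring.potentiation(-4.0, 40.0) == -10.0

    def test_failed_positive_control_rejected(self):
        with pytest.raises(ValueError, match="positive control failed"):
            scoring.potentiation(10.0, 0.0)


class TestGeneScore:
    def test_reproduces_published_scores_within_one(self):
        """Every printed (SI, Potentiation) pair reproduces its printed
        Gene Score after rounding, within the rounding of 2-decimal inputs."""
        ref = load_reference_gene_table()
        computed = np.rint(
            [scoring.gene_score(r.survival_index, r.potentiation)
             for r in ref.itertuples()]
        )
        assert (np.abs(computed - ref["gene_score"]) <= 1).all()

    def test_formula_limits(self):
        assert scoring.gene_score(100.0, 37.5) == 100.0 * 37.5
        assert scoring.gene_score(0.0, 37.5) == 0.0

    @given(d=st.floats(0, 100), p=st.floats(-100, 100))
    @settings(derandomize=True, max_examples=100)
    def test_symmetric_about_si_100(self, d, p):
        assert scoring.gene_score(100 + d, p) == pytest.approx(
            scoring.gene_score(100 - d, p)
        )


class TestRankGenes:
    def test_highest_score_first_and_tie_break(self):
        ranks = scoring.rank_genes(pd.Series({"A": 10.0, "B": 5.0, "C": 7.0}))
        assert ranks.to_dict() == {"A": 1, "C": 2, "B": 3}
        ranks = scoring.rank_genes(pd.Series({"B": 5.0, "A": 5.0}))
        assert ranks.to_dict() == {"A": 1, "B": 2}

    def test_ranks_are_permutation_matching_sort_oracle(self, rng):
        n = 2000
        scores = pd.Series(rng.normal(size=n), index=[f"G{i:04d}" for i in range(n)])
        ranks = scoring.rank_genes(scores)
        assert sorted(ranks) == list(range(1, n + 1))
        oracle = scores.sort_values(ascending=False).index
        assert list(ranks.sort_values().index) == list(oracle)


@pytest.mark.parametrize(
    "si, expected",
    [(12.43, True), (30.0, True), (30.0001, False), (100.0, False)],
)
def test_classify_lethal_boundary_inclusive(si, expected):
    assert scoring.classify_lethal(si) is expected


class TestSelectHitSet:
    def test_independent_null_size(self, rng):
        n = 10000
        df = pd.DataFrame(
            {
                "gene": [f"G{i}" for i in range(n)],
                "difference": rng.uniform(size=n),
                "survival_index": rng.uniform(size=n),
            }
        )
        hits = scoring.select_hit_set(df)
        # expected 0.10 * 0.25 * n = 250 under independence
        assert 190 <= len(hits) <= 310

    def test_degenerate_constant_passes_all(self):
        df = pd.DataFrame(
            {"gene": list("abc"), "difference": [1.0] * 3, "survival_index": [2.0] * 3}
        )
        assert scoring.select_hit_set(df) == {"a", "b", "c"}

    def test_dominating_gene_selected(self, rng):
        df = pd.DataFrame(
            {
                "gene": [f"G{i}" for i in range(100)],
                "difference": rng.uniform(size=100),
                "survival_index": rng.uniform(size=100),
            }
        )
        df.loc[0, ["difference", "survival_index"]] = [10.0, 10.0]
        assert "G0" in scoring.select_hit_set(df)


@pytest.mark.parametrize(
    "treated, untreated, expected",
    [(900, 1000, 0.1), (1000, 1000, 0.0), (1100, 1000, 0.0)],
)
def test_fraction_affected(treated, untreated, expected):
    assert scoring.fraction_affected(treated, untreated) == pytest.approx(expected)


class TestEstimateNoel:
    def test_exact_node(self):
        assert scoring.estimate_noel([0.1, 1, 10], [0, 0.1, 0.9]) == 1.0

    def test_log_scale_interpolation(self):
        # halfway in Fa between 0 and 0.2 -> halfway in log10 dose
        assert scoring.estimate_noel([1, 10], [0, 0.2]) == pytest.approx(10**0.5)

    def test_no_bracketing_doses(self):
        with pytest.raises(ValueError, match="no bracketing doses"):
            scoring.estimate_noel([1, 10], [0, 0])


class TestScoreScreen:
    def test_controls_score_as_expected_pseudo_genes(self, null_screen):
        plates, _ = null_screen
        s = scoring.score_screen(plates, include_controls=True).set_index("gene")
        assert s.loc["rnaimax", "survival_index"] == 100.0
        assert s.loc["brca2", "potentiation"] == 100.0

    def test_difference_scales_agree_on_sign(self, null_screen):
        plates, _ = null_screen
        pct = scoring.score_screen(plates, difference_scale="percent")
        cnt = scoring.score_screen(plates, difference_scale="count")
        assert (np.sign(pct["difference"]) == np.sign(cnt["difference"])).all()
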