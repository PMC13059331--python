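"""Positivity/co-expression summaries, ranking, module score, LSC gate."""

import numpy as np
import pandas as pd
import pytest

from citequant.synthetic import generate_expression
from citequant.targets import (
    LscGateParams,
    co_expression_fraction,
    lsc_gate,
    module_score,
    positivity_and_intensity,
    rank_targets,
)


def _estimates(**cols):
    return pd.DataFrame({k: np.asarray(v, float) for k, v in cols.items()})


class TestPositivity:
    def test_worked_example(self):
        est = _estimates(CD33=[500, 1500, 2000, 800])
        s = positivity_and_intensity(est, "CD33", 1000)
        assert s.pct_positive == pytest.approx(0.5)
        assert s.mean_positive == pytest.approx(1750)
        assert s.median_positive == pytest.approx(1750)

    def test_none_positive_reports_missing(self):
        est = _estimates(CD33=[999.9, 500, 100])
        s = positivity_and_intensity(est, "CD33", 1000)
        assert s.pct_positive == 0.0
        assert np.isnan(s.mean_positive) and np.isnan(s.median_positive)

    def test_zero_threshold_all_positive(self):
        est = _estimates(CD33=[1.0, 2.0, 3.0])
        assert positivity_and_intensity(est, "CD33", 0).pct_positive == 1.0

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            positivity_and_intensity(_estimates(CD33=[]), "CD33", 1000)

    def test_undersaturated_antibody_flagged(self):
        est = _estimates(CD99=[2000.0], CD33=[2000.0])
        assert positivity_and_intensity(est, "CD99", 1000).caution
        assert not positivity_and_intensity(est, "CD33", 1000).caution


class TestCoExpression:
    def test_worked_example(self):
        est = _estimates(A=[1500, 1500, 500, 500], B=[1500, 500, 1500, 500])
        assert co_expression_fraction(est, "A", "B", 1000) == pytest.approx(0.25)

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        est = _estimates(A=rng.lognormal(7, 1, 200), B=rng.lognormal(7, 1, 200))
        assert co_expression_fraction(est, "A", "B", 1000) == co_expression_fraction(
            est, "B", "A", 1000
        )

    def test_self_pairing_equals_positivity(self):
        est = _estimates(A=[1500, 800, 1200, 300])
        pct = positivity_and_intensity(est, "A", 1000).pct_positive
        assert co_expression_fraction(est, "A", "A", 1000) == pytest.approx(pct)

    def test_bounded_by_individual_positivity(self):
        rng = np.random.default_rng(1)
        est = _estimates(A=rng.lognormal(7, 1, 500), B=rng.lognormal(7, 1, 500))
        dual = co_expression_fraction(est, "A", "B", 1000)
        assert dual <= positivity_and_intensity(est, "A", 1000).pct_positive
        assert dual <= positivity_and_intensity(est, "B", 1000).pct_positive

    def test_zero_threshold_is_one(self):
        est = _estimates(A=[1.0, 2.0], B=[3.0, 4.0])
        assert co_expression_fraction(est, "A", "B", 0) == 1.0

    def test_unknown_antigen_rejected(self):
        with pytest.raises(KeyError):
            co_expression_fraction(_estimates(A=[1.0]), "A", "Z", 10)


class TestRankTargets:
    def _summary(self, antigen, sample, pct, median):
        from citequant.targets import AntigenSummary

        return AntigenSummary(
            sample_id=sample, antigen=antigen, population="blast", threshold=1000,
            pct_positive=pct, mean_positive=median, median_positive=median,
            n_cells=10, caution=False,
        )

    def test_universal_passer_ranked_first(self):
        summaries = [
            self._summary("GOOD", f"s{i}", 0.9, 2000) for i in range(3)
        ] + [self._summary("WEAK", f"s{i}", 0.5, 1500) for i in range(3)]
        ranked = rank_targets(summaries)
        assert ranked.iloc[0]["antigen"] == "GOOD"
        assert ranked.iloc[0]["criterion_fraction"] == 1.0

    def test_and_semantics_of_criterion(self):
        # high positivity but median below the count floor fails
        summaries = [self._summary("A", "s1", 0.9, 900)]
        ranked = rank_targets(summaries)
        assert ranked.iloc[0]["criterion_fraction"] == 0.0

    def test_ordering_matches_manual_sort(self):
        summaries = [
            self._summary("X", "s1", 0.9, 3000),
            self._summary("Y", "s1", 0.9, 1200),
            self._summary("Z", "s1", 0.9, 5000),
        ]
        ranked = rank_targets(summaries)
        assert list(ranked["antigen"]) == ["Z", "X", "Y"]

    def test_alphabetical_tie_break(self):
        summaries = [
            self._summary("B", "s1", 0.9, 2000),
            self._summary("A", "s1", 0.9, 2000),
        ]
        ranked = rank_targets(summaries)
        assert list(ranked["antigen"]) == ["A", "B"]


class TestModuleScore:
    def test_constant_expression_scores_zero(self):
        expr = pd.DataFrame(
            np.full((5, 48), 3.0), columns=[f"g{i}" for i in range(48)]
        )
        scores = module_score(expr, ["g0", "g1"], n_bins=24, seed=0)
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)

    def test_uniform_shift_recovered(self):
        """A gene set shifted by delta within its expression bins scores
        delta: controls are drawn from the unshifted bin mates."""
        delta = 3.0
        # 24 bins x 10 genes with identical within-bin expression; the shift
        # is smaller than the between-bin gap so bin membership is unchanged
        n_bins, per_bin = 24, 10
        values = np.repeat(10.0 * np.arange(1, n_bins + 1), per_bin)
        genes = [f"g{i}" for i in range(n_bins * per_bin)]
        expr = pd.DataFrame(np.tile(values, (20, 1)), columns=genes)
        gene_set = [f"g{k * per_bin}" for k in range(n_bins)]  # one per bin
        expr[gene_set] = expr[gene_set] + delta
        for seed in range(5):
            scores = module_score(expr, gene_set, n_bins=n_bins, seed=seed)
            np.testing.assert_allclose(scores, delta, atol=1e-9)

    def test_seed_determinism(self):
        expr = generate_expression(50, n_genes=200, seed=3)
        gene_set = list(expr.columns[:17])
        a = module_score(expr, gene_set, seed=11)
        b = module_score(expr, gene_set, seed=11)
        pd.testing.assert_series_equal(a, b)

    def test_missing_genes_dropped_with_warning(self):
        expr = generate_expression(20, n_genes=100, seed=4)
        with pytest.warns(UserWarning, match="absent"):
            scores = module_score(expr, [expr.columns[0], "NOT_A_GENE"], seed=0)
        assert len(scores) == 20

    def test_empty_gene_set_rejected(self):
        expr = generate_expression(20, n_genes=100, seed=5)
        with pytest.raises(ValueError), pytest.warns(UserWarning):
            module_score(expr, ["NOPE"], seed=0)


class TestLscGate:
    def test_default_thresholds_admit_stem_like_cell(self):
        mask = lsc_gate([0.5], [1.5], [0.2])
        assert mask[0]

    @pytest.mark.parametrize(
        "score,cd34,cd38",
        [
            (0.0, 1.5, 0.2),  # score not strictly positive
            (0.5, 1.0, 0.2),  # CD34 not strictly above 1
            (0.5, 1.5, 1.0),  # CD38 not strictly below 1
        ],
    )
    def test_strict_boundaries_excluded(self, score, cd34, cd38):
        assert not lsc_gate([score], [cd34], [cd38])[0]

    def test_gate_size_bounded_and_deterministic(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(0, 1, 500)
        cd34 = rng.normal(1, 0.5, 500)
        cd38 = rng.normal(1, 0.5, 500)
        mask = lsc_gate(scores, cd34, cd38)
        assert mask.sum() <= 500
        np.testing.assert_array_equal(mask, lsc_gate(scores, cd34, cd38))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lsc_gate([0.5, 0.2], [1.5], [0.2])
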