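"""Normalization, the moderated double-difference contrast, and calling."""

import numpy as np
import pandas as pd
import pytest

from ripscan import (
    ContrastResult,
    CountMatrix,
    RipSimConfig,
    TranscriptSet,
    adjust_bh,
    call_enriched,
    call_enriched_dual,
    fit_contrast,
    intersect_sets,
    normalize_counts,
    simulate_ripseq_counts,
)


def toy_design(conditions=("C", "W"), reps=3, cell_line="X"):
    rows = []
    for cond in conditions:
        for frac in ("input", "IP"):
            for rep in range(1, reps + 1):
                rows.append(
                    {
                        "sample": f"{cell_line}_{cond}_{frac}_{rep}",
                        "cell_line": cell_line,
                        "condition": cond,
                        "fraction": frac,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def toy_counts(values, design):
    genes = [f"g{i}" for i in range(len(values))]
    return CountMatrix(
        counts=pd.DataFrame(values, index=genes, columns=design["sample"].tolist()),
        design=design,
    )


class TestNormalize:
    def test_log_cpm_formula_at_zero_count(self):
        # one zero-count observation in a million-read library
        design = toy_design()
        vals = np.full((50, 12), 1000)
        vals[0, 0] = 0
        cm = toy_counts(vals, design)
        cm.lib_size[:] = 1e6
        norm = normalize_counts(CountMatrix(cm.counts, design, cm.lib_size), pseudocount=0.5)
        expected = np.log2(0.5 / (1e6 + 1.0) * 1e6)
        assert norm.logcpm.iloc[0, 0] == pytest.approx(expected)
        assert norm.logcpm.iloc[0, 0] == pytest.approx(-1.0, abs=1e-5)

    def test_scale_invariance_of_proportional_columns(self):
        design = toy_design()
        rng = np.random.default_rng(0)
        base = rng.integers(10, 1000, size=(100, 12))
        base[:, 1] = base[:, 0] * 2  # sample 2 is exactly twice sample 1
        cm = toy_counts(base, design)
        norm = normalize_counts(cm, pseudocount=0.0)
        np.testing.assert_allclose(norm.logcpm.iloc[:, 0], norm.logcpm.iloc[:, 1])

    def test_trend_monotone_decreasing_on_nb_counts(self):
        cfg = RipSimConfig(n_genes=2000, n_enriched=0, dispersion=0.2, seed=5)
        cm, _ = simulate_ripseq_counts(cfg)
        norm = normalize_counts(cm)
        # weights grow with expression when variance falls with the mean
        mean_expr = norm.logcpm.mean(axis=1)
        w = norm.weights.mean(axis=1)
        order = np.argsort(mean_expr.values)
        lo = w.values[order[: len(order) // 4]].mean()
        hi = w.values[order[-len(order) // 4 :]].mean()
        assert hi > lo

    def test_all_zero_genes_dropped(self):
        design = toy_design()
        vals = np.full((10, 12), 100)
        vals[3, :] = 0
        norm = normalize_counts(toy_counts(vals, design))
        assert "g3" not in norm.logcpm.index
        assert len(norm.logcpm) == 9

    def test_negative_counts_rejected(self):
        design = toy_design()
        vals = np.full((5, 12), 10)
        vals[2, 4] = -1
        with pytest.raises(ValueError, match="negative count"):
            toy_counts(vals, design)


class TestFitContrast:
    def test_zero_effect_dispersion_zero_gives_null_result(self):
        cfg = RipSimConfig(
            n_genes=100, n_enriched=0, enrichment_log2fc=0.0, dispersion=0.0,
            lib_sizes=tuple([1e6] * 12), seed=0,
        )
        cm, _ = simulate_ripseq_counts(cfg)
        res = fit_contrast(normalize_counts(cm))
        assert res.table["log2FC"].abs().max() == 0.0
        assert res.table["p"].min() > 0.99
        assert not res.table["enriched"].any()

    def test_planted_effect_recovered(self, recovery_run):
        _, _, truth, res = recovery_run
        enriched = truth.index[truth["is_enriched"]]
        mean_est = res.table.loc[enriched, "log2FC"].mean()
        assert mean_est == pytest.approx(2.0, abs=0.15)

    def test_unit_weight_contrast_equals_difference_of_group_means(self):
        # hand-checkable toy: the weighted fit with flat weights reduces to
        # the plain double difference of group means
        design = toy_design(reps=2)
        rng = np.random.default_rng(1)
        vals = rng.integers(100, 10000, size=(3, 8))
        cm = toy_counts(vals, design)
        norm = normalize_counts(cm)
        norm.weights.iloc[:, :] = 1.0
        res = fit_contrast(norm)
        y = norm.logcpm
        groups = design["condition"] + "." + design["fraction"]
        gm = {g: y.loc[:, (groups == g).values].mean(axis=1) for g in groups.unique()}
        expected = (gm["W.IP"] - gm["C.IP"]) - (gm["W.input"] - gm["C.input"])
        np.testing.assert_allclose(res.table["log2FC"], expected, rtol=1e-10)

    def test_type_one_error_calibrated_across_seeds(self):
        fracs = []
        for seed in range(5):
            cfg = RipSimConfig(n_genes=1000, n_enriched=0, seed=seed)
            cm, _ = simulate_ripseq_counts(cfg)
            res = fit_contrast(normalize_counts(cm))
            fracs.append((res.table["p"] < 0.05).mean())
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.02)

    def test_missing_design_cell_rejected(self):
        design = toy_design(conditions=("C",))
        cm = toy_counts(np.full((5, 6), 100), design)
        with pytest.raises(ValueError, match="lacks cells"):
            fit_contrast(normalize_counts(cm))


class TestAdjustBH:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    @pytest.mark.parametrize("p,expected", [([0.2], [0.2]), ([1.0, 1.0, 1.0], [1.0] * 3)])
    def test_degenerate_cases(self, p, expected):
        np.testing.assert_allclose(adjust_bh(p), expected)

    def test_adjusted_at_least_raw_and_bounded(self, rng):
        p = rng.random(200)
        adj = adjust_bh(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])


class TestCalling:
    def make_result(self, lfc, adj):
        tab = pd.DataFrame(
            {"log2FC": lfc, "t": 0.0, "p": adj, "adj_p": adj,
             "enriched": [False] * len(lfc)},
            index=[f"g{i}" for i in range(len(lfc))],
        )
        return ContrastResult(table=tab, contrast="W_vs_C")

    def test_strict_boundaries(self):
        # 1.36 / 0.01 sits inside the validated enrichment range and passes;
        # exactly 1.0 or alpha-boundary p fails the strict inequalities
        res = self.make_result([1.0, 1.36, 3.0], [0.001, 0.01, 0.06])
        called = call_enriched(res)
        assert called.genes == {"g1"}

    def test_monotone_in_thresholds(self, recovery_run):
        _, _, _, res = recovery_run
        base = call_enriched(res, 1.0, 0.05).genes
        assert call_enriched(res, 1.5, 0.05).genes <= base
        assert call_enriched(res, 1.0, 0.01).genes <= base

    def test_dual_criterion_is_intersection(self):
        a = self.make_result([2.0, 2.0, 0.0], [0.01, 0.01, 0.9])
        b = self.make_result([2.0, 0.5, 2.0], [0.01, 0.5, 0.01])
        dual = call_enriched_dual(a, b)
        assert dual.genes == {"g0"}

    def test_dual_requires_same_universe(self):
        a = self.make_result([1.5], [0.01])
        b = self.make_result([1.5, 2.0], [0.01, 0.01])
        with pytest.raises(ValueError, match="universe"):
            call_enriched_dual(a, b)

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"g1", "g2", "g3"}, {"g2", "g3", "g4"}, {"g2", "g3"}),
            ({"g1"}, {"g2"}, set()),
            ({"g1", "g2"}, {"g1", "g2"}, {"g1", "g2"}),
        ],
    )
    def test_intersect_sets(self, a, b, expected):
        out = intersect_sets(
            TranscriptSet("a", frozenset(a)), TranscriptSet("b", frozenset(b))
        )
        assert out.genes == expected
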