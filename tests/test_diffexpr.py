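"""Factorial ANOVA contrasts, BH adjustment, proximal-distal classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from conftest import summarize_raw_log2
from wingarray import adjust_fdr, fit_anova, proximal_distal_genes, log2_loess_normalize
from wingarray.diffexpr import ModelSpec, significant_contigs
from wingarray.preprocess import summarize_probes


def two_group_design(n=3):
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(2 * n)],
        "group": ["a"] * n + ["b"] * n,
    })


def bh_stepup_oracle(p):
    """Exhaustive BH step-up: q_(i) = min_{j>=i} m p_(j) / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q[order[rank - 1]] = running
    return q


class TestFitAnova:
    def test_two_group_closed_form(self):
        """(4,5,6) vs (1,2,3): estimate 3.0, t 3.674, df 4, p 0.0213."""
        design = two_group_design()
        expr = pd.DataFrame([[4.0, 5.0, 6.0, 1.0, 2.0, 3.0]],
                            index=["ctgA"], columns=design["sample_id"])
        res = fit_anova(expr, design, ModelSpec.two_group("group", "a", "b"))
        row = res.iloc[0]
        assert row["estimate"] == pytest.approx(3.0)
        assert row["statistic"] == pytest.approx(3.674, abs=5e-4)
        assert row["df"] == 4
        assert row["p"] == pytest.approx(0.0213, abs=5e-5)

    def test_matches_pooled_t_test_exactly(self):
        """Balanced two-group contrast p equals scipy's pooled t-test to 1e-10."""
        rng = np.random.default_rng(12)
        design = two_group_design(n=5)
        data = rng.normal(size=(40, 10))
        expr = pd.DataFrame(data, index=[f"c{i:03d}" for i in range(40)],
                            columns=design["sample_id"])
        res = fit_anova(expr, design, ModelSpec.two_group("group", "a", "b"))
        res = res.set_index("contig_id")
        _, p_ref = stats.ttest_ind(data[:, :5], data[:, 5:], axis=1)
        assert np.allclose(res.loc[[f"c{i:03d}" for i in range(40)], "p"], p_ref,
                           atol=1e-10, rtol=0)

    def test_constant_contig_degenerate(self):
        design = two_group_design()
        expr = pd.DataFrame([[2.0] * 6], index=["flat"], columns=design["sample_id"])
        res = fit_anova(expr, design, ModelSpec.two_group("group", "a", "b"))
        row = res.iloc[0]
        assert row["estimate"] == 0.0
        assert row["p"] == 1.0
        assert row["note"] == "degenerate"

    def test_empty_cell_reported_missing(self):
        design = two_group_design()
        expr = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]],
                            index=["c"], columns=design["sample_id"])
        res = fit_anova(expr, design, ModelSpec.two_group("group", "a", "zz"))
        assert res.iloc[0]["note"] == "empty_cell"
        assert np.isnan(res.iloc[0]["p"])

    def test_null_rejection_rate_calibrated(self, null_dataset):
        """Hindwing race contrasts on generator-null contigs reject at ~5%."""
        _, design, table, _, _ = null_dataset
        hw = design[design["wing"] == "hindwing"]
        sub = table[["probe_id", "x", "y", "contig_id"] + hw["sample_id"].tolist()]
        expr = summarize_probes(log2_loess_normalize(sub))
        res = fit_anova(expr, design, "pairwise_hindwing")
        one = res[res["comparison_id"] == "pw:D3:emma_vs_favorinus"]
        alpha = 0.05
        rate = (one["p"] < alpha).mean()
        se = np.sqrt(alpha * (1 - alpha) / len(one))
        assert abs(rate - alpha) < 3 * se

    def test_effect_size_monotonicity(self):
        """Doubling a two-group shift increases the mean |t| over 200 contigs."""
        rng = np.random.default_rng(5)
        design = two_group_design(n=4)
        spec = ModelSpec.two_group("group", "a", "b")
        mean_abs_t = []
        for delta in (0.5, 1.0):
            data = rng.normal(size=(200, 8))
            data[:, :4] += delta
            expr = pd.DataFrame(data, index=[f"c{i:03d}" for i in range(200)],
                                columns=design["sample_id"])
            res = fit_anova(expr, design, spec)
            mean_abs_t.append(res["statistic"].abs().mean())
        assert mean_abs_t[1] > mean_abs_t[0]

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            ModelSpec.for_family("nonsense")


class TestAdjustFdr:
    def test_worked_example(self):
        q = adjust_fdr([0.001, 0.01, 0.02, 0.9])
        assert np.allclose(q, [0.004, 0.02, 0.0266667, 0.9], atol=1e-6)

    def test_all_equal_is_fixed_point(self):
        assert np.allclose(adjust_fdr([0.3, 0.3, 0.3]), 0.3)

    def test_single_p_unchanged(self):
        assert adjust_fdr([0.123]) == pytest.approx(0.123)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.5], [np.nan, 0.2]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            adjust_fdr(bad)

    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0, exclude_min=False),
                    min_size=1, max_size=20))
    def test_matches_exhaustive_stepup(self, pvals):
        """BH adjustment equals the exhaustive step-up definition on any
        vector of length <= 20."""
        assert np.allclose(adjust_fdr(pvals), bh_stepup_oracle(pvals), atol=1e-12)

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=2, max_size=20))
    def test_q_monotone_in_p_rank(self, pvals):
        p = np.asarray(pvals)
        q = adjust_fdr(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all()


class TestProximalDistal:
    def _results(self, contig, est_pd, est_md, q=0.001):
        """Section-family rows for one contig at one stage with given relative
        means (proximal-distal and medial-distal estimates)."""
        rows = []
        for pair, est in (("proximal_vs_medial", est_pd - est_md),
                          ("proximal_vs_distal", est_pd),
                          ("medial_vs_distal", est_md)):
            rows.append({"contig_id": contig, "comparison_id": f"sec:D3:{pair}",
                         "estimate": est, "statistic": 5.0, "df": 40,
                         "p": q / 10, "q": q, "note": ""})
        return rows

    def test_pattern_classification(self):
        rows = (self._results("prox", 1.5, 0.0)
                + self._results("dist", -1.5, 0.0)
                + self._results("medial", 0.0, 1.2))
        res = proximal_distal_genes(pd.DataFrame(rows), fdr=0.01)
        patterns = res.set_index("contig_id")["pattern"]
        assert patterns["prox"] == "higher_proximal"
        assert patterns["dist"] == "higher_distal"
        assert patterns["medial"] == "medial_vs_peripheral"

    def test_fdr_zero_gives_empty_list(self):
        rows = self._results("prox", 1.5, 0.0)
        res = proximal_distal_genes(pd.DataFrame(rows), fdr=0.0)
        assert res.empty

    def test_planted_genes_recovered(self, recovery_run):
        """Planted proximal-up contigs appear with pattern higher_proximal."""
        truth = recovery_run.truth.set_index("contig_id")
        pd_genes = recovery_run.pd_genes.set_index("contig_id")
        planted = truth.index[truth["effect_class"] == "proximal_up"]
        recovered = pd_genes.index.intersection(planted)
        assert len(recovered) / len(planted) >= 0.8
        assert (pd_genes.loc[recovered, "pattern"] == "higher_proximal").mean() >= 0.9

    def test_realized_fdr_within_twice_nominal(self, recovery_run):
        """Fraction of the proximal-distal list without a planted section
        effect stays <= 2x the nominal 0.01 FDR."""
        assert recovery_run.report.pd_realized_fdr is not None
        assert recovery_run.report.pd_realized_fdr <= 0.02

    def test_significant_contigs_threshold(self):
        rows = self._results("a", 1.0, 0.0, q=0.005) + self._results("b", 1.0, 0.0, q=0.5)
        res = pd.DataFrame(rows)
        assert significant_contigs(res, 0.01) == ["a"]
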