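"""Group statistics against hand/rank-formula oracles, degenerate-input
conventions, and null-calibration simulations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from meanet.stats import (
    condition_genotype_comparison,
    kruskal_wallis,
    paired_t,
    sidak_adjust,
    welch_t,
)


def _kw_rank_formula(groups):
    """Independent oracle: H from average ranks, no tie correction needed for
    distinct values."""
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    return 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)


class TestKruskalWallis:
    def test_rank_formula_oracle(self):
        groups = [[1, 2, 3], [4, 5, 6]]
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(_kw_rank_formula(groups))
        assert res.statistic == pytest.approx(3.857, abs=0.001)
        assert res.df == 1
        assert res.p_value == pytest.approx(sps.chi2.sf(res.statistic, 1))

    def test_identical_groups_degenerate(self):
        res = kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert res.degenerate and res.statistic == 0.0 and res.p_value == 1.0

    def test_monotone_transform_invariance(self, rng):
        a = rng.normal(0, 1, 20).tolist()
        b = rng.normal(0.5, 1, 25).tolist()
        r1 = kruskal_wallis([a, b])
        r2 = kruskal_wallis([np.exp(a).tolist(), np.exp(b).tolist()])
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(777)
        rejections = 0
        n_reps = 1000
        for _ in range(n_reps):
            a = rng.poisson(5, 50)
            b = rng.poisson(5, 50)
            if kruskal_wallis([a, b]).p_value < 0.05:
                rejections += 1
        lo, hi = sps.binom.ppf([0.025, 0.975], n_reps, 0.05)
        assert lo <= rejections <= hi

    def test_input_validation(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


class TestPairedT:
    def test_no_change_degenerate(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.p_value == 1.0 and res.statistic == 0.0

    def test_constant_nonzero_differences_flagged(self):
        res = paired_t([0.0, 0.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0])
        assert res.degenerate
        assert res.statistic > 0  # direction of the common difference

    def test_hand_formula(self):
        # d = {1,2,3,4}: mean 2.5, sd sqrt(5/3), t = 2.5 / (sd/2)
        before = [0.0, 0.0, 0.0, 0.0]
        after = [1.0, 2.0, 3.0, 4.0]
        res = paired_t(before, after)
        expected = 2.5 / (np.sqrt(5.0 / 3.0) / 2.0)
        assert res.statistic == pytest.approx(expected)
        assert res.df == 3

    def test_null_p_uniform(self):
        rng = np.random.default_rng(55)
        ps = []
        for _ in range(1000):
            b = rng.normal(0, 1, 50)
            a = b + rng.normal(0, 1, 50)
            ps.append(paired_t(b, a).p_value)
        d = sps.kstest(ps, "uniform").statistic
        assert d < 0.05


class TestWelchT:
    def test_identical_groups_zero(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0

    def test_shift_oracle(self):
        a = [1.0, 2.0, 3.0]
        b = [11.0, 12.0, 13.0]
        res = welch_t(a, b)
        # equal variances 1: se = sqrt(2/3), |t| = 10/se
        assert abs(res.statistic) == pytest.approx(10.0 / np.sqrt(2.0 / 3.0))

    def test_antisymmetry(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(1, 2, 12)
        r1 = welch_t(a, b)
        r2 = welch_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)


class TestSidak:
    def test_single_contrast_identity(self):
        assert sidak_adjust(0.04, 1) == pytest.approx(0.04)

    def test_direct_formula(self):
        assert sidak_adjust(0.02, 3) == pytest.approx(1 - 0.98**3)

    def test_monotone_and_bounded(self):
        p = 0.03
        adj = [sidak_adjust(p, m) for m in range(1, 8)]
        assert adj == sorted(adj)
        assert all(a >= p for a in adj)


class TestFactorial:
    def _table(self, values):
        rows = []
        k = 0
        for g in ("APOE3", "APOE4"):
            for a in range(4):
                for c in ("BL", "GABA", "PTX"):
                    rows.append(
                        {"assembloid": f"{g}-{a}", "genotype": g, "condition": c,
                         "value": values[k]}
                    )
                    k += 1
        return pd.DataFrame(rows)

    def test_constant_metric_all_f_zero(self):
        results = condition_genotype_comparison(self._table([1.0] * 24))
        anova = [r for r in results if r.test_name.startswith("anova")]
        assert len(anova) == 3
        assert all(r.statistic == 0.0 and r.degenerate for r in anova)

    def test_genotype_effect_detected_and_sidak_applied(self, rng):
        base = {"BL": 1.0, "GABA": 0.5, "PTX": 2.0}
        values = []
        for g_off in (0.0, 3.0):
            for _ in range(4):
                for c in ("BL", "GABA", "PTX"):
                    values.append(base[c] + g_off + rng.normal(0, 0.1))
        results = condition_genotype_comparison(self._table(values))
        anova = {r.test_name: r for r in results if r.test_name.startswith("anova")}
        assert anova["anova_genotype"].p_value < 0.001
        contrasts = [r for r in results if r.adjustment == "sidak"]
        assert len(contrasts) == 3
        for r in contrasts:
            assert r.p_adjusted == pytest.approx(sidak_adjust(r.p_value, 3))

    def test_missing_cell_reported(self):
        table = self._table([1.0] * 24)
        table = table[~((table.genotype == "APOE4") & (table.condition == "PTX"))]
        with pytest.raises(ValueError, match="APOE4"):
            condition_genotype_comparison(table)
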