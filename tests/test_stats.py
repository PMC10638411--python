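import numpy as np
import pandas as pd
import pytest

from semdem import stats as S


def toy_counts():
    rows = []
    for inst in (0, 1):
        for lt in ("GM", "WM"):
            for sev in (0, 90):
                for wid, cat in (("w0", "object"), ("w1", "action")):
                    for area, n0 in (("A1", 40), ("AT", 20)):
                        n = n0 if sev == 0 else int(n0 * (0.75 if area == "A1" else 0.25))
                        rows.append((inst, lt, sev, wid, cat, area, n))
    return pd.DataFrame(rows, columns=["instance", "lesion_type", "severity",
                                       "word_id", "category", "area",
                                       "responsive_ca_count"])


class TestNormalisation:
    def test_ratio_arithmetic(self):
        t = S.normalize_to_intact(toy_counts())
        r = t[(t.severity == 90) & (t.area == "A1")]["ratio"].unique()
        assert np.allclose(r, 0.75)
        assert np.allclose(t[t.severity == 0]["ratio"], 1.0)

    def test_zero_intact_rows_dropped(self):
        df = toy_counts()
        df.loc[(df.area == "AT") & (df.word_id == "w0"), "responsive_ca_count"] = 0
        t = S.normalize_to_intact(df)
        assert not ((t.area == "AT") & (t.word_id == "w0")).any()

    def test_missing_baseline_rejected(self):
        df = toy_counts()
        df = df[~((df.severity == 0) & (df.word_id == "w1") & (df.lesion_type == "GM"))]
        with pytest.raises(ValueError):
            S.normalize_to_intact(df)

    def test_system_aggregate_is_sum_ratio(self):
        t = S.normalize_to_intact(toy_counts())
        sr = S.system_ratios(t)
        # brute force: sum counts within system cells, then divide
        for _, row in sr.iterrows():
            sub = t[(t.instance == row.instance) & (t.lesion_type == row.lesion_type)
                    & (t.severity == row.severity) & (t.category == row.category)
                    & (t.system == row.system)]
            assert row.ratio == pytest.approx(
                sub.responsive_ca_count.sum() / sub.intact_count.sum())

    def test_decline_percent(self):
        t = S.normalize_to_intact(toy_counts())
        d = S.decline_percent(t)
        extra = d[d.system == "extrasylvian"]["decline_pct"].unique()
        peri = d[d.system == "perisylvian"]["decline_pct"].unique()
        assert np.allclose(extra, 75.0) and np.allclose(peri, 25.0)


def manual_oneway_rm_anova(data: np.ndarray):
    """Textbook partitioned sums of squares for a one-way within-subject
    design; data has shape (subjects, levels)."""
    n, k = data.shape
    grand = data.mean()
    ss_between = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_subject = k * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_error = ss_total - ss_between - ss_subject
    df_b, df_e = k - 1, (k - 1) * (n - 1)
    return (ss_between / df_b) / (ss_error / df_e), df_b, df_e


class TestRmAnova:
    @staticmethod
    def long(data):
        n, k = data.shape
        return pd.DataFrame({
            "instance": np.repeat(np.arange(n), k),
            "severity": np.tile(np.arange(k), n),
            "ratio": data.ravel(),
        })

    def test_matches_hand_partitioned_sums_of_squares(self):
        data = np.array([[4.0, 6.0, 8.0],
                         [3.0, 7.0, 9.0],
                         [5.0, 6.0, 10.0],
                         [4.5, 5.5, 7.5]])
        f_manual, df_b, df_e = manual_oneway_rm_anova(data)
        res = S.rm_anova(self.long(data), dv="ratio", within=["severity"])
        assert len(res) == 1
        assert res[0].F == pytest.approx(f_manual, abs=1e-10)
        assert res[0].df_num == df_b and res[0].df_den == df_e

    def test_constant_table_degenerate(self):
        data = np.full((4, 3), 2.0)
        res = S.rm_anova(self.long(data), dv="ratio", within=["severity"])
        assert np.isnan(res[0].F) or res[0].F == pytest.approx(0.0)

    def test_two_factor_effects_reported(self):
        rng = np.random.default_rng(0)
        rows = []
        for inst in range(6):
            for sys_ in (0, 1):
                for sev in range(4):
                    rows.append((inst, sys_, sev,
                                 sys_ * sev + rng.normal(scale=0.1)))
        df = pd.DataFrame(rows, columns=["instance", "system", "severity", "ratio"])
        res = S.rm_anova(df, dv="ratio", within=["system", "severity"])
        effects = {r.effect for r in res}
        assert any("*" in e or "Interaction" in e for e in effects)
        inter = [r for r in res if "*" in r.effect or "Interaction" in r.effect][0]
        assert inter.p < 0.001  # strong built-in interaction is detected

    def test_unbalanced_table_rejected(self):
        df = self.long(np.ones((4, 3)))
        with pytest.raises(ValueError, match="missing"):
            S.rm_anova(df.iloc[:-1], dv="ratio", within=["severity"])

    def test_power_on_known_interaction(self):
        """A built-in system x severity interaction plus noise is detected at
        alpha=0.001 in at least 95% of simulations at n=13 subjects."""
        rng = np.random.default_rng(1)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            rows = []
            for inst in range(13):
                for sys_ in (0, 1):
                    for sev in range(4):
                        y = sys_ * sev + rng.normal(scale=0.5)
                        rows.append((inst, sys_, sev, y))
            df = pd.DataFrame(rows, columns=["instance", "system", "severity", "ratio"])
            res = S.rm_anova(df, dv="ratio", within=["system", "severity"])
            inter = [r for r in res if "*" in r.effect][0]
            hits += inter.p < 0.001
        assert hits / n_sim >= 0.95


class TestPairedTests:
    def test_identical_vectors(self):
        out = S.paired_t_bonferroni({"null": (np.ones(5), np.ones(5))})
        assert out[0].t == 0.0 and out[0].p_corrected == 1.0

    def test_single_contrast_uncorrected(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=13)
        y = x + rng.normal(size=13)
        out = S.paired_t_bonferroni({"c": (x, y)})
        assert out[0].p_corrected == pytest.approx(out[0].p_raw)

    def test_known_shift_matches_direct_formula(self):
        rng = np.random.default_rng(4)
        d = rng.normal(loc=1.0, scale=1.0, size=13)
        x = rng.normal(size=13)
        out = S.paired_t_bonferroni({"c": (x + d, x)})
        t_direct = d.mean() / (d.std(ddof=1) / np.sqrt(13))
        assert out[0].t == pytest.approx(t_direct, abs=1e-10)
        assert out[0].df == 12

    def test_bonferroni_scales_with_family(self):
        rng = np.random.default_rng(5)
        fam = {f"c{i}": (rng.normal(size=8), rng.normal(size=8)) for i in range(4)}
        out = S.paired_t_bonferroni(fam)
        for c in out:
            assert c.p_corrected == pytest.approx(min(1.0, c.p_raw * 4))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            S.paired_t_bonferroni({"c": (np.array([1.0]), np.array([2.0]))})


class TestLesionExpectationOracle:
    def test_two_assembly_toy_cells(self):
        cells = [{"c1"}, {"c2"}]
        assert S.lesion_expectation_oracle(cells, "cells", 1) == pytest.approx(1.0)

    def test_two_assembly_toy_links(self):
        links = [{"a", "b"}, {"g", "d"}]
        e = S.lesion_expectation_oracle(links, "links", 2)
        assert e == pytest.approx(10.0 / 6.0)

    def test_remove_everything(self):
        links = [{"a", "b"}, {"g", "d"}]
        assert S.lesion_expectation_oracle(links, "links", 4) == pytest.approx(2.0)

    def test_remove_nothing(self):
        assert S.lesion_expectation_oracle([{"a"}, {"b"}], "cells", 0) == 0.0

    def test_over_removal_rejected(self):
        with pytest.raises(ValueError):
            S.lesion_expectation_oracle([{"a"}], "cells", 2)
        with pytest.raises(ValueError):
            S.lesion_expectation_oracle([{"a"}], "bonds", 1)

    def test_exhaustive_equals_hypergeometric(self):
        rng = np.random.default_rng(6)
        universe = list(range(12))
        for _ in range(10):
            k = rng.integers(2, 5)
            cas = [set(rng.choice(universe, size=rng.integers(1, 5), replace=False).tolist())
                   for _ in range(k)]
            pop = sorted(set().union(*cas))
            n_rm = int(rng.integers(1, len(pop) + 1))
            exact = S.lesion_expectation_oracle(cas, "cells", n_rm)
            hyper = S.lesion_expectation_oracle(cas, "cells", n_rm, exhaustive_limit=0)
            assert exact == pytest.approx(hyper, abs=1e-12)

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(7)
        cas = [{0, 1, 2}, {2, 3}, {4, 5, 6, 7}]
        pop = sorted(set().union(*cas))
        n_rm = 3
        exact = S.lesion_expectation_oracle(cas, "cells", n_rm)
        draws = 100_000
        ranks = rng.random((draws, len(pop))).argpartition(n_rm, axis=1)[:, :n_rm]
        removed = np.asarray(pop)[ranks]              # (draws, n_rm) removed cells
        hits = np.zeros(draws)
        for ca in cas:
            hits += np.isin(removed, list(ca)).any(axis=1)
        assert abs(hits.mean() - exact) < 3 * hits.std(ddof=1) / np.sqrt(draws)
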