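import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from qpcrkinetics.design import MONOLAYER
from qpcrkinetics.stats import (
    SCOPE_MONOLAYER,
    SCOPE_TIME,
    anova_oneway,
    celltype_contrasts,
    log_transform,
    timecourse_contrasts,
    tukey_contrasts,
)


def anova_f_oracle(groups):
    """Brute-force between/within sums-of-squares computation."""
    values = np.concatenate(list(groups.values()))
    grand = values.mean()
    ssb = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
    ssw = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in groups.values())
    dfb = len(groups) - 1
    dfw = len(values) - len(groups)
    return (ssb / dfb) / (ssw / dfw)


def _expr_frame(values_by_time, gene="G", cell_type="IZ"):
    rows = []
    for t, values in values_by_time.items():
        for i, v in enumerate(values):
            rows.append(
                {
                    "gene": gene, "sample_id": f"{t}_{i}", "cell_type": cell_type,
                    "time_point": t, "replicate": i + 1, "rq": 2.0**v, "log2_rq": v,
                }
            )
    return pd.DataFrame(rows)


class TestLogTransform:
    def test_log2_of_rq(self):
        rq = pd.DataFrame({"gene": ["G", "G"], "sample_id": ["a", "b"], "rq": [1.0, 0.25]})
        out = log_transform(rq)
        assert list(out["log2_rq"]) == [0.0, -2.0]

    def test_nonpositive_rq_rejected(self):
        rq = pd.DataFrame({"gene": ["G"], "sample_id": ["a"], "rq": [0.0]})
        with pytest.raises(ValueError, match="nonpositive"):
            log_transform(rq)

    def test_f_statistic_invariant_to_log_base(self):
        rng = np.random.default_rng(1)
        groups2 = {k: rng.normal(size=5) for k in "abc"}
        f_log2 = anova_oneway(groups2).f_stat
        f_ln = anova_oneway({k: v * np.log(2) for k, v in groups2.items()}).f_stat
        assert f_log2 == pytest.approx(f_ln, rel=1e-12)


class TestAnova:
    def test_two_groups_f_is_t_squared(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=6), rng.normal(loc=0.8, size=9)
        fit = anova_oneway({"a": a, "b": b})
        t, p = sps.ttest_ind(a, b)
        assert fit.f_stat == pytest.approx(t**2, rel=1e-12)
        assert fit.p_value == pytest.approx(p, rel=1e-10)

    def test_matches_hand_computed_sums_of_squares(self):
        groups = {"g1": [1, 2, 3], "g2": [2, 3, 4], "g3": [6, 7, 8]}
        fit = anova_oneway(groups)
        # means 2, 3, 7; grand mean 4; SSB = 3*(4+1+9) = 42; SSW = 6; F = 21
        assert fit.ss_between == pytest.approx(42.0)
        assert fit.ss_within == pytest.approx(6.0)
        assert fit.f_stat == pytest.approx(21.0)
        assert fit.f_stat == pytest.approx(anova_f_oracle(groups), rel=1e-12)

    def test_degenerate_zero_variance(self):
        with pytest.warns(UserWarning, match="degenerate"):
            fit = anova_oneway({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        assert fit.ss_between == 0.0 and fit.ss_within == 0.0
        with pytest.warns(UserWarning, match="degenerate"):
            fit = anova_oneway({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert fit.p_value == 0.0

    def test_small_group_rejected_by_name(self):
        with pytest.raises(ValueError, match="tiny"):
            anova_oneway({"ok": [1.0, 2.0], "tiny": [1.0]})


class TestTukey:
    def test_k2_equals_pooled_ttest(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a, b = rng.normal(size=7), rng.normal(loc=0.5, size=7)
            fit = anova_oneway({"a": a, "b": b})
            (contrast,) = tukey_contrasts(fit)
            _, p = sps.ttest_ind(a, b)
            assert contrast.p_adj == pytest.approx(p, abs=1e-6)

    def test_q_critical_matches_published_table(self):
        # studentized range upper 5% point for k=3 groups, 10 df: 3.88
        q = sps.studentized_range.ppf(0.95, 3, 10)
        assert q == pytest.approx(3.88, abs=5e-3)

    def test_identical_means_give_p_one(self):
        fit = anova_oneway({"a": [1.0, 2.0, 3.0], "b": [3.0, 2.0, 1.0], "c": [0.0, 2.0, 4.0]})
        results = {(" ".join((c.level_a, c.level_b))): c for c in tukey_contrasts(fit)}
        assert results["a b"].p_adj == pytest.approx(1.0)

    def test_adjustment_never_anticonservative(self):
        """Tukey p is never below the unadjusted pooled-variance pairwise p."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            groups = {k: rng.normal(loc=rng.normal(), size=6) for k in "abcd"}
            fit = anova_oneway(groups)
            for c in tukey_contrasts(fit):
                se = np.sqrt(fit.mse * (1 / fit.n(c.level_a) + 1 / fit.n(c.level_b)))
                t = abs(c.estimate) / se
                p_raw = 2 * sps.t.sf(t, fit.df_resid)
                assert c.p_adj >= p_raw - 1e-12

    def test_agrees_with_reference_implementations(self):
        """F vs scipy.f_oneway and Tukey p vs statsmodels on random data."""
        sm = pytest.importorskip("statsmodels.stats.multicomp")
        rng = np.random.default_rng(5)
        for _ in range(100):
            k = int(rng.integers(3, 6))
            sizes = rng.integers(4, 9, size=k)
            groups = {
                f"g{j}": rng.normal(loc=rng.normal(scale=0.5), size=n)
                for j, n in enumerate(sizes)
            }
            fit = anova_oneway(groups)
            f_ref, _ = sps.f_oneway(*groups.values())
            assert fit.f_stat == pytest.approx(f_ref, abs=1e-8, rel=1e-10)
            values = np.concatenate(list(groups.values()))
            labels = np.concatenate([[g] * len(v) for g, v in groups.items()])
            ref = sm.pairwise_tukeyhsd(values, labels)
            ours = {
                frozenset((c.level_a, c.level_b)): c.p_adj for c in tukey_contrasts(fit)
            }
            for row, p_ref in zip(ref.summary().data[1:], ref.pvalues):
                key = frozenset((str(row[0]), str(row[1])))
                assert ours[key] == pytest.approx(p_ref, abs=1e-8)


class TestTimecourse:
    def _step_gene(self, seed=6, magnitude=2.0, onset=12.0, noise=0.2, n=7):
        rng = np.random.default_rng(seed)
        times = [MONOLAYER, "0", "1.5", "3", "6", "12", "24", "48", "96", "168", "336"]
        values = {
            t: (magnitude if t not in (MONOLAYER,) and float(t) >= onset else 0.0)
            + rng.normal(0, noise, size=n)
            for t in times
        }
        return _expr_frame(values)

    def test_step_gene_significant_exactly_after_onset(self):
        expr = self._step_gene()
        contrasts = timecourse_contrasts(expr, "G", "IZ")
        assert len(contrasts) == 10
        by_level = {c.level_a: c for c in contrasts}
        for t in ("12", "24", "48", "96", "168", "336"):
            assert by_level[t].significant and by_level[t].direction == "UP"
        for t in ("1.5", "3", "6"):
            assert not by_level[t].significant

    def test_monolayer_contrast_scope_and_direction(self):
        rng = np.random.default_rng(7)
        times = [MONOLAYER, "0", "1.5", "3"]
        # monolayer expressed 1 cycle lower (log2RQ -1), all else flat
        values = {
            t: (-1.0 if t == MONOLAYER else 0.0) + rng.normal(0, 0.1, size=7) for t in times
        }
        contrasts = timecourse_contrasts(_expr_frame(values), "G", "IZ")
        mono = [c for c in contrasts if c.scope == SCOPE_MONOLAYER]
        assert len(mono) == 1
        assert mono[0].significant and mono[0].direction == "DOWN"
        assert all(c.scope == SCOPE_TIME for c in contrasts if c is not mono[0])

    def test_missing_baseline_is_an_error(self):
        expr = self._step_gene()
        expr = expr[expr["time_point"] != "0"]
        with pytest.raises(ValueError, match="baseline"):
            timecourse_contrasts(expr, "G", "IZ")

    def test_sparse_level_dropped_with_warning(self):
        expr = self._step_gene()
        expr = expr.drop(expr[expr["time_point"] == "3"].index[1:])
        with pytest.warns(UserWarning, match="dropped"):
            contrasts = timecourse_contrasts(expr, "G", "IZ")
        assert "3" not in {c.level_a for c in contrasts}


class TestCelltype:
    def _three_groups(self, shift=0.0, seed=8, noise=0.2, n=7):
        """Identical replicate values in every cell type; FB optionally shifted."""
        rng = np.random.default_rng(seed)
        base = rng.normal(0, noise, size=n)
        rows = []
        for ct in ("IZ", "ANL", "FB"):
            offset = shift if ct == "FB" else 0.0
            for i, v in enumerate(offset + base):
                rows.append(
                    {
                        "gene": "G", "sample_id": f"{ct}_{i}", "cell_type": ct,
                        "time_point": "6", "replicate": i + 1, "rq": 2.0**v, "log2_rq": v,
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_groups_not_significant(self):
        contrasts = celltype_contrasts(self._three_groups(), "G", "6")
        assert len(contrasts) == 3
        assert not any(c.significant for c in contrasts)
        assert all(c.p_adj == pytest.approx(1.0) for c in contrasts)

    def test_shifted_celltype_flags_its_two_pairs(self):
        contrasts = celltype_contrasts(self._three_groups(shift=3.0), "G", "6")
        sig = {frozenset((c.level_a, c.level_b)) for c in contrasts if c.significant}
        assert sig == {frozenset(("FB", "IZ")), frozenset(("FB", "ANL"))}

    def test_missing_celltype_omits_its_pairs(self):
        full = self._three_groups()
        one_fb = full[full["cell_type"] == "FB"].iloc[:1]
        data = pd.concat([full[full["cell_type"] != "FB"], one_fb])
        with pytest.warns(UserWarning, match="omitted"):
            contrasts = celltype_contrasts(data, "G", "6")
        assert {frozenset((c.level_a, c.level_b)) for c in contrasts} == {
            frozenset(("IZ", "ANL"))
        }
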