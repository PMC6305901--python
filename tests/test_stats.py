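import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perturbstance.errors import InvalidParameterError, UnbalancedDesignError
from perturbstance.stats import (
    fdr_by,
    normalize_to_predicted,
    render_report,
    rm_anova,
    spearman,
    summary_table,
)


# ---------------------------------------------------------------------------
# normalization


class TestNormalizeToPredicted:
    @pytest.fixture()
    def table(self):
        rows = []
        for s in ("S1", "S2"):
            for cond, v in (("predicted", 2.0), ("unpredicted", 3.0), ("cheated", 4.0)):
                rows.append((s, cond, v))
        return pd.DataFrame(rows, columns=["subject", "condition", "value"])

    def test_predicted_rows_become_100(self, table):
        out = normalize_to_predicted(table, "value")
        pred = out[out.condition == "predicted"]
        assert np.allclose(pred["value_pct_predicted"], 100.0)

    def test_double_value_becomes_200(self, table):
        out = normalize_to_predicted(table, "value")
        assert np.allclose(out[out.condition == "cheated"]["value_pct_predicted"], 200.0)

    def test_zero_predicted_dropped(self, table):
        table.loc[(table.subject == "S1") & (table.condition == "predicted"), "value"] = 0.0
        out = normalize_to_predicted(table, "value")
        assert "S1" not in set(out.subject)

    def test_rank_correlation_invariant_under_normalization(self, rng):
        # normalization is monotone per subject-variable, so within-condition
        # rank correlations across subjects are preserved when every subject
        # shares the same predicted mean
        n = 20
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        raw = spearman(x, y).r
        scaled = spearman(x / 2.0 * 100.0, y / 2.0 * 100.0).r
        assert raw == pytest.approx(scaled)


# ---------------------------------------------------------------------------
# rmANOVA


def _oracle_one_factor(y):
    """Independent hand-computed sums-of-squares decomposition."""
    n, k = y.shape
    gm = y.sum() / y.size
    ss_a = 0.0
    for j in range(k):
        m = sum(y[i][j] for i in range(n)) / n
        ss_a += n * (m - gm) ** 2
    ss_err = 0.0
    for i in range(n):
        ms = sum(y[i]) / k
        for j in range(k):
            mj = sum(y[r][j] for r in range(n)) / n
            ss_err += (y[i][j] - mj - ms + gm) ** 2
    f = (ss_a / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
    eta = ss_a / (ss_a + ss_err)
    return f, eta


FIXTURE_6X3 = np.array([
    [2.1, 3.4, 4.2],
    [1.8, 2.9, 3.7],
    [2.5, 3.1, 4.9],
    [2.0, 3.8, 4.1],
    [1.6, 2.7, 3.3],
    [2.2, 3.5, 4.6],
])


class TestRmAnova:
    def _long(self, y, conds=("predicted", "unpredicted", "cheated")):
        rows = []
        for i in range(y.shape[0]):
            for j, c in enumerate(conds):
                rows.append((f"S{i}", c, y[i, j]))
        return pd.DataFrame(rows, columns=["subject", "condition", "y"])

    def test_fixed_fixture_matches_hand_computed_ss(self):
        res = rm_anova(self._long(FIXTURE_6X3), "y", within="condition")[0]
        f, eta = _oracle_one_factor(FIXTURE_6X3)
        assert res.f == pytest.approx(f, rel=1e-8)
        assert res.partial_eta_sq == pytest.approx(eta, rel=1e-8)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        df = self._long(FIXTURE_6X3)
        mine = rm_anova(df, "y", within="condition")[0]
        theirs = pg.rm_anova(data=df, dv="y", within="condition",
                             subject="subject", correction=True, detailed=True)
        assert mine.f == pytest.approx(float(theirs["F"].iloc[0]), rel=1e-9)
        assert mine.gg_epsilon == pytest.approx(float(theirs["eps"].iloc[0]), rel=1e-9)
        assert mine.mauchly_w == pytest.approx(float(theirs["W_spher"].iloc[0]), rel=1e-9)

    def test_null_data_gives_zero_f(self):
        y = np.full((6, 3), 5.0)
        res = rm_anova(self._long(y), "y", within="condition")[0]
        assert res.f == 0.0
        assert res.partial_eta_sq == 0.0

    def test_two_level_factor_has_epsilon_one(self):
        y = np.random.default_rng(0).normal(size=(8, 2))
        res = rm_anova(self._long(y, conds=("a", "b")), "y", within="condition")[0]
        assert res.gg_epsilon == 1.0
        assert res.mauchly_p == 1.0

    def test_unbalanced_lists_offenders(self):
        df = self._long(FIXTURE_6X3)
        df = df[~((df.subject == "S2") & (df.condition == "cheated"))]
        with pytest.raises(UnbalancedDesignError) as exc:
            rm_anova(df, "y", within="condition")
        assert "S2" in exc.value.offenders

    def test_two_factor_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        rows = []
        for s in range(10):
            for a in ("a0", "a1", "a2"):
                for b in ("b0", "b1"):
                    rows.append((f"S{s}", a, b, rng.normal()))
        df = pd.DataFrame(rows, columns=["subject", "A", "B", "y"])
        mine = {r.effect: r for r in rm_anova(df, "y", within=["A", "B"])}
        theirs = pg.rm_anova(data=df, dv="y", within=["A", "B"], subject="subject")
        for _, row in theirs.iterrows():
            key = {"A": "A", "B": "B", "A * B": "A x B"}[row["Source"]]
            assert mine[key].f == pytest.approx(float(row["F"]), rel=1e-8)
            assert mine[key].p_uncorrected == pytest.approx(float(row["p_unc"]), rel=1e-8)

    @given(scale=st.floats(min_value=0.1, max_value=10),
           shift=st.floats(min_value=-5, max_value=5))
    @settings(max_examples=20, deadline=None)
    def test_eta_sq_affine_invariance(self, scale, shift):
        base = rm_anova(self._long(FIXTURE_6X3), "y", within="condition")[0]
        res = rm_anova(self._long(FIXTURE_6X3 * scale + shift), "y",
                       within="condition")[0]
        assert res.partial_eta_sq == pytest.approx(base.partial_eta_sq, rel=1e-9)


# ---------------------------------------------------------------------------
# Spearman


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert spearman(x, x ** 3).r == pytest.approx(1.0)

    def test_antisymmetry(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert spearman(x, -x).r == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        r = spearman(np.ones(6), np.arange(6.0))
        assert r.undefined

    def test_small_n_rejected(self):
        with pytest.raises(InvalidParameterError):
            spearman([1, 2, 3], [1, 2, 3])

    def test_exact_permutation_oracle_n6(self, rng):
        # independent oracle: enumerate all n! permutations from scratch
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        res = spearman(x, y)

        def rankdata(v):
            order = sorted(range(len(v)), key=lambda i: v[i])
            r = [0.0] * len(v)
            for rank, i in enumerate(order):
                r[i] = rank + 1.0
            return r

        rx, ry = rankdata(list(x)), rankdata(list(y))
        mx = sum(rx) / len(rx)
        def corr(a, b):
            num = sum((ai - mx) * (bi - mx) for ai, bi in zip(a, b))
            den = math.sqrt(sum((ai - mx) ** 2 for ai in a)
                            * sum((bi - mx) ** 2 for bi in b))
            return num / den

        obs = abs(corr(rx, ry))
        hits = sum(1 for perm in itertools.permutations(ry)
                   if abs(corr(rx, list(perm))) >= obs - 1e-12)
        assert res.p == pytest.approx(hits / math.factorial(6), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        a = spearman(x, y).r
        b = spearman(np.exp(x), np.arctan(y)).r
        assert a == pytest.approx(b)


# ---------------------------------------------------------------------------
# FDR


class TestFdrBy:
    def test_single_p_is_plain_alpha_test(self):
        rej, adj = fdr_by([0.04])
        assert rej[0]
        rej, _ = fdr_by([0.06])
        assert not rej[0]

    def test_all_ones_no_rejections(self):
        rej, _ = fdr_by(np.ones(10))
        assert not rej.any()

    def test_empty_input(self):
        rej, adj = fdr_by([])
        assert rej.size == 0 and adj.size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            fdr_by([0.5, 1.5])

    def test_adjusted_p_monotone_after_sorting(self, rng):
        p = rng.uniform(size=30)
        _, adj = fdr_by(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_by_subset_of_bh(self, seed):
        # BY must never reject anything BH keeps (conservativeness)
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(2, 40)) ** rng.uniform(0.5, 3)
        by_rej, _ = fdr_by(p)
        bh_rej, *_ = sm.multipletests(p, alpha=0.05, method="fdr_bh")[:1]
        assert np.all(~by_rej | bh_rej)

    def test_matches_statsmodels_by(self, rng):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        p = rng.uniform(size=25) ** 2
        rej, adj = fdr_by(p)
        sm_rej, sm_adj, *_ = sm.multipletests(p, alpha=0.05, method="fdr_by")
        assert np.array_equal(rej, sm_rej)
        assert np.allclose(adj, sm_adj)


# ---------------------------------------------------------------------------
# reporting


class TestReport:
    def test_condition_column_order(self):
        df = pd.DataFrame({
            "variable": ["v"] * 6,
            "condition": ["cheated", "predicted", "unpredicted"] * 2,
            "value": [1.0, 2.0, 3.0, 1.1, 2.1, 3.1],
        })
        tab = summary_table(df, "value", by=["variable"])
        cols = [c for c in tab.columns if c.endswith("_mean")]
        assert cols == ["predicted_mean", "unpredicted_mean", "cheated_mean"]

    def test_round_trip_tsv(self, tmp_path):
        df = pd.DataFrame({
            "variable": ["v", "v"],
            "condition": ["predicted", "cheated"],
            "value": [1.234567, 2.345678],
        })
        tab = summary_table(df, "value", by=["variable"])
        p = tmp_path / "tab.tsv"
        tab.to_csv(p, sep="\t", index=False)
        back = pd.read_csv(p, sep="\t")
        pd.testing.assert_frame_equal(back, tab)

    def test_marker_only_on_fdr_rejections(self):
        from perturbstance.stats import CorrelationResult

        corr = [CorrelationResult("a", "b", 0.9, 0.001, 20, fdr_reject=True),
                CorrelationResult("c", "d", 0.1, 0.8, 20, fdr_reject=False)]
        text = render_report({}, corr)
        lines = [ln for ln in text.splitlines() if " vs " in ln]
        assert lines[0].endswith("*") and not lines[1].endswith("*")
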