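import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from proteffect import (
    AnalysisConfig,
    ModeratedTTest,
    bh_adjust,
    student_ttest,
)

from conftest import make_matrix


def _pooled_t(x, y):
    """Independent textbook pooled two-sample t (the brute-force oracle)."""
    nx, ny = len(x), len(y)
    sp2 = (
        ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
    ) / (nx + ny - 2)
    return (y.mean() - x.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))


@pytest.fixture(scope="module")
def sim_fit():
    rng = np.random.default_rng(12)
    n = 500
    sd = np.sqrt(1.0 / rng.gamma(3.0, 1.0 / 0.08, size=n))
    X = 20.0 + rng.normal(size=(n, 8)) * sd[:, None]
    X[: n // 10, 4:] += 1.0
    m = make_matrix(X, scale="log2")
    cols = m.sample_ids
    return m, (cols[:4], cols[4:]), X


class TestModeratedFit:
    def test_zero_prior_df_equals_ordinary_t(self, sim_fit):
        m, groups, X = sim_fit
        res = ModeratedTTest(m, group_samples=groups).fit(df_prior=0)
        oracle = np.array([_pooled_t(X[i, :4], X[i, 4:]) for i in range(len(X))])
        assert np.abs(res.frame["t_mod"].to_numpy() - oracle).max() < 1e-10

    def test_identical_groups_give_null_result(self):
        X = np.tile([[1.0, 2.0, 3.0, 4.0]], (3, 2)).reshape(3, 8)
        m = make_matrix(np.column_stack([X[:, :4], X[:, :4]]), scale="log2")
        cols = m.sample_ids
        res = ModeratedTTest(m, group_samples=(cols[:4], cols[4:])).fit()
        row = res.frame.iloc[0]
        assert row["log2fc"] == 0 and row["t_mod"] == 0 and row["p"] == 1.0

    def test_infinite_prior_df_closed_form(self, sim_fit):
        m, groups, X = sim_fit
        s20 = 0.05
        res = ModeratedTTest(m, group_samples=groups).fit(
            df_prior=np.inf, s2_prior=s20
        )
        expected = res.frame["log2fc"] / np.sqrt(s20 * 0.5)
        np.testing.assert_allclose(res.frame["t_mod"], expected, rtol=1e-12)
        np.testing.assert_allclose(
            res.frame["p"], 2 * stats.norm.sf(np.abs(expected)), rtol=1e-12
        )

    def test_posterior_variance_identity(self, sim_fit):
        m, groups, _ = sim_fit
        res = ModeratedTTest(m, group_samples=groups).fit()
        f = res.frame
        expected = (
            res.df_prior * res.s2_prior + f["df_resid"] * f["s2"]
        ) / (res.df_prior + f["df_resid"])
        np.testing.assert_allclose(f["s2_post"], expected, rtol=1e-12)
        assert res.df_prior >= 0
        assert (f["p_adj"] >= f["p"] - 1e-15).all()

    def test_matches_limma_ebayes(self, sim_fit, tmp_path):
        """Independent oracle: bioconductor-limma's eBayes on the same data."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        m, groups, _ = sim_fit
        fixture = tmp_path / "x.tsv"
        m.values.to_csv(fixture, sep="\t")
        script = tmp_path / "fit.R"
        script.write_text(
            """
            suppressMessages(library(limma))
            args <- commandArgs(trailingOnly=TRUE)
            x <- as.matrix(read.delim(args[1], row.names=1))
            design <- cbind(Intercept=1, group=c(0,0,0,0,1,1,1,1))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(t=fit$t[,2], p=fit$p.value[,2],
                              d0=fit$df.prior, s20=fit$s2.prior)
            write.table(out, args[2], sep="\t", quote=FALSE)
            """
        )
        out = tmp_path / "r.tsv"
        subprocess.run(
            ["Rscript", str(script), str(fixture), str(out)],
            check=True, capture_output=True,
        )
        r = pd.read_csv(out, sep="\t", index_col=0)
        res = ModeratedTTest(m, group_samples=groups).fit()
        assert np.isclose(res.df_prior, r["d0"].iloc[0], rtol=1e-6)
        assert np.isclose(res.s2_prior, r["s20"].iloc[0], rtol=1e-6)
        assert np.abs(res.frame["t_mod"].to_numpy() - r["t"].to_numpy()).max() < 1e-8
        assert np.abs(res.frame["p"].to_numpy() - r["p"].to_numpy()).max() < 1e-8

    def test_null_pvalues_calibrated(self):
        rng = np.random.default_rng(99)
        n = 2000
        sd = np.sqrt(1.0 / rng.gamma(3.0, 1.0 / 0.08, size=n))
        X = 20.0 + rng.normal(size=(n, 8)) * sd[:, None]
        m = make_matrix(X, scale="log2")
        cols = m.sample_ids
        res = ModeratedTTest(m, group_samples=(cols[:4], cols[4:])).fit()
        frac = (res.pvalues < 0.05).mean()
        bound = 3 * np.sqrt(0.05 * 0.95 / n)
        assert abs(frac - 0.05) < bound


class TestCallDaps:
    def _calls(self, log2fc, p, cfg):
        res = type("R", (), {})()
        frame = pd.DataFrame(
            {
                "protein_id": [f"P{i}" for i in range(len(log2fc))],
                "log2fc": log2fc,
                "p": p,
                "p_adj": p,
            }
        ).set_index("protein_id", drop=False)
        from proteffect.diffabund import ModeratedTTestResults

        r = ModeratedTTestResults(
            model=None, frame=frame, s2_prior=0.1, df_prior=1.0,
            df_total=7.0, n1=4, n2=4,
        )
        return r.call_daps(cfg)["label"].tolist()

    @pytest.mark.parametrize(
        "fc_raw,p,expected",
        [
            (1.5, 0.01, "increased"),
            (1.29, 0.001, "unchanged"),
            (0.76, 0.049, "decreased"),  # boundary FC inclusive
            (1.3, 0.049, "increased"),  # boundary FC inclusive
            (1.5, 0.05, "unchanged"),  # boundary p exclusive
            (0.9, 0.001, "unchanged"),
        ],
    )
    def test_dual_threshold_rule(self, fc_raw, p, expected, default_cfg):
        got = self._calls([np.log2(fc_raw)], [p], default_cfg)
        assert got == [expected]

    def test_label_swap_symmetry_with_reciprocal_thresholds(self):
        cfg = AnalysisConfig(fc_up=1.3, fc_down=1 / 1.3)
        rng = np.random.default_rng(3)
        fc = rng.normal(0, 1, 200)
        p = rng.random(200)
        a = self._calls(fc, p, cfg)
        b = self._calls(-fc, p, cfg)
        swap = {"increased": "decreased", "decreased": "increased",
                "unchanged": "unchanged"}
        assert [swap[x] for x in a] == b


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_value_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_adjust([1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=1e-12, max_value=1.0, exclude_min=False),
            min_size=1, max_size=40,
        )
    )
    def test_never_decreases_and_sorted_monotone(self, ps):
        adj = bh_adjust(ps)
        assert (adj >= np.asarray(ps) - 1e-15).all()
        assert (adj <= 1.0 + 1e-15).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestStudentTTest:
    def test_identical_samples(self):
        t, p = student_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_hand_computed_example(self):
        t, p = student_ttest([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert t == pytest.approx(1.2247448, abs=1e-6)
        assert p == pytest.approx(0.2878641, abs=1e-4)
        # scipy as an independent check
        sp = stats.ttest_ind([2, 3, 4], [1, 2, 3], equal_var=True)
        assert t == pytest.approx(sp.statistic, abs=1e-12)
        assert p == pytest.approx(sp.pvalue, abs=1e-12)

    def test_swap_negates_t_keeps_p(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(0, 1, 5), rng.normal(0.5, 1, 6)
        t1, p1 = student_ttest(x, y)
        t2, p2 = student_ttest(y, x)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_zero_variance_contract(self):
        assert student_ttest([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)
        with pytest.raises(ValueError, match="zero pooled variance"):
            student_ttest([2.0, 2.0], [3.0, 3.0])
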