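import numpy as np
import pandas as pd
import pytest

from proteffect import (
    AnalysisConfig,
    ProteinMatrix,
    SimConfig,
    filter_by_detection,
    generate_design,
    generate_matrix,
    log2_transform,
    mle_impute,
    vsn_normalize,
)
from proteffect.io import ConfigError

from conftest import make_design, make_matrix


def _detection_matrix(det_a, det_b):
    """Row with det_a observed cells in A1..A4 and det_b in B1..B4."""
    row = [100.0 if i < det_a else np.nan for i in range(4)]
    row += [100.0 if i < det_b else np.nan for i in range(4)]
    cols = [f"A{i}" for i in range(1, 5)] + [f"B{i}" for i in range(1, 5)]
    m = make_matrix(np.array([row]), sample_ids=cols, scale="raw")
    d = make_design(cols, list("AAAABBBB"))
    return m, d


class TestDetectionFilter:
    @pytest.mark.parametrize(
        "det_a,det_b,scope,kept",
        [
            (3, 0, "any_group", True),
            (3, 0, "all_groups", False),
            (2, 2, "any_group", False),
            (2, 2, "all_groups", False),
            (4, 3, "all_groups", True),
        ],
    )
    def test_detection_rule(self, det_a, det_b, scope, kept):
        m, d = _detection_matrix(det_a, det_b)
        cfg = AnalysisConfig(detection_scope=scope)
        out = filter_by_detection(m, d, cfg, ("A", "B"))
        assert out.n_proteins == (1 if kept else 0)

    def test_group_smaller_than_min_detect_rejected(self):
        m, d = _detection_matrix(4, 4)
        cfg = AnalysisConfig()
        with pytest.raises(ConfigError, match="min_detect"):
            filter_by_detection(
                m, d, cfg, group_samples=(["A1", "A2"], d.samples(diet="B"))
            )


class TestLog2:
    def test_known_values_and_missing_preserved(self):
        m = make_matrix([[8.0, 1.0, np.nan]], scale="raw")
        out = log2_transform(m)
        np.testing.assert_array_equal(
            out.values.to_numpy(), [[3.0, 0.0, np.nan]]
        )
        assert out.scale == "log2"

    def test_requires_raw_scale(self):
        m = make_matrix([[1.0, 2.0]], scale="log2")
        with pytest.raises(ValueError, match="raw"):
            log2_transform(m)


class TestVsn:
    def test_doubled_sample_calibrated_to_reference(self):
        rng = np.random.default_rng(0)
        base = np.power(2.0, rng.normal(20, 2, size=400))
        m = make_matrix(np.column_stack([base, 2 * base]), scale="raw")
        norm, model = vsn_normalize(m)
        diff = norm.values["s2"] - norm.values["s1"]
        assert abs(np.median(diff)) < 1e-6
        assert norm.scale == "normalized"
        assert (model.scales > 0).all()

    def test_identical_samples_give_zero_differences(self):
        rng = np.random.default_rng(1)
        base = np.power(2.0, rng.normal(18, 1.5, size=100))
        m = make_matrix(np.column_stack([base] * 4), scale="raw")
        norm, _ = vsn_normalize(m)
        v = norm.values.to_numpy()
        assert np.abs(v - v[:, [0]]).max() < 1e-9

    def test_monotone_within_sample(self):
        rng = np.random.default_rng(2)
        X = np.power(2.0, rng.normal(20, 2, size=(200, 3)))
        X[:, 1] *= 3.0
        norm, _ = vsn_normalize(make_matrix(X, scale="raw"))
        for s in range(3):
            order = np.argsort(X[:, s])
            transformed = norm.values.to_numpy()[order, s]
            assert (np.diff(transformed) > 0).all()

    def test_recovers_planted_log2fc_under_4x_scale_factors(self):
        """Group-mean differences after normalization match planted effects
        to ±0.05 despite per-sample scale factors spanning 4×.  The planted
        fraction stays inside the trim budget: least-trimmed-squares can
        only reject outlying (differential) rows up to its trim fraction."""
        rng = np.random.default_rng(4)
        n = 500
        baseline = rng.normal(20, 2, size=n)
        effect = np.where(rng.random(n) < 0.08,
                          rng.choice([-1.0, 1.0], size=n), 0.0)
        shifts = np.array([-1.0, -0.4, 0.2, 1.0, 0.9, -0.8, 0.3, -0.2])
        group = np.repeat([0.0, 1.0], 4)
        latent = (
            baseline[:, None]
            + np.outer(effect, group)
            + shifts[None, :]
            + rng.normal(0, 0.01, size=(n, 8))
        )
        m = make_matrix(np.power(2.0, latent), scale="raw")
        norm, _ = vsn_normalize(m)
        v = norm.values.to_numpy()
        est = v[:, 4:].mean(axis=1) - v[:, :4].mean(axis=1)
        assert np.abs(est - effect).max() < 0.05

    def test_too_few_shared_values_error(self):
        X = np.full((4, 2), np.nan)
        X[:, 0] = [10.0, 20.0, 30.0, 40.0]
        X[0, 1] = 15.0
        with pytest.raises(ValueError, match="fewer than 3"):
            vsn_normalize(make_matrix(X, scale="raw"))


class TestMleImpute:
    def test_complete_matrix_unchanged(self):
        rng = np.random.default_rng(4)
        X = rng.normal(20, 1, size=(50, 4))
        m = make_matrix(X, scale="log2")
        out, model = mle_impute(m)
        np.testing.assert_array_equal(out.values.to_numpy(), X)
        np.testing.assert_allclose(model.mean, X.mean(axis=0))

    def test_perfectly_correlated_conditional_mean(self):
        """One missing cell in a sample2 = sample1 + 1 matrix is imputed at
        the closed-form conditional mean, observed + 1."""
        X = np.array(
            [[1.0, 2.0], [2.0, 3.0], [3.0, 4.0], [4.0, 5.0], [10.0, np.nan]]
        )
        out, model = mle_impute(make_matrix(X, scale="log2"))
        assert abs(out.values.iloc[4, 1] - 11.0) < 1e-8
        assert model.converged

    def test_observed_cells_never_altered(self):
        rng = np.random.default_rng(5)
        X = rng.normal(20, 1, size=(100, 6))
        mask = rng.random(X.shape) < 0.15
        mask[mask.all(axis=1)] = False
        Xm = np.where(mask, np.nan, X)
        m = make_matrix(Xm, scale="log2")
        out, _ = mle_impute(m)
        obs = ~mask
        np.testing.assert_array_equal(
            out.values.to_numpy()[obs], X[obs]
        )
        assert np.isfinite(out.values.to_numpy()).all()

    def test_all_missing_rows_dropped_and_counted(self):
        X = np.array([[1.0, 2.0], [np.nan, np.nan], [3.0, 4.0]])
        out, model = mle_impute(make_matrix(X, scale="log2"))
        assert out.n_proteins == 2
        assert model.n_dropped_rows == 1

    def test_loglik_trace_nondecreasing(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, size=(200, 5))
        X[rng.random(X.shape) < 0.2] = np.nan
        X = X[np.isfinite(X).any(axis=1)]
        _, model = mle_impute(make_matrix(X, scale="log2"))
        ll = np.array(model.loglik_trace)
        assert (np.diff(ll) > -1e-6 * np.maximum(1.0, np.abs(ll[:-1]))).all()

    def test_raw_scale_rejected(self):
        m = make_matrix([[1.0, 2.0]], scale="raw")
        with pytest.raises(ValueError, match="raw"):
            mle_impute(m)


class TestPipelineOrder:
    def test_scale_tags_enforce_filter_normalize_impute(self):
        cfg = SimConfig(seed=9, n_proteins=300)
        matrix, _ = generate_matrix(cfg)
        design = generate_design(cfg)
        acfg = AnalysisConfig()
        filtered = filter_by_detection(matrix, design, acfg, ("A", "B"))
        assert filtered.scale == "raw"
        normalized, _ = vsn_normalize(filtered)
        assert normalized.scale == "normalized"
        # cannot normalize twice nor impute before normalizing/logging
        with pytest.raises(ValueError):
            vsn_normalize(normalized)
        imputed, _ = mle_impute(normalized)
        assert imputed.scale == "normalized"
        assert np.isfinite(imputed.values.to_numpy()).all()
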