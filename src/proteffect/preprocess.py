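"""Detection filtering, variance-stabilizing normalization and EM imputation.

The preprocessing chain for a two-group comparison is

    filter_by_detection → vsn_normalize → mle_impute

i.e. normalize first, impute after, so imputed values live on the stabilized
scale.  The scale tags on :class:`~proteffect.io.ProteinMatrix` enforce the
order.

Variance stabilization uses the generalized-log family: each sample ``s`` is
calibrated by an affine map and passed through arsinh,

    h_s(x) = arsinh(a_s · x + b_s) / ln 2,

so that at high intensity h_s behaves like log2(2·a_s·x) and between-sample
differences read as log2 ratios, while low intensities are compressed rather
than exploding.  The per-sample parameters are fitted by least trimmed
squares of the calibrated sample against the across-sample row-median
reference profile, alternating reference and fits.

Imputation fits a multivariate normal over the sample dimension by
expectation–maximization (proteins are observations, samples variables) and
replaces each missing cell by its conditional mean given the observed cells
of the same protein row.  This targets missingness of moderately low-abundant
proteins; it is deterministic and never alters observed cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .io import AnalysisConfig, ConfigError, ProteinMatrix, SampleDesign

__all__ = [
    "NormalizationModel",
    "ImputationModel",
    "filter_by_detection",
    "log2_transform",
    "vsn_normalize",
    "mle_impute",
]

_LN2 = np.log(2.0)


@dataclass
class NormalizationModel:
    """Fitted per-sample glog calibration parameters."""

    sample_ids: list[str]
    scales: np.ndarray  # a_s, > 0
    offsets: np.ndarray  # b_s
    trim: float
    n_passes: int

    def transform(self, x: np.ndarray, sample_index: int) -> np.ndarray:
        a = self.scales[sample_index]
        b = self.offsets[sample_index]
        return np.arcsinh(a * x + b) / _LN2


@dataclass
class ImputationModel:
    """Multivariate-normal EM state over the sample dimension."""

    sample_ids: list[str]
    mean: np.ndarray
    covariance: np.ndarray
    ridge: float
    converged: bool
    n_iterations: int
    loglik_trace: list[float] = field(default_factory=list)
    n_dropped_rows: int = 0


def filter_by_detection(
    matrix: ProteinMatrix,
    design: SampleDesign,
    cfg: AnalysisConfig,
    groups: tuple[str, str] | None = None,
    *,
    group_samples: tuple[list[str], list[str]] | None = None,
) -> ProteinMatrix:
    """Keep proteins detected in at least ``cfg.min_detect`` replicates.

    ``detection_scope`` decides whether the quota must be met in at least
    one group (``any_group``) or in every group (``all_groups``).  The
    returned matrix is restricted to the two groups' sample columns; its
    row count is the comparison's "total identified" denominator.
    """
    if group_samples is None:
        if groups is None:
            raise ConfigError("either groups or group_samples is required")
        g1 = design.samples(diet=groups[0])
        g2 = design.samples(diet=groups[1])
    else:
        g1, g2 = [list(g) for g in group_samples]
    for label, g in (("first", g1), ("second", g2)):
        if len(g) < cfg.min_detect:
            raise ConfigError(
                f"{label} group has {len(g)} samples < min_detect={cfg.min_detect}"
            )
    sub = matrix.subset_samples(g1 + g2)
    obs = sub.values.notna()
    det1 = obs[g1].sum(axis=1)
    det2 = obs[g2].sum(axis=1)
    if cfg.detection_scope == "all_groups":
        keep = (det1 >= cfg.min_detect) & (det2 >= cfg.min_detect)
    else:
        keep = (det1 >= cfg.min_detect) | (det2 >= cfg.min_detect)
    return sub.subset_proteins(keep.to_numpy())


def log2_transform(matrix: ProteinMatrix) -> ProteinMatrix:
    """Plain log2; missing cells stay missing."""
    if matrix.scale != "raw":
        raise ValueError(f"expected raw scale, got {matrix.scale}")
    vals = matrix.values.to_numpy(dtype=float)
    if np.any(vals[np.isfinite(vals)] <= 0):
        raise ValueError("log2 requires strictly positive intensities")
    out = pd.DataFrame(
        np.log2(vals), index=matrix.values.index, columns=matrix.values.columns
    )
    return matrix.with_values(out, "log2")


def _fit_sample_glog(
    x: np.ndarray, ref: np.ndarray, theta0: np.ndarray, trim: float
) -> np.ndarray:
    """Least-trimmed-squares fit of arsinh(a·x+b)/ln2 against ref.

    The offset b is only identified by the low-intensity tail, so an extra
    penalty residual charges for the log2 distortion the offset induces at
    the 5th-percentile intensity; without it b can drift to values that
    bend the transform around a handful of faint proteins.
    """
    x05 = np.quantile(x, 0.05)
    w_pen = np.sqrt(0.05 * x.size)

    def resid(theta, xx, rr):
        a = np.exp(theta[0])
        b = theta[1]
        data = np.arcsinh(a * xx + b) / _LN2 - rr
        pen = w_pen * (np.arcsinh(a * x05 + b) - np.arcsinh(a * x05)) / _LN2
        return np.append(data, pen)

    def data_resid(theta, xx, rr):
        return np.arcsinh(np.exp(theta[0]) * xx + theta[1]) / _LN2 - rr

    # median-match the scale first so the optimizer starts near calibration
    delta = -np.median(data_resid(theta0, x, ref))  # log2 units
    theta0 = np.array([theta0[0] + delta * _LN2, theta0[1]])
    sol = optimize.least_squares(
        resid, theta0, args=(x, ref), xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    r = np.abs(data_resid(sol.x, x, ref))
    n_keep = max(3, int(np.ceil((1.0 - trim) * x.size)))
    if n_keep < x.size:
        keep = np.argsort(r)[:n_keep]
        sol = optimize.least_squares(
            resid, sol.x, args=(x[keep], ref[keep]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    return sol.x


def vsn_normalize(
    matrix: ProteinMatrix, *, trim: float = 0.1, n_passes: int = 2
) -> tuple[ProteinMatrix, NormalizationModel]:
    """Variance-stabilizing normalization (per-sample affine + glog).

    Two alternating passes: (re)compute the row-median reference profile of
    calibrated values, then refit each sample's (scale, offset) by least
    trimmed squares (trim fraction of the largest residuals discarded)
    against it.  Output is on the ``normalized`` (log2-like) scale; within
    each sample the ranks of observed values are preserved because the
    transform is strictly increasing.
    """
    if matrix.scale != "raw":
        raise ValueError(f"vsn_normalize expects raw scale, got {matrix.scale}")
    X = matrix.values.to_numpy(dtype=float)
    n_prot, n_samp = X.shape
    if n_samp < 2:
        raise ValueError("need at least 2 samples")

    log_a = np.zeros(n_samp)
    b = np.zeros(n_samp)
    H = np.arcsinh(np.exp(log_a) * X + b) / _LN2
    for _ in range(n_passes):
        ref = np.nanmedian(H, axis=1)
        for s in range(n_samp):
            obs = np.isfinite(X[:, s]) & np.isfinite(ref)
            if obs.sum() < 3:
                raise ValueError(
                    f"sample {matrix.sample_ids[s]!r} shares fewer than 3 "
                    "observed values with the reference profile"
                )
            theta = _fit_sample_glog(
                X[obs, s], ref[obs], np.array([log_a[s], b[s]]), trim
            )
            log_a[s], b[s] = theta
            H[:, s] = np.arcsinh(np.exp(log_a[s]) * X[:, s] + b[s]) / _LN2

    out = pd.DataFrame(H, index=matrix.values.index, columns=matrix.values.columns)
    model = NormalizationModel(
        sample_ids=matrix.sample_ids,
        scales=np.exp(log_a),
        offsets=b,
        trim=trim,
        n_passes=n_passes,
    )
    return matrix.with_values(out, "normalized"), model


# ---------------------------------------------------------------------------
# EM imputation
# ---------------------------------------------------------------------------

def _mvn_em(
    X: np.ndarray, ridge_factor: float, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float], bool, int]:
    """EM for a multivariate normal with missing data; returns completed X.

    A minute ridge (``ridge_factor`` × mean diagonal) keeps the covariance
    positive definite when the data are (nearly) perfectly correlated; it is
    small enough not to bias the conditional means beyond ~1e-10.
    Convergence is declared on a relative log-likelihood change below
    ``tol`` or on parameter stagnation (the likelihood grows without bound
    as the covariance approaches singularity, so the parameter criterion
    matters for degenerate data).
    """
    n, p = X.shape
    miss = ~np.isfinite(X)
    mu = np.nanmean(X, axis=0)
    X0 = np.where(miss, mu, X)
    sigma = np.atleast_2d(np.cov(X0, rowvar=False, ddof=0))
    sigma += ridge_factor * np.trace(sigma) / p * np.eye(p)

    patterns, inverse = np.unique(miss, axis=0, return_inverse=True)
    loglik_trace: list[float] = []
    Xc = X0.copy()
    converged = False
    near_singular = False
    it = 0
    for it in range(1, max_iter + 1):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        loglik = 0.0
        for k, pat in enumerate(patterns):
            rows = np.where(inverse == k)[0]
            o = ~pat
            m = pat
            Xo = X[np.ix_(rows, o)]
            So = sigma[np.ix_(o, o)]
            # observed-data log-likelihood for this pattern
            L = np.linalg.cholesky(So)
            dev = Xo - mu[o]
            z = np.linalg.solve(L, dev.T)
            loglik += (
                -0.5 * np.sum(z**2)
                - rows.size * (np.sum(np.log(np.diag(L))) + 0.5 * o.sum() * np.log(2 * np.pi))
            )
            if m.any():
                Som = sigma[np.ix_(o, m)]
                B = np.linalg.solve(So, Som)  # (o × m) regression coefs
                cond_mean = mu[m] + dev @ B
                cond_cov = sigma[np.ix_(m, m)] - Som.T @ B
                Xc[np.ix_(rows, m)] = cond_mean
            else:
                cond_cov = None
            Xr = Xc[rows]
            sum_x += Xr.sum(axis=0)
            sum_xx += Xr.T @ Xr
            if cond_cov is not None:
                add = np.zeros((p, p))
                add[np.ix_(m, m)] = rows.size * cond_cov
                sum_xx += add
        loglik_trace.append(loglik)
        if len(loglik_trace) > 1:
            prev = loglik_trace[-2]
            # monotone by EM theory; the ridge perturbs it once the
            # covariance is near-singular, so only assert away from there
            if not near_singular and loglik < prev - 1e-6 * max(1.0, abs(prev)):
                raise RuntimeError(
                    f"EM log-likelihood decreased at iteration {it}: "
                    f"{prev} -> {loglik}"
                )
            if abs(loglik - prev) / max(1.0, abs(prev)) < tol:
                converged = True
                break
        mu_new = sum_x / n
        sigma_new = sum_xx / n - np.outer(mu_new, mu_new)
        sigma_new = (sigma_new + sigma_new.T) / 2
        ridge_eps = ridge_factor * np.trace(sigma_new) / p
        near_singular = bool(
            np.linalg.eigvalsh(sigma_new)[0] < 1e8 * ridge_eps
        )
        sigma_new += ridge_eps * np.eye(p)
        scale = max(1.0, np.trace(sigma_new) / p)
        dparam = max(
            np.abs(mu_new - mu).max(), np.abs(sigma_new - sigma).max()
        )
        mu, sigma = mu_new, sigma_new
        if dparam < 1e-13 * scale:
            converged = True
            break
    return Xc, mu, sigma, loglik_trace, converged, it


def mle_impute(
    matrix: ProteinMatrix,
    *,
    max_iter: int = 1000,
    tol: float = 1e-10,
    ridge_factor: float = 1e-12,
) -> tuple[ProteinMatrix, ImputationModel]:
    """Conditional-mean completion under an EM-fitted multivariate normal.

    Proteins are the observations and the comparison's samples the
    variables.  Rows that are entirely missing are dropped (they could not
    have passed the detection filter).  Observed cells are never altered.
    """
    if matrix.scale == "raw":
        raise ValueError("impute on log2/normalized scale, not raw")
    X = matrix.values.to_numpy(dtype=float)
    all_missing = ~np.isfinite(X).any(axis=1)
    n_dropped = int(all_missing.sum())
    if n_dropped:
        matrix = matrix.subset_proteins(~all_missing)
        X = matrix.values.to_numpy(dtype=float)

    Xc, mu, sigma, trace, converged, n_iter = _mvn_em(
        X, ridge_factor, max_iter, tol
    )
    if not converged and np.isfinite(X).all():
        converged = True  # complete data: single M-step is the MLE
    if not converged:
        raise RuntimeError(
            f"EM did not converge in {max_iter} iterations; "
            f"log-likelihood trace: {trace}"
        )
    out = pd.DataFrame(Xc, index=matrix.values.index, columns=matrix.values.columns)
    model = ImputationModel(
        sample_ids=matrix.sample_ids,
        mean=mu,
        covariance=sigma,
        ridge=ridge_factor,
        converged=converged,
        n_iterations=n_iter,
        loglik_trace=trace,
        n_dropped_rows=n_dropped,
    )
    return matrix.with_values(out, matrix.scale), model
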