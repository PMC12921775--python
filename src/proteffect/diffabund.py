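"""Empirical-Bayes moderated two-group testing and DAP calling.

The model is the standard proteomics/transcriptomics moderated t-test: each
protein g gets a pooled two-sample residual variance s²_g with d_g degrees of
freedom; the ensemble of variances is modelled as scaled-F around a prior
(s²₀, d₀) estimated by moment matching on log s² (trigamma inversion), and the
per-protein variance is shrunk to its posterior

    s²_post = (d₀·s²₀ + d_g·s²_g) / (d₀ + d_g).

The moderated statistic t = Δmean / sqrt(s²_post·(1/n₁+1/n₂)) is referred to
a Student t with d_g + d₀ degrees of freedom (a normal reference when d₀ is
infinite).

A protein is called differentially abundant when its unadjusted p-value is
below ``p_cut`` and its raw-scale fold change 2^Δ is ≥ ``fc_up`` (increased)
or ≤ ``fc_down`` (decreased); fold-change boundaries are inclusive, the
p boundary is not.  Benjamini–Hochberg adjusted p-values are reported
alongside but deliberately not used for calling: at group sizes of four, FDR
adjustment trades too much power for its type-I control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import AnalysisConfig, ProteinMatrix, SampleDesign

__all__ = [
    "ModeratedTTest",
    "ModeratedTTestResults",
    "bh_adjust",
    "student_ttest",
    "trigamma_inverse",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def student_ttest(x, y) -> tuple[float, float]:
    """Two-sided pooled-variance Student t-test.

    Sign convention: t > 0 when mean(y) > mean(x).  If the pooled variance
    is exactly zero the test degenerates: equal means give (0, 1); unequal
    means are an error (an infinite statistic carries no usable p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    nx, ny = x.size, y.size
    df = nx + ny - 2
    diff = y.mean() - x.mean()
    ss = ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
    s2 = ss / df
    if s2 == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t = diff / np.sqrt(s2 * (1.0 / nx + 1.0 / ny))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def trigamma_inverse(y: float, *, max_iter: int = 50, tol: float = 1e-8) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/trigamma)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < tol:
            break
    return float(x)


def _squeeze_variances(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (s2_prior, df_prior) on log s² (scaled-F model).

    Returns ``df_prior = inf`` when the observed spread of log variances is
    no larger than expected from chi-square sampling alone (all shrink to a
    common value).
    """
    x = np.maximum(np.asarray(s2, dtype=float), 0.0)
    m = np.median(x)
    if m == 0:
        raise ValueError(
            "cannot estimate prior variance: most residual variances are zero"
        )
    x = np.maximum(x, 1e-5 * m)  # offset exact zeros away from log(0)
    z = np.log(x)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = e.size
    if n < 2:
        return float(x[0]), 0.0
    evar = ((e - emean) ** 2).sum() / (n - 1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        return float(x.mean()), np.inf
    df_prior = 2.0 * trigamma_inverse(evar)
    s2_prior = np.exp(
        emean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0)
    )
    return float(s2_prior), float(df_prior)


class ModeratedTTest:
    """Two-group empirical-Bayes moderated t model on a complete matrix.

    Parameters
    ----------
    matrix : ProteinMatrix
        Complete (imputed) matrix on a log2-like scale.
    design : SampleDesign, optional
        Used with ``groups`` to resolve the two sample sets by diet label.
    groups : (str, str), optional
        Diet labels; the reported log2 fold change is group2 − group1.
    group_samples : (list, list), optional
        Explicit sample-id lists, bypassing the design lookup.
    """

    def __init__(
        self,
        matrix: ProteinMatrix,
        design: SampleDesign | None = None,
        groups: tuple[str, str] | None = None,
        *,
        group_samples: tuple[list[str], list[str]] | None = None,
    ) -> None:
        if matrix.scale == "raw":
            raise ValueError("fit on log2/normalized scale, not raw")
        if group_samples is not None:
            g1, g2 = [list(g) for g in group_samples]
        else:
            if design is None or groups is None:
                raise ValueError("need design+groups or group_samples")
            g1 = design.samples(diet=groups[0])
            g2 = design.samples(diet=groups[1])
        if len(g1) < 2 or len(g2) < 2:
            raise ValueError("each group needs at least 2 samples")
        if not np.isfinite(matrix.values[g1 + g2].to_numpy()).all():
            raise ValueError("matrix has missing values; impute first")
        self.matrix = matrix
        self.group1_samples = g1
        self.group2_samples = g2

    def fit(
        self,
        *,
        df_prior: float | None = None,
        s2_prior: float | None = None,
    ) -> "ModeratedTTestResults":
        """Fit group means, pooled variances and the moderated statistics.

        ``df_prior``/``s2_prior`` override the empirical-Bayes estimates:
        ``df_prior=0`` reproduces the ordinary pooled two-sample t-test;
        ``df_prior=inf`` with a fixed ``s2_prior`` gives the known-variance
        z-limit.
        """
        X1 = self.matrix.values[self.group1_samples].to_numpy(dtype=float)
        X2 = self.matrix.values[self.group2_samples].to_numpy(dtype=float)
        n1, n2 = X1.shape[1], X2.shape[1]
        m1 = X1.mean(axis=1)
        m2 = X2.mean(axis=1)
        log2fc = m2 - m1
        df_resid = float(n1 + n2 - 2)
        ss = ((X1 - m1[:, None]) ** 2).sum(axis=1) + (
            (X2 - m2[:, None]) ** 2
        ).sum(axis=1)
        s2 = ss / df_resid

        if df_prior is None:
            est_s2p, est_dfp = _squeeze_variances(s2, df_resid)
            d0 = est_dfp
            s20 = est_s2p if s2_prior is None else float(s2_prior)
        else:
            d0 = float(df_prior)
            if d0 > 0 and s2_prior is None:
                s20, _ = _squeeze_variances(s2, df_resid)
            else:
                s20 = float(s2_prior) if s2_prior is not None else 0.0

        if np.isinf(d0):
            s2_post = np.full_like(s2, s20)
            df_total = np.inf
        elif d0 == 0:
            s2_post = s2
            df_total = df_resid
        else:
            s2_post = (d0 * s20 + df_resid * s2) / (d0 + df_resid)
            df_total = df_resid + d0

        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_mod = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
            t_mod = np.where((se == 0) & (log2fc == 0), 0.0, t_mod)
        if np.any((se == 0) & (log2fc != 0)):
            raise ValueError("zero posterior variance with nonzero fold change")
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t_mod))
        else:
            p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
        p = np.clip(p, np.nextafter(0, 1), 1.0)

        frame = pd.DataFrame(
            {
                "protein_id": self.matrix.protein_ids,
                "mean_g1": m1,
                "mean_g2": m2,
                "log2fc": log2fc,
                "s2": s2,
                "df_resid": df_resid,
                "s2_post": s2_post,
                "t_mod": t_mod,
                "p": p,
                "p_adj": bh_adjust(p) if len(p) else np.array([]),
            }
        ).set_index("protein_id", drop=False)
        return ModeratedTTestResults(
            model=self,
            frame=frame,
            s2_prior=s20,
            df_prior=d0,
            df_total=df_total,
            n1=n1,
            n2=n2,
        )


@dataclass
class ModeratedTTestResults:
    """Per-protein estimates from :meth:`ModeratedTTest.fit`.

    ``frame`` holds protein_id, group means, log2fc, s2, df_resid, s2_post,
    t_mod, p and BH-adjusted p_adj (reported, not used for calling).
    """

    model: ModeratedTTest
    frame: pd.DataFrame
    s2_prior: float
    df_prior: float
    df_total: float
    n1: int
    n2: int

    @property
    def pvalues(self) -> np.ndarray:
        return self.frame["p"].to_numpy()

    @property
    def log2fc(self) -> np.ndarray:
        return self.frame["log2fc"].to_numpy()

    def call_daps(self, cfg: AnalysisConfig) -> pd.DataFrame:
        """Classify each protein as increased / decreased / unchanged.

        Fold-change thresholds are inclusive (≥ fc_up, ≤ fc_down); the
        p-value threshold is strict (< p_cut).  Adds raw-scale fold change
        and volcano-plot coordinates (log2fc, −log10 p).
        """
        f = self.frame
        fc_raw = np.power(2.0, f["log2fc"].to_numpy())
        sig = f["p"].to_numpy() < cfg.p_cut
        label = np.where(
            sig & (fc_raw >= cfg.fc_up),
            "increased",
            np.where(sig & (fc_raw <= cfg.fc_down), "decreased", "unchanged"),
        )
        return pd.DataFrame(
            {
                "protein_id": f["protein_id"],
                "label": label,
                "fc_raw": fc_raw,
                "log2fc": f["log2fc"],
                "neg_log10_p": -np.log10(f["p"].to_numpy()),
                "p": f["p"],
                "p_adj": f["p_adj"],
            },
            index=f.index,
        )

    def volcano(self) -> pd.DataFrame:
        """Volcano coordinates: x = log2fc, y = −log10 unadjusted p."""
        return pd.DataFrame(
            {
                "protein_id": self.frame["protein_id"],
                "log2fc": self.frame["log2fc"],
                "neg_log10_p": -np.log10(self.frame["p"].to_numpy()),
            },
            index=self.frame.index,
        )

    def plot_volcano(self, cfg: AnalysisConfig | None = None, ax=None):
        """Scatter the volcano coordinates (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        v = self.volcano()
        if cfg is not None:
            calls = self.call_daps(cfg)["label"]
            colors = calls.map(
                {"increased": "tab:red", "decreased": "tab:blue",
                 "unchanged": "0.7"}
            )
            ax.scatter(v["log2fc"], v["neg_log10_p"], s=8, c=colors)
            ax.axhline(-np.log10(cfg.p_cut), ls="--", lw=0.8, c="0.4")
            for fc in (cfg.fc_up, cfg.fc_down):
                ax.axvline(np.log2(fc), ls="--", lw=0.8, c="0.4")
        else:
            ax.scatter(v["log2fc"], v["neg_log10_p"], s=8, c="0.5")
        ax.set_xlabel("log2 fold change")
        ax.set_ylabel("-log10 p")
        return ax

    def summary(self, cfg: AnalysisConfig | None = None) -> str:
        """Plain-text summary of the fit and (optionally) DAP counts."""
        lines = [
            "Moderated two-group t-test",
            "=" * 40,
            f"proteins:            {len(self.frame)}",
            f"group sizes:         {self.n1} vs {self.n2}",
            f"residual df:         {self.frame['df_resid'].iloc[0] if len(self.frame) else 'n/a'}",
            f"prior df (d0):       {self.df_prior:.4g}",
            f"prior variance s2_0: {self.s2_prior:.6g}",
        ]
        if cfg is not None and len(self.frame):
            calls = self.call_daps(cfg)["label"]
            up = int((calls == "increased").sum())
            down = int((calls == "decreased").sum())
            lines += [
                f"increased:           {up}",
                f"decreased:           {down}",
                f"unchanged:           {len(calls) - up - down}",
            ]
        return "\n".join(lines)
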