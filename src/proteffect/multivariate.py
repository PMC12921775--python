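"""PLS-DA via NIPALS, with score-plot confidence ellipses.

Two-class partial least squares discriminant analysis is PLS1 regression of
a ±1 class indicator on the (auto)scaled protein matrix.  NIPALS extracts
components one at a time: weight w ∝ X'y, scores t = Xw, loading
p = X't/(t't); X and y are deflated by the extracted component before the
next one.  Scores of different components are exactly orthogonal.  Per
component the explained fraction of X variance is ‖t p'‖² / ‖X‖² — for PLS
(unlike PCA) these need not be non-increasing.

The 95% confidence ellipse for one class's 2-D scores comes from the class
mean and covariance scaled by the chi-square(2 df) quantile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ProteinMatrix, SampleDesign

__all__ = ["PLSDA", "PLSDAResults", "ConfidenceEllipse", "confidence_ellipse"]


class PLSDA:
    """Two-class PLS-DA model on a complete, imputed protein matrix.

    Parameters
    ----------
    matrix : ProteinMatrix
        Complete matrix on a log2-like scale (samples = columns).
    design : SampleDesign
        Supplies the class (diet) of each matrix sample.
    n_components : int
    scaling : {"autoscale", "mean_center"}
        Autoscale (default) mean-centers and scales each protein to unit
        variance before fitting, matching the convention of the usual
        metabolomics tools; proteins with zero variance are dropped.
    """

    def __init__(
        self,
        matrix: ProteinMatrix,
        design: SampleDesign,
        n_components: int = 2,
        scaling: str = "autoscale",
    ) -> None:
        if scaling not in ("autoscale", "mean_center"):
            raise ValueError("scaling must be autoscale or mean_center")
        design.validate_against(matrix)
        classes = (
            design.table.set_index("sample_id")
            .loc[matrix.sample_ids, "diet"]
            .to_numpy()
        )
        uniq = np.unique(classes)
        if uniq.size != 2:
            raise ValueError(f"need exactly 2 classes, found {list(uniq)}")
        n_samples = matrix.n_samples
        if not 1 <= n_components <= min(n_samples - 1, matrix.n_proteins):
            raise ValueError(
                f"n_components must lie in [1, {min(n_samples - 1, matrix.n_proteins)}]"
            )
        X = matrix.values.to_numpy(dtype=float).T  # samples × proteins
        if not np.isfinite(X).all():
            raise ValueError("matrix has missing values; impute first")
        self.matrix = matrix
        self.classes = classes
        self.class_labels = list(uniq)
        self.y = np.where(classes == uniq[1], 1.0, -1.0)
        self.n_components = n_components
        self.scaling = scaling
        self._X = X

    def fit(self) -> "PLSDAResults":
        X = self._X.copy()
        center = X.mean(axis=0)
        X -= center
        if self.scaling == "autoscale":
            sd = X.std(axis=0, ddof=1)
            keep = sd > 0
            X = X[:, keep] / sd[keep]
            kept_proteins = self.matrix.protein_ids[keep]
        else:
            kept_proteins = self.matrix.protein_ids
        y = self.y - self.y.mean()
        total_ss = float((X**2).sum())
        n, p = X.shape

        scores = np.empty((n, self.n_components))
        weights = np.empty((p, self.n_components))
        loadings = np.empty((p, self.n_components))
        xvar = np.empty(self.n_components)
        for a in range(self.n_components):
            w = X.T @ y
            nw = np.linalg.norm(w)
            if nw < 1e-12 * max(1.0, np.abs(X).max() * np.abs(y).max() * np.sqrt(p)) or nw == 0:
                raise ValueError(
                    f"degenerate component {a + 1}: X carries no covariance "
                    "with the class labels"
                )
            w /= nw
            # sign convention: largest-magnitude weight element positive
            j = int(np.argmax(np.abs(w)))
            if w[j] < 0:
                w = -w
            t = X @ w
            tt = float(t @ t)
            if tt == 0:
                raise ValueError(f"degenerate component {a + 1}: zero scores")
            pvec = X.T @ t / tt
            q = float(y @ t) / tt
            X = X - np.outer(t, pvec)
            y = y - q * t
            scores[:, a] = t
            weights[:, a] = w
            loadings[:, a] = pvec
            xvar[a] = tt * float(pvec @ pvec) / total_ss
        return PLSDAResults(
            model=self,
            scores=pd.DataFrame(
                scores,
                index=pd.Index(self.matrix.sample_ids, name="sample_id"),
                columns=[f"comp{a + 1}" for a in range(self.n_components)],
            ),
            weights=pd.DataFrame(
                weights,
                index=kept_proteins,
                columns=[f"comp{a + 1}" for a in range(self.n_components)],
            ),
            loadings=pd.DataFrame(
                loadings,
                index=kept_proteins,
                columns=[f"comp{a + 1}" for a in range(self.n_components)],
            ),
            x_variance_explained=xvar,
            classes=pd.Series(self.classes, index=self.matrix.sample_ids),
        )


@dataclass
class PLSDAResults:
    model: PLSDA
    scores: pd.DataFrame
    weights: pd.DataFrame
    loadings: pd.DataFrame
    x_variance_explained: np.ndarray
    classes: pd.Series

    def class_ellipses(self, level: float = 0.95) -> dict:
        """95% (by default) confidence ellipse per class on comp1/comp2."""
        if self.scores.shape[1] < 2:
            raise ValueError("need at least 2 components for ellipses")
        out = {}
        pts = self.scores.iloc[:, :2].to_numpy()
        for label in self.model.class_labels:
            out[label] = confidence_ellipse(
                pts[self.classes.to_numpy() == label], level
            )
        return out

    def plot_scores(self, level: float = 0.95, ax=None):
        """Score plot with per-class confidence ellipses (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pts = self.scores.iloc[:, :2]
        for label, color in zip(self.model.class_labels, ("tab:blue", "tab:orange")):
            mask = self.classes.to_numpy() == label
            ax.scatter(pts.iloc[mask, 0], pts.iloc[mask, 1], label=str(label), c=color)
            ell = confidence_ellipse(pts.to_numpy()[mask], level)
            theta = np.linspace(0, 2 * np.pi, 200)
            circle = np.column_stack(
                [ell.semi_axes[0] * np.cos(theta), ell.semi_axes[1] * np.sin(theta)]
            )
            rot = np.array(
                [
                    [np.cos(ell.angle), -np.sin(ell.angle)],
                    [np.sin(ell.angle), np.cos(ell.angle)],
                ]
            )
            path = circle @ rot.T + ell.center
            ax.plot(path[:, 0], path[:, 1], c=color, lw=1)
        ax.set_xlabel(
            f"Component 1 ({100 * self.x_variance_explained[0]:.1f}% X var)"
        )
        ax.set_ylabel(
            f"Component 2 ({100 * self.x_variance_explained[1]:.1f}% X var)"
        )
        ax.legend()
        return ax

    def summary(self) -> str:
        lines = ["PLS-DA (NIPALS)", "=" * 40]
        lines.append(f"classes: {self.model.class_labels}")
        lines.append(f"samples: {len(self.scores)}")
        for a, v in enumerate(self.x_variance_explained):
            lines.append(f"component {a + 1}: {100 * v:.1f}% of X variance")
        return "\n".join(lines)


@dataclass
class ConfidenceEllipse:
    """Ellipse (center, semi-axes, rotation angle in radians)."""

    center: np.ndarray
    semi_axes: np.ndarray  # major, minor
    angle: float
    level: float


def confidence_ellipse(points: np.ndarray, level: float = 0.95) -> ConfidenceEllipse:
    """Gaussian confidence ellipse of 2-D points.

    Semi-axes are sqrt(eigenvalue × χ²(level, 2 df)) of the sample
    covariance; the angle orients the major axis.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be n × 2")
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 1e-12 * max(evals[1], 1.0):
        raise ValueError("singular covariance: points are (nearly) collinear")
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    q = stats.chi2.ppf(level, df=2)
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return ConfidenceEllipse(
        center=center,
        semi_axes=np.sqrt(evals * q),
        angle=angle,
        level=level,
    )
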