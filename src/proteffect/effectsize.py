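"""Within-group vs between-group DAP percentages as an empirical effect size.

With eight replicates per diet, each diet's replicates are split into two
halves of four.  Comparing half against half of the *same* diet (A vs A,
B vs B) runs the full differential-abundance pipeline on samples that differ
only by biological and technical variability — an empirical null.  Comparing
a half of one diet against a half of the other (A vs B) adds the induced
dietary signal.  Expressing DAP counts as a percentage of the proteins
surviving the detection filter *in that comparison* gives a comparable
effect-size scale; the gap between the between-diet and within-diet
percentages measures how much of the observed change the diet explains.

Each comparison reruns filter → normalize → impute → moderated fit → call on
its own eight columns, which is why the "total" denominator differs between
rows of a tissue's summary table: only the detection filter sees different
data, never the normalization or imputation of another comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np
import pandas as pd

from .diffabund import ModeratedTTest
from .io import AnalysisConfig, DesignError, ProteinMatrix, SampleDesign
from .preprocess import filter_by_detection, mle_impute, vsn_normalize

__all__ = [
    "ComparisonPlan",
    "ComparisonSummary",
    "EffectSizeReport",
    "build_plan",
    "assign_halves",
    "run_comparison",
    "summarize_effect_size",
    "EffectSizeStudy",
    "EffectSizeResults",
]


def _round2(x: float) -> float:
    """Round-half-even to 2 decimals (decimal arithmetic, not float repr)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), ROUND_HALF_EVEN))


@dataclass
class ComparisonPlan:
    """One two-group comparison: disjoint, equally sized sample lists."""

    label: str  # within_g1 | within_g2 | between
    left: list[str]
    right: list[str]
    description: str = ""

    def __post_init__(self) -> None:
        if set(self.left) & set(self.right):
            raise DesignError("left/right sample sets overlap")
        if len(self.left) != len(self.right):
            raise DesignError("left/right sample sets differ in size")


@dataclass
class ComparisonSummary:
    """DAP counts for one comparison; percentage of the filtered total."""

    label: str
    tissue: str
    total: int
    n_increased: int
    n_decreased: int
    n_changed: int = field(init=False)
    pct_changed: float = field(init=False)

    def __post_init__(self) -> None:
        self.n_changed = self.n_increased + self.n_decreased
        if self.n_changed > self.total:
            raise ValueError("changed count exceeds total")
        pct = 100.0 * self.n_changed / self.total if self.total else 0.0
        self.pct_changed = _round2(pct)


def assign_halves(
    design: SampleDesign, cfg: AnalysisConfig, *, mode: str = "by_replicate"
) -> SampleDesign:
    """Assign each diet's replicates to two equal halves within each tissue.

    ``by_replicate`` puts the lowest replicate numbers in half 1 (exactly
    reproducible without a seed); ``random`` shuffles with ``cfg.seed``.
    Pre-assigned halves are kept.
    """
    t = design.table.copy()
    rng = np.random.default_rng(cfg.seed)
    for (tissue, diet), sub in t.groupby(["tissue", "diet"]):
        if (sub["half"] != 0).all():
            continue
        idx = sub.sort_values("replicate").index.to_numpy()
        if len(idx) != 2 * cfg.group_size:
            raise DesignError(
                f"tissue {tissue!r} diet {diet!r} has {len(idx)} replicates; "
                f"need exactly {2 * cfg.group_size} to split into halves"
            )
        if mode == "random":
            idx = rng.permutation(idx)
        elif mode != "by_replicate":
            raise ValueError(f"unknown half-assignment mode {mode!r}")
        t.loc[idx[: cfg.group_size], "half"] = 1
        t.loc[idx[cfg.group_size:], "half"] = 2
    return SampleDesign(t)


def build_plan(
    design: SampleDesign,
    cfg: AnalysisConfig,
    *,
    tissue: str | None = None,
    mode: str = "by_replicate",
    between_all: bool = False,
) -> list[ComparisonPlan]:
    """The study's three comparisons for one tissue.

    within_g1: diet-1 half 1 vs half 2; within_g2: likewise for diet 2;
    between: diet-1 half 1 vs diet-2 half 1 (or all replicates of each diet
    when ``between_all``).
    """
    if tissue is not None:
        design = design.for_tissue(tissue)
    else:
        tissues = design.tissues
        if len(tissues) != 1:
            raise DesignError(f"specify tissue; design has {tissues}")
        tissue = tissues[0]
    diets = design.diets
    if len(diets) != 2:
        raise DesignError(f"need exactly 2 diets, found {diets}")
    counts = design.table.groupby("diet").size()
    if set(counts) != {2 * cfg.group_size}:
        raise DesignError(
            f"each diet needs exactly {2 * cfg.group_size} replicates, "
            f"found {counts.to_dict()}"
        )
    if (design.table["half"] == 0).any():
        design = assign_halves(design, cfg, mode=mode)
    d1, d2 = diets
    h = lambda diet, half: design.samples(diet=diet, half=half)
    plans = [
        ComparisonPlan(
            "within_g1", h(d1, 1), h(d1, 2), f"{d1} vs. {d1} ({tissue})"
        ),
        ComparisonPlan(
            "within_g2", h(d2, 1), h(d2, 2), f"{d2} vs. {d2} ({tissue})"
        ),
    ]
    if between_all:
        plans.append(
            ComparisonPlan(
                "between",
                design.samples(diet=d1),
                design.samples(diet=d2),
                f"{d1} vs. {d2} ({tissue})",
            )
        )
    else:
        plans.append(
            ComparisonPlan(
                "between", h(d1, 1), h(d2, 1), f"{d1} vs. {d2} ({tissue})"
            )
        )
    return plans


def run_comparison(
    matrix: ProteinMatrix,
    plan: ComparisonPlan,
    cfg: AnalysisConfig,
    *,
    tissue: str = "",
    return_details: bool = False,
):
    """Full pipeline on one comparison's columns; summarize the DAP counts."""
    filtered = filter_by_detection(
        matrix, None, cfg, group_samples=(plan.left, plan.right)
    )
    total = filtered.n_proteins
    normalized, norm_model = vsn_normalize(filtered)
    imputed, imp_model = mle_impute(normalized)
    fit = ModeratedTTest(
        imputed, group_samples=(plan.left, plan.right)
    ).fit()
    calls = fit.call_daps(cfg)
    labels = calls["label"]
    summary = ComparisonSummary(
        label=plan.label,
        tissue=tissue,
        total=total - imp_model.n_dropped_rows
        if imp_model.n_dropped_rows
        else total,
        n_increased=int((labels == "increased").sum()),
        n_decreased=int((labels == "decreased").sum()),
    )
    if return_details:
        return summary, {
            "filtered": filtered,
            "normalization": norm_model,
            "imputation": imp_model,
            "fit": fit,
            "calls": calls,
        }
    return summary


@dataclass
class EffectSizeReport:
    """Aggregated within- vs between-group DAP percentages."""

    summaries: list[ComparisonSummary]
    mean_within: float
    mean_between: float
    ratio: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "tissue": s.tissue,
                "comparison": s.label,
                "total": s.total,
                "increased": s.n_increased,
                "decreased": s.n_decreased,
                "total_changed": s.n_changed,
                "pct_changed": s.pct_changed,
            }
            for s in self.summaries
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "mean_within_pct": round(self.mean_within, 1),
            "mean_between_pct": round(self.mean_between, 1),
            "ratio": round(self.ratio, 2),
            "comparisons": self.to_frame().to_dict(orient="records"),
        }


def summarize_effect_size(summaries) -> EffectSizeReport:
    """Average within and between percentages over all tissues; take the ratio.

    Means are arithmetic over the comparisons actually run and are reported
    to one decimal; the ratio between-diet/within-diet is the headline
    effect-size multiplier.
    """
    summaries = list(summaries)
    within = [s.pct_changed for s in summaries if s.label.startswith("within")]
    between = [s.pct_changed for s in summaries if s.label == "between"]
    if not within or not between:
        raise ValueError("need at least one within and one between summary")
    mean_within = float(np.mean(within))
    mean_between = float(np.mean(between))
    if mean_within <= 0:
        raise ValueError("mean within-group percentage is zero; ratio undefined")
    return EffectSizeReport(
        summaries=summaries,
        mean_within=mean_within,
        mean_between=mean_between,
        ratio=mean_between / mean_within,
    )


class EffectSizeStudy:
    """Model object running the three comparisons for each tissue.

    Parameters
    ----------
    matrices : mapping tissue -> ProteinMatrix, or a single ProteinMatrix
    design : SampleDesign
    cfg : AnalysisConfig
    """

    def __init__(self, matrices, design: SampleDesign, cfg: AnalysisConfig,
                 *, half_mode: str = "by_replicate", between_all: bool = False):
        if isinstance(matrices, ProteinMatrix):
            tissues = design.tissues
            if len(tissues) != 1:
                raise DesignError(
                    "single matrix given but design spans several tissues"
                )
            matrices = {tissues[0]: matrices}
        self.matrices = dict(matrices)
        self.design = design
        self.cfg = cfg
        self.half_mode = half_mode
        self.between_all = between_all
        for tissue, m in self.matrices.items():
            design.for_tissue(tissue).validate_against(m)

    def fit(self) -> "EffectSizeResults":
        summaries = []
        plans = {}
        for tissue, matrix in self.matrices.items():
            tissue_plans = build_plan(
                self.design, self.cfg, tissue=tissue,
                mode=self.half_mode, between_all=self.between_all,
            )
            plans[tissue] = tissue_plans
            for plan in tissue_plans:
                summaries.append(
                    run_comparison(matrix, plan, self.cfg, tissue=tissue)
                )
        report = summarize_effect_size(summaries)
        return EffectSizeResults(model=self, report=report, plans=plans)


@dataclass
class EffectSizeResults:
    model: EffectSizeStudy
    report: EffectSizeReport
    plans: dict

    def summary(self) -> str:
        frame = self.report.to_frame()
        lines = ["Within- vs between-group effect size", "=" * 48]
        lines.append(frame.to_string(index=False))
        lines += [
            "-" * 48,
            f"mean within-group DAP percentage:  {self.report.mean_within:.1f}%",
            f"mean between-group DAP percentage: {self.report.mean_between:.1f}%",
            f"between/within ratio:              {self.report.ratio:.2f}",
        ]
        return "\n".join(lines)
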