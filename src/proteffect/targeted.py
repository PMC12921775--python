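"""PRM (parallel reaction monitoring) quantification and DIA concordance.

For each peptide and sample, the areas of all monitored fragment-ion
transitions are summed and log2-transformed; a protein's per-sample value is
the unweighted mean of its peptides' log2 sums.  Group differences are tested
with the pooled two-sample Student t-test, and each protein's direction of
change is checked against the discovery (DIA) call.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffabund import student_ttest
from .io import SampleDesign

__all__ = ["summarize_prm", "prm_compare", "concordance"]

TRANSITION_COLUMNS = ("protein_id", "peptide", "transition", "sample_id", "area")


def summarize_prm(transitions: pd.DataFrame) -> pd.DataFrame:
    """Sum transition areas per (peptide, sample) and log2-transform.

    Returns a peptide × sample matrix with a ``protein_id`` level on the
    index.  A zero total area means the peptide was not seen → missing.
    """
    t = transitions
    for col in TRANSITION_COLUMNS:
        if col not in t.columns:
            raise ValueError(f"transition table lacks column {col!r}")
    if (t["area"] < 0).any():
        raise ValueError("negative transition area")
    dup = t.duplicated(subset=["peptide", "transition", "sample_id"])
    if dup.any():
        raise ValueError("duplicate (peptide, transition, sample) rows")
    sums = (
        t.groupby(["protein_id", "peptide", "sample_id"])["area"]
        .sum()
        .unstack("sample_id")
    )
    with np.errstate(divide="ignore"):
        logm = np.log2(sums.where(sums > 0))
    return logm


def prm_compare(
    pepmatrix: pd.DataFrame,
    design: SampleDesign | None = None,
    groups: tuple[str, str] | None = None,
    *,
    group_samples: tuple[list[str], list[str]] | None = None,
) -> pd.DataFrame:
    """Protein-level two-group comparison of PRM log2 abundances.

    Protein value per sample = mean over its peptides' log2 transition sums;
    then a pooled Student t across groups.  ``direction`` is the sign of the
    group-2 minus group-1 difference.
    """
    if group_samples is not None:
        g1, g2 = [list(g) for g in group_samples]
    else:
        if design is None or groups is None:
            raise ValueError("need design+groups or group_samples")
        g1 = design.samples(diet=groups[0])
        g2 = design.samples(diet=groups[1])
    missing = [s for s in g1 + g2 if s not in pepmatrix.columns]
    if missing:
        raise ValueError(f"samples absent from peptide matrix: {missing}")

    protein_level = pepmatrix.groupby(level="protein_id").mean()
    if protein_level.empty:
        raise ValueError("no proteins in peptide matrix")
    rows = []
    for pid, vals in protein_level.iterrows():
        x = vals[g1].dropna().to_numpy()
        y = vals[g2].dropna().to_numpy()
        if x.size < 2 or y.size < 2:
            raise ValueError(f"protein {pid!r} has <2 observed values per group")
        log2fc = float(y.mean() - x.mean())
        t, p = student_ttest(x, y)
        rows.append(
            {
                "protein_id": pid,
                "log2fc": log2fc,
                "t": t,
                "p": p,
                "direction": int(np.sign(log2fc)),
            }
        )
    return pd.DataFrame(rows).set_index("protein_id", drop=False)


def concordance(dia_calls: pd.DataFrame, prm_results: pd.DataFrame):
    """Direction agreement between DIA fold changes and PRM fold changes.

    ``dia_calls`` needs ``protein_id`` and ``log2fc`` (a
    :meth:`ModeratedTTestResults.call_daps` frame works); ``prm_results``
    is the :func:`prm_compare` output.  Returns (per-protein table,
    fraction agreeing).
    """
    dia = dia_calls.set_index("protein_id") if "protein_id" in dia_calls.columns else dia_calls
    shared = dia.index.intersection(prm_results.index)
    if shared.empty:
        raise ValueError("no shared protein ids between DIA and PRM results")
    dia_dir = np.sign(dia.loc[shared, "log2fc"].to_numpy()).astype(int)
    prm_dir = prm_results.loc[shared, "direction"].to_numpy().astype(int)
    agree = dia_dir == prm_dir
    table = pd.DataFrame(
        {
            "protein_id": shared,
            "dia_direction": dia_dir,
            "prm_direction": prm_dir,
            "agree": agree,
        }
    ).set_index("protein_id", drop=False)
    return table, float(agree.mean())
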