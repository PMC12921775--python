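"""Containers and TSV I/O for protein-group matrices, study designs and results.

The quantification input is the protein-group matrix dialect written by DIA-NN
(``report.pg_matrix.tsv``): a tab-separated table whose leading columns are
annotations (``Protein.Group``, ``Protein.Ids``, ``Protein.Names``, ``Genes``,
optionally ``First.Protein.Description``) followed by one MaxLFQ intensity
column per sample.  Non-quantified cells appear as blanks or zeros; both are
treated as missing here, on the grounds that a zero is a non-detection rather
than a measurement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MatrixFormatError",
    "DesignError",
    "ConfigError",
    "ProteinMatrix",
    "SampleDesign",
    "AnalysisConfig",
    "read_pg_matrix",
    "write_matrix",
    "read_design",
    "write_results",
]

#: recognised DIA-NN annotation headers, in canonical order
ANNOTATION_COLUMNS = (
    "Protein.Group",
    "Protein.Ids",
    "Protein.Names",
    "Genes",
    "First.Protein.Description",
)

_SCALE_ORDER = {"raw": 0, "log2": 1, "normalized": 2}


class MatrixFormatError(ValueError):
    """Malformed protein-group matrix file."""


class DesignError(ValueError):
    """Invalid or inconsistent sample-design table."""


class ConfigError(ValueError):
    """Invalid analysis configuration."""


@dataclass
class ProteinMatrix:
    """A proteins × samples intensity table with explicit missingness.

    Parameters
    ----------
    values : pandas.DataFrame
        Float intensities, proteins on the index (protein-group accession),
        samples on the columns.  ``NaN`` encodes a missing (non-quantified)
        cell.
    annotations : pandas.DataFrame
        Free-text annotation columns aligned to ``values.index``.  May be
        empty.
    scale : {"raw", "log2", "normalized"}
        Current intensity scale.  Raw values must be strictly positive where
        observed; transformations may only move forward along
        raw → log2 → normalized.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame = None  # type: ignore[assignment]
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.annotations is None:
            self.annotations = pd.DataFrame(index=self.values.index)
        if self.scale not in _SCALE_ORDER:
            raise ValueError(f"unknown scale {self.scale!r}")
        cols = list(self.values.columns)
        if len(cols) != len(set(cols)):
            raise MatrixFormatError("duplicate sample column names")
        idx = self.values.index
        if idx.hasnans or (idx.astype(str) == "").any():
            raise MatrixFormatError("every row needs a non-empty protein id")
        vals = self.values.to_numpy(dtype=float)
        if self.scale == "raw" and np.any(vals[np.isfinite(vals)] <= 0):
            raise MatrixFormatError(
                "raw-scale intensities must be strictly positive or missing"
            )

    # -- basic introspection -------------------------------------------------
    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    # -- derivation ----------------------------------------------------------
    def subset_samples(self, sample_ids: Sequence[str]) -> "ProteinMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return replace(self, values=self.values.loc[:, list(sample_ids)].copy())

    def subset_proteins(self, keep) -> "ProteinMatrix":
        return replace(
            self,
            values=self.values.loc[keep].copy(),
            annotations=self.annotations.loc[keep].copy(),
        )

    def with_values(self, values: pd.DataFrame, scale: str) -> "ProteinMatrix":
        """Return a copy with new values on a (weakly) later scale."""
        if _SCALE_ORDER[scale] < _SCALE_ORDER[self.scale]:
            raise ValueError(
                f"scale may only advance raw→log2→normalized, "
                f"not {self.scale}→{scale}"
            )
        return replace(self, values=values, scale=scale)


@dataclass
class SampleDesign:
    """Maps sample columns to (tissue, diet, replicate, half).

    ``half`` records the within-diet split membership used by the
    within-diet null comparisons: 1 or 2, or 0 for unassigned.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "tissue", "diet", "replicate")

    def __post_init__(self) -> None:
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise DesignError(f"design table lacks column {col!r}")
        if "half" not in t.columns:
            t = t.assign(half=0)
        t = t.copy()
        t["replicate"] = t["replicate"].astype(int)
        t["half"] = t["half"].fillna(0).astype(int)
        if not t["half"].isin([0, 1, 2]).all():
            raise DesignError("half must be 0 (unassigned), 1 or 2")
        if t["sample_id"].duplicated().any():
            dups = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise DesignError(f"duplicated sample_id(s): {dups}")
        dup = t.duplicated(subset=["tissue", "diet", "replicate"])
        if dup.any():
            raise DesignError("duplicate (tissue, diet, replicate) entries")
        for tissue, sub in t.groupby("tissue"):
            counts = sub.groupby("diet").size()
            if counts.nunique() > 1:
                warnings.warn(
                    f"unequal replicate counts across diets in tissue "
                    f"{tissue!r}: {counts.to_dict()}",
                    stacklevel=2,
                )
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def diets(self) -> list[str]:
        return sorted(self.table["diet"].unique())

    @property
    def tissues(self) -> list[str]:
        return sorted(self.table["tissue"].unique())

    def samples(self, *, tissue=None, diet=None, half=None) -> list[str]:
        t = self.table
        if tissue is not None:
            t = t[t["tissue"] == tissue]
        if diet is not None:
            t = t[t["diet"] == diet]
        if half is not None:
            t = t[t["half"] == half]
        return t["sample_id"].tolist()

    def for_tissue(self, tissue: str) -> "SampleDesign":
        sub = self.table[self.table["tissue"] == tissue]
        if sub.empty:
            raise DesignError(f"no samples for tissue {tissue!r}")
        return SampleDesign(sub.reset_index(drop=True))

    def validate_against(self, matrix: ProteinMatrix) -> None:
        """Raise if any design sample is absent from the matrix."""
        missing = sorted(set(self.sample_ids) - set(matrix.sample_ids))
        if missing:
            raise DesignError(f"design samples absent from matrix: {missing}")


@dataclass
class AnalysisConfig:
    """Thresholds and sizes for the differential-abundance analysis.

    Defaults follow the study settings: a protein is differentially
    abundant when p < 0.05 (unadjusted) and its raw-scale fold change is
    ≥ 1.3 or ≤ 0.76, with detection required in at least 3 of the 4
    replicates per group.
    """

    p_cut: float = 0.05
    fc_up: float = 1.3
    fc_down: float = 0.76
    min_detect: int = 3
    group_size: int = 4
    detection_scope: str = "any_group"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_cut < 1:
            raise ConfigError("p_cut must lie in (0, 1)")
        if self.fc_up <= 1:
            raise ConfigError("fc_up must exceed 1")
        if not 0 < self.fc_down < 1:
            raise ConfigError("fc_down must lie in (0, 1)")
        if not 1 <= self.min_detect <= self.group_size:
            raise ConfigError("need 1 <= min_detect <= group_size")
        if self.detection_scope not in ("any_group", "all_groups"):
            raise ConfigError("detection_scope must be any_group or all_groups")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _mostly_non_numeric(values: Iterable[str]) -> bool:
    """True when more than half of the non-empty cells fail float parsing.

    A sample column with one corrupt cell stays a sample column (and gets a
    precise error later); a genuine free-text annotation column is nearly
    all non-numeric.
    """
    n_seen = n_bad = 0
    for v in values:
        if v is None or v == "":
            continue
        n_seen += 1
        try:
            float(v)
        except ValueError:
            n_bad += 1
    return n_seen > 0 and n_bad * 2 > n_seen


def read_pg_matrix(path) -> ProteinMatrix:
    """Read a DIA-NN ``report.pg_matrix`` style TSV into a raw-scale matrix.

    Blank cells and literal zeros become missing.  Annotation columns (1–5
    leading columns) are auto-detected from their headers and non-numeric
    content; the first is always the protein-group id.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
    if not header_line.strip():
        raise MatrixFormatError(f"{path}: missing header line")
    header = header_line.split("\t")
    if len(header) != len(set(header)):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise MatrixFormatError(f"{path}: duplicate column names {dups}")

    raw = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8"
    )
    n_anno = 1  # first column is always the protein id
    for j in range(1, min(5, len(header))):
        col = header[j]
        if col in ANNOTATION_COLUMNS or _mostly_non_numeric(raw.iloc[:, j]):
            n_anno = j + 1
        else:
            break
    sample_cols = header[n_anno:]
    if not sample_cols:
        raise MatrixFormatError(f"{path}: no sample intensity columns found")

    ids = raw.iloc[:, 0].astype(str)
    if (ids.str.strip() == "").any():
        row = int(np.where(ids.str.strip() == "")[0][0]) + 2
        raise MatrixFormatError(f"{path}: empty protein id at line {row}")

    values = pd.DataFrame(index=pd.Index(ids, name=header[0]))
    for col in sample_cols:
        cell = raw[col].str.strip()
        numeric = pd.to_numeric(cell.mask(cell == ""), errors="coerce")
        bad = numeric.isna() & (cell != "")
        if bad.any():
            row = int(np.where(bad)[0][0]) + 2
            raise MatrixFormatError(
                f"{path}: non-numeric intensity {cell[bad].iloc[0]!r} "
                f"in column {col!r}, line {row}"
            )
        numeric = numeric.mask(numeric == 0)  # zero = non-detection
        values[col] = numeric.to_numpy()

    annotations = raw.iloc[:, 1:n_anno].set_index(values.index)
    return ProteinMatrix(values=values, annotations=annotations, scale="raw")


def write_matrix(matrix: ProteinMatrix, path) -> None:
    """Write a matrix back to the pg_matrix TSV dialect (missing → blank)."""
    out = pd.concat([matrix.annotations, matrix.values], axis=1)
    out.index.name = matrix.values.index.name or "Protein.Group"
    out.to_csv(path, sep="\t", na_rep="", encoding="utf-8")


def read_design(path) -> SampleDesign:
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "diet": str})
    return SampleDesign(table)


def write_design(design: SampleDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False, encoding="utf-8")


def write_results(table, path) -> None:
    """Write result rows (DataFrame or dataclass records) as a stable TSV.

    Columns keep their given order; missing values serialize as empty
    strings; floats use full repr precision so a re-read reproduces them
    bit for bit.
    """
    if not isinstance(table, pd.DataFrame):
        from dataclasses import asdict, is_dataclass

        rows = [asdict(r) if is_dataclass(r) else dict(r) for r in table]
        table = pd.DataFrame(rows)
    table.to_csv(path, sep="\t", index=False, na_rep="", encoding="utf-8")
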