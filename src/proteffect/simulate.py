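"""Synthetic DIA-like data with known ground truth.

The generator emulates the structure of a two-diet feeding-trial proteome:
per-protein log2 baselines drawn from a broad normal, per-protein residual
variances from an inverse-gamma (so the variance ensemble looks like the
scaled-F population the moderated test assumes), a planted fraction
``pi_dap`` of diet-responsive proteins with ±``effect_log2fc`` shifts,
per-sample global log2 shifts (the normalization challenge), and
intensity-dependent (MNAR) missingness: after sample scaling, each cell is
detected with probability logistic((log2 intensity − threshold)/slope), so
low-abundance cells go missing preferentially — the dominant missingness
mode of label-free proteomics.

Defaults are sized like one tissue of the study: 4000 proteins, 8 replicates
per diet (split into halves of 4), MaxLFQ-like intensities around 2^20.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import GrowthRecord
from .io import ProteinMatrix, SampleDesign

__all__ = ["SimConfig", "SyntheticTruth", "generate_matrix", "generate_prm",
           "generate_growth", "generate_design"]


@dataclass
class SimConfig:
    """Knobs of the synthetic feeding-trial proteome.

    All intensity parameters are on the log2 scale.  ``protein_sd_shape`` /
    ``protein_sd_scale`` parameterize an inverse-gamma over per-protein
    residual *variances* (shape 3, scale 0.08 gives typical residual SDs
    near 0.2 log2 units, as seen in well-behaved DIA data).  Setting
    ``mnar_threshold`` to ``None`` disables missingness.
    """

    seed: int = 0
    n_proteins: int = 4000
    n_per_group: int = 8
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    protein_sd_shape: float = 3.0
    protein_sd_scale: float = 0.08
    pi_dap: float = 0.1
    effect_log2fc: float = 1.5
    sample_scale_sd: float = 0.5
    mnar_threshold: float | None = 17.0
    mnar_slope: float = 1.5
    tissue: str = "brain"
    diets: tuple[str, str] = ("A", "B")
    # PRM layer
    prm_n_proteins: int = 9
    prm_noise_sd: float = 0.1
    prm_n_samples_per_group: int = 4

    def __post_init__(self) -> None:
        if not 0 <= self.pi_dap <= 1:
            raise ValueError("pi_dap must lie in [0, 1]")
        if min(self.baseline_sd, self.sample_scale_sd, self.prm_noise_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.protein_sd_shape <= 0 or self.protein_sd_scale <= 0:
            raise ValueError("inverse-gamma parameters must be positive")
        if self.n_per_group < 2 or self.n_per_group % 2:
            raise ValueError("n_per_group must be an even number >= 2")


@dataclass
class SyntheticTruth:
    """Ground truth emitted beside a generated matrix."""

    protein_ids: list[str]
    is_dap: np.ndarray
    true_log2fc: np.ndarray
    true_sd: np.ndarray
    baseline: np.ndarray
    sample_shift: pd.Series  # per sample log2 shift
    latent_log2: pd.DataFrame  # pre-missingness log2 intensities
    mnar_threshold: float | None
    mnar_slope: float

    def per_protein_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": self.protein_ids,
                "is_dap": self.is_dap.astype(int),
                "true_log2fc": self.true_log2fc,
                "true_sd": self.true_sd,
                "baseline": self.baseline,
            }
        )


def generate_design(cfg: SimConfig) -> SampleDesign:
    """Design table: two diets × n_per_group replicates, halves by replicate."""
    rows = []
    half_size = cfg.n_per_group // 2
    for diet in cfg.diets:
        for rep in range(1, cfg.n_per_group + 1):
            rows.append(
                {
                    "sample_id": f"{cfg.tissue}_{diet}{rep}",
                    "tissue": cfg.tissue,
                    "diet": diet,
                    "replicate": rep,
                    "half": 1 if rep <= half_size else 2,
                }
            )
    return SampleDesign(pd.DataFrame(rows))


def generate_matrix(cfg: SimConfig) -> tuple[ProteinMatrix, SyntheticTruth]:
    """Draw a raw-scale protein matrix plus its ground truth.

    Cell model (log2 scale):  baseline_i + effect_i·1[diet B] + shift_s + ε,
    ε ~ N(0, sd_i²).  Missingness (if enabled) is applied to the *scaled*
    intensity — detection depends on what the instrument saw, not the latent
    biology.
    """
    rng = np.random.default_rng(cfg.seed)
    design = generate_design(cfg)
    samples = design.sample_ids
    n = cfg.n_proteins
    protein_ids = [f"P{i:05d}" for i in range(n)]

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n)
    variances = 1.0 / rng.gamma(cfg.protein_sd_shape,
                                1.0 / cfg.protein_sd_scale, size=n)
    sds = np.sqrt(variances)
    is_dap = rng.random(n) < cfg.pi_dap
    signs = rng.choice([-1.0, 1.0], size=n)
    effects = np.where(is_dap, signs * cfg.effect_log2fc, 0.0)

    shift = pd.Series(
        rng.normal(0.0, cfg.sample_scale_sd, size=len(samples)), index=samples
    )
    in_b = np.array(
        [design.table.set_index("sample_id").loc[s, "diet"] == cfg.diets[1]
         for s in samples]
    )
    eps = rng.normal(0.0, 1.0, size=(n, len(samples))) * sds[:, None]
    latent = (
        baseline[:, None]
        + np.outer(effects, in_b.astype(float))
        + shift.to_numpy()[None, :]
        + eps
    )
    latent_df = pd.DataFrame(latent, index=pd.Index(protein_ids, name="Protein.Group"),
                             columns=samples)

    intensity = np.power(2.0, latent)
    if cfg.mnar_threshold is not None:
        detect_p = 1.0 / (1.0 + np.exp(-(latent - cfg.mnar_threshold) / cfg.mnar_slope))
        detected = rng.random(latent.shape) < detect_p
        intensity = np.where(detected, intensity, np.nan)

    values = pd.DataFrame(intensity, index=latent_df.index, columns=samples)
    annotations = pd.DataFrame(
        {
            "Protein.Ids": protein_ids,
            "Genes": [f"gene{i}" for i in range(n)],
        },
        index=latent_df.index,
    )
    matrix = ProteinMatrix(values=values, annotations=annotations, scale="raw")
    truth = SyntheticTruth(
        protein_ids=protein_ids,
        is_dap=is_dap,
        true_log2fc=effects,
        true_sd=sds,
        baseline=baseline,
        sample_shift=shift,
        latent_log2=latent_df,
        mnar_threshold=cfg.mnar_threshold,
        mnar_slope=cfg.mnar_slope,
    )
    return matrix, truth


def generate_prm(truth: SyntheticTruth, cfg: SimConfig) -> pd.DataFrame:
    """Transition-area table for a subset of proteins sharing the DIA truth.

    Picks the strongest planted responders (padding with nulls if needed),
    gives each 2–4 peptides with 3–6 transitions, and draws areas lognormal
    around the protein's latent abundance apportioned by fixed peptide and
    transition weights.  Samples are the first ``prm_n_samples_per_group``
    replicates of each diet.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    order = np.argsort(-np.abs(truth.true_log2fc), kind="stable")
    chosen = order[: cfg.prm_n_proteins]
    design = generate_design(cfg)
    samples = []
    for diet in cfg.diets:
        samples.extend(design.samples(diet=diet)[: cfg.prm_n_samples_per_group])

    rows = []
    for idx in chosen:
        pid = truth.protein_ids[idx]
        n_pep = int(rng.integers(2, 5))
        pep_weights = rng.dirichlet(np.full(n_pep, 5.0))
        for pi in range(n_pep):
            pep = f"{pid}_PEP{pi + 1}"
            n_tr = int(rng.integers(3, 7))
            tr_weights = rng.dirichlet(np.full(n_tr, 5.0))
            for s in samples:
                latent = truth.latent_log2.loc[pid, s]
                pep_area = pep_weights[pi] * np.power(
                    2.0, latent + rng.normal(0.0, cfg.prm_noise_sd)
                )
                for ti in range(n_tr):
                    rows.append(
                        {
                            "protein_id": pid,
                            "peptide": pep,
                            "transition": f"{pep}_y{ti + 3}",
                            "sample_id": s,
                            "area": tr_weights[ti] * pep_area,
                        }
                    )
    return pd.DataFrame(rows)


def generate_growth(
    cfg: SimConfig,
    *,
    days: int = 84,
    initial_mean: float = 513.9,
    gain_mean: tuple[float, float] = (683.0, 683.5),
    intake_mean: tuple[float, float] = (864.0, 828.0),
    n_tanks: int = 3,
    tank_sd: float = 5.0,
) -> list[GrowthRecord]:
    """Tank-level growth records for two diets (defaults shaped like a
    12-week trial on ~500 g fish); gain = final − initial by construction."""
    rng = np.random.default_rng(cfg.seed + 2)
    records = []
    for d, diet in enumerate(cfg.diets):
        for tank in range(1, n_tanks + 1):
            initial = rng.normal(initial_mean, 1.0)
            gain = rng.normal(gain_mean[d], tank_sd)
            intake = rng.normal(intake_mean[d], tank_sd)
            records.append(
                GrowthRecord(
                    group=f"{diet}_tank{tank}",
                    initial_weight=round(initial, 2),
                    final_weight=round(initial, 2) + round(gain, 2),
                    days=days,
                    feed_intake=round(intake, 2),
                )
            )
    return records
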