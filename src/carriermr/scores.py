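"""Polygenic genetic-score construction and theoretical per-SD trait effects.

A score for individual *i* is the weighted allele-dosage sum
``GS_i = sum_k beta_k x_ik`` over the model's SNPs; scores are standardized
using the analysis sample's mean and SD. Under Hardy-Weinberg equilibrium
and independence between SNPs the population SD of the raw score is
``sqrt(sum_k 2 p_k (1 - p_k) beta_k^2)``, which — because the weights are
per-allele trait effects in years — equals the expected trait shift per
1-SD score difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .sumstats import harmonize, validate_assoc_table

logger = logging.getLogger(__name__)


class ScoreError(ValueError):
    pass


@dataclass(frozen=True)
class GeneticScoreModel:
    """SNP weights and allele frequencies defining a genetic score.

    Parameters
    ----------
    variant_id, effect_allele : arrays of str
    weight : array of float
        Per-allele trait effect (e.g. years of ANM per effect allele).
    eaf : array of float
        Effect-allele frequency in the source population, in (0, 1).
    label : str
        Score name, e.g. ``"ANM-GS"``, ``"AAM-GS"``, ``"AAMBMI-GS"``.
    """

    variant_id: tuple
    effect_allele: tuple
    weight: tuple
    eaf: tuple
    label: str = "GS"

    def __post_init__(self):
        n = len(self.variant_id)
        if not (len(self.effect_allele) == len(self.weight) == len(self.eaf) == n):
            raise ScoreError("model field lengths differ")
        if n == 0:
            raise ScoreError("empty score model")
        if len(set(self.variant_id)) != n:
            raise ScoreError("duplicate variant IDs in score model")
        w = np.asarray(self.weight, float)
        if not np.all(np.isfinite(w)):
            raise ScoreError("non-finite weight")
        p = np.asarray(self.eaf, float)
        if np.any(np.isnan(p)):
            missing = self.variant_id[int(np.flatnonzero(np.isnan(p))[0])]
            raise ScoreError(f"missing allele frequency for SNP {missing}")
        if np.any((p <= 0) | (p >= 1)):
            raise ScoreError("allele frequencies must lie in (0, 1)")

    @property
    def n_snps(self) -> int:
        return len(self.variant_id)

    @property
    def weights(self) -> np.ndarray:
        return np.asarray(self.weight, float)

    @property
    def frequencies(self) -> np.ndarray:
        return np.asarray(self.eaf, float)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label: str = "GS") -> "GeneticScoreModel":
        return cls(
            variant_id=tuple(df["variant_id"]),
            effect_allele=tuple(df["effect_allele"]),
            weight=tuple(np.asarray(df["weight"], float)),
            eaf=tuple(np.asarray(df["eaf"], float)),
            label=label,
        )

    @classmethod
    def read(cls, path, label: str = "GS") -> "GeneticScoreModel":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype={"variant_id": str}), label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.variant_id,
                "effect_allele": self.effect_allele,
                "weight": self.weight,
                "eaf": self.eaf,
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def compute_scores(model: GeneticScoreModel, dosages: pd.DataFrame) -> pd.DataFrame:
    """Raw and sample-standardized scores from an individuals-by-SNP dosage matrix.

    ``dosages`` columns are variant IDs (values in [0, 2]); missing dosages
    are mean-imputed as ``2 p_k`` and flagged per individual. Standardization
    uses the analysis sample's mean and SD (ddof=0), so the returned
    ``score_std`` has mean 0 and SD 1 exactly.
    """
    missing_cols = [v for v in model.variant_id if v not in dosages.columns]
    if missing_cols:
        raise ScoreError(f"dosage matrix lacks model SNPs: {missing_cols[:5]} ...")
    X = dosages[list(model.variant_id)].to_numpy(float)
    n_imputed = np.isnan(X).sum(axis=1)
    if n_imputed.any():
        fill = 2.0 * model.frequencies
        X = np.where(np.isnan(X), fill[None, :], X)
    raw = X @ model.weights
    sd = raw.std(ddof=0)
    if sd == 0 or not np.isfinite(sd):
        raise ScoreError("raw scores have zero variance; cannot standardize")
    std = (raw - raw.mean()) / sd
    return pd.DataFrame(
        {"score_raw": raw, "score_std": std, "n_imputed": n_imputed},
        index=dosages.index,
    )


def build_bmi_weighted_score(
    aam_model: GeneticScoreModel,
    bmi_assoc: pd.DataFrame,
    max_dropped_fraction: float = 0.5,
) -> GeneticScoreModel:
    """Reweight an AAM score's SNPs by their BMI effect sizes (AAMBMI-GS).

    BMI betas are harmonized to the score's effect alleles (sign-flip where
    the effect allele is the BMI table's other allele). SNPs absent from
    ``bmi_assoc`` are dropped with a log message; more than
    ``max_dropped_fraction`` dropped is an error.
    """
    bmi = validate_assoc_table(bmi_assoc, "bmi")
    bmi = bmi.set_index("variant_id")
    keep_ids, weights, alleles, eafs = [], [], [], []
    for vid, ea, p in zip(aam_model.variant_id, aam_model.effect_allele, aam_model.eaf):
        if vid not in bmi.index:
            continue
        row = bmi.loc[vid]
        if row["effect_allele"] == ea:
            w = float(row["beta"])
        elif row["other_allele"] == ea:
            w = -float(row["beta"])
        else:
            continue  # allele mismatch: treated as uncovered
        keep_ids.append(vid)
        weights.append(w)
        alleles.append(ea)
        eafs.append(p)
    dropped = aam_model.n_snps - len(keep_ids)
    if dropped:
        logger.info("AAMBMI-GS: dropped %d/%d SNP(s) without BMI coverage",
                    dropped, aam_model.n_snps)
    if dropped > max_dropped_fraction * aam_model.n_snps:
        raise ScoreError(
            f"{dropped}/{aam_model.n_snps} SNPs lack BMI coverage "
            f"(> {max_dropped_fraction:.0%} dropped)"
        )
    return GeneticScoreModel(
        variant_id=tuple(keep_ids),
        effect_allele=tuple(alleles),
        weight=tuple(weights),
        eaf=tuple(eafs),
        label="AAMBMI-GS",
    )


def theoretical_sd_effect(model: GeneticScoreModel) -> float:
    """Expected trait shift (years) per population SD of the raw score.

    Under HWE and independence between SNPs, ``Var(GS) =
    sum_k 2 p_k (1-p_k) beta_k^2``; the square root is both the population
    SD of the score and the trait change per 1-SD score difference.
    Invariant to allele re-orientation (beta -> -beta, p -> 1-p).
    """
    p = model.frequencies
    b = model.weights
    return float(np.sqrt(np.sum(2.0 * p * (1.0 - p) * b**2)))


def reorient(model: GeneticScoreModel, flip_mask) -> GeneticScoreModel:
    """Re-express a subset of SNPs on the opposite allele (testing utility)."""
    flip = np.asarray(flip_mask, bool)
    w = np.where(flip, -model.weights, model.weights)
    p = np.where(flip, 1.0 - model.frequencies, model.frequencies)
    return replace(model, weight=tuple(w), eaf=tuple(p))
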