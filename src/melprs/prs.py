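"""Weighted-sum polygenic risk score and control-series standardization.

The score for an individual is the additive sum over panel SNPs of the
per-allele log odds ratio times the effect-allele dosage,

    PRS = sum_i beta_i * x_i,   x_i in {0, 1, 2}.

Raw scores are standardized to the mean and SD of the control series so a
unit of the reported score is one control-series standard deviation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_qc import GenotypeMatrix, WeightsTable

__all__ = ["StandardizationParams", "ScoreSet", "compute_prs", "standardize"]


@dataclass(frozen=True)
class StandardizationParams:
    """Control-series mean and SD of the raw score (SD with n-1 denominator)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("standardization SD must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"mean": self.mean, "sd": self.sd}, indent=2) + "\n"
        )


@dataclass
class ScoreSet:
    """Raw and standardized PRS per individual, with the parameters used."""

    individual_ids: list[str]
    raw_score: np.ndarray
    std_score: np.ndarray
    params: StandardizationParams

    def __post_init__(self) -> None:
        self.raw_score = np.asarray(self.raw_score, dtype=float)
        self.std_score = np.asarray(self.std_score, dtype=float)
        n = len(self.individual_ids)
        if self.raw_score.shape != (n,) or self.std_score.shape != (n,):
            raise ValueError("score vectors must match individual_ids in length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": self.individual_ids,
                "raw_score": self.raw_score,
                "std_score": self.std_score,
            }
        )

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path


def compute_prs(
    matrix: GenotypeMatrix,
    weights: WeightsTable,
    missing_policy: str = "impute_mean_dosage",
) -> np.ndarray:
    """Per-individual raw PRS over the panel SNPs present in ``matrix``.

    missing_policy:
        ``"impute_mean_dosage"`` (default) — a missing dosage is replaced by
        that SNP's mean non-missing dosage over all individuals;
        ``"error"`` — any missing dosage raises, naming individual and SNP.
    """
    if missing_policy not in ("error", "impute_mean_dosage"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    beta_of = {r.snp_id: r.beta for r in weights.records}
    unknown = [s for s in matrix.snp_ids if s not in beta_of]
    if unknown:
        raise ValueError(f"matrix SNP(s) absent from weights: {', '.join(unknown)}")

    dos = matrix.dosages.copy()
    miss = np.isnan(dos)
    if miss.any():
        if missing_policy == "error":
            i, j = np.argwhere(miss)[0]
            raise ValueError(
                f"missing dosage for individual {matrix.individual_ids[i]!r} "
                f"at SNP {matrix.snp_ids[j]!r}"
            )
        col_all_missing = miss.all(axis=0)
        if col_all_missing.any():
            bad = [s for s, m in zip(matrix.snp_ids, col_all_missing) if m]
            raise ValueError(
                f"cannot impute: all dosages missing for SNP(s) {', '.join(bad)}"
            )
        col_means = np.nanmean(dos, axis=0)
        dos = np.where(miss, col_means, dos)

    betas = np.array([beta_of[s] for s in matrix.snp_ids])
    return dos @ betas


def standardize(raw: np.ndarray, control_mask: np.ndarray, individual_ids=None) -> ScoreSet:
    """Standardize all scores to the control-series mean and SD.

    The mean and SD (n-1 denominator) are computed over controls only and
    applied to every individual, so controls have mean 0 / SD 1 by
    construction and case scores are expressed in control-SD units.
    """
    raw = np.asarray(raw, dtype=float)
    control_mask = np.asarray(control_mask, dtype=bool)
    if raw.shape != control_mask.shape:
        raise ValueError("raw scores and control mask must have the same length")
    controls = raw[control_mask]
    if controls.size < 2:
        raise ValueError("need at least 2 controls to standardize")
    mean = float(controls.mean())
    sd = float(controls.std(ddof=1))
    if sd == 0.0:
        raise ValueError("control scores are all equal; SD is zero")
    params = StandardizationParams(mean=mean, sd=sd)
    if individual_ids is None:
        individual_ids = [str(i) for i in range(raw.size)]
    return ScoreSet(
        individual_ids=list(individual_ids),
        raw_score=raw,
        std_score=(raw - mean) / sd,
        params=params,
    )
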