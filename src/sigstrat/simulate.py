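"""Synthetic cohorts with planted truth for every pipeline stage.

Expression model (log2 scale, baseline 0):

    x[g, s] = category effect  (effect_ra on RA genes of RA-D samples,
                                effect_erk on ERK genes of ERK-I samples)
            + anti_corr_loading * f_s * sign(g)   (latent factor f_s,
                                sign +1 for ERK genes, -1 for RA genes)
            + Normal(0, noise_sd)

The shared latent factor makes the two signature scores anti-correlated
even with category effects switched off.  Survival is exponential with a
category-multiplicative hazard (baseline * hr_ra^[RA-D] * hr_erk^[ERK-I])
under independent Uniform(0, censor_max) censoring; relapse-free times use
the same model with hazards scaled by ``rfs_hazard_scale``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .classify import CATEGORIES
from .data import ClinicalTable, ExpressionMatrix, GeneSignature, ValidationError

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort", "generate_de_experiment"]

# one planted intrinsic-subtype label per category, purely to exercise
# subtype-stratified reporting
SUBTYPE_BY_CATEGORY = {
    "RA-ND/ERK-NI": "LumA",
    "RA-ND/ERK-I": "LumB",
    "RA-D/ERK-NI": "HER2",
    "RA-D/ERK-I": "Basal",
}
CLUSTER_BY_CATEGORY = {  # 3 planted prognostic groups: none / one / both hits
    "RA-ND/ERK-NI": 0,
    "RA-ND/ERK-I": 1,
    "RA-D/ERK-NI": 1,
    "RA-D/ERK-I": 2,
}


@dataclass(frozen=True)
class CohortConfig:
    n_samples: int = 200
    n_genes: int = 1000
    sig_size_ra: int = 50
    sig_size_erk: int = 50
    category_probs: tuple[float, float, float, float] = (0.55, 0.15, 0.15, 0.15)
    effect_ra: float = -1.5
    effect_erk: float = 1.5
    anti_corr_loading: float = 0.8
    latent_sd: float = 0.25
    noise_sd: float = 0.3
    baseline_hazard: float = 0.02
    hr_ra: float = 2.0
    hr_erk: float = 2.0
    censor_max: float = 160.0
    rfs_hazard_scale: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sig_size_ra + self.sig_size_erk > self.n_genes:
            raise ValidationError("signatures must be disjoint and fit within n_genes")
        if abs(sum(self.category_probs) - 1.0) > 1e-12:
            raise ValidationError("category_probs must sum to 1")
        if len(self.category_probs) != 4 or any(p < 0 for p in self.category_probs):
            raise ValidationError("category_probs must be 4 non-negative values")
        if not (0.0 <= self.anti_corr_loading <= 1.0):
            raise ValidationError("anti_corr_loading must lie in [0, 1]")
        for name in ("n_samples", "n_genes", "sig_size_ra", "sig_size_erk"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        for name in ("baseline_hazard", "hr_ra", "hr_erk", "censor_max", "rfs_hazard_scale"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("noise_sd", "latent_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    clinical: ClinicalTable
    ra_signature: GeneSignature
    erk_signature: GeneSignature
    truth: pd.DataFrame  # index sample_id: category, cluster, latent, hazard, subtype
    config: CohortConfig = field(repr=False, default=None)


def expected_event_fraction(config: CohortConfig, hazards: np.ndarray) -> float:
    """Analytic mean P(event observed) under Uniform(0, C) censoring.

    P(T <= U) = 1 - (1 - exp(-hC)) / (hC) for T ~ Exp(h), U ~ Uniform(0, C).
    """
    hc = hazards * config.censor_max
    return float(np.mean(1.0 - (1.0 - np.exp(-hc)) / hc))


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n, g = config.n_samples, config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(g)]
    sample_ids = [f"S{i:04d}" for i in range(n)]
    ra_genes = tuple(gene_ids[: config.sig_size_ra])
    erk_genes = tuple(gene_ids[config.sig_size_ra : config.sig_size_ra + config.sig_size_erk])

    cat_idx = rng.choice(4, size=n, p=np.asarray(config.category_probs))
    category = np.array([CATEGORIES[i] for i in cat_idx])
    ra_d = np.isin(cat_idx, [2, 3])  # RA-D/ERK-NI, RA-D/ERK-I
    erk_i = np.isin(cat_idx, [1, 3])  # RA-ND/ERK-I, RA-D/ERK-I
    latent = rng.normal(0.0, config.latent_sd, size=n)

    values = rng.normal(0.0, config.noise_sd, size=(g, n))
    ra_slice = slice(0, config.sig_size_ra)
    erk_slice = slice(config.sig_size_ra, config.sig_size_ra + config.sig_size_erk)
    values[ra_slice, :] += np.where(ra_d, config.effect_ra, 0.0)[None, :]
    values[erk_slice, :] += np.where(erk_i, config.effect_erk, 0.0)[None, :]
    values[ra_slice, :] -= config.anti_corr_loading * latent[None, :]
    values[erk_slice, :] += config.anti_corr_loading * latent[None, :]

    hazard = config.baseline_hazard * np.where(ra_d, config.hr_ra, 1.0) * np.where(
        erk_i, config.hr_erk, 1.0
    )
    os_t = rng.exponential(1.0 / hazard)
    os_c = rng.uniform(0.0, config.censor_max, size=n)
    rfs_t = rng.exponential(1.0 / (hazard * config.rfs_hazard_scale))
    rfs_c = rng.uniform(0.0, config.censor_max, size=n)

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "os_time": np.minimum(os_t, os_c),
                "os_event": (os_t <= os_c).astype(int),
                "rfs_time": np.minimum(rfs_t, rfs_c),
                "rfs_event": (rfs_t <= rfs_c).astype(int),
                "subtype": [SUBTYPE_BY_CATEGORY[c] for c in category],
            }
        )
    )
    truth = pd.DataFrame(
        {
            "category": category,
            "cluster": [CLUSTER_BY_CATEGORY[c] for c in category],
            "latent": latent,
            "hazard": hazard,
            "subtype": [SUBTYPE_BY_CATEGORY[c] for c in category],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return SyntheticCohort(
        expression=ExpressionMatrix(values, gene_ids, sample_ids),
        clinical=clinical,
        ra_signature=GeneSignature(
            "RA_dependent_up", ra_genes, "up", {"planted": True, "effect": config.effect_ra}
        ),
        erk_signature=GeneSignature(
            "ERK_dependent_up", erk_genes, "up", {"planted": True, "effect": config.effect_erk}
        ),
        truth=truth,
        config=config,
    )


def generate_de_experiment(
    n_per_group: int,
    n_genes: int,
    n_de: int,
    log2_effect: float,
    seed: int = 0,
    noise_sd: float = 0.4,
) -> tuple[ExpressionMatrix, dict, frozenset]:
    """Two-group expression matrix with the first ``n_de`` genes shifted.

    Returns (matrix, sample -> group labels, planted gene-id set); feeds
    the signature-derivation recovery tests.
    """
    if n_de > n_genes:
        raise ValidationError("n_de must not exceed n_genes")
    if n_per_group < 2:
        raise ValidationError("need at least 2 samples per group")
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    sample_ids = [f"C{i:03d}" for i in range(n_per_group)] + [
        f"T{i:03d}" for i in range(n_per_group)
    ]
    values = rng.normal(0.0, noise_sd, size=(n_genes, 2 * n_per_group))
    values[:n_de, n_per_group:] += log2_effect
    labels = {s: ("control" if s.startswith("C") else "condition") for s in sample_ids}
    return (
        ExpressionMatrix(values, gene_ids, sample_ids),
        labels,
        frozenset(gene_ids[:n_de]),
    )
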