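"""End-to-end pipeline driver.

Stage order mirrors the analysis it packages: per-sample classification
into the four RA/ERK categories, Kaplan–Meier + log-rank per category,
signature-score correlation, bootstrap-Jaccard stability selection of the
cluster count on the signature genes, and cluster-level survival
comparison (log-rank plus Kruskal–Wallis / gatekept pairwise Wilcoxon on
uncensored times).  Every run writes one TSV per stage and a JSON manifest
recording version, seed, parameters, and the convention decisions baked
into the classification step.  Inputs on disk are never mutated.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .classify import CATEGORIES, ClassificationParams, classify_samples, signature_score
from .data import ClinicalTable, ExpressionMatrix, GeneSignature, ValidationError
from .io import read_clinical, read_expression
from .signatures import read_signatures
from .stability import choose_k, standardize_features
from .survival import (
    km_estimate,
    logrank_test,
    pairwise_logrank,
    uncensored_location_test,
)

log = logging.getLogger("sigstrat")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


@dataclass
class PipelineConfig:
    expression_path: str
    clinical_path: str
    ra_signature_path: str
    erk_signature_path: str
    out_dir: str
    params: ClassificationParams = field(default_factory=ClassificationParams)
    endpoints: tuple[str, ...] = ("os", "rfs")
    k_range: tuple[int, int] = (2, 10)
    n_bootstrap: int = 100
    jaccard_hi: float = 0.85
    seed: int = 0
    log_level: str = "INFO"

    def validate_paths(self) -> None:
        for name in ("expression_path", "clinical_path", "ra_signature_path", "erk_signature_path"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ValidationError(f"{name} does not exist: {p}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = dataclasses.asdict(self.params)
        return d


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


def _config_hash(config: PipelineConfig) -> str:
    d = config.to_dict()
    d.pop("out_dir", None)  # hash the analysis parameters, not the output location
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _substream(seed: int, name: str) -> int:
    """Named, order-independent substream seed derived from the root seed."""
    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big")


def _curves_frame(clinical: ClinicalTable, groups: pd.Series, endpoint: str) -> pd.DataFrame:
    times, events, idx = clinical.endpoint(endpoint)
    frames = []
    for g in pd.unique(groups.reindex(idx).dropna()):
        mask = (groups.reindex(idx) == g).to_numpy()
        if mask.sum() == 0:
            continue
        curve = km_estimate(times[mask], events[mask]).to_dataframe()
        curve.insert(0, "group", g)
        frames.append(curve)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def _survival_tests(clinical: ClinicalTable, groups: pd.Series, endpoint: str) -> list[dict]:
    times, events, idx = clinical.endpoint(endpoint)
    g = groups.reindex(idx)
    keep = g.notna().to_numpy()
    times, events, labels = times[keep], events[keep], g[keep].to_numpy()
    rows = []
    if len(pd.unique(labels)) >= 2:
        lr = logrank_test(times, events, labels)
        rows.append(
            {"endpoint": endpoint, "test": "logrank", "groups": "all",
             "statistic": lr.statistic, "p_value": lr.p_value, "df": lr.df}
        )
        for item in pairwise_logrank(times, events, labels):
            res = item["result"]
            rows.append(
                {"endpoint": endpoint, "test": "logrank_pairwise",
                 "groups": "|".join(map(str, item["pair"])),
                 "statistic": res.statistic, "p_value": res.p_value, "df": res.df}
            )
        try:
            loc = uncensored_location_test(times, events, labels)
            rows.append(
                {"endpoint": endpoint, "test": "kruskal_wallis_uncensored", "groups": "all",
                 "statistic": loc["kw"].statistic, "p_value": loc["kw"].p_value,
                 "df": loc["kw"].df}
            )
            for item in loc["pairwise"]:
                res = item["result"]
                rows.append(
                    {"endpoint": endpoint, "test": "wilcoxon_uncensored",
                     "groups": "|".join(map(str, item["pair"])),
                     "statistic": res.statistic, "p_value": item["p_adjusted"], "df": None}
                )
        except ValidationError as exc:
            log.warning("uncensored location test skipped (%s): %s", endpoint, exc)
    return rows


def run_pipeline(
    config: PipelineConfig,
    *,
    expression: Optional[ExpressionMatrix] = None,
    clinical: Optional[ClinicalTable] = None,
    ra_signature: Optional[GeneSignature] = None,
    erk_signature: Optional[GeneSignature] = None,
) -> dict:
    """Run classification -> survival -> scores -> stability -> cluster survival.

    In-memory inputs may be passed to bypass file reading (used by
    ``run-all`` on freshly simulated cohorts).  Returns the manifest dict.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "stages": {},
        "decisions": {
            "fisher_reference": "rounded cohort mean count (ties-to-even)",
            "fisher_sidedness": "greater",
            "tie_convention": "deaths precede censorings",
            "cluster_features": "signature-gene union, gene-standardized",
        },
    }

    def _fail(stage: str, exc: Exception):
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise PipelineError(stage, exc) from exc

    # --- read ---------------------------------------------------------
    stage = "read_inputs"
    try:
        if expression is None or clinical is None or ra_signature is None or erk_signature is None:
            config.validate_paths()
        if expression is None:
            expression = read_expression(config.expression_path)
        if clinical is None:
            clinical = read_clinical(config.clinical_path)
        if ra_signature is None:
            ra_signature = read_signatures(config.ra_signature_path)[0]
        if erk_signature is None:
            erk_signature = read_signatures(config.erk_signature_path)[0]
    except Exception as exc:
        _fail(stage, exc)
    manifest["stages"][stage] = {
        "status": "ok",
        "n_genes": expression.n_genes,
        "n_samples": expression.n_samples,
    }

    # --- classification ----------------------------------------------
    stage = "classify"
    try:
        strat = classify_samples(expression, ra_signature, erk_signature, config.params)
        strat_path = out / "stratification.tsv"
        strat.table.to_csv(strat_path, sep="\t", na_rep="NA")
    except Exception as exc:
        _fail(stage, exc)
    manifest["stages"][stage] = {
        "status": "ok",
        "output": strat_path.name,
        "category_counts": {k: int(v) for k, v in strat.category_counts().items()},
        "metadata": strat.metadata,
    }

    # --- category survival -------------------------------------------
    stage = "category_survival"
    try:
        cat = strat.table["category"]
        rows, curve_frames = [], []
        for endpoint in config.endpoints:
            rows.extend(_survival_tests(clinical, cat, endpoint))
            cf = _curves_frame(clinical, cat, endpoint)
            cf.insert(0, "endpoint", endpoint)
            curve_frames.append(cf)
        pd.DataFrame(rows).to_csv(out / "category_tests.tsv", sep="\t", index=False, na_rep="NA")
        pd.concat(curve_frames, ignore_index=True).to_csv(
            out / "category_curves.tsv", sep="\t", index=False
        )
    except Exception as exc:
        _fail(stage, exc)
    manifest["stages"][stage] = {
        "status": "ok",
        "outputs": ["category_tests.tsv", "category_curves.tsv"],
    }

    # --- signature scores --------------------------------------------
    stage = "signature_scores"
    try:
        ra_score = signature_score(expression, ra_signature)
        erk_score = signature_score(expression, erk_signature)
        scores = pd.DataFrame(
            {"ra_score": ra_score.scores, "erk_score": erk_score.scores}
        )
        scores.index.name = "sample_id"
        scores.to_csv(out / "signature_scores.tsv", sep="\t", na_rep="NA")
        corr = float(scores["ra_score"].corr(scores["erk_score"]))
    except Exception as exc:
        _fail(stage, exc)
    manifest["stages"][stage] = {
        "status": "ok",
        "output": "signature_scores.tsv",
        "ra_erk_score_correlation": corr,
    }

    # --- stability clustering ----------------------------------------
    stage = "cluster_stability"
    try:
        sig_genes = list(dict.fromkeys([*ra_signature.genes, *erk_signature.genes]))
        feats = expression.subset_genes(sig_genes)
        x = standardize_features(np.nan_to_num(feats.values, nan=0.0).T)
        kmin, kmax = config.k_range
        kmax = min(kmax, expression.n_samples - 1)
        sel = choose_k(
            x,
            range(kmin, kmax + 1),
            jaccard_hi=config.jaccard_hi,
            n_bootstrap=config.n_bootstrap,
            seed=_substream(config.seed, "stability"),
        )
        rows = [
            {
                "k": k,
                "min_jaccard": rep.min_jaccard,
                "per_cluster_mean_jaccard": ",".join(
                    f"{v:.4f}" for v in rep.per_cluster_mean_jaccard
                ),
                "chosen": rep.chosen,
            }
            for k, rep in sorted(sel["reports"].items())
        ]
        pd.DataFrame(rows).to_csv(out / "stability.tsv", sep="\t", index=False)
        from .stability import kmeans_cluster

        km = kmeans_cluster(x, sel["k_star"], seed=_substream(config.seed, "final_kmeans"))
        clusters = pd.Series(km.labels, index=expression.sample_ids, name="cluster")
        clusters.rename_axis("sample_id").to_csv(out / "clusters.tsv", sep="\t")
    except Exception as exc:
        _fail(stage, exc)
    manifest["stages"][stage] = {
        "status": "ok",
        "outputs": ["stability.tsv", "clusters.tsv"],
        "k_star": sel["k_star"],
        "stable": sel["stable"],
    }

    # --- cluster survival --------------------------------------------
    stage = "cluster_survival"
    try:
        cl = clusters.astype(str)
        rows, curve_frames = [], []
        for endpoint in config.endpoints:
            rows.extend(_survival_tests(clinical, cl, endpoint))
            cf = _curves_frame(clinical, cl, endpoint)
            cf.insert(0, "endpoint", endpoint)
            curve_frames.append(cf)
        pd.DataFrame(rows).to_csv(out / "cluster_tests.tsv", sep="\t", index=False, na_rep="NA")
        pd.concat(curve_frames, ignore_index=True).to_csv(
            out / "cluster_curves.tsv", sep="\t", index=False
        )
    except Exception as exc:
        _fail(stage, exc)
    manifest["stages"][stage] = {
        "status": "ok",
        "outputs": ["cluster_tests.tsv", "cluster_curves.tsv"],
    }

    manifest["status"] = "ok"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
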