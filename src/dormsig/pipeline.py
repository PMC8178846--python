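"""End-to-end orchestration: simulate/load -> derive -> score -> survival -> meta.

Every stage persists its inputs and outputs as plain-text files under the
output directory, so any later stage can be re-run from disk, and a run
with the same config and seed reproduces all outputs byte-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from dormsig import __version__
from dormsig.data_model import (
    CohortSurvival,
    ExpressionMatrix,
    GeneSignature,
    read_clinical,
    read_expression,
    read_signature_gmt,
    write_signature_gmt,
)
from dormsig.diffexpr import regularized_ttest, write_de_table
from dormsig.signature import (
    ComparisonSet,
    derive_dormancy_signature,
    dichotomize_by_median,
    score_samples,
)
from dormsig.survival import (
    CoxConvergenceError,
    cox_binary,
    forest_table,
    landmark_late,
    meta_analyze,
    select_endpoint,
    truncate_5y,
)
from dormsig.synthetic import (
    HumanSimConfig,
    MouseSimConfig,
    generate_human_cohorts,
    generate_mouse_models,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a stage cannot proceed; message names the stage."""


@dataclass
class PipelineConfig:
    """Declarative configuration for a full run.

    Exactly one of ``mouse_sim`` / ``mouse_files`` and one of
    ``human_sim`` / ``human_files`` must be set.
    """

    mouse_sim: dict | None = None
    mouse_files: dict | None = None
    human_sim: dict | None = None
    human_files: dict | None = None
    fc_threshold: float = 1.5
    fdr_threshold: float = 0.1
    het_alpha: float = 0.05
    horizon_months: float = 60.0
    landmark_months: float = 60.0
    late_relapse: bool = False
    adjust_proliferation: bool = False
    proliferation_gmt: str | None = None
    window: int = 101
    nu0: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.mouse_sim is None) == (self.mouse_files is None):
            raise ValueError("set exactly one of mouse_sim / mouse_files")
        if (self.human_sim is None) == (self.human_files is None):
            raise ValueError("set exactly one of human_sim / human_files")
        for name in ("fc_threshold", "het_alpha", "horizon_months",
                     "landmark_months"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fdr_threshold < 0:
            raise ValueError("fdr_threshold must be nonnegative")
        if self.adjust_proliferation and not self.proliferation_gmt:
            raise ValueError(
                "adjust_proliferation requires a proliferation_gmt path"
            )

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _load_mouse(config: PipelineConfig, outdir: Path):
    if config.mouse_sim is not None:
        sim = MouseSimConfig(**{**config.mouse_sim, "seed": config.seed})
        (m1, m2), truth = generate_mouse_models(sim)
        for tag, mat in (("model1", m1), ("model2", m2)):
            mat.write(
                outdir / f"mouse_{tag}_expression.tsv",
                outdir / f"mouse_{tag}_annotations.tsv",
            )
        truth.write(outdir / "mouse_truth.json")
        return m1, m2
    files = config.mouse_files
    m1 = read_expression(files["expression1"], files["annotation1"])
    m2 = read_expression(files["expression2"], files["annotation2"])
    return m1, m2


def _derive_signature(
    config: PipelineConfig, m1: ExpressionMatrix, m2: ExpressionMatrix,
    outdir: Path,
) -> GeneSignature:
    tables = {}
    for tag, mat in (("model1", m1), ("model2", m2)):
        rl = mat.samples_in_group("RL")
        for comp in ("PT", "RT"):
            other = mat.samples_in_group(comp)
            if len(rl) < 2 or len(other) < 2:
                raise PipelineError(
                    f"diffexpr: model {tag} lacks >=2 samples in RL or {comp}"
                )
            window = min(config.window, mat.shape[0])
            if window % 2 == 0:
                window -= 1
            de = regularized_ttest(mat, rl, other, window=window, nu0=config.nu0)
            write_de_table(de, outdir / f"de_{tag}_RL_vs_{comp}.tsv")
            tables[(tag, comp)] = de
    comparisons = ComparisonSet(
        tables[("model1", "PT")],
        tables[("model1", "RT")],
        tables[("model2", "PT")],
        tables[("model2", "RT")],
    )
    signature = derive_dormancy_signature(
        comparisons,
        fc_threshold=config.fc_threshold,
        fdr_threshold=config.fdr_threshold,
    )
    if len(signature) == 0:
        raise PipelineError(
            "derive: no genes passed the derivation thresholds "
            f"(|FC| > {config.fc_threshold}, FDR < {config.fdr_threshold})"
        )
    write_signature_gmt([signature], outdir / "dormancy_signature.gmt")
    return signature


def _load_human(
    config: PipelineConfig, signature: GeneSignature, outdir: Path
) -> list[tuple[ExpressionMatrix, CohortSurvival]]:
    if config.human_sim is not None:
        sim = HumanSimConfig(**{**config.human_sim, "seed": config.seed + 1})
        cohorts, truth = generate_human_cohorts(sim, signature=signature)
        truth.write(outdir / "human_truth.json")
        clinical = pd.concat([s.to_frame() for _, s in cohorts])
        clinical.to_csv(outdir / "human_clinical.tsv", sep="\t", index=False)
        for mat, surv in cohorts:
            mat.write(
                outdir / f"human_{surv.cohort_id}_expression.tsv",
                outdir / f"human_{surv.cohort_id}_annotations.tsv",
            )
        return cohorts
    files = config.human_files
    survivals = {
        c.cohort_id: c for c in read_clinical(files["clinical"])
    }
    cohorts = []
    for expr_path, ann_path in zip(files["expression"], files["annotations"]):
        mat = read_expression(expr_path, ann_path)
        cid = mat.sample_annotations["cohort_id"].iloc[0]
        if cid not in survivals:
            raise PipelineError(f"survival: no clinical data for cohort {cid!r}")
        cohorts.append((mat, survivals[cid]))
    return cohorts


def _survival_meta(
    config: PipelineConfig,
    cohorts: list[tuple[ExpressionMatrix, CohortSurvival]],
    signature: GeneSignature,
    prolif: GeneSignature | None,
    outdir: Path,
    analysis: str,
) -> tuple[dict, list[str]]:
    """Score, dichotomize, per-cohort Cox (5-year or landmark), meta-analyze."""
    fits, dropped = [], []
    score_frames = []
    for mat, surv in cohorts:
        scores = score_samples(mat, signature)
        labeled = dichotomize_by_median(scores)
        score_frames.append(labeled)
        labels = pd.Series(
            labeled["label"].to_numpy(), index=labeled["sample_id"].to_numpy()
        )
        adjustment = None
        if prolif is not None:
            pscores = score_samples(mat, prolif).table
            adjustment = pd.Series(
                pscores["score"].to_numpy(),
                index=pscores["sample_id"].to_numpy(),
            )
        try:
            if analysis == "late":
                sub = landmark_late(surv, landmark=config.landmark_months)
            else:
                sub = truncate_5y(surv, horizon=config.horizon_months)
            keep = pd.Index(sub.patient_ids)
            fit = cox_binary(
                sub,
                labels.loc[keep],
                adjustment.loc[keep] if adjustment is not None else None,
            )
            fits.append(fit)
        except (ValueError, CoxConvergenceError) as exc:
            logger.warning(
                "dropping cohort %s from %s analysis: %s",
                surv.cohort_id, analysis, exc,
            )
            dropped.append(f"{surv.cohort_id}: {exc}")
    if len(fits) < 2:
        raise PipelineError(
            f"meta ({analysis}): fewer than 2 analyzable cohorts"
        )
    pd.concat(score_frames).to_csv(
        outdir / f"scores_{analysis}.tsv", sep="\t", index=False,
        float_format="%.10g",
    )
    meta = meta_analyze(fits, het_alpha=config.het_alpha)
    forest = forest_table(meta)
    forest.to_csv(
        outdir / f"forest_{analysis}.tsv", sep="\t", index=False,
        float_format="%.10g",
    )
    with open(outdir / f"meta_{analysis}.json", "w") as fh:
        json.dump(meta.to_dict(), fh, indent=2, sort_keys=True)
    return meta.to_dict(), dropped


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages; returns the run report (also written as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    m1, m2 = _load_mouse(config, outdir)
    signature = _derive_signature(config, m1, m2, outdir)
    cohorts = _load_human(config, signature, outdir)

    endpoints = {surv.endpoint for _, surv in cohorts}
    endpoint = select_endpoint(endpoints)
    cohorts = [
        (mat, surv) for mat, surv in cohorts if surv.endpoint == endpoint
    ] or cohorts

    prolif = None
    if config.adjust_proliferation:
        prolif = read_signature_gmt(config.proliferation_gmt)[0]

    meta_5y, dropped_5y = _survival_meta(
        config, cohorts, signature, prolif, outdir, analysis="5y"
    )
    report = {
        "version": __version__,
        "config": asdict(config),
        "endpoint": endpoint,
        "signature": {
            "name": signature.name,
            "n_genes": len(signature),
            "genes": [[g, w] for g, w in signature.entries],
        },
        "meta_5y": meta_5y,
        "dropped_cohorts_5y": dropped_5y,
    }
    if config.late_relapse:
        meta_late, dropped_late = _survival_meta(
            config, cohorts, signature, prolif, outdir, analysis="late"
        )
        report["meta_late"] = meta_late
        report["dropped_cohorts_late"] = dropped_late

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
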