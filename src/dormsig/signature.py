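"""Cross-model concordant signature derivation and signed z-score scoring."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from dormsig.data_model import ExpressionMatrix, GeneSignature

logger = logging.getLogger(__name__)


class ComparisonSet(NamedTuple):
    """Four DE tables, all oriented residual-lesion minus comparator."""

    model1_rl_vs_pt: pd.DataFrame
    model1_rl_vs_rt: pd.DataFrame
    model2_rl_vs_pt: pd.DataFrame
    model2_rl_vs_rt: pd.DataFrame


def derive_dormancy_signature(
    comparisons: ComparisonSet,
    fc_threshold: float = 1.5,
    fdr_threshold: float = 0.1,
) -> GeneSignature:
    """Select genes concordantly differential in all four comparisons.

    A gene enters the signature iff in every comparison (RL vs PT and RL
    vs RT, in both models) it satisfies |log2fc| > log2(fc_threshold) and
    q < fdr_threshold, with the same sign of log2fc throughout.  The
    weight is that common sign: +1 = up in residual lesions.

    Gene universes of the four tables may differ; derivation uses their
    intersection and raises if it is empty.
    """
    # fdr_threshold = 0 is legal and selects nothing (q < 0 is impossible);
    # callers surface the resulting empty signature
    if fc_threshold <= 0 or fdr_threshold < 0:
        raise ValueError("thresholds must be positive")
    tables = list(comparisons)
    universe = tables[0].index
    for tab in tables[1:]:
        universe = universe.intersection(tab.index)
    if len(universe) == 0:
        raise ValueError("gene universes of the four comparisons are disjoint")
    universe = universe.sort_values()

    lfc = np.column_stack([t.loc[universe, "log2fc"].to_numpy() for t in tables])
    q = np.column_stack([t.loc[universe, "q"].to_numpy() for t in tables])

    log2_thr = math.log2(fc_threshold)
    passes = (np.abs(lfc) > log2_thr) & (q < fdr_threshold)
    signs = np.sign(lfc)
    concordant = (signs == signs[:, [0]]).all(axis=1) & (signs[:, 0] != 0)
    keep = passes.all(axis=1) & concordant

    entries = [
        (gene, float(signs[i, 0]))
        for i, gene in enumerate(universe)
        if keep[i]
    ]
    return GeneSignature(
        entries,
        name="dormancy_signature",
        provenance=(
            f"concordant RL-vs-PT and RL-vs-RT in both models; "
            f"|FC|>{fc_threshold}, FDR<{fdr_threshold}"
        ),
    )


@dataclass
class SignatureScoreTable:
    """Per-sample signature scores: sample_id, cohort_id, score, n_genes_used."""

    table: pd.DataFrame
    signature_name: str = ""

    def __post_init__(self) -> None:
        required = {"sample_id", "cohort_id", "score", "n_genes_used"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"score table missing columns: {sorted(missing)}")
        if not np.isfinite(self.table["score"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite scores")

    def __len__(self) -> int:
        return len(self.table)

    def scores_for(self, cohort_id: str) -> pd.Series:
        sub = self.table[self.table["cohort_id"] == cohort_id]
        return pd.Series(
            sub["score"].to_numpy(), index=sub["sample_id"].to_numpy()
        )

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def score_samples(
    matrix: ExpressionMatrix, signature: GeneSignature
) -> SignatureScoreTable:
    """Score each sample as a weighted average of within-cohort z-scores.

    Within each cohort independently, every measured signature gene is
    standardized across that cohort's samples; zero-spread genes are
    dropped with a warning.  The score of sample j is

        sum_g w_g * z_gj / sum_g |w_g|

    over the retained genes, so scores stay comparable in magnitude
    across cohorts with different signature coverage.  Works for
    direction-only (+/-1) signatures and for real-weighted ones alike.
    """
    ann = matrix.sample_annotations
    weights = signature.weights
    measured = [g for g in signature.gene_ids if g in set(matrix.gene_ids)]
    if not measured:
        raise ValueError(
            f"no gene of signature {signature.name!r} is measured"
        )

    rows = []
    for cohort_id, samples in ann.groupby("cohort_id", sort=True).groups.items():
        samples = list(samples)
        if len(samples) < 2:
            raise ValueError(
                f"cohort {cohort_id!r} has a single sample; z-scores need >= 2"
            )
        sub = matrix.values.loc[measured, samples].to_numpy(dtype=float)
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        ok = sd[:, 0] > 0
        if not ok.all():
            dropped = [g for g, flag in zip(measured, ok) if not flag]
            logger.warning(
                "cohort %s: dropping %d zero-variance signature gene(s): %s",
                cohort_id,
                len(dropped),
                dropped[:5],
            )
        if not ok.any():
            raise ValueError(
                f"cohort {cohort_id!r}: all signature genes have zero variance"
            )
        z = (sub[ok] - mu[ok]) / sd[ok]
        w = np.array([weights[g] for g, flag in zip(measured, ok) if flag])
        scores = (w[:, None] * z).sum(axis=0) / np.abs(w).sum()
        for sample, score in zip(samples, scores):
            rows.append(
                {
                    "sample_id": sample,
                    "cohort_id": cohort_id,
                    "score": float(score),
                    "n_genes_used": int(ok.sum()),
                }
            )
    return SignatureScoreTable(pd.DataFrame(rows), signature_name=signature.name)


def dichotomize_by_median(scores: SignatureScoreTable) -> pd.DataFrame:
    """Label each sample high/low by its cohort's median score.

    ``high`` iff score > cohort median; scores equal to the median go to
    the low group (deterministic splits).  Labels are computed per cohort
    over all scored samples, before any survival subsetting.  A cohort
    with constant scores raises (degenerate split).
    """
    table = scores.table.copy()
    labels = np.empty(len(table), dtype=object)
    for cohort_id, idx in table.groupby("cohort_id", sort=True).groups.items():
        sub = table.loc[idx, "score"].to_numpy(dtype=float)
        if len(sub) < 2:
            raise ValueError(f"cohort {cohort_id!r} has fewer than 2 samples")
        if np.ptp(sub) == 0:
            raise ValueError(
                f"cohort {cohort_id!r}: all scores identical; median split "
                "is degenerate"
            )
        median = np.median(sub)
        labels[table.index.get_indexer(idx)] = np.where(
            sub > median, "high", "low"
        )
    table["label"] = labels
    return table
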