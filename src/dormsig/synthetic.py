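"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators, all deterministic given their integer seed:

* two mouse-model expression matrices (groups PT/RL/RT) with a planted set
  of genes concordantly shifted in residual lesions in both models, plus
  model-specific and discordant distractors;
* human patient cohorts whose expression carries a signature signal through
  a latent per-patient activity, and whose survival is exponential with the
  hazard attached to the *dichotomized* realized signature score — so the
  configured hazard ratio is the literal estimand of the downstream
  median-split Cox analysis;
* limiting-dilution assays with single-hit Poisson take probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from dormsig.data_model import CohortSurvival, ExpressionMatrix, GeneSignature
from dormsig.limiting_dilution import LDAssay
from dormsig.signature import dichotomize_by_median, score_samples


@dataclass
class MouseSimConfig:
    """Configuration for the two-model grouped expression simulation."""

    n_genes: int = 2000
    n_per_group: int = 4
    n_planted: int = 60
    planted_lfc: float = 1.2
    n_model_specific: int = 0
    n_discordant: int = 0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_per_group) < 1:
            raise ValueError("n_genes and n_per_group must be positive")
        if min(self.n_planted, self.n_model_specific, self.n_discordant) < 0:
            raise ValueError("gene counts must be nonnegative")
        if self.n_planted + self.n_model_specific + self.n_discordant > self.n_genes:
            raise ValueError("planted + distractor genes exceed n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class HumanSimConfig:
    """Configuration for the patient-cohort expression + survival simulation."""

    n_cohorts: int = 17
    n_patients: int = 260
    coupling: float = 1.0
    true_hr: float = 0.49
    baseline_rate: float = 0.01
    censor_rate: float = 0.005
    horizon_months: float = 180.0
    n_background_genes: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_hr <= 0:
            raise ValueError("true_hr must be positive")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be nonnegative")
        if self.n_cohorts < 1 or self.n_patients < 2:
            raise ValueError("need >= 1 cohort with >= 2 patients each")


@dataclass
class TruthSet:
    """Ground truth planted by a generator, for recovery experiments."""

    planted_genes: list[tuple[str, int]] = field(default_factory=list)
    true_hr: float | None = None
    true_frequency: float | None = None

    def __post_init__(self) -> None:
        if any(d not in (-1, 1) for _, d in self.planted_genes):
            raise ValueError("planted directions must be +1 or -1")

    @property
    def directions(self) -> dict[str, int]:
        return dict(self.planted_genes)

    def as_signature(self, name: str = "planted") -> GeneSignature:
        return GeneSignature(
            [(g, float(d)) for g, d in self.planted_genes],
            name=name,
            provenance="synthetic ground truth",
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "planted_genes": [[g, d] for g, d in self.planted_genes],
                    "true_hr": self.true_hr,
                    "true_frequency": self.true_frequency,
                },
                fh,
                indent=2,
            )

    @classmethod
    def read(cls, path: str | Path) -> "TruthSet":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            planted_genes=[(g, int(d)) for g, d in raw["planted_genes"]],
            true_hr=raw.get("true_hr"),
            true_frequency=raw.get("true_frequency"),
        )


GROUPS = ("PT", "RL", "RT")


def generate_mouse_models(
    config: MouseSimConfig,
) -> tuple[tuple[ExpressionMatrix, ExpressionMatrix], TruthSet]:
    """Simulate grouped expression for two tumor models.

    Gene roles (assigned to the first genes in order): ``n_planted`` genes
    shifted by +/-planted_lfc in RL only, same sign in both models;
    ``n_model_specific`` genes shifted in RL of one model only (alternating
    models); ``n_discordant`` genes shifted in RL of both models with
    opposite signs.  Baseline means are drawn once per model and shared
    across groups; iid Gaussian noise with sd ``noise_sd`` is added.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    width = max(5, len(str(config.n_genes)))
    genes = [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]

    n_p, n_ms, n_dc = (
        config.n_planted,
        config.n_model_specific,
        config.n_discordant,
    )
    dir_planted = rng.choice([-1, 1], size=n_p)
    dir_ms = rng.choice([-1, 1], size=n_ms)
    ms_model = np.arange(n_ms) % 2  # which model carries the shift
    dir_dc = rng.choice([-1, 1], size=n_dc)

    # per-model, per-gene RL shift on the log2 scale
    shifts = np.zeros((2, config.n_genes))
    shifts[:, :n_p] = dir_planted * config.planted_lfc
    for m in (0, 1):
        sel = np.arange(n_p, n_p + n_ms)[ms_model == m]
        shifts[m, sel] = dir_ms[ms_model == m] * config.planted_lfc
    shifts[0, n_p + n_ms : n_p + n_ms + n_dc] = dir_dc * config.planted_lfc
    shifts[1, n_p + n_ms : n_p + n_ms + n_dc] = -dir_dc * config.planted_lfc

    matrices = []
    for m, model_id in enumerate(("model1", "model2")):
        baseline = rng.uniform(4.0, 12.0, size=config.n_genes)
        cols, data, ann_rows = [], [], []
        for group in GROUPS:
            mean = baseline + (shifts[m] if group == "RL" else 0.0)
            noise = rng.normal(
                0.0, config.noise_sd, size=(config.n_genes, config.n_per_group)
            )
            data.append(mean[:, None] + noise)
            for i in range(config.n_per_group):
                sid = f"{model_id}_{group}_{i + 1}"
                cols.append(sid)
                ann_rows.append(
                    {
                        "sample_id": sid,
                        "model_id": model_id,
                        "group": group,
                        "cohort_id": "",
                    }
                )
        values = pd.DataFrame(
            np.concatenate(data, axis=1), index=genes, columns=cols
        )
        ann = pd.DataFrame(ann_rows).set_index("sample_id")
        matrices.append(ExpressionMatrix(values, ann))

    truth = TruthSet(
        planted_genes=[
            (genes[i], int(dir_planted[i])) for i in range(n_p)
        ]
    )
    return (matrices[0], matrices[1]), truth


def generate_human_cohorts(
    config: HumanSimConfig,
    signature: GeneSignature | None = None,
) -> tuple[list[tuple[ExpressionMatrix, CohortSurvival]], TruthSet]:
    """Simulate patient cohorts with signature-coupled expression and survival.

    Per patient, a latent activity a ~ N(0, 1) shifts each signature gene
    by weight * coupling * a on top of a per-cohort gene baseline, with
    unit Gaussian noise; background genes are pure noise.  The planted
    signature score (weighted within-cohort z-score average) is split at
    its realized cohort median, and survival is exponential with hazard
    baseline_rate * true_hr^[high], independently censored at rate
    censor_rate and administratively at horizon_months.

    If no signature is given, a default +/-1 signature of 60 genes named
    ``SG...`` is created and reported in the TruthSet.
    """
    if signature is None:
        genes = [f"SG{i + 1:04d}" for i in range(60)]
        rng0 = np.random.default_rng(np.random.SeedSequence((config.seed, 971)))
        dirs = rng0.choice([-1.0, 1.0], size=60)
        signature = GeneSignature(
            list(zip(genes, dirs)), name="planted", provenance="synthetic"
        )
    sig_genes = signature.gene_ids
    weights = np.array([w for _, w in signature.entries])
    bg_genes = [f"BG{i + 1:04d}" for i in range(config.n_background_genes)]

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_cohorts)
    cohorts: list[tuple[ExpressionMatrix, CohortSurvival]] = []
    for c, subseed in enumerate(seeds):
        rng = np.random.default_rng(subseed)
        cohort_id = f"cohort{c + 1:02d}"
        n = config.n_patients
        patients = [f"{cohort_id}_P{j + 1:04d}" for j in range(n)]

        a = rng.normal(size=n)
        baseline_sig = rng.normal(8.0, 1.0, size=len(sig_genes))
        expr_sig = (
            baseline_sig[:, None]
            + config.coupling * weights[:, None] * a[None, :]
            + rng.normal(size=(len(sig_genes), n))
        )
        baseline_bg = rng.normal(8.0, 1.0, size=len(bg_genes))
        expr_bg = baseline_bg[:, None] + rng.normal(size=(len(bg_genes), n))

        values = pd.DataFrame(
            np.concatenate([expr_sig, expr_bg], axis=0),
            index=sig_genes + bg_genes,
            columns=patients,
        )
        ann = pd.DataFrame(
            {
                "model_id": "",
                "group": "",
                "cohort_id": cohort_id,
            },
            index=pd.Index(patients, name="sample_id"),
        )
        matrix = ExpressionMatrix(values, ann)

        labeled = dichotomize_by_median(score_samples(matrix, signature))
        high = (labeled["label"] == "high").to_numpy()

        rate = config.baseline_rate * np.where(high, config.true_hr, 1.0)
        t_event = rng.exponential(1.0 / rate)
        if config.censor_rate > 0:
            t_cens = rng.exponential(1.0 / config.censor_rate, size=n)
        else:
            t_cens = np.full(n, np.inf)
        t_cens = np.minimum(t_cens, config.horizon_months)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)

        survival = CohortSurvival(
            patient_ids=np.array(patients, dtype=object),
            time_months=time,
            event=event,
            endpoint="RFS",
            cohort_id=cohort_id,
        )
        cohorts.append((matrix, survival))

    truth = TruthSet(
        planted_genes=[(g, int(w)) for g, w in signature.entries],
        true_hr=config.true_hr,
    )
    return cohorts, truth


def generate_ld_assay(
    true_frequency: float,
    doses: Sequence[int],
    n_per_dose: int,
    seed: int,
    group_label: str = "simulated",
) -> LDAssay:
    """Simulate a limiting-dilution assay under the single-hit Poisson model.

    The number of positive injections at dose d is Binomial with take
    probability 1 - exp(-f * d).
    """
    if not 0 < true_frequency <= 1:
        raise ValueError("true_frequency must lie in (0, 1]")
    doses = np.asarray(doses, dtype=int)
    if (doses <= 0).any():
        raise ValueError("doses must be positive integers")
    if n_per_dose < 1:
        raise ValueError("n_per_dose must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    p_take = 1.0 - np.exp(-true_frequency * doses.astype(float))
    takes = rng.binomial(n_per_dose, p_take)
    return LDAssay(
        group_label=group_label,
        dose=doses,
        n_injected=np.full(len(doses), n_per_dose),
        n_tumors=takes,
    )
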