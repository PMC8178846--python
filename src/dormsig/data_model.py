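"""Shared domain types and tab-delimited / GMT readers and writers.

Conventions
-----------
* Expression matrices are genes x samples, log2 scale, tab-delimited with a
  header row of sample ids and gene ids in the first column.
* Sample annotations are tab-delimited, keyed by ``sample_id``, with columns
  ``model_id``, ``group`` (one of PT/RL/RT/RS) and ``cohort_id``.
* Clinical tables are tab-delimited with columns ``patient_id``,
  ``time_months``, ``event``, ``endpoint``.
* Signed gene lists use a GMT dialect in which a token ``GENE`` carries
  weight +1 and ``GENE:w`` carries real weight ``w``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_GROUPS = frozenset({"PT", "RL", "RT", "RS"})
VALID_ENDPOINTS = ("RFS", "DMFS", "DSS")


@dataclass
class ExpressionMatrix:
    """Log2 gene x sample expression values with per-sample annotations.

    Parameters
    ----------
    values
        DataFrame of shape (n_genes, n_samples); index = gene ids,
        columns = sample ids, all entries finite.
    sample_annotations
        DataFrame indexed by sample id with columns ``model_id``,
        ``group`` and ``cohort_id`` (any may be empty strings, but every
        sample must carry a group or a cohort).
    """

    values: pd.DataFrame
    sample_annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups)[:5]}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                "non-finite expression value at gene "
                f"{self.values.index[bad[0]]!r}, sample "
                f"{self.values.columns[bad[1]]!r}"
            )
        missing = set(self.values.columns) - set(self.sample_annotations.index)
        if missing:
            raise ValueError(f"samples without annotation: {sorted(missing)}")
        ann = self.sample_annotations.loc[list(self.values.columns)]
        for col in ("model_id", "group", "cohort_id"):
            if col not in ann.columns:
                raise ValueError(f"annotation table missing column {col!r}")
        bad_group = set(ann["group"].unique()) - VALID_GROUPS - {""}
        if bad_group:
            raise ValueError(f"invalid group labels: {sorted(bad_group)}")
        unlabeled = ann[(ann["group"] == "") & (ann["cohort_id"] == "")]
        if len(unlabeled):
            raise ValueError(
                "samples carry neither group nor cohort annotation: "
                f"{list(unlabeled.index)[:5]}"
            )
        self.sample_annotations = ann

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def samples_in_group(self, group: str, model_id: str | None = None) -> list[str]:
        """Sample ids with the given group (optionally restricted to a model)."""
        ann = self.sample_annotations
        mask = ann["group"] == group
        if model_id is not None:
            mask &= ann["model_id"] == model_id
        return list(ann.index[mask])

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(sample_ids)].copy(),
            self.sample_annotations.loc[list(sample_ids)].copy(),
        )

    def write(self, path: str | Path, annotation_path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")
        ann = self.sample_annotations.copy()
        ann.index.name = "sample_id"
        ann.to_csv(annotation_path, sep="\t")


@dataclass
class CohortSurvival:
    """Per-patient follow-up for one cohort with a single endpoint type."""

    patient_ids: np.ndarray
    time_months: np.ndarray
    event: np.ndarray
    endpoint: str
    cohort_id: str

    def __post_init__(self) -> None:
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        self.time_months = np.asarray(self.time_months, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise ValueError("duplicate patient ids")
        if not (
            len(self.patient_ids) == len(self.time_months) == len(self.event)
        ):
            raise ValueError("field lengths differ")
        if (self.time_months < 0).any():
            raise ValueError("negative follow-up time")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")
        if self.endpoint not in VALID_ENDPOINTS:
            raise ValueError(
                f"endpoint must be one of {VALID_ENDPOINTS}, got {self.endpoint!r}"
            )

    def __len__(self) -> int:
        return len(self.patient_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_ids,
                "time_months": self.time_months,
                "event": self.event,
                "endpoint": self.endpoint,
                "cohort_id": self.cohort_id,
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class GeneSignature:
    """Signed gene list: unique gene ids with nonzero real weights."""

    entries: list[tuple[str, float]]
    name: str = "signature"
    provenance: str = ""

    def __post_init__(self) -> None:
        genes = [g for g, _ in self.entries]
        if len(set(genes)) != len(genes):
            raise ValueError(f"signature {self.name!r} has duplicate gene ids")
        if any(w == 0 for _, w in self.entries):
            raise ValueError(f"signature {self.name!r} has zero weights")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.entries]

    @property
    def weights(self) -> dict[str, float]:
        return dict(self.entries)

    def restrict(self, genes: Iterable[str]) -> "GeneSignature":
        keep = set(genes)
        return GeneSignature(
            [(g, w) for g, w in self.entries if g in keep],
            name=self.name,
            provenance=self.provenance,
        )


def read_expression(
    path: str | Path, annotation_path: str | Path
) -> ExpressionMatrix:
    """Load a tab-delimited expression matrix plus its sample annotations.

    Duplicate gene ids are collapsed by arithmetic mean on the log2 scale
    (with a logged warning).  Samples lacking an annotation row are
    rejected; non-numeric cells raise naming the gene and sample.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    values = pd.DataFrame(index=raw.index.astype(str), columns=raw.columns)
    for col in raw.columns:
        try:
            values[col] = pd.to_numeric(raw[col], errors="raise")
        except (ValueError, TypeError):
            bad = raw[pd.to_numeric(raw[col], errors="coerce").isna()].index[0]
            raise ValueError(
                f"non-numeric expression value for gene {bad!r}, sample {col!r}"
            ) from None
    if values.index.duplicated().any():
        dup = sorted(values.index[values.index.duplicated()].unique())
        logger.warning(
            "collapsing %d duplicate gene id(s) by mean: %s",
            len(dup),
            dup[:5],
        )
        # groupby(sort=True) makes collapsing independent of row order
        values = values.groupby(level=0, sort=True).mean()

    ann = pd.read_csv(
        annotation_path, sep="\t", index_col=0, dtype=str
    ).fillna("")
    for col in ("model_id", "group", "cohort_id"):
        if col not in ann.columns:
            ann[col] = ""
    orphans = sorted(set(values.columns) - set(ann.index))
    if orphans:
        raise ValueError(f"samples missing from annotations: {orphans}")
    return ExpressionMatrix(values.astype(float), ann)


def read_clinical(path: str | Path) -> list[CohortSurvival]:
    """Load one or more cohorts from a tab-delimited clinical table.

    The table must carry patient_id, time_months, event, endpoint columns;
    an optional cohort_id column splits rows into cohorts (default: one
    cohort named after the file stem).  Each cohort must use one endpoint.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"patient_id", "time_months", "event", "endpoint"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    if "cohort_id" not in df.columns:
        df["cohort_id"] = Path(path).stem
    cohorts = []
    for cid, sub in df.groupby("cohort_id", sort=True):
        endpoints = sub["endpoint"].unique()
        if len(endpoints) != 1:
            raise ValueError(
                f"cohort {cid!r} mixes endpoints: {sorted(endpoints)}"
            )
        cohorts.append(
            CohortSurvival(
                patient_ids=sub["patient_id"].to_numpy(dtype=object),
                time_months=sub["time_months"].to_numpy(dtype=float),
                event=sub["event"].to_numpy(dtype=int),
                endpoint=str(endpoints[0]),
                cohort_id=str(cid),
            )
        )
    return cohorts


def read_signature_gmt(path: str | Path) -> list[GeneSignature]:
    """Parse a weighted-dialect GMT file into GeneSignature objects.

    Each line: name, description, then gene tokens.  ``GENE`` means weight
    +1; ``GENE:w`` carries real weight w.  Empty gene lists and
    non-numeric weight suffixes raise.
    """
    signatures = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: signature {parts[0]!r} has no genes"
                )
            name, desc, *tokens = parts
            entries: list[tuple[str, float]] = []
            for tok in tokens:
                if not tok:
                    continue
                gene, sep, wtxt = tok.rpartition(":")
                if sep:
                    try:
                        weight = float(wtxt)
                    except ValueError:
                        raise ValueError(
                            f"{path}:{lineno}: bad weight in token {tok!r}"
                        ) from None
                else:
                    gene, weight = tok, 1.0
                entries.append((gene, weight))
            if not entries:
                raise ValueError(
                    f"{path}:{lineno}: signature {name!r} has no genes"
                )
            signatures.append(
                GeneSignature(entries, name=name, provenance=desc)
            )
    return signatures


def write_signature_gmt(
    signatures: Iterable[GeneSignature], path: str | Path
) -> None:
    """Write signatures in the weighted GMT dialect read_signature_gmt parses."""
    with open(path, "w") as fh:
        for sig in signatures:
            tokens = [
                gene if w == 1.0 else f"{gene}:{w:g}"
                for gene, w in sig.entries
            ]
            fh.write("\t".join([sig.name, sig.provenance, *tokens]) + "\n")


def harmonize(
    cohorts: dict[str, ExpressionMatrix] | list[ExpressionMatrix],
    signature: GeneSignature,
) -> dict[str, tuple[GeneSignature, float]]:
    """Restrict a signature to the genes each cohort actually measures.

    Returns ``{cohort_key: (restricted_signature, coverage_fraction)}``.
    A cohort measuring none of the signature genes raises.
    """
    if isinstance(cohorts, list):
        cohorts = {
            mat.sample_annotations["cohort_id"].iloc[0] or str(i): mat
            for i, mat in enumerate(cohorts)
        }
    out: dict[str, tuple[GeneSignature, float]] = {}
    for key, mat in cohorts.items():
        restricted = signature.restrict(mat.gene_ids)
        if len(restricted) == 0:
            raise ValueError(
                f"cohort {key!r} measures no gene of signature "
                f"{signature.name!r}"
            )
        out[key] = (restricted, len(restricted) / len(signature))
    return out
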