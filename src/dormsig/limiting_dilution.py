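"""Single-hit Poisson limiting-dilution frequency estimation.

Under the single-hit model the probability that an injection of d cells
seeds a tumor is 1 - exp(-f * d), where f is the tumor-initiating-cell
frequency.  The log-likelihood over dose rows (dose d, n injected, r
tumors) is

    l(f) = sum_d [ r_d * log(1 - exp(-f d)) - (n_d - r_d) * f * d ]

maximized by 1-D optimization on log f, with 95% confidence intervals
from the profile likelihood (drop of chi2_{1,0.95}/2 = 1.92).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

_LOGF_LO = -30.0  # f = e^-30 ~ 1e-13, far below any practical assay
_LOGF_HI = 0.0  # f <= 1 by definition
_CHI2_DROP = stats.chi2.ppf(0.95, df=1) / 2.0  # 1.9207...


@dataclass
class LDAssay:
    """Limiting-dilution outcomes for one group."""

    group_label: str
    dose: np.ndarray
    n_injected: np.ndarray
    n_tumors: np.ndarray

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.n_injected = np.asarray(self.n_injected, dtype=int)
        self.n_tumors = np.asarray(self.n_tumors, dtype=int)
        if not (len(self.dose) == len(self.n_injected) == len(self.n_tumors)):
            raise ValueError("row lengths differ")
        if (self.dose <= 0).any():
            raise ValueError("doses must be positive")
        if (self.n_injected <= 0).any():
            raise ValueError("n_injected must be positive")
        if ((self.n_tumors < 0) | (self.n_tumors > self.n_injected)).any():
            raise ValueError("n_tumors must lie in [0, n_injected]")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, group_label: str) -> "LDAssay":
        return cls(
            group_label=group_label,
            dose=df["dose"].to_numpy(),
            n_injected=df["n_injected"].to_numpy(),
            n_tumors=df["n_tumors"].to_numpy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group_label,
                "dose": self.dose.astype(int),
                "n_injected": self.n_injected,
                "n_tumors": self.n_tumors,
            }
        )

    def pooled_with(self, other: "LDAssay") -> "LDAssay":
        return LDAssay(
            group_label=f"{self.group_label}+{other.group_label}",
            dose=np.concatenate([self.dose, other.dose]),
            n_injected=np.concatenate([self.n_injected, other.n_injected]),
            n_tumors=np.concatenate([self.n_tumors, other.n_tumors]),
        )


@dataclass
class LDFit:
    """Maximum-likelihood frequency with profile-likelihood 95% CI."""

    frequency: float
    ci95: tuple[float, float]
    loglik: float
    n_doses: int

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not lo <= self.frequency <= hi:
            raise ValueError("CI must bracket the estimate")
        if not np.isfinite(self.loglik):
            raise ValueError("log-likelihood must be finite")

    @property
    def one_in(self) -> float:
        return 1.0 / self.frequency


def log_likelihood(f: float | np.ndarray, assay: LDAssay) -> float | np.ndarray:
    """Single-hit Poisson log-likelihood l(f) for an assay (utility/oracle)."""
    f = np.asarray(f, dtype=float)
    d, n, r = assay.dose, assay.n_injected, assay.n_tumors
    fd = np.multiply.outer(f, d)
    with np.errstate(divide="ignore"):
        log_p = np.log(-np.expm1(-fd))
    ll = (r * log_p - (n - r) * fd).sum(axis=-1)
    return float(ll) if ll.ndim == 0 else ll


def _check_fittable(assay: LDAssay) -> None:
    if assay.n_tumors.sum() == 0:
        raise ValueError(
            f"assay {assay.group_label!r}: all injections negative; "
            "frequency not identifiable; report upper bound"
        )
    if (assay.n_tumors == assay.n_injected).all():
        raise ValueError(
            f"assay {assay.group_label!r}: all injections positive; "
            "frequency not identifiable; report lower bound"
        )


def _mle_logf(assay: LDAssay) -> tuple[float, float]:
    """Maximize l over log f; returns (logf_hat, loglik_max)."""
    res = optimize.minimize_scalar(
        lambda lf: -log_likelihood(np.exp(lf), assay),
        bounds=(_LOGF_LO, _LOGF_HI),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x), float(-res.fun)


def fit_frequency(assay: LDAssay) -> LDFit:
    """Maximum-likelihood single-hit frequency with profile-likelihood CI.

    Raises for all-negative or all-positive assays (frequency only
    bounded, not identifiable).
    """
    _check_fittable(assay)
    logf_hat, ll_max = _mle_logf(assay)
    target = ll_max - _CHI2_DROP

    def drop(lf: float) -> float:
        return log_likelihood(np.exp(lf), assay) - target

    if drop(_LOGF_LO) < 0:
        lo = float(np.exp(optimize.brentq(drop, _LOGF_LO, logf_hat, xtol=1e-14)))
    else:
        lo = float(np.exp(_LOGF_LO))
    if logf_hat < _LOGF_HI and drop(_LOGF_HI) < 0:
        hi = float(np.exp(optimize.brentq(drop, logf_hat, _LOGF_HI, xtol=1e-14)))
    else:
        hi = 1.0
    f_hat = float(np.exp(logf_hat))
    return LDFit(
        frequency=f_hat,
        ci95=(min(lo, f_hat), max(hi, f_hat)),
        loglik=ll_max,
        n_doses=len(np.unique(assay.dose)),
    )


def compare_frequencies(a: LDAssay, b: LDAssay) -> tuple[float, float]:
    """Likelihood-ratio comparison of two groups' frequencies.

    Fits each assay separately and the pooled data under a shared f; the
    statistic 2 * (l_a + l_b - l_shared) is referred to chi-squared with
    1 df.  Returns (frequency ratio f_a / f_b, LRT p-value).
    """
    fit_a = fit_frequency(a)
    fit_b = fit_frequency(b)
    _, ll_shared = _mle_logf(a.pooled_with(b))
    lrt = max(0.0, 2.0 * (fit_a.loglik + fit_b.loglik - ll_shared))
    p = float(stats.chi2.sf(lrt, df=1))
    return fit_a.frequency / fit_b.frequency, p


def read_ld_assays(path) -> dict[str, LDAssay]:
    """Read assays from a tab-delimited table: group, dose, n_injected, n_tumors."""
    df = pd.read_csv(path, sep="\t")
    required = {"group", "dose", "n_injected", "n_tumors"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assay table missing columns: {sorted(missing)}")
    return {
        str(g): LDAssay.from_frame(sub, str(g))
        for g, sub in df.groupby("group", sort=True)
    }


def fit_table(fits: dict[str, LDFit]) -> pd.DataFrame:
    """Tabulate fits: group, frequency, one_in, CI bounds, loglik."""
    rows = []
    for label, fit in fits.items():
        rows.append(
            {
                "group": label,
                "frequency": fit.frequency,
                "one_in": round(fit.one_in),
                "ci_lo": fit.ci95[0],
                "ci_hi": fit.ci95[1],
                "loglik": fit.loglik,
                "n_doses": fit.n_doses,
            }
        )
    return pd.DataFrame(rows)
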