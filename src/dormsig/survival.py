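"""Dichotomized Cox proportional-hazards fits and inverse-variance meta-analysis.

Per-cohort fits maximize the Cox partial likelihood (Efron correction for
tied event times) by Newton iteration, with standard errors from the
inverse observed information.  Cohort effects are combined by
inverse-variance weighting; between-study heterogeneity is tested with a
chi-squared test on Cochran's Q, and when significant (p < het_alpha) the
DerSimonian-Laird random-effects model replaces the fixed-effects model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from dormsig.data_model import VALID_ENDPOINTS, CohortSurvival

logger = logging.getLogger(__name__)

#: Endpoint preference order: relapse-free first, then distant-metastasis-free,
#: then disease-specific survival.
ENDPOINT_PRIORITY = ("RFS", "DMFS", "DSS")


@dataclass
class CoxFit:
    """Result of one cohort's Cox fit for the high-vs-low score contrast."""

    cohort_id: str
    log_hr: float
    se: float
    n: int
    n_events: int
    covariates: tuple[str, ...] = ()
    extra_coefs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.se <= 0 or not np.isfinite(self.se):
            raise ValueError(f"cohort {self.cohort_id!r}: se must be positive")
        if self.n_events < 1:
            raise ValueError(f"cohort {self.cohort_id!r}: no events")

    @property
    def hr(self) -> float:
        return float(np.exp(self.log_hr))

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            float(np.exp(self.log_hr - 1.96 * self.se)),
            float(np.exp(self.log_hr + 1.96 * self.se)),
        )


@dataclass
class MetaResult:
    """Combined effect with heterogeneity diagnostics and model choice."""

    fits: list[CoxFit]
    Q: float
    q_pvalue: float
    tau2: float
    model: str
    combined_log_hr: float
    combined_se: float

    def __post_init__(self) -> None:
        if self.model not in ("fixed", "random"):
            raise ValueError("model must be 'fixed' or 'random'")
        if self.model == "fixed" and self.tau2 != 0.0:
            raise ValueError("tau2 must be 0 under the fixed-effects model")
        if self.combined_se <= 0:
            raise ValueError("combined se must be positive")

    @property
    def combined_hr(self) -> float:
        return float(np.exp(self.combined_log_hr))

    @property
    def ci95(self) -> tuple[float, float]:
        return (
            float(np.exp(self.combined_log_hr - 1.96 * self.combined_se)),
            float(np.exp(self.combined_log_hr + 1.96 * self.combined_se)),
        )

    @property
    def p(self) -> float:
        z = self.combined_log_hr / self.combined_se
        return float(2.0 * stats.norm.sf(abs(z)))

    def to_dict(self) -> dict:
        return {
            "Q": self.Q,
            "q_pvalue": self.q_pvalue,
            "tau2": self.tau2,
            "model": self.model,
            "combined_hr": self.combined_hr,
            "combined_log_hr": self.combined_log_hr,
            "combined_se": self.combined_se,
            "ci95": list(self.ci95),
            "p": self.p,
            "n_cohorts": len(self.fits),
            "n_patients": int(sum(f.n for f in self.fits)),
            "n_events": int(sum(f.n_events for f in self.fits)),
        }


def select_endpoint(available: set[str] | list[str]) -> str:
    """Pick the analysis endpoint: RFS, else DMFS, else DSS."""
    available = set(available)
    if not available:
        raise ValueError("no endpoint available")
    unknown = available - set(VALID_ENDPOINTS)
    if unknown:
        raise ValueError(f"unknown endpoints: {sorted(unknown)}")
    for ep in ENDPOINT_PRIORITY:
        if ep in available:
            return ep
    raise AssertionError("unreachable")


def truncate_5y(cohort: CohortSurvival, horizon: float = 60.0) -> CohortSurvival:
    """Administratively censor follow-up at `horizon` months.

    Patients with time > horizon become (horizon, censored); an event at
    exactly the horizon is retained.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    beyond = cohort.time_months > horizon
    return CohortSurvival(
        patient_ids=cohort.patient_ids.copy(),
        time_months=np.where(beyond, horizon, cohort.time_months),
        event=np.where(beyond, 0, cohort.event),
        endpoint=cohort.endpoint,
        cohort_id=cohort.cohort_id,
    )


def landmark_late(
    cohort: CohortSurvival, landmark: float = 60.0
) -> CohortSurvival:
    """Restrict to patients event-free past `landmark` months; reset origin.

    Only patients with time > landmark are kept (an event or censoring at
    exactly the landmark is excluded: it contributes nothing beyond it);
    retained times are shifted to time - landmark with events unchanged.
    Raises if fewer than 2 patients or no events remain.
    """
    if landmark <= 0:
        raise ValueError("landmark must be positive")
    keep = cohort.time_months > landmark
    if keep.sum() < 2 or cohort.event[keep].sum() < 1:
        raise ValueError(
            f"cohort {cohort.cohort_id!r} not analyzable beyond the "
            f"{landmark}-month landmark (kept {int(keep.sum())} patients, "
            f"{int(cohort.event[keep].sum())} events)"
        )
    return CohortSurvival(
        patient_ids=cohort.patient_ids[keep].copy(),
        time_months=cohort.time_months[keep] - landmark,
        event=cohort.event[keep].copy(),
        endpoint=cohort.endpoint,
        cohort_id=cohort.cohort_id,
    )


def _efron_loglik_grad_info(
    beta: np.ndarray,
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Partial log-likelihood, gradient and observed information (Efron ties).

    Inputs must be pre-sorted by ascending time.  Vectorized over tie
    groups: each event occupies a "slot" l = 0..d-1 within its tie group
    and contributes log(S0_risk - (l/d) * S0_tied) to the denominator.
    """
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]

    # suffix sums over ascending time = risk-set sums at each index
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ut, first = np.unique(time, return_index=True)
    S0 = s0[first]
    S1 = s1[first]
    S2 = s2[first]

    ev = event.astype(bool)
    key = np.searchsorted(ut, time[ev])
    m = len(ut)
    d = np.bincount(key, minlength=m).astype(float)
    D0 = np.bincount(key, weights=w[ev], minlength=m)
    D1 = np.column_stack(
        [np.bincount(key, weights=wx[ev, j], minlength=m) for j in range(p)]
    )
    D2 = np.stack(
        [
            np.column_stack(
                [
                    np.bincount(key, weights=wxx[ev, j, k], minlength=m)
                    for k in range(p)
                ]
            )
            for j in range(p)
        ],
        axis=1,
    )

    starts = np.concatenate(([0], np.cumsum(np.bincount(key, minlength=m))))
    slot = np.arange(ev.sum()) - starts[key]
    frac = slot / d[key]

    phi = S0[key] - frac * D0[key]
    Phi1 = S1[key] - frac[:, None] * D1[key]
    Phi2 = S2[key] - frac[:, None, None] * D2[key]

    loglik = float(eta[ev].sum() - np.log(phi).sum())
    r = Phi1 / phi[:, None]
    grad = X[ev].sum(axis=0) - r.sum(axis=0)
    info = (Phi2 / phi[:, None, None]).sum(axis=0) - np.einsum(
        "ei,ej->ij", r, r
    )
    return loglik, grad, info


def cox_partial_loglik(
    beta: np.ndarray | float,
    time: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
) -> float:
    """Efron partial log-likelihood at `beta` (utility for oracles/profiling)."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    order = np.argsort(time, kind="stable")
    ll, _, _ = _efron_loglik_grad_info(
        beta, X[order], np.asarray(time, float)[order],
        np.asarray(event, int)[order],
    )
    return ll


class CoxConvergenceError(RuntimeError):
    """Raised when the Newton iteration fails (e.g. monotone likelihood)."""


def _newton_cox(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Newton maximization with step-halving; returns (beta, cov, loglik)."""
    order = np.argsort(time, kind="stable")
    X, time, event = X[order], time[order], event[order]
    beta = np.zeros(X.shape[1])
    ll, grad, info = _efron_loglik_grad_info(beta, X, time, event)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise CoxConvergenceError(
                "singular information matrix (monotone likelihood?)"
            ) from exc
        # step halving keeps the iteration monotone in the log-likelihood
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, grad_new, info_new = _efron_loglik_grad_info(
                cand, X, time, event
            )
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        else:
            raise CoxConvergenceError("step halving failed to improve")
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if np.abs(beta).max() > 15:
            raise CoxConvergenceError(
                "coefficient diverging (monotone likelihood)"
            )
        if np.abs(grad).max() < tol:
            break
    else:
        if np.abs(grad).max() > 1e-4:
            raise CoxConvergenceError("Newton iteration did not converge")
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise CoxConvergenceError("information matrix not invertible") from exc
    if (np.diag(cov) <= 0).any():
        raise CoxConvergenceError("non-positive variance estimate")
    return beta, cov, ll


def cox_binary(
    cohort: CohortSurvival,
    labels: pd.Series | dict | np.ndarray,
    adjustment: pd.Series | dict | np.ndarray | None = None,
) -> CoxFit:
    """Cox fit of the high-vs-low label, optionally adjusted for a covariate.

    Parameters
    ----------
    cohort
        Survival data for one cohort.
    labels
        'high'/'low' per patient: a mapping/Series keyed by patient id, or
        an array aligned with ``cohort.patient_ids``.
    adjustment
        Optional real covariate (e.g. proliferation score), same keying.

    Returns a CoxFit whose log_hr is the high-vs-low coefficient with se
    from the inverse observed information (Efron ties, Newton iteration).
    """
    lab = _aligned(labels, cohort, "labels")
    x1 = np.where(np.asarray(lab, dtype=object) == "high", 1.0, 0.0)
    if x1.min() == x1.max():
        raise ValueError(
            f"cohort {cohort.cohort_id!r}: both label groups must be present"
        )
    if cohort.n_events < 1:
        raise ValueError(f"cohort {cohort.cohort_id!r}: no events")
    cols = [x1]
    covariates: tuple[str, ...] = ()
    if adjustment is not None:
        adj = np.asarray(_aligned(adjustment, cohort, "adjustment"), float)
        if not np.isfinite(adj).all():
            raise ValueError("non-finite adjustment covariate")
        cols.append(adj)
        covariates = ("adjustment",)
    X = np.column_stack(cols)
    try:
        beta, cov, _ = _newton_cox(X, cohort.time_months, cohort.event)
    except CoxConvergenceError as exc:
        raise CoxConvergenceError(
            f"cohort {cohort.cohort_id!r}: {exc}"
        ) from exc
    extra = (
        {"adjustment": (float(beta[1]), float(np.sqrt(cov[1, 1])))}
        if adjustment is not None
        else {}
    )
    return CoxFit(
        cohort_id=cohort.cohort_id,
        log_hr=float(beta[0]),
        se=float(np.sqrt(cov[0, 0])),
        n=len(cohort),
        n_events=cohort.n_events,
        covariates=covariates,
        extra_coefs=extra,
    )


def _aligned(values, cohort: CohortSurvival, what: str) -> np.ndarray:
    if isinstance(values, dict):
        values = pd.Series(values)
    if isinstance(values, pd.Series):
        missing = [p for p in cohort.patient_ids if p not in values.index]
        if missing:
            raise ValueError(f"{what} missing for patients: {missing[:5]}")
        return values.loc[list(cohort.patient_ids)].to_numpy()
    arr = np.asarray(values)
    if len(arr) != len(cohort):
        raise ValueError(f"{what} length {len(arr)} != cohort size {len(cohort)}")
    return arr


def meta_analyze(fits: list[CoxFit], het_alpha: float = 0.05) -> MetaResult:
    """Inverse-variance meta-analysis with heterogeneity-driven model choice.

    Fixed-effects weights w_i = 1/se_i^2 give the pooled estimate and
    Cochran's Q; if the chi-squared test on Q (k-1 df) is significant at
    `het_alpha`, the DerSimonian-Laird tau^2 re-weights the studies
    (random-effects model), otherwise the fixed-effects result stands.
    """
    if len(fits) < 2:
        raise ValueError("meta-analysis needs at least 2 cohort fits")
    theta = np.array([f.log_hr for f in fits])
    se = np.array([f.se for f in fits])
    if (se <= 0).any():
        raise ValueError("all standard errors must be positive")
    w = 1.0 / se**2
    theta_fixed = float((w * theta).sum() / w.sum())
    Q = float((w * (theta - theta_fixed) ** 2).sum())
    k = len(fits)
    q_pvalue = float(stats.chi2.sf(Q, df=k - 1))

    if q_pvalue < het_alpha:
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (Q - (k - 1)) / denom)
        w_star = 1.0 / (se**2 + tau2)
        combined = float((w_star * theta).sum() / w_star.sum())
        combined_se = float(1.0 / np.sqrt(w_star.sum()))
        model = "random"
    else:
        tau2 = 0.0
        combined = theta_fixed
        combined_se = float(1.0 / np.sqrt(w.sum()))
        model = "fixed"

    return MetaResult(
        fits=list(fits),
        Q=Q,
        q_pvalue=q_pvalue,
        tau2=tau2,
        model=model,
        combined_log_hr=combined,
        combined_se=combined_se,
    )


def forest_table(meta: MetaResult) -> pd.DataFrame:
    """Per-cohort forest-plot table with inverse-variance weight percentages."""
    se = np.array([f.se for f in meta.fits])
    w = 1.0 / (se**2 + meta.tau2)
    w_pct = 100.0 * w / w.sum()
    rows = []
    for f, pct in zip(meta.fits, w_pct):
        lo, hi = f.ci95
        rows.append(
            {
                "cohort_id": f.cohort_id,
                "n": f.n,
                "n_events": f.n_events,
                "hr": f.hr,
                "ci_lo": lo,
                "ci_hi": hi,
                "weight_pct": float(pct),
            }
        )
    return pd.DataFrame(rows)
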