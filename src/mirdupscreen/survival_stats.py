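"""First-principles survival machinery.

Implements the statistics the screen rests on, from scratch:

* Kaplan-Meier product-limit estimator under right censoring;
* median dichotomization of a continuous expression value (ties -> low);
* the two-group log-rank test;
* Cox proportional-hazards regression maximizing the partial likelihood by
  Newton-Raphson with the Efron correction for tied event times;
* Spearman rank correlation with mid-rank tie handling.

Only scipy's distribution functions (chi2, normal, t) are used, for p-values
and confidence limits; every statistic is computed here. Established
survival packages serve as independent cross-checks in the test suite, never
as the implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ClinicalTable

MAX_NEWTON_ITER = 50
SCORE_TOL = 1e-8


# ---------------------------------------------------------------------------
# median dichotomization
# ---------------------------------------------------------------------------


def median_split(values: Sequence[float]) -> np.ndarray:
    """Label each value 'low' or 'high' relative to the sample median.

    Values strictly below the median are low, strictly above are high, and
    values equal to the median are assigned to the low group so the split is
    deterministic. An all-constant vector has no defined split.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("median split needs at least 2 values")
    if np.ptp(v) == 0:
        raise ValueError("all values identical; median split undefined")
    med = np.median(v)
    return np.where(v <= med, "low", "high")


def truncate_follow_up(
    times: Sequence[float], events: Sequence[int], horizon: float
) -> tuple[np.ndarray, np.ndarray]:
    """Administratively censor follow-up at ``horizon`` months.

    Observations beyond the horizon are recoded as censored at the horizon
    (e.g. 60 months for a 5-year analysis).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    over = t > horizon
    t = np.where(over, horizon, t)
    e = np.where(over, 0, e)
    return t, e


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    S(t) = prod over event times t_i <= t of (1 - d_i / n_i) where d_i is
    the number of events and n_i the number at risk at t_i. Censored-only
    data gives S == 1.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival data")
    if (t <= 0).any():
        raise ValueError("survival times must be > 0")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    td = t[e == 1]
    uniq, starts = np.unique(td, return_index=True)
    d = np.diff(np.append(starts, td.size))
    at_risk = t.size - np.searchsorted(t, uniq, side="left")
    surv = np.cumprod(1.0 - d / at_risk) if uniq.size else np.array([])
    return KMCurve(uniq, at_risk.astype(int), d.astype(int), surv)


# ---------------------------------------------------------------------------
# log-rank test
# ---------------------------------------------------------------------------


def logrank_test(
    group_a: tuple[Sequence[float], Sequence[int]],
    group_b: tuple[Sequence[float], Sequence[int]],
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p) with 1 df.

    chi2 = (sum(O_A - E_A))^2 / sum(V) over the pooled distinct event times,
    with the hypergeometric variance at each time. Zero total events (or a
    degenerate variance) is reported as chi2 = 0, p = 1.
    """
    ta = np.asarray(group_a[0], dtype=float)
    ea = np.asarray(group_a[1], dtype=int)
    tb = np.asarray(group_b[0], dtype=float)
    eb = np.asarray(group_b[1], dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    uniq = np.unique(t[e == 1])
    if uniq.size == 0:
        return 0.0, 1.0
    ta_s = np.sort(ta)
    t_s = np.sort(t)
    tda = np.sort(ta[ea == 1])
    td = np.sort(t[e == 1])
    n = t.size - np.searchsorted(t_s, uniq, side="left")
    n1 = ta.size - np.searchsorted(ta_s, uniq, side="left")
    d = np.searchsorted(td, uniq, side="right") - np.searchsorted(td, uniq, side="left")
    d1 = np.searchsorted(tda, uniq, side="right") - np.searchsorted(tda, uniq, side="left")
    o_minus_e = float(np.sum(d1 - d * n1 / n))
    frac = n1 / n
    with np.errstate(invalid="ignore", divide="ignore"):
        v_terms = np.where(n > 1, d * frac * (1 - frac) * (n - d) / np.maximum(n - 1, 1), 0.0)
    var = float(v_terms.sum())
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


@dataclass
class CoxResult:
    """Fitted Cox model: per-covariate effects plus convergence diagnostics."""

    covariates: list[str]
    log_hr: np.ndarray
    se: np.ndarray
    n: int
    n_events: int
    converged: bool
    iterations: int
    log_likelihood: float = float("nan")

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.log_hr)

    @property
    def wald_z(self) -> np.ndarray:
        return self.log_hr / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.wald_z))

    @property
    def ci95_low(self) -> np.ndarray:
        return np.exp(self.log_hr - 1.96 * self.se)

    @property
    def ci95_high(self) -> np.ndarray:
        return np.exp(self.log_hr + 1.96 * self.se)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.covariates,
                "log_hr": self.log_hr,
                "hr": self.hr,
                "se": self.se,
                "wald_z": self.wald_z,
                "p": self.p,
                "ci95_low": self.ci95_low,
                "ci95_high": self.ci95_high,
            }
        ).set_index("covariate")

    def __getitem__(self, covariate: str) -> dict[str, float]:
        i = self.covariates.index(covariate)
        return {
            "log_hr": float(self.log_hr[i]),
            "hr": float(self.hr[i]),
            "se": float(self.se[i]),
            "wald_z": float(self.wald_z[i]),
            "p": float(self.p[i]),
            "ci95_low": float(self.ci95_low[i]),
            "ci95_high": float(self.ci95_high[i]),
        }


def _efron_derivatives(
    beta: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    x: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log partial likelihood, score and Hessian with Efron tie handling.

    Risk-set sums are suffix cumulative sums over the time-sorted data, and
    tied-death sums use ``np.add.reduceat`` per distinct event time, so one
    evaluation costs O(n p^2 + E p^2) rather than O(n^2 p^2).
    """
    order = np.argsort(times, kind="mergesort")
    t = times[order]
    e = events[order]
    xs = x[order]
    n, p = xs.shape
    eta = xs @ beta
    eta -= eta.max()  # guard overflow; the partial likelihood is shift-invariant
    w = np.exp(eta)
    wx = w[:, None] * xs
    wxx = wx[:, :, None] * xs[:, None, :]
    s0_suf = np.cumsum(w[::-1])[::-1]
    s1_suf = np.cumsum(wx[::-1], axis=0)[::-1]
    s2_suf = np.cumsum(wxx[::-1], axis=0)[::-1]

    died = e == 1
    td = t[died]
    uniq, starts = np.unique(td, return_index=True)
    d_g = np.diff(np.append(starts, td.size))
    s0d = np.add.reduceat(w[died], starts)
    s1d = np.add.reduceat(wx[died], starts, axis=0)
    s2d = np.add.reduceat(wxx[died], starts, axis=0)
    risk_start = np.searchsorted(t, uniq, side="left")

    loglik = float(eta[died].sum())
    score = xs[died].sum(axis=0)
    hess = np.zeros((p, p))
    for g in range(uniq.size):
        i = risk_start[g]
        s0, s1, s2 = s0_suf[i], s1_suf[i], s2_suf[i]
        d = int(d_g[g])
        for ell in range(d):
            phi = ell / d
            denom = s0 - phi * s0d[g]
            z1 = s1 - phi * s1d[g]
            z2 = s2 - phi * s2d[g]
            loglik -= np.log(denom)
            score -= z1 / denom
            hess -= z2 / denom - np.outer(z1, z1) / denom**2
    return loglik, score, hess


def cox_fit(
    records: ClinicalTable | pd.DataFrame,
    covariates: Sequence[str],
    time_col: str = "time",
    event_col: str = "event",
) -> CoxResult:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    The partial likelihood uses the Efron correction for tied event times.
    Convergence is declared when the largest score component falls below
    1e-8; after 50 iterations the result is returned flagged unconverged
    rather than raising. A rank-deficient design (for instance a constant
    covariate) is rejected with the offending column named.
    """
    df = records.data if isinstance(records, ClinicalTable) else records
    covariates = list(covariates)
    x = df[covariates].to_numpy(dtype=float)
    times = df[time_col].to_numpy(dtype=float)
    events = df[event_col].to_numpy(dtype=int)
    n, p = x.shape
    n_events = int(events.sum())
    if n_events < 1:
        raise ValueError("Cox fit needs at least one event")
    for j, name in enumerate(covariates):
        if np.ptp(x[:, j]) == 0:
            raise ValueError(f"constant covariate {name!r}: design is rank deficient")
    if np.linalg.matrix_rank(x - x.mean(axis=0)) < p:
        raise ValueError(f"rank-deficient design over covariates {covariates}")

    # standardize for numerical stability; back-transform at the end
    mu, sd = x.mean(axis=0), x.std(axis=0)
    xs = (x - mu) / sd
    beta = np.zeros(p)
    converged = False
    loglik = -np.inf
    it = 0
    for it in range(1, MAX_NEWTON_ITER + 1):
        loglik, score, hess = _efron_derivatives(beta, times, events, xs)
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, score)
        except np.linalg.LinAlgError:
            break
        # halve the step if the likelihood would degrade (rare, near-separable data)
        new = beta + step
        for _ in range(20):
            ll_new, _, _ = _efron_derivatives(new, times, events, xs)
            if ll_new >= loglik - 1e-12:
                break
            step /= 2.0
            new = beta + step
        beta = new
    loglik, score, hess = _efron_derivatives(beta, times, events, xs)
    if np.max(np.abs(score)) < SCORE_TOL:
        converged = True
    cov = np.linalg.inv(-hess)
    se_s = np.sqrt(np.diag(cov))
    return CoxResult(
        covariates=covariates,
        log_hr=beta / sd,
        se=se_s / sd,
        n=n,
        n_events=n_events,
        converged=converged,
        iterations=it,
        log_likelihood=float(loglik),
    )


def cox_score_at_zero(
    times: Sequence[float], events: Sequence[int], covariate: Sequence[float]
) -> float:
    """Score of the Cox partial likelihood at beta = 0 for one covariate.

    For a binary covariate without tied event times this equals the log-rank
    observed-minus-expected statistic — the classical score-test equivalence.
    """
    x = np.asarray(covariate, dtype=float).reshape(-1, 1)
    _, score, _ = _efron_derivatives(
        np.zeros(1), np.asarray(times, float), np.asarray(events, int), x
    )
    return float(score[0])


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------


def _midranks(v: np.ndarray) -> np.ndarray:
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(v.size, dtype=float)
    sv = v[order]
    i = 0
    while i < v.size:
        j = i
        while j + 1 < v.size and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Ties receive average ranks; the p-value uses the t approximation with
    n - 2 degrees of freedom.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    if xv.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("constant vector; correlation undefined")
    rx, ry = _midranks(xv), _midranks(yv)
    rx -= rx.mean()
    ry -= ry.mean()
    rho = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    n = xv.size
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    tstat = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2.0 * stats.t.sf(abs(tstat), df=n - 2)
    return rho, float(p)


# ---------------------------------------------------------------------------
# forest summary
# ---------------------------------------------------------------------------


def forest_summary(
    results: Mapping[str, CoxResult], covariate: str = "expression_low"
) -> pd.DataFrame:
    """One forest-plot row per gene for the expression covariate, by p."""
    rows = []
    for gene, res in results.items():
        cell = res[covariate]
        rows.append(
            {
                "gene": gene,
                "hr": cell["hr"],
                "ci95_low": cell["ci95_low"],
                "ci95_high": cell["ci95_high"],
                "p": cell["p"],
            }
        )
    df = pd.DataFrame(rows, columns=["gene", "hr", "ci95_low", "ci95_high", "p"])
    return df.sort_values(["p", "gene"], kind="mergesort").reset_index(drop=True)
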