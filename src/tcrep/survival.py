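"""Survival analysis: Kaplan-Meier estimation, log-rank tests,
maximally-selected optimal cutpoints with permutation p-values, and Cox
proportional-hazards fits (Breslow ties, Newton-Raphson).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConvergenceError, ValidationError

__all__ = [
    "SurvivalRecord",
    "km_estimate",
    "log_rank_test",
    "two_group_logrank_z",
    "optimal_cutpoint",
    "cox_ph_fit",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's overall-survival observation."""

    patient_id: str
    time: float  # months
    event: bool  # death observed
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.time <= 0:
            raise ValidationError(
                f"patient {self.patient_id}: non-positive survival time")


def _as_arrays(records: Sequence[SurvivalRecord]):
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=bool)
    if (t <= 0).any():
        raise ValidationError("non-positive survival time")
    return t, e


def km_estimate(
    records: Sequence[SurvivalRecord],
    groups: Mapping[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimate, optionally per group.

    Returns, per group, a table of event times with at-risk counts,
    events and the running survival probability (starting at 1).
    """
    if groups is None:
        split = {"all": list(records)}
    else:
        split = {}
        for r in records:
            split.setdefault(groups[r.patient_id], []).append(r)
    out = {}
    for name, recs in split.items():
        if not recs:
            raise ValidationError(f"group {name!r} has no records")
        t, e = _as_arrays(recs)
        order = np.argsort(t, kind="stable")
        t, e = t[order], e[order]
        times, surv, at_risk, events = [], [], [], []
        s = 1.0
        n = len(t)
        i = 0
        while i < n:
            ti = t[i]
            d = 0
            j = i
            while j < n and t[j] == ti:
                d += int(e[j])
                j += 1
            risk = n - i
            if d > 0:
                s *= 1.0 - d / risk
            times.append(ti)
            at_risk.append(risk)
            events.append(d)
            surv.append(s)
            i = j
        out[name] = pd.DataFrame({
            "time": times, "at_risk": at_risk, "events": events,
            "survival": surv,
        })
    return out


def _logrank_moments(times, events, group_codes, n_groups):
    """Per-group observed and expected events plus the covariance matrix
    of (O - E) accumulated over distinct event times."""
    order = np.argsort(times, kind="stable")
    times = times[order]
    events = events[order]
    group_codes = group_codes[order]
    n = len(times)
    observed = np.zeros(n_groups)
    expected = np.zeros(n_groups)
    cov = np.zeros((n_groups, n_groups))
    at_risk = np.zeros(n_groups)
    for g in range(n_groups):
        at_risk[g] = np.sum(group_codes == g)
    i = 0
    while i < n:
        ti = times[i]
        j = i
        d_total = 0
        d_group = np.zeros(n_groups)
        removed = np.zeros(n_groups)
        while j < n and times[j] == ti:
            g = group_codes[j]
            removed[g] += 1
            if events[j]:
                d_total += 1
                d_group[g] += 1
            j += 1
        r_total = at_risk.sum()
        if d_total > 0 and r_total > 1:
            frac = at_risk / r_total
            observed += d_group
            expected += d_total * frac
            mult = d_total * (r_total - d_total) / (r_total - 1)
            cov += mult * (np.diagflat(frac) - np.outer(frac, frac))
        at_risk -= removed
        i = j
    return observed, expected, cov


def log_rank_test(
    records: Sequence[SurvivalRecord],
    groups: Mapping[str, str],
) -> dict:
    """k-sample log-rank test (chi-square with k-1 dof)."""
    names = sorted({groups[r.patient_id] for r in records})
    if len(names) < 2:
        raise ValidationError("log_rank_test needs >= 2 groups")
    code = {name: i for i, name in enumerate(names)}
    t, e = _as_arrays(records)
    g = np.array([code[groups[r.patient_id]] for r in records])
    observed, expected, cov = _logrank_moments(t, e, g, len(names))
    k = len(names) - 1
    diff = (observed - expected)[:k]
    sub_cov = cov[:k, :k]
    try:
        stat = float(diff @ np.linalg.solve(sub_cov, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(sub_cov) @ diff)
    stat = max(stat, 0.0)
    return {"statistic": stat, "dof": k, "p_value": float(sps.chi2.sf(stat, k)),
            "observed": observed.tolist(), "expected": expected.tolist(),
            "groups": names}


def _two_group_logrank_z_many(times, events, masks) -> np.ndarray:
    """Standardized two-sample log-rank z for each row of ``masks``
    (boolean membership of the "high" group), vectorised over rows.

    Uses the same O-E accumulation and hypergeometric variance as
    :func:`log_rank_test`; rows with degenerate variance get z = 0.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    masks = np.atleast_2d(np.asarray(masks, dtype=bool))
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    m = masks[:, order]
    n = len(t)
    # block boundaries of tied times
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    ends = np.r_[starts[1:], n]
    at_risk_total = n - starts                      # (n_blocks,)
    d_total = np.add.reduceat(e.astype(np.int64), starts)
    # per-row at-risk/death counts in the "high" group per block
    rev_cumsum = np.cumsum(m[:, ::-1].astype(np.int64), axis=1)[:, ::-1]
    at_risk_high = rev_cumsum[:, starts]            # (rows, n_blocks)
    d_high = np.add.reduceat((m & e).astype(np.int64), starts, axis=1)
    valid = (d_total > 0) & (at_risk_total > 1)
    frac = np.where(at_risk_total > 0,
                    at_risk_high / at_risk_total, 0.0)
    oe = ((d_high - d_total * frac)[:, valid]).sum(axis=1)
    mult = d_total * (at_risk_total - d_total) / np.maximum(
        at_risk_total - 1, 1)
    var = (mult * frac * (1.0 - frac))[:, valid].sum(axis=1)
    z = np.zeros(masks.shape[0])
    ok = var > 0
    z[ok] = oe[ok] / np.sqrt(var[ok])
    return z


def two_group_logrank_z(times, events, mask_high) -> float:
    """Standardized two-sample log-rank statistic (z score) for a binary
    split; 0 when the variance degenerates."""
    return float(_two_group_logrank_z_many(times, events,
                                           np.asarray(mask_high))[0])


def optimal_cutpoint(
    values: Mapping[str, float],
    records: Sequence[SurvivalRecord],
    minprop: float = 0.1,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> dict:
    """Maximally selected log-rank cutpoint for a continuous biomarker.

    Candidate cutpoints are the distinct biomarker values between the
    ``minprop`` and ``1 - minprop`` quantiles; the selected cutpoint
    maximizes |z| of the two-group log-rank split (high = value >
    cutpoint).  The selection-corrected p-value is obtained by permuting
    biomarker values against the survival outcomes.
    """
    recs = [r for r in records if r.patient_id in values]
    if len(recs) < 10:
        raise ValidationError("optimal_cutpoint needs >= 10 patients")
    x = np.array([values[r.patient_id] for r in recs], dtype=float)
    if np.ptp(x) == 0:
        raise ValidationError("constant biomarker")
    t, e = _as_arrays(recs)
    lo, hi = np.quantile(x, [minprop, 1.0 - minprop])
    candidates = np.unique(x[(x >= lo) & (x <= hi)])
    candidates = candidates[candidates < x.max()]  # a split must be non-trivial
    if len(candidates) == 0:
        raise ValidationError("no candidate cutpoints inside the quantile band")

    def max_stat(vals):
        masks = vals[None, :] > candidates[:, None]
        z = np.abs(_two_group_logrank_z_many(t, e, masks))
        best = int(np.argmax(z))
        return float(z[best]), float(candidates[best])

    observed_stat, cutpoint = max_stat(x)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm_stat, _ = max_stat(rng.permutation(x))
        if perm_stat >= observed_stat:
            exceed += 1
    p = (1 + exceed) / (n_permutations + 1)
    return {"cutpoint": float(cutpoint), "statistic": float(observed_stat),
            "p_value": float(p), "n_candidates": int(len(candidates))}


# ---------------------------------------------------------------------------
# Cox proportional hazards

def _cox_loglik(beta, x, t, e):
    """Breslow partial log-likelihood, gradient and information matrix.

    Assumes rows sorted by descending time so risk sets are prefixes.
    """
    eta = x @ beta
    eta -= eta.max()  # stabilise exponentials; cancels in the ratios
    w = np.exp(eta)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w[:, None] * x, axis=0)
    s2 = np.cumsum(w[:, None, None] * (x[:, :, None] * x[:, None, :]), axis=0)

    ll = 0.0
    grad = np.zeros(x.shape[1])
    info = np.zeros((x.shape[1], x.shape[1]))
    n = len(t)
    i = 0
    while i < n:
        ti = t[i]
        j = i
        while j < n and t[j] == ti:
            j += 1
        last = j - 1  # risk set = all rows with time >= ti = prefix 0..j-1
        d_idx = [k for k in range(i, j) if e[k]]
        d = len(d_idx)
        if d > 0:
            s0r = s0[last]
            s1r = s1[last]
            s2r = s2[last]
            ll += eta[d_idx].sum() - d * np.log(s0r)
            grad += x[d_idx].sum(axis=0) - d * s1r / s0r
            mean = s1r / s0r
            info += d * (s2r / s0r - np.outer(mean, mean))
        i = j
    return ll, grad, info


def cox_ph_fit(
    records: Sequence[SurvivalRecord],
    covariates: Sequence[str],
    max_iter: int = 100,
    tol: float = 1e-8,
) -> dict:
    """Cox proportional-hazards fit by Newton-Raphson on the Breslow
    partial likelihood, iterated to gradient norm < ``tol``.

    Returns per-covariate coefficients, hazard ratios, standard errors,
    Wald p-values and 95% confidence intervals, plus the model
    likelihood-ratio statistic against the null model.
    """
    t, e = _as_arrays(records)
    x = np.array([[float(r.covariates[c]) for c in covariates]
                  for r in records], dtype=float)
    if x.shape[1] == 0:
        raise ValidationError("no covariates")
    for k, name in enumerate(covariates):
        if np.ptp(x[:, k]) == 0:
            raise ValidationError(f"constant covariate {name!r}")
    if e.sum() < len(covariates) + 1:
        raise ValidationError("too few events for the number of covariates")

    order = np.argsort(-t, kind="stable")
    t, e, x = t[order], e[order], x[order]
    center = x.mean(axis=0)
    xc = x - center

    beta = np.zeros(len(covariates))
    ll_null, _, _ = _cox_loglik(beta, xc, t, e)
    ll = ll_null
    converged = False
    for it in range(max_iter):
        ll, grad, info = _cox_loglik(beta, xc, t, e)
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                "singular information matrix (possible separation)",
                {"iteration": it, "beta": beta.tolist()}) from exc
        # step-halving keeps the likelihood monotone
        scale = 1.0
        for _ in range(30):
            trial = beta + scale * step
            ll_trial, _, _ = _cox_loglik(trial, xc, t, e)
            if ll_trial >= ll - 1e-12:
                break
            scale /= 2.0
        beta = beta + scale * step
    else:
        ll, grad, info = _cox_loglik(beta, xc, t, e)
        converged = np.linalg.norm(grad) < tol
    if not converged:
        raise ConvergenceError(
            "Newton-Raphson did not converge (monotone likelihood?)",
            {"beta": beta.tolist(), "grad_norm": float(np.linalg.norm(grad))})
    if np.abs(beta).max() > 15:
        raise ConvergenceError(
            "diverging coefficient (perfect separation)",
            {"beta": beta.tolist()})

    ll, grad, info = _cox_loglik(beta, xc, t, e)
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    wald_p = 2.0 * sps.norm.sf(np.abs(z))
    zcrit = sps.norm.ppf(0.975)
    lr_stat = 2.0 * (ll - ll_null)
    lr_p = float(sps.chi2.sf(lr_stat, len(covariates)))
    table = pd.DataFrame({
        "covariate": list(covariates),
        "coef": beta,
        "hazard_ratio": np.exp(beta),
        "se": se,
        "z": z,
        "wald_p": wald_p,
        "hr_ci_low": np.exp(beta - zcrit * se),
        "hr_ci_high": np.exp(beta + zcrit * se),
    })
    return {"table": table, "log_likelihood": float(ll),
            "ll_null": float(ll_null), "lr_statistic": float(lr_stat),
            "lr_p": lr_p, "converged": True}
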