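"""Cohort-level statistics: rank tests, exact tests, correlations,
hierarchical clustering with gap-statistic model selection, per-peptide
prognosis association and flow-marker utilities.

The rank/exact tests are implemented directly from their defining
formulas (tie-corrected Kruskal-Wallis, Dunn z from the pooled rank
variance, Fisher two-sided p by hypergeometric enumeration) so they can
be cross-checked against library implementations in the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ValidationError
from .repertoire import Repertoire

__all__ = [
    "PrognosisLabel",
    "derive_prognosis_label",
    "GROUP_ORDER",
    "FAVORABLE_GROUPS",
    "UNFAVORABLE_GROUPS",
    "add_cd8_treg",
    "kruskal_wallis",
    "dunn_posthoc",
    "fisher_exact_2x2",
    "chi_square_gof",
    "pearson_r",
    "peptide_prognosis_association",
    "cluster_flow_profiles",
]

#: canonical 4-level prognosis ordering, worst outcome first
GROUP_ORDER = ("worst", "poor", "good", "excellent")
FAVORABLE_GROUPS = frozenset({"good", "excellent"})
UNFAVORABLE_GROUPS = frozenset({"worst", "poor"})


@dataclass(frozen=True)
class PrognosisLabel:
    """4-level prognosis derived from recurrence-free survival."""

    patient_id: str
    rfs_months: float | None
    responded: bool
    label: str

    def __post_init__(self):
        if self.label not in GROUP_ORDER:
            raise ValidationError(f"unknown prognosis label {self.label!r}")


def derive_prognosis_label(patient_id: str, rfs_months: float,
                           responded: bool) -> PrognosisLabel:
    """worst: RFS < 6 and no response; poor: RFS < 6 with response;
    good: 6 <= RFS <= 12; excellent: RFS > 12.

    RFS of exactly 6 months falls in "good" (boundary convention).
    """
    if rfs_months < 0:
        raise ValidationError("rfs_months must be >= 0")
    if rfs_months < 6:
        label = "poor" if responded else "worst"
    elif rfs_months <= 12:
        label = "good"
    else:
        label = "excellent"
    return PrognosisLabel(patient_id, rfs_months, responded, label)


def add_cd8_treg(flow: pd.DataFrame, cd8_col: str = "cd8",
                 treg_col: str = "cd4_foxp3") -> pd.DataFrame:
    """Append the CD8-to-Treg ratio column (%CD8+ / %CD4+FoxP3+).

    The ratio is missing (NaN) wherever the Treg percentage is zero.
    """
    out = flow.copy()
    denom = out[treg_col].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = out[cd8_col].to_numpy(dtype=float) / denom
    ratio[denom == 0] = np.nan
    out["cd8_treg"] = ratio
    return out


# ---------------------------------------------------------------------------
# rank tests

def _rank_with_ties(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Average ranks and the tie-correction term sum(t^3 - t)."""
    ranks = sps.rankdata(values, method="average")
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    return ranks, tie_term


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> dict:
    """Tie-corrected Kruskal-Wallis H with the chi-square approximation."""
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValidationError("kruskal_wallis needs >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    n = len(pooled)
    if n < 3:
        raise ValidationError("kruskal_wallis needs total n >= 3")
    ranks, tie_term = _rank_with_ties(pooled)
    dof = len(groups) - 1
    correction = 1.0 - tie_term / (n**3 - n)
    if correction == 0.0:  # every value identical
        return {"statistic": 0.0, "dof": dof, "p_value": 1.0}
    h = 0.0
    start = 0
    for g in groups:
        r_sum = ranks[start:start + len(g)].sum()
        h += r_sum**2 / len(g)
        start += len(g)
    h = (12.0 / (n * (n + 1))) * h - 3.0 * (n + 1)
    h /= correction
    p = float(sps.chi2.sf(h, dof))
    return {"statistic": float(h), "dof": dof, "p_value": p}


def dunn_posthoc(groups: Sequence[Sequence[float]],
                 labels: Sequence[str] | None = None,
                 adjust: str | None = None) -> pd.DataFrame:
    """Pairwise Dunn z tests from the pooled tie-corrected rank variance.

    Returns a DataFrame with columns (group_a, group_b, z, p_value) and,
    when ``adjust='bh'``, an additional Benjamini-Hochberg column.
    Empty groups are excluded.
    """
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    kept = [(lab, np.asarray(g, dtype=float))
            for lab, g in zip(labels, groups) if len(g) > 0]
    if len(kept) < 2:
        raise ValidationError("dunn_posthoc needs >= 2 non-empty groups")
    pooled = np.concatenate([g for _, g in kept])
    n = len(pooled)
    ranks, tie_term = _rank_with_ties(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for lab, g in kept:
        mean_ranks[lab] = ranks[start:start + len(g)].mean()
        sizes[lab] = len(g)
        start += len(g)
    var_base = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    rows = []
    for (la, _), (lb, _) in itertools.combinations(kept, 2):
        se = np.sqrt(var_base * (1.0 / sizes[la] + 1.0 / sizes[lb]))
        z = (mean_ranks[la] - mean_ranks[lb]) / se if se > 0 else 0.0
        p = float(2.0 * sps.norm.sf(abs(z)))
        rows.append({"group_a": la, "group_b": lb, "z": float(z), "p_value": p})
    out = pd.DataFrame(rows)
    if adjust == "bh":
        out["p_adjusted"] = _benjamini_hochberg(out["p_value"].to_numpy())
    elif adjust is not None:
        raise ValidationError(f"unknown adjustment {adjust!r}")
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m, dtype=float)
    running_min = 1.0
    for rank_idx in range(m - 1, -1, -1):
        idx = order[rank_idx]
        val = p[idx] * m / (rank_idx + 1)
        running_min = min(running_min, val)
        adjusted[idx] = min(running_min, 1.0)
    return adjusted


# ---------------------------------------------------------------------------
# exact / goodness-of-fit tests

def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table by hypergeometric
    enumeration: sum the probabilities of all margin-fixed tables whose
    point probability does not exceed the observed one."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("fisher_exact_2x2 expects a non-negative 2x2 table")
    a = int(t[0, 0])
    row1 = int(t[0].sum())
    col1 = int(t[:, 0].sum())
    n = int(t.sum())
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        return 1.0  # a zero margin fixes the table completely
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[a - lo]
    # relative tolerance guards against ties broken by rounding
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-9)].sum())
    return min(p, 1.0)


def chi_square_gof(observed: Sequence[float],
                   expected_props: Sequence[float]) -> dict:
    """Chi-square goodness-of-fit of observed counts against expected
    proportions; categories with zero expectation are dropped from the
    statistic and the degrees of freedom."""
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_props, dtype=float)
    if obs.shape != props.shape:
        raise ValidationError("observed and expected shapes differ")
    total = obs.sum()
    if total <= 0:
        raise ValidationError("chi_square_gof: zero total observed count")
    if abs(props.sum() - 1.0) > 1e-6:
        raise ValidationError("expected proportions must sum to 1")
    mask = props > 0
    if obs[~mask].sum() > 0:
        raise ValidationError("observed count in a zero-expectation category")
    expected = props[mask] * total
    k = int(mask.sum())
    dof = k - 1
    if dof < 1:
        raise ValidationError("chi_square_gof needs >= 2 non-degenerate categories")
    stat = float(np.sum((obs[mask] - expected) ** 2 / expected))
    return {"statistic": stat, "dof": dof, "p_value": float(sps.chi2.sf(stat, dof))}


def pearson_r(x: Sequence[float], y: Sequence[float]) -> dict:
    """Pearson correlation with the t-transform p-value (n-2 dof)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("pearson_r needs matched vectors, n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("pearson_r requires finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r": float("nan"), "p_value": float("nan"), "defined": False}
    r, p = sps.pearsonr(x, y)
    return {"r": float(r), "p_value": float(p), "defined": True}


# ---------------------------------------------------------------------------
# per-peptide prognosis association

def peptide_prognosis_association(
    reps: Sequence[Repertoire],
    labels: Mapping[str, str],
    alpha: float = 0.05,
    min_patients: int = 2,
) -> pd.DataFrame:
    """Associate each CDR3beta peptide with the 4-level prognosis.

    Per peptide (present in >= ``min_patients`` patients): a Kruskal-Wallis
    test of per-patient productive frequency across the prognosis groups,
    and a Fisher exact test of presence in favorable (good + excellent)
    versus unfavorable (poor + worst) patients.  A peptide is flagged
    associated when min(KW p, Fisher p) < alpha, unadjusted.
    """
    patient_groups = {r.patient_id: labels[r.patient_id] for r in reps}
    freq_by_patient: dict[str, dict[str, float]] = {}
    for rep in reps:
        freqs = rep.productive_frequencies()
        table: dict[str, float] = {}
        for clone, f in zip(rep.productive_clonotypes(), freqs):
            table[clone.cdr3_aa] = table.get(clone.cdr3_aa, 0.0) + float(f)
        freq_by_patient[rep.patient_id] = table

    peptides: dict[str, set[str]] = {}
    for pid, table in freq_by_patient.items():
        for pep in table:
            peptides.setdefault(pep, set()).add(pid)

    pids = sorted(freq_by_patient)
    n_fav = sum(patient_groups[p] in FAVORABLE_GROUPS for p in pids)
    n_unf = len(pids) - n_fav
    rows = []
    for pep, carriers in peptides.items():
        if len(carriers) < min_patients:
            continue
        groups = {g: [] for g in GROUP_ORDER}
        for pid in pids:
            groups[patient_groups[pid]].append(
                freq_by_patient[pid].get(pep, 0.0))
        kw = kruskal_wallis([groups[g] for g in GROUP_ORDER if groups[g]])
        fav_present = sum(patient_groups[p] in FAVORABLE_GROUPS for p in carriers)
        unf_present = len(carriers) - fav_present
        fisher_p = fisher_exact_2x2([
            [fav_present, n_fav - fav_present],
            [unf_present, n_unf - unf_present],
        ])
        min_p = min(kw["p_value"], fisher_p)
        rows.append({
            "cdr3_aa": pep,
            "n_patients": len(carriers),
            "kw_p": kw["p_value"],
            "fisher_p": fisher_p,
            "min_p": min_p,
            "associated": min_p < alpha,
        })
    out = pd.DataFrame(
        rows, columns=["cdr3_aa", "n_patients", "kw_p", "fisher_p",
                       "min_p", "associated"])
    if len(out):
        out = out.sort_values(["min_p", "cdr3_aa"]).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# flow-marker clustering with gap-statistic model selection

def _log2_eps_normalise(flow: pd.DataFrame) -> pd.DataFrame:
    """Per marker: log2(x + eps) with eps = half the smallest positive
    value, then z-score. Constant markers are dropped."""
    cols = {}
    for col in flow.columns:
        x = flow[col].to_numpy(dtype=float)
        positive = x[x > 0]
        if len(positive) == 0:
            continue
        eps = positive.min() / 2.0
        lx = np.log2(x + eps)
        sd = lx.std(ddof=0)
        if sd == 0:
            continue
        cols[col] = (lx - lx.mean()) / sd
    if not cols:
        raise ValidationError("no informative flow markers after normalisation")
    return pd.DataFrame(cols, index=flow.index)


def _pearson_distance_matrix(x: np.ndarray) -> np.ndarray:
    c = np.corrcoef(x)
    c = np.clip(c, -1.0, 1.0)
    d = 1.0 - c
    np.fill_diagonal(d, 0.0)
    return d


def _cut_average_linkage(d: np.ndarray, k: int) -> np.ndarray:
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    return hierarchy.fcluster(z, t=k, criterion="maxclust")


def _within_dispersion(x: np.ndarray, assignment: np.ndarray) -> float:
    """Pooled within-cluster dispersion W_k: per cluster, the sum of
    pairwise squared Euclidean distances divided by twice the cluster
    size (computed in the normalized marker space)."""
    w = 0.0
    for lab in np.unique(assignment):
        idx = np.flatnonzero(assignment == lab)
        if len(idx) > 1:
            sub = x[idx]
            sq = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(axis=2)
            w += sq.sum() / (2.0 * len(idx))
    return w


def cluster_flow_profiles(
    flow: pd.DataFrame,
    k_range: Sequence[int] = range(1, 7),
    b_refs: int = 50,
    seed: int | None = None,
    dropna: bool = True,
) -> dict:
    """Hierarchically cluster patients on normalized flow-marker profiles.

    Markers are log2(x + eps) transformed and z-scored; patients are
    clustered by average linkage on 1 - Pearson correlation distance.
    The number of clusters is chosen by the gap statistic (uniform
    reference draws in the normalized marker space, 1-SE rule).
    """
    if dropna:
        flow = flow.dropna(axis=0, how="any")
    if flow.shape[0] < 4 or flow.shape[1] < 2:
        raise ValidationError("cluster_flow_profiles needs >= 4 patients, >= 2 markers")
    norm = _log2_eps_normalise(flow)
    x = norm.to_numpy()
    d = _pearson_distance_matrix(x)
    rng = np.random.default_rng(seed)
    k_range = [int(k) for k in k_range if 1 <= k <= x.shape[0]]

    log_w = {}
    assignments = {}
    for k in k_range:
        assignment = (np.ones(x.shape[0], dtype=int) if k == 1
                      else _cut_average_linkage(d, k))
        assignments[k] = assignment
        log_w[k] = np.log(max(_within_dispersion(x, assignment), 1e-300))

    lo, hi = x.min(axis=0), x.max(axis=0)
    ref_log_w = {k: [] for k in k_range}
    for _ in range(b_refs):
        ref = rng.uniform(lo, hi, size=x.shape)
        dref = _pearson_distance_matrix(ref)
        for k in k_range:
            assignment = (np.ones(x.shape[0], dtype=int) if k == 1
                          else _cut_average_linkage(dref, k))
            ref_log_w[k].append(
                np.log(max(_within_dispersion(ref, assignment), 1e-300)))

    gap, s_k = {}, {}
    for k in k_range:
        refs = np.array(ref_log_w[k])
        gap[k] = refs.mean() - log_w[k]
        s_k[k] = refs.std(ddof=0) * np.sqrt(1.0 + 1.0 / b_refs)

    chosen = k_range[-1]
    for i, k in enumerate(k_range[:-1]):
        nxt = k_range[i + 1]
        if gap[k] >= gap[nxt] - s_k[nxt]:
            chosen = k
            break

    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    return {
        "k": chosen,
        "labels": pd.Series(assignments[chosen], index=flow.index, name="cluster"),
        "gap": gap,
        "gap_se": s_k,
        "linkage": z,
        "normalized": norm,
    }
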