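"""Antigen-database annotation of cohort CDR3beta peptides.

Two annotation modes mirror the two curated-database conventions:
``fuzzy`` matching at Levenshtein distance <= 1 and ``exact`` matching
(distance 0 only).  Downstream summaries: functional-category
enrichment against a database background, per-condition prognosis
association, group-level cancer-match frequencies, epitope-gene
presence matrices and V/J segment usage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats as cstats
from .errors import FormatError, ValidationError
from .repertoire import Repertoire

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "DEFAULT_CATEGORY_BACKGROUND",
    "ReferenceRecord",
    "AnnotationHit",
    "levenshtein_distance",
    "load_reference_db",
    "annotate_cohort",
    "category_enrichment",
    "condition_prognosis_test",
    "cancer_match_group_frequency",
    "epitope_gene_matrix",
    "vj_usage",
]

CATEGORIES = ("pathogens", "cancer", "autoimmune", "allergy", "other")

#: database-wide category proportions used as the enrichment background
DEFAULT_CATEGORY_BACKGROUND = {
    "pathogens": 0.68,
    "cancer": 0.16,
    "autoimmune": 0.13,
    "allergy": 0.027,
    "other": 0.003,
}


@dataclass(frozen=True)
class ReferenceRecord:
    """A curated CDR3beta -> (category, pathology, epitope) record."""

    cdr3_aa: str
    category: str
    pathology: str = ""
    epitope_peptide: str = ""
    epitope_gene: str = ""

    def __post_init__(self):
        if not self.cdr3_aa:
            raise ValidationError("reference record with empty cdr3_aa")
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class AnnotationHit:
    """A cohort peptide matched to a reference record."""

    patient_id: str
    cdr3_aa: str
    record: ReferenceRecord
    edit_distance: int
    mode: str  # "fuzzy" or "exact"

    def __post_init__(self):
        if self.mode not in ("fuzzy", "exact"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.mode == "exact" and self.edit_distance != 0:
            raise ValidationError("exact hits must have edit distance 0")


def levenshtein_distance(a: str, b: str) -> int:
    """Unit-cost insert/delete/substitute edit distance (two-row DP)."""
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    previous = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        current = [i]
        for j, cb in enumerate(b, start=1):
            current.append(min(
                previous[j] + 1,        # deletion
                current[j - 1] + 1,     # insertion
                previous[j - 1] + (ca != cb),  # substitution
            ))
        previous = current
    return previous[-1]


def _within_one(a: str, b: str) -> bool:
    """Fast Levenshtein <= 1 check (used for bulk fuzzy annotation)."""
    la, lb = len(a), len(b)
    if abs(la - lb) > 1:
        return False
    if la == lb:
        mism = 0
        for ca, cb in zip(a, b):
            if ca != cb:
                mism += 1
                if mism > 1:
                    return False
        return True
    if la < lb:
        a, b, la, lb = b, a, lb, la
    # a is longer by one: allow a single skipped character
    i = j = 0
    skipped = False
    while i < la and j < lb:
        if a[i] == b[j]:
            i += 1
            j += 1
        elif not skipped:
            skipped = True
            i += 1
        else:
            return False
    return True


def load_reference_db(path: str | Path) -> list[ReferenceRecord]:
    """Read a reference TSV with columns cdr3_aa, category, pathology,
    epitope_peptide, epitope_gene."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"cdr3_aa", "category"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"reference db missing column(s): {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(ReferenceRecord(
            cdr3_aa=row["cdr3_aa"],
            category=row["category"],
            pathology=row.get("pathology", ""),
            epitope_peptide=row.get("epitope_peptide", ""),
            epitope_gene=row.get("epitope_gene", ""),
        ))
    return records


def annotate_cohort(
    reps: Sequence[Repertoire],
    db: Sequence[ReferenceRecord],
    mode: str = "fuzzy",
    max_dist: int | None = None,
    record_filter=None,
) -> list[AnnotationHit]:
    """Match every productive cohort peptide against the reference.

    ``mode='fuzzy'`` uses Levenshtein distance <= ``max_dist`` (default 1);
    ``mode='exact'`` requires identity (max_dist forced to 0).  A
    (patient, peptide, record) triple is emitted at most once, regardless
    of how many clonotypes share the CDR3.  ``record_filter`` is an
    optional predicate applied to reference records before matching.
    """
    if mode == "exact":
        max_dist = 0
    elif mode == "fuzzy":
        max_dist = 1 if max_dist is None else max_dist
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    if record_filter is not None:
        db = [r for r in db if record_filter(r)]
    if not db:
        warnings.warn("annotate_cohort: empty reference database", stacklevel=2)
        return []

    by_peptide: dict[str, list[ReferenceRecord]] = {}
    for rec in db:
        by_peptide.setdefault(rec.cdr3_aa, []).append(rec)
    by_length: dict[int, list[str]] = {}
    for pep in by_peptide:
        by_length.setdefault(len(pep), []).append(pep)

    hits: list[AnnotationHit] = []
    for rep in reps:
        queries = sorted({c.cdr3_aa for c in rep.productive_clonotypes()})
        for q in queries:
            if max_dist == 0:
                matches = [(q, 0)] if q in by_peptide else []
            else:
                matches = []
                for length in (len(q) - 1, len(q), len(q) + 1):
                    for ref_pep in by_length.get(length, ()):
                        if ref_pep == q:
                            matches.append((ref_pep, 0))
                        elif max_dist >= 1 and _within_one(q, ref_pep):
                            matches.append((ref_pep, 1))
            for ref_pep, dist in matches:
                for rec in by_peptide[ref_pep]:
                    hits.append(AnnotationHit(
                        patient_id=rep.patient_id, cdr3_aa=q,
                        record=rec, edit_distance=dist, mode=mode))
    return hits


def category_enrichment(
    hits: Sequence[AnnotationHit],
    background_props: Mapping[str, float] | None = None,
) -> dict:
    """Chi-square goodness of fit of annotation-category counts against
    the database background distribution."""
    if background_props is None:
        background_props = DEFAULT_CATEGORY_BACKGROUND
    props = np.array([background_props.get(c, 0.0) for c in CATEGORIES])
    if abs(props.sum() - 1.0) > 1e-6:
        raise ValidationError("background proportions must sum to 1")
    counts = {c: 0 for c in CATEGORIES}
    for hit in hits:
        counts[hit.record.category] += 1
    observed = np.array([counts[c] for c in CATEGORIES], dtype=float)
    if observed.sum() == 0:
        raise ValidationError("category_enrichment: zero annotations")
    gof = cstats.chi_square_gof(observed, props)
    total = observed.sum()
    return {
        "observed_counts": counts,
        "observed_proportions": {c: counts[c] / total for c in CATEGORIES},
        "background_proportions": dict(zip(CATEGORIES, props)),
        "statistic": gof["statistic"],
        "dof": gof["dof"],
        "p_value": gof["p_value"],
    }


def condition_prognosis_test(
    hits: Sequence[AnnotationHit],
    reps: Sequence[Repertoire],
    labels: Mapping[str, str],
    alpha: float = 0.05,
    denominator: str = "productive_rearrangements",
) -> pd.DataFrame:
    """Per-pathology Kruskal-Wallis of normalized annotation counts
    across the prognosis groups, with Dunn post-hoc on significant ones.

    Normalization divides each patient's annotation-record count for a
    condition by that patient's number of unique productive
    rearrangements (``denominator='productive_rearrangements'``, default)
    or by the patient's total annotated record count
    (``denominator='total_annotations'``).
    """
    if denominator not in ("productive_rearrangements", "total_annotations"):
        raise ValidationError(f"unknown denominator {denominator!r}")
    pids = sorted({r.patient_id for r in reps})
    denom = {}
    if denominator == "productive_rearrangements":
        for rep in reps:
            denom[rep.patient_id] = max(len(rep.productive_clonotypes()), 1)
    else:
        totals = {pid: 0 for pid in pids}
        for hit in hits:
            totals[hit.patient_id] = totals.get(hit.patient_id, 0) + 1
        denom = {pid: max(totals.get(pid, 0), 1) for pid in pids}

    counts: dict[str, dict[str, int]] = {}
    seen: set[tuple] = set()
    for hit in hits:
        key = (hit.patient_id, hit.cdr3_aa, hit.record)
        if key in seen:
            continue
        seen.add(key)
        counts.setdefault(hit.record.pathology, {})
        counts[hit.record.pathology][hit.patient_id] = \
            counts[hit.record.pathology].get(hit.patient_id, 0) + 1

    rows = []
    for pathology in sorted(counts):
        per_patient = counts[pathology]
        if len(per_patient) < 2:
            rows.append({"pathology": pathology, "n_patients": len(per_patient),
                         "kw_statistic": np.nan, "kw_p": np.nan,
                         "skipped": True, "dunn": None})
            continue
        groups, group_names = [], []
        for g in cstats.GROUP_ORDER:
            members = [pid for pid in pids if labels[pid] == g]
            if members:
                groups.append([per_patient.get(pid, 0) / denom[pid]
                               for pid in members])
                group_names.append(g)
        if len(groups) < 2:
            raise ValidationError("condition_prognosis_test needs >= 2 groups")
        kw = cstats.kruskal_wallis(groups)
        dunn = None
        if kw["p_value"] < alpha:
            dunn = cstats.dunn_posthoc(groups, labels=group_names)
        rows.append({"pathology": pathology, "n_patients": len(per_patient),
                     "kw_statistic": kw["statistic"], "kw_p": kw["p_value"],
                     "skipped": False, "dunn": dunn})
    return pd.DataFrame(
        rows, columns=["pathology", "n_patients", "kw_statistic", "kw_p",
                       "skipped", "dunn"])


def cancer_match_group_frequency(
    hits: Sequence[AnnotationHit],
    labels: Mapping[str, str],
) -> pd.DataFrame:
    """Per-prognosis-group frequency of exact cancer matches: distinct
    (patient, peptide) occurrences divided by the group's patient count.

    Empty groups are excluded with a warning.
    """
    occurrences: set[tuple[str, str]] = {
        (h.patient_id, h.cdr3_aa) for h in hits
        if h.mode == "exact" and h.record.category == "cancer"
    }
    group_sizes = {g: 0 for g in cstats.GROUP_ORDER}
    for g in labels.values():
        group_sizes[g] += 1
    rows = []
    for g in cstats.GROUP_ORDER:
        if group_sizes[g] == 0:
            warnings.warn(f"group {g!r} has no patients; excluded", stacklevel=2)
            continue
        n_matches = sum(1 for pid, _ in occurrences if labels[pid] == g)
        rows.append({"group": g, "n_patients": group_sizes[g],
                     "n_matches": n_matches,
                     "frequency": n_matches / group_sizes[g]})
    return pd.DataFrame(rows, columns=["group", "n_patients", "n_matches",
                                       "frequency"])


def epitope_gene_matrix(
    hits: Sequence[AnnotationHit],
    labels: Mapping[str, str],
    prevalence_cutoff: float = 0.75,
) -> pd.DataFrame:
    """Binary patient x epitope-gene presence matrix from exact hits.

    Genes present in strictly more than ``prevalence_cutoff`` of patients
    are excluded.  Columns are ordered by decreasing patient count; rows
    are grouped by prognosis and ordered by per-patient gene count within
    each group.
    """
    pids = sorted(labels)
    presence: dict[str, set[str]] = {}
    for h in hits:
        if h.mode != "exact" or not h.record.epitope_gene:
            continue
        presence.setdefault(h.record.epitope_gene, set()).add(h.patient_id)
    n = len(pids)
    genes = [g for g in presence if len(presence[g]) / n <= prevalence_cutoff]
    genes.sort(key=lambda g: (-len(presence[g]), g))
    mat = pd.DataFrame(0, index=pids, columns=genes, dtype=int)
    for g in genes:
        for pid in presence[g]:
            mat.loc[pid, g] = 1
    gene_counts = mat.sum(axis=1)
    order = sorted(
        pids,
        key=lambda p: (cstats.GROUP_ORDER.index(labels[p]), -gene_counts[p], p))
    return mat.loc[order]


def vj_usage(
    reps: Sequence[Repertoire],
    cdr3_filter: str | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-patient V- and J-segment frequency tables over productive
    clonotypes (unique-clonotype proportions; unresolved calls pooled).

    ``cdr3_filter`` restricts counting to clonotypes carrying that exact
    CDR3beta peptide.
    """
    out = {}
    for segment in ("v_gene", "j_gene"):
        counts: dict[str, dict[str, int]] = {}
        for rep in reps:
            clones = rep.productive_clonotypes()
            if cdr3_filter is not None:
                clones = [c for c in clones if c.cdr3_aa == cdr3_filter]
            if not clones:
                continue
            per = counts.setdefault(rep.patient_id, {})
            for c in clones:
                gene = getattr(c, segment) or "unresolved"
                per[gene] = per.get(gene, 0) + 1
        table = pd.DataFrame(counts).T.fillna(0.0).sort_index()
        if len(table):
            table = table.div(table.sum(axis=1), axis=0)
            table = table[sorted(table.columns)]
        out[segment] = table
    return out
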