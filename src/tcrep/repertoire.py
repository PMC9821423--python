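"""Clonotype tables and sample-level repertoire characteristics.

Reads immunoSEQ-style tab-separated clonotype exports, restricts to
productive rearrangements (in-frame, no stop codon, non-empty CDR3
amino-acid sequence) and computes the six sample-level summary
statistics used throughout the downstream analyses: productive
rearrangements, total productive templates, productive entropy (bits),
productive clonality, and the maximum / top-10 / top-100 productive
frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyRepertoireError, FormatError, ValidationError

__all__ = [
    "Clonotype",
    "Repertoire",
    "RepertoireStats",
    "parse_immunoseq_table",
    "compute_repertoire_stats",
    "cohort_stats_table",
    "COHORT_STATS_COLUMNS",
]

#: amino-acid alphabet; '*' denotes a stop codon inside a CDR3 translation
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
STOP_SYMBOL = "*"

# accepted header synonyms for the mandatory and optional columns
_CDR3_COLUMNS = ("cdr3_aa", "amino_acid", "aminoAcid", "cdr3_amino_acid")
_TEMPLATE_COLUMNS = ("templates", "count (templates/reads)", "seq_reads", "count")
_FRAME_COLUMNS = ("frame", "frame_type", "sequenceStatus")
_V_COLUMNS = ("v_gene", "v_resolved", "vGeneName")
_D_COLUMNS = ("d_gene", "d_resolved", "dGeneName")
_J_COLUMNS = ("j_gene", "j_resolved", "jGeneName")

_FRAME_ALIASES = {
    "in": "in",
    "in-frame": "in",
    "inframe": "in",
    "out": "out",
    "out-of-frame": "out",
    "outofframe": "out",
    "stop": "stop",
    "has stop": "stop",
}


@dataclass(frozen=True)
class Clonotype:
    """One unique CDR3beta rearrangement with its abundance."""

    cdr3_aa: str
    v_gene: str = "unresolved"
    d_gene: str = "unresolved"
    j_gene: str = "unresolved"
    templates: int = 0
    frame: str = "in"  # one of {"in", "out", "stop"}

    def __post_init__(self):
        if self.templates < 0:
            raise ValidationError(
                f"negative template count {self.templates} for {self.cdr3_aa!r}"
            )
        if self.frame not in ("in", "out", "stop"):
            raise ValidationError(f"unknown frame {self.frame!r}")

    @property
    def productive(self) -> bool:
        """In-frame, non-empty CDR3 with no stop symbol."""
        return (
            self.frame == "in"
            and bool(self.cdr3_aa)
            and STOP_SYMBOL not in self.cdr3_aa
        )


@dataclass
class Repertoire:
    """One patient's clonotype list, unique by (cdr3_aa, v_gene, j_gene)."""

    patient_id: str
    clonotypes: list[Clonotype] = field(default_factory=list)

    def productive_clonotypes(self) -> list[Clonotype]:
        return [c for c in self.clonotypes if c.productive]

    def productive_frequencies(self) -> np.ndarray:
        """Frequencies of productive clonotypes among productive templates."""
        counts = np.array(
            [c.templates for c in self.productive_clonotypes()], dtype=float
        )
        total = counts.sum()
        if total <= 0:
            raise EmptyRepertoireError(
                f"patient {self.patient_id}: empty productive repertoire"
            )
        return counts / total


@dataclass(frozen=True)
class RepertoireStats:
    """The six sample-level TCR characteristics."""

    patient_id: str
    productive_rearrangements: int
    total_productive_templates: int
    productive_entropy: float  # bits
    productive_clonality: float
    max_productive_frequency: float
    top10_productive_frequency: float
    top100_productive_frequency: float


def _normalise_frame(raw: object) -> str:
    key = str(raw).strip().lower()
    if key in _FRAME_ALIASES:
        return _FRAME_ALIASES[key]
    raise FormatError(f"unrecognised frame value {raw!r}")


def _find_column(columns: Sequence[str], candidates: Sequence[str], what: str,
                 required: bool = True) -> str | None:
    lowered = {c.lower(): c for c in columns}
    for cand in candidates:
        if cand.lower() in lowered:
            return lowered[cand.lower()]
    if required:
        raise FormatError(
            f"missing mandatory column for {what}; accepted names: {candidates}"
        )
    return None


def parse_immunoseq_table(path: str | Path, patient_id: str) -> Repertoire:
    """Read one immunoSEQ-style TSV into a :class:`Repertoire`.

    Rows with an empty CDR3 amino-acid sequence are retained but can never
    be productive.  Duplicate (cdr3_aa, v_gene, j_gene) rows are merged by
    summing template counts.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cdr3_col = _find_column(df.columns, _CDR3_COLUMNS, "CDR3 amino acid")
    tmpl_col = _find_column(df.columns, _TEMPLATE_COLUMNS, "templates")
    frame_col = _find_column(df.columns, _FRAME_COLUMNS, "frame type")
    v_col = _find_column(df.columns, _V_COLUMNS, "V gene", required=False)
    d_col = _find_column(df.columns, _D_COLUMNS, "D gene", required=False)
    j_col = _find_column(df.columns, _J_COLUMNS, "J gene", required=False)

    merged: dict[tuple[str, str, str], dict] = {}
    for _, row in df.iterrows():
        cdr3 = row[cdr3_col].strip()
        try:
            templates = int(float(row[tmpl_col]))
        except ValueError as exc:
            raise FormatError(
                f"non-numeric template count {row[tmpl_col]!r}"
            ) from exc
        if templates < 0:
            raise ValidationError(f"negative template count {templates}")
        v = row[v_col].strip() if v_col else "unresolved"
        d = row[d_col].strip() if d_col else "unresolved"
        j = row[j_col].strip() if j_col else "unresolved"
        v = v or "unresolved"
        d = d or "unresolved"
        j = j or "unresolved"
        frame = _normalise_frame(row[frame_col])
        key = (cdr3, v, j)
        if key in merged:
            merged[key]["templates"] += templates
        else:
            merged[key] = {
                "cdr3_aa": cdr3, "v_gene": v, "d_gene": d, "j_gene": j,
                "templates": templates, "frame": frame,
            }
    clonotypes = [Clonotype(**rec) for rec in merged.values()]
    return Repertoire(patient_id=patient_id, clonotypes=clonotypes)


def compute_repertoire_stats(rep: Repertoire) -> RepertoireStats:
    """Entropy, clonality and top-k productive frequencies for one sample.

    entropy = -sum f_i log2 f_i over productive frequencies; clonality =
    1 - entropy / log2(R) for R > 1 and 1 by convention for R == 1.
    """
    productive = rep.productive_clonotypes()
    if not productive:
        raise EmptyRepertoireError(
            f"patient {rep.patient_id}: empty productive repertoire"
        )
    freqs = rep.productive_frequencies()
    r = len(freqs)
    nz = freqs[freqs > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    if r > 1:
        clonality = 1.0 - entropy / np.log2(r)
    else:
        clonality = 1.0  # degenerate single-clone repertoire
    ordered = np.sort(freqs)[::-1]
    return RepertoireStats(
        patient_id=rep.patient_id,
        productive_rearrangements=r,
        total_productive_templates=int(sum(c.templates for c in productive)),
        productive_entropy=entropy,
        productive_clonality=float(clonality),
        max_productive_frequency=float(ordered[0]),
        top10_productive_frequency=float(ordered[:10].sum()),
        top100_productive_frequency=float(ordered[:100].sum()),
    )


COHORT_STATS_COLUMNS = [
    "patient_id",
    "productive_rearrangements",
    "total_productive_templates",
    "productive_entropy_bits",
    "productive_clonality",
    "max_pf",
    "top10_pf",
    "top100_pf",
]


def cohort_stats_table(reps: Iterable[Repertoire]) -> pd.DataFrame:
    """One stats row per patient, ordered by patient_id."""
    reps = list(reps)
    if not reps:
        raise ValidationError("cohort_stats_table: empty repertoire list")
    ids = [r.patient_id for r in reps]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate patient_id(s): {dupes}")
    rows = []
    for rep in sorted(reps, key=lambda r: r.patient_id):
        s = compute_repertoire_stats(rep)
        rows.append({
            "patient_id": s.patient_id,
            "productive_rearrangements": s.productive_rearrangements,
            "total_productive_templates": s.total_productive_templates,
            "productive_entropy_bits": s.productive_entropy,
            "productive_clonality": s.productive_clonality,
            "max_pf": s.max_productive_frequency,
            "top10_pf": s.top10_productive_frequency,
            "top100_pf": s.top100_productive_frequency,
        })
    return pd.DataFrame(rows, columns=COHORT_STATS_COLUMNS)
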