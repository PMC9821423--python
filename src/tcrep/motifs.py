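"""Specificity grouping of CDR3beta peptides.

A simplified re-implementation of paratope-hotspot clustering: peptides
covered by more than one read are grouped when they either share an
interior k-mer enriched against a naive reference repertoire (local
component) or are global neighbours (equal length, Hamming distance
<= 1).  Clusters with at least four subjects are tested for prognosis
association by a 2x2 chi-square contingency table, and cluster members
are summarised by a wildcard pattern, a position-frequency matrix and a
neighbour-joining tree on uncorrected normalized edit distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .annotation import levenshtein_distance
from .errors import ValidationError
from .repertoire import Repertoire

__all__ = [
    "MotifPattern",
    "MotifHit",
    "SpecificityCluster",
    "clustering_input",
    "interior_kmers",
    "enriched_motifs",
    "global_similarity_pairs",
    "build_specificity_clusters",
    "cluster_pattern",
    "cluster_prognosis_association",
    "neighbor_joining_tree",
]

WILDCARD = "%"

#: interior margin excluded from k-mer extraction at both ends
INTERIOR_MARGIN = 3


@dataclass(frozen=True)
class MotifPattern:
    """Wildcard consensus over cluster members of the modal length."""

    pattern: str
    length: int


@dataclass(frozen=True)
class MotifHit:
    """An interior k-mer enriched in the sample versus the reference."""

    motif: str
    sample_count: int
    fold: float
    p_value: float


@dataclass
class SpecificityCluster:
    """A connected component of motif-sharing / near-identical peptides."""

    cluster_id: str
    members: set = field(default_factory=set)  # {(patient_id, cdr3_aa)}
    seed_motifs: list = field(default_factory=list)
    pattern: MotifPattern | None = None
    association: dict | None = None

    @property
    def subjects(self) -> int:
        return len({pid for pid, _ in self.members})

    @property
    def peptides(self) -> set:
        return {pep for _, pep in self.members}


def clustering_input(reps: Sequence[Repertoire],
                     min_templates: int = 2) -> list[tuple[str, str]]:
    """(patient, peptide) pairs for clustering: productive clonotypes
    covered by more than one read, deduplicated per patient."""
    members = set()
    for rep in reps:
        for clone in rep.productive_clonotypes():
            if clone.templates >= min_templates:
                members.add((rep.patient_id, clone.cdr3_aa))
    if not members:
        raise ValidationError(
            "no clonotypes pass the read threshold; lower min_templates")
    return sorted(members)


def interior_kmers(seq: str, k: int, margin: int = INTERIOR_MARGIN,
                   whole_string_fallback: bool = True) -> set[str]:
    """Contiguous k-mers from the CDR3 interior (first/last ``margin``
    residues excluded).  Sequences shorter than k + 2*margin fall back to
    whole-string k-mers unless the fallback is disabled."""
    if len(seq) >= k + 2 * margin:
        core = seq[margin:len(seq) - margin]
    elif whole_string_fallback:
        core = seq
    else:
        return set()
    return {core[i:i + k] for i in range(len(core) - k + 1)}


def enriched_motifs(
    sample_cdr3s: Sequence[str],
    reference_cdr3s: Sequence[str],
    k_set: Iterable[int] = (3, 4),
    fold_min: float = 10.0,
    p_max: float = 0.001,
    n_resamples: int = 1000,
    min_sample_count: int = 3,
    seed: int | None = None,
    whole_string_fallback: bool = True,
) -> list[MotifHit]:
    """Interior k-mers over-represented in the sample relative to
    size-matched resamples of a reference repertoire.

    Per motif: sample count = number of distinct sample sequences whose
    interior contains the motif; fold = sample frequency divided by the
    mean frequency across ``n_resamples`` resamples of the reference
    (infinite when the motif never occurs in a resample); empirical
    p = (1 + #resamples with count >= observed) / (n_resamples + 1).
    """
    if not reference_cdr3s:
        raise ValidationError("enriched_motifs: empty reference")
    sample = sorted(set(sample_cdr3s))
    if not sample:
        return []
    rng = np.random.default_rng(seed)
    k_set = sorted(set(int(k) for k in k_set))

    sample_kmers = [
        set().union(*(interior_kmers(s, k, whole_string_fallback=whole_string_fallback)
                      for k in k_set))
        for s in sample
    ]
    counts: dict[str, int] = {}
    for kmers in sample_kmers:
        for m in kmers:
            counts[m] = counts.get(m, 0) + 1
    candidates = sorted(m for m, c in counts.items() if c >= min_sample_count)
    if not candidates:
        warnings.warn("no candidate motifs (k exceeds all interior regions?)",
                      stacklevel=2)
        return []

    ref = list(reference_cdr3s)
    ref_kmer_sets = [
        set().union(*(interior_kmers(s, k, whole_string_fallback=whole_string_fallback)
                      for k in k_set))
        for s in ref
    ]
    candidate_set = set(candidates)
    ref_counts_total: dict[str, int] = {m: 0 for m in candidates}
    for kmers in ref_kmer_sets:
        for m in kmers & candidate_set:
            ref_counts_total[m] += 1

    # motifs whose expected resample count already rules out the fold
    # threshold (with 2x slack for resampling noise) are skipped before
    # the expensive resampling step; they cannot pass the filter.
    n_sample = len(sample)
    def _could_pass(m: str) -> bool:
        rc = ref_counts_total[m]
        if rc == 0:
            return True
        expected = n_sample * rc / len(ref)
        return counts[m] / expected >= fold_min / 2.0

    candidates = [m for m in candidates if _could_pass(m)]
    if not candidates:
        return []
    motif_index = {m: i for i, m in enumerate(candidates)}
    presence = np.zeros((len(ref), len(candidates)), dtype=np.float32)
    for row, kmers in enumerate(ref_kmer_sets):
        for m in kmers:
            idx = motif_index.get(m)
            if idx is not None:
                presence[row, idx] = 1.0

    draws = rng.integers(0, len(ref), size=(n_resamples, n_sample))
    offsets = np.arange(n_resamples)[:, None] * len(ref)
    flat = np.bincount((draws + offsets).ravel(),
                       minlength=n_resamples * len(ref))
    draw_counts = flat.reshape(n_resamples, len(ref)).astype(np.float32)
    resample_counts = draw_counts @ presence  # (n_resamples, n_motifs)

    hits = []
    for m in candidates:
        i = motif_index[m]
        obs = counts[m]
        ref_counts = resample_counts[:, i]
        mean_ref = float(ref_counts.mean())
        fold = obs / mean_ref if mean_ref > 0 else float("inf")
        p = float((1 + np.sum(ref_counts >= obs)) / (n_resamples + 1))
        if fold >= fold_min and p <= p_max:
            hits.append(MotifHit(motif=m, sample_count=obs, fold=fold, p_value=p))
    hits.sort(key=lambda h: (h.p_value, -h.sample_count, h.motif))
    return hits


def global_similarity_pairs(cdr3s: Iterable[str]) -> list[tuple[str, str]]:
    """Unordered pairs of distinct peptides of equal length at Hamming
    distance <= 1, found by single-position masking."""
    seqs = sorted(set(cdr3s))
    buckets: dict[tuple[int, int, str], list[int]] = {}
    for idx, s in enumerate(seqs):
        for pos in range(len(s)):
            masked = s[:pos] + "\0" + s[pos + 1:]
            buckets.setdefault((len(s), pos, masked), []).append(idx)
    pairs = set()
    for members in buckets.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.add((seqs[members[i]], seqs[members[j]]))
    return sorted(pairs)


def build_specificity_clusters(
    members: Sequence[tuple[str, str]],
    motif_hits: Sequence[MotifHit],
    pairs: Sequence[tuple[str, str]] | None = None,
    k_set: Iterable[int] = (3, 4),
    whole_string_fallback: bool = True,
) -> list[SpecificityCluster]:
    """Connected components over peptides linked by a shared enriched
    motif or by global similarity; components with >= 2 distinct
    peptides become clusters with deterministic ids."""
    peptides = sorted({pep for _, pep in members})
    if pairs is None:
        pairs = global_similarity_pairs(peptides)
    parent = {p: p for p in peptides}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    k_set = sorted(set(int(k) for k in k_set))
    motif_set = {h.motif for h in motif_hits}
    motif_carriers: dict[str, list[str]] = {m: [] for m in motif_set}
    for pep in peptides:
        kmers = set().union(
            *(interior_kmers(pep, k, whole_string_fallback=whole_string_fallback)
              for k in k_set))
        for m in kmers & motif_set:
            motif_carriers[m].append(pep)
    for carrier_list in motif_carriers.values():
        for other in carrier_list[1:]:
            union(carrier_list[0], other)
    for a, b in pairs:
        union(a, b)

    components: dict[str, set[str]] = {}
    for pep in peptides:
        components.setdefault(find(pep), set()).add(pep)

    member_lookup: dict[str, set[tuple[str, str]]] = {}
    for pid, pep in members:
        member_lookup.setdefault(pep, set()).add((pid, pep))

    clusters = []
    for comp in components.values():
        if len(comp) < 2:
            continue
        comp_members = set()
        for pep in comp:
            comp_members |= member_lookup[pep]
        seed_motifs = sorted(
            m for m, carriers in motif_carriers.items()
            if sum(1 for c in carriers if c in comp) >= 2)
        cluster = SpecificityCluster(
            cluster_id=f"SG_{min(comp)}",
            members=comp_members,
            seed_motifs=seed_motifs,
        )
        cluster.pattern = cluster_pattern(sorted(comp))[0]
        clusters.append(cluster)
    clusters.sort(key=lambda c: c.cluster_id)
    return clusters


def cluster_pattern(sequences: Sequence[str]) -> tuple[MotifPattern, dict]:
    """Wildcard consensus and position-frequency matrix over the members
    of the modal length: per position the unanimous residue, else '%'."""
    if not sequences:
        raise ValidationError("cluster_pattern: empty cluster")
    lengths = [len(s) for s in sequences]
    modal = max(sorted(set(lengths)), key=lengths.count)
    same = [s for s in sequences if len(s) == modal]
    chars = []
    pfm: dict[int, dict[str, int]] = {}
    for pos in range(modal):
        column = [s[pos] for s in same]
        pfm[pos] = {}
        for c in column:
            pfm[pos][c] = pfm[pos].get(c, 0) + 1
        chars.append(column[0] if len(set(column)) == 1 else WILDCARD)
    return MotifPattern(pattern="".join(chars), length=modal), pfm


def cluster_prognosis_association(
    cluster: SpecificityCluster,
    labels: Mapping[str, str],
    group1: Iterable[str],
    dataset_members: Sequence[tuple[str, str]],
    min_subjects: int = 4,
    alpha: float = 0.05,
    strict_exclusive: bool = False,
    opposing_groups: Iterable[str] = (),
) -> dict:
    """2x2 chi-square contingency test of cluster membership against the
    rest of the dataset: member occurrences from ``group1`` patients vs
    the remaining groups, inside the cluster vs in the remaining
    (patient, peptide) dataset.  No continuity correction.

    Clusters with fewer than ``min_subjects`` distinct patients are not
    evaluated.  With ``strict_exclusive``, association additionally
    requires zero members from ``opposing_groups``.
    """
    group1 = set(group1)
    record = {"group1": sorted(group1), "evaluated": False, "associated": False,
              "statistic": None, "p_value": None, "direction": None,
              "degenerate": False, "low_expected": False}
    if cluster.subjects < min_subjects:
        record["reason"] = f"fewer than {min_subjects} subjects"
        return record
    in_cluster = cluster.members
    out_cluster = set(dataset_members) - in_cluster
    a = sum(1 for pid, _ in in_cluster if labels[pid] in group1)
    b = len(in_cluster) - a
    c = sum(1 for pid, _ in out_cluster if labels[pid] in group1)
    d = len(out_cluster) - c
    record["evaluated"] = True
    record["table"] = [[a, b], [c, d]]
    if min(a + b, c + d, a + c, b + d) == 0:
        record.update({"statistic": 0.0, "p_value": 1.0, "degenerate": True})
        return record
    table = np.array([[a, b], [c, d]], dtype=float)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    stat = float(((table - expected) ** 2 / expected).sum())
    p = float(sps.chi2.sf(stat, 1))
    record["low_expected"] = bool((expected < 5).any())
    record["statistic"] = stat
    record["p_value"] = p
    cluster_prop = a / (a + b)
    dataset_prop = c / (c + d) if (c + d) else 0.0
    record["direction"] = "group1" if cluster_prop > dataset_prop else "group2"
    associated = p < alpha and record["direction"] == "group1"
    if strict_exclusive and associated:
        opposing = set(opposing_groups)
        if any(labels[pid] in opposing for pid, _ in in_cluster):
            associated = False
            record["exclusivity_violated"] = True
    record["associated"] = bool(associated)
    return record


# ---------------------------------------------------------------------------
# neighbour joining

def _normalized_levenshtein(a: str, b: str) -> float:
    if not a and not b:
        return 0.0
    return levenshtein_distance(a, b) / max(len(a), len(b))


def neighbor_joining_tree(
    sequences: Mapping[str, str] | Sequence[str],
    distance_matrix: np.ndarray | None = None,
) -> str:
    """Neighbour-joining tree in newick form over labelled sequences.

    Pairwise distance is the Levenshtein distance divided by the longer
    length (no model-based correction); a pre-computed ``distance_matrix``
    may be supplied instead.  Negative branch lengths produced by the
    agglomeration are clamped to zero.
    """
    if isinstance(sequences, Mapping):
        labels = list(sequences.keys())
        seqs = [sequences[k] for k in labels]
    else:
        seqs = list(sequences)
        labels = seqs
    if len(labels) != len(set(labels)):
        raise ValidationError("duplicate sequence labels")
    n = len(labels)
    if n < 2:
        raise ValidationError("neighbor_joining_tree needs >= 2 sequences")
    if distance_matrix is None:
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = _normalized_levenshtein(seqs[i], seqs[j])
    else:
        d = np.asarray(distance_matrix, dtype=float).copy()
        if d.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")

    nodes = [f"{lab}" for lab in labels]  # newick fragments
    active = list(range(n))
    dist = d

    while len(active) > 2:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = divmod(int(np.argmin(q)), m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = sub[i_loc, j_loc]
        li = 0.5 * dij + (totals[i_loc] - totals[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new_row = 0.5 * (dist[i, :] + dist[j, :] - dij)
        dist = np.vstack([dist, new_row])
        new_col = np.append(new_row, 0.0)
        dist = np.column_stack([dist, new_col])
        nodes.append(f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})")
        new_index = dist.shape[0] - 1
        active = [k for k in active if k not in (i, j)] + [new_index]

    i, j = active
    dij = max(dist[i, j], 0.0)
    return f"({nodes[i]}:{dij:.10g},{nodes[j]}:0);"
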