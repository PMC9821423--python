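"""Synthetic-cohort generator with planted ground truth.

Emulates the four pipeline inputs — per-patient clonotype tables, a
curated reference-annotation table, a clinical table and a flow-marker
abundance table — for a 47-patient cohort in four prognosis groups
(4/16/13/14 by default).  Planted structure: per-group power-law clone
frequencies (steeper in poor/worst, hence lower entropy and higher
top-100 frequency), group-exclusive motif-sharing clone clusters,
reference-matching clones densest in the excellent group, group-shifted
flow markers (higher CD8 and lower Treg in poor/worst) and per-group
exponential survival with administrative censoring.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import CATEGORIES, ReferenceRecord
from .errors import ValidationError
from .motifs import SpecificityCluster
from .repertoire import AA_ALPHABET, Clonotype, Repertoire
from .stats import GROUP_ORDER, derive_prognosis_label

__all__ = [
    "PlantedClusterSpec",
    "CohortConfig",
    "PlantedTruth",
    "SyntheticCohort",
    "generate_reference_db",
    "generate_reference_repertoire",
    "generate_cohort",
    "truth_report",
    "SENTINEL_CDR3",
    "SENTINEL_EPITOPE",
]

#: fixed sentinel reference record used by end-to-end tests
SENTINEL_CDR3 = "CASSLVNTEAFF"
SENTINEL_EPITOPE = "RCSDSDGLAPPQNLIRVEGNLRVEY"

_DEFAULT_CATEGORY_PROPS = (0.68, 0.16, 0.13, 0.027, 0.003)

_PATHOLOGIES = {
    "pathogens": ["Influenza", "Cytomegalovirus", "Epstein-Barr virus",
                  "M. tuberculosis", "HIV"],
    "cancer": ["Epithelial ovarian cancer", "Melanoma", "NSCLC",
               "Colorectal cancer"],
    "autoimmune": ["Type 1 diabetes", "Multiple sclerosis", "Celiac disease"],
    "allergy": ["Peanut allergy", "Birch pollen"],
    "other": ["Unclassified"],
}

_EPITOPE_GENES = {
    "pathogens": ["M1", "BMLF1", "pp65", "ESAT6", "Gag"],
    "cancer": ["TP53", "TEAD1", "MLANA", "NY-ESO-1", "PMEL", "IGF2BP2"],
    "autoimmune": ["INS", "MBP", "GAD2"],
    "allergy": ["ARA-H2", "BETV1"],
    "other": [""],
}


def _random_cdr3(rng: np.random.Generator, min_len: int = 10,
                 max_len: int = 17) -> str:
    length = int(rng.integers(min_len, max_len + 1))
    middle = "".join(rng.choice(list(AA_ALPHABET), size=length - 2))
    return "C" + middle + "F"


def _random_v(rng):
    return f"TCRBV{int(rng.integers(1, 31)):02d}-0{int(rng.integers(1, 3))}*0{int(rng.integers(1, 3))}"


def _random_j(rng):
    return f"TCRBJ0{int(rng.integers(1, 3))}-0{int(rng.integers(1, 8))}*01"


@dataclass(frozen=True)
class PlantedClusterSpec:
    """A motif-sharing clone family confined to the given groups.

    Members are copies of ``base`` mutated at one of ``variable_positions``
    (0-based; keep them outside the interior region used for motif
    extraction at position < 3 or inside it for wildcard demonstrations).
    """

    name: str
    base: str
    groups: tuple[str, ...]
    carrier_fraction: float = 0.6
    variable_positions: tuple[int, ...] = (2, 5)


def _default_planted_clusters() -> list[PlantedClusterSpec]:
    return [
        PlantedClusterSpec("exc_tp53", SENTINEL_CDR3, ("excellent",), 0.8),
        PlantedClusterSpec("exc_b", "CASRGDWQPQHF", ("excellent",), 0.75),
        PlantedClusterSpec("exc_c", "CAWMDHENYGYTF", ("excellent",), 0.75),
        PlantedClusterSpec("pw_a", "CATSEYKKMNEKLF", ("poor", "worst"), 0.5),
        PlantedClusterSpec("pw_b", "CASIPGQGFYGYTF", ("poor", "worst"), 0.5),
        PlantedClusterSpec("pw_c", "CAIRHQDCVKWHQF", ("poor", "worst"), 0.5),
    ]


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort; identical seed => identical cohort."""

    group_sizes: dict = field(default_factory=lambda: {
        "worst": 4, "poor": 16, "good": 13, "excellent": 14})
    clones_per_patient: int = 150
    total_templates: int = 450
    power_exponents: dict = field(default_factory=lambda: {
        "worst": 1.2, "poor": 1.1, "good": 0.6, "excellent": 0.5})
    planted_clusters: list = field(default_factory=_default_planted_clusters)
    # expected planted db-matching clones per patient, by group and category
    annotation_rates: dict = field(default_factory=lambda: {
        "worst": {"cancer": 1.0}, "poor": {"cancer": 1.0},
        "good": {"cancer": 2.0}, "excellent": {"cancer": 4.0}})
    background_annotation_rate: float = 1.0
    survival_hazards: dict = field(default_factory=lambda: {
        "worst": 0.09, "poor": 0.05, "good": 0.025, "excellent": 0.012})
    censor_horizon: float = 60.0
    flow_effects: dict = field(default_factory=lambda: {
        "cd8": {"worst": 1.6, "poor": 1.5, "good": 1.0, "excellent": 0.75},
        "cd4_foxp3": {"worst": 0.6, "poor": 0.65, "good": 1.0,
                      "excellent": 1.35}})
    n_reference_records: int = 400
    reference_repertoire_size: int = 10000
    seed: int = 0

    def validate(self):
        if any(v <= 0 for v in self.group_sizes.values()):
            raise ValidationError("group sizes must be positive")
        if set(self.group_sizes) != set(GROUP_ORDER):
            raise ValidationError(f"group_sizes must cover {GROUP_ORDER}")
        for spec in self.planted_clusters:
            unknown = set(spec.groups) - set(self.group_sizes)
            if unknown:
                raise ValidationError(
                    f"planted cluster {spec.name!r}: unknown group(s) {unknown}")
            if not 0.0 <= spec.carrier_fraction <= 1.0:
                raise ValidationError("carrier_fraction must be in [0, 1]")


@dataclass
class PlantedTruth:
    """Ground truth recorded alongside an emitted cohort."""

    labels: dict                # patient -> group
    clusters: dict              # name -> {"groups": [...], "members": [[pid, pep]]}
    planted_annotations: dict   # patient -> {category: count}
    survival_hazards: dict
    seed: int

    def to_json(self) -> str:
        payload = {
            "labels": self.labels,
            "clusters": {
                name: {"groups": list(info["groups"]),
                       "members": sorted(map(list, info["members"]))}
                for name, info in self.clusters.items()},
            "planted_annotations": self.planted_annotations,
            "survival_hazards": self.survival_hazards,
            "seed": self.seed,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        payload = json.loads(text)
        clusters = {
            name: {"groups": tuple(info["groups"]),
                   "members": {tuple(m) for m in info["members"]}}
            for name, info in payload["clusters"].items()}
        return cls(labels=payload["labels"], clusters=clusters,
                   planted_annotations=payload["planted_annotations"],
                   survival_hazards=payload["survival_hazards"],
                   seed=payload["seed"])


@dataclass
class SyntheticCohort:
    """In-memory cohort bundle plus writers for the on-disk formats."""

    repertoires: list
    clinical: pd.DataFrame
    flow: pd.DataFrame
    reference_db: list
    cd4_reference: list
    cd8_reference: list
    truth: PlantedTruth
    config: CohortConfig

    def labels(self) -> dict[str, str]:
        return dict(self.truth.labels)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        rep_dir = outdir / "repertoires"
        rep_dir.mkdir(parents=True, exist_ok=True)
        for rep in self.repertoires:
            rows = [{
                "amino_acid": c.cdr3_aa, "v_resolved": c.v_gene,
                "d_resolved": c.d_gene, "j_resolved": c.j_gene,
                "templates": c.templates,
                "frame_type": {"in": "In", "out": "Out", "stop": "Stop"}[c.frame],
            } for c in rep.clonotypes]
            pd.DataFrame(rows).to_csv(rep_dir / f"{rep.patient_id}.tsv",
                                      sep="\t", index=False)
        self.clinical.to_csv(outdir / "clinical.csv", index=False)
        self.flow.to_csv(outdir / "flow.csv", index=True, index_label="patient_id")
        db_rows = [dataclasses.asdict(r) for r in self.reference_db]
        pd.DataFrame(db_rows).to_csv(outdir / "reference_db.tsv", sep="\t",
                                     index=False)
        for name, seqs in (("cd4_reference.txt", self.cd4_reference),
                           ("cd8_reference.txt", self.cd8_reference)):
            (outdir / name).write_text("\n".join(seqs) + "\n")
        (outdir / "truth.json").write_text(self.truth.to_json() + "\n")


def generate_reference_db(
    n_records: int = 400,
    category_props: Sequence[float] = _DEFAULT_CATEGORY_PROPS,
    seed: int | None = None,
) -> list[ReferenceRecord]:
    """Random CDR3-like reference records with multinomial category
    assignment, plus the fixed sentinel ovarian-cancer/TP53 record."""
    props = np.asarray(category_props, dtype=float)
    if abs(props.sum() - 1.0) > 1e-6:
        raise ValidationError("category proportions must sum to 1")
    if n_records < len(CATEGORIES):
        raise ValidationError("n_records smaller than the number of categories")
    rng = np.random.default_rng(seed)
    assignments = rng.choice(len(CATEGORIES), size=n_records - 1, p=props)
    records = [ReferenceRecord(
        cdr3_aa=SENTINEL_CDR3, category="cancer",
        pathology="Epithelial ovarian cancer",
        epitope_peptide=SENTINEL_EPITOPE, epitope_gene="TP53")]
    seen = {SENTINEL_CDR3}
    for a in assignments:
        category = CATEGORIES[a]
        cdr3 = _random_cdr3(rng)
        while cdr3 in seen:
            cdr3 = _random_cdr3(rng)
        seen.add(cdr3)
        records.append(ReferenceRecord(
            cdr3_aa=cdr3,
            category=category,
            pathology=str(rng.choice(_PATHOLOGIES[category])),
            epitope_peptide=_random_cdr3(rng, 9, 15),
            epitope_gene=str(rng.choice(_EPITOPE_GENES[category])),
        ))
    return records


def generate_reference_repertoire(n: int = 5000, seed: int | None = None,
                                  flavor: str = "cd4") -> list[str]:
    """A naive CDR3 reference list (distinct seeds per flavor)."""
    offset = {"cd4": 0, "cd8": 1}.get(flavor)
    if offset is None:
        raise ValidationError(f"unknown reference flavor {flavor!r}")
    rng = np.random.default_rng(None if seed is None else seed * 2 + offset)
    alphabet = np.array(list(AA_ALPHABET))
    lengths = rng.integers(10, 18, size=n)
    chars = rng.integers(0, len(alphabet), size=(n, 16))
    return ["C" + "".join(alphabet[chars[i, :lengths[i] - 2]]) + "F"
            for i in range(n)]


def _mutate(rng: np.random.Generator, base: str, pos: int) -> str:
    choices = [c for c in AA_ALPHABET if c != base[pos]]
    return base[:pos] + str(rng.choice(choices)) + base[pos + 1:]


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort with recorded planted truth."""
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    patients = []
    for group in GROUP_ORDER:
        for _ in range(config.group_sizes[group]):
            patients.append((f"P{len(patients) + 1:02d}", group))
    labels = {pid: grp for pid, grp in patients}

    reference_db = generate_reference_db(
        config.n_reference_records, seed=config.seed + 101)
    db_by_category: dict[str, list[ReferenceRecord]] = {}
    for rec in reference_db:
        db_by_category.setdefault(rec.category, []).append(rec)

    cd4_reference = generate_reference_repertoire(
        config.reference_repertoire_size, seed=config.seed + 211, flavor="cd4")
    cd8_reference = generate_reference_repertoire(
        config.reference_repertoire_size, seed=config.seed + 211, flavor="cd8")

    # ---- planted motif clusters --------------------------------------
    truth_clusters: dict[str, dict] = {}
    planted_clones: dict[str, list[Clonotype]] = {pid: [] for pid, _ in patients}
    for spec in config.planted_clusters:
        carriers = []
        for group in spec.groups:
            pool = [pid for pid, grp in patients if grp == group]
            n_carriers = max(1, int(round(spec.carrier_fraction * len(pool))))
            chosen = rng.choice(pool, size=n_carriers, replace=False)
            carriers.extend(sorted(chosen))
        members = set()
        for idx, pid in enumerate(carriers):
            if idx == 0:
                seq = spec.base  # anchor the unmutated base sequence
            else:
                pos = int(rng.choice(spec.variable_positions))
                seq = _mutate(rng, spec.base, pos)
            members.add((pid, seq))
            planted_clones[pid].append(Clonotype(
                cdr3_aa=seq, v_gene=_random_v(rng), d_gene="unresolved",
                j_gene="TCRBJ01-01*01", templates=int(rng.integers(2, 9)),
                frame="in"))
        truth_clusters[spec.name] = {"groups": spec.groups, "members": members}

    # ---- planted database-matching clones ----------------------------
    planted_annotations: dict[str, dict[str, int]] = {}
    for pid, group in patients:
        per_cat: dict[str, int] = {}
        for category, rate in config.annotation_rates.get(group, {}).items():
            pool = db_by_category.get(category, [])
            n_planted = int(rng.poisson(rate))
            if not pool or n_planted == 0:
                continue
            recs = rng.choice(len(pool), size=min(n_planted, len(pool)),
                              replace=False)
            for ridx in recs:
                rec = pool[int(ridx)]
                planted_clones[pid].append(Clonotype(
                    cdr3_aa=rec.cdr3_aa, v_gene=_random_v(rng),
                    d_gene="unresolved", j_gene=_random_j(rng),
                    templates=int(rng.integers(1, 4)), frame="in"))
                per_cat[category] = per_cat.get(category, 0) + 1
        n_bg = int(rng.poisson(config.background_annotation_rate))
        for _ in range(n_bg):
            rec = reference_db[int(rng.integers(0, len(reference_db)))]
            planted_clones[pid].append(Clonotype(
                cdr3_aa=rec.cdr3_aa, v_gene=_random_v(rng),
                d_gene="unresolved", j_gene=_random_j(rng),
                templates=int(rng.integers(1, 4)), frame="in"))
            per_cat[rec.category] = per_cat.get(rec.category, 0) + 1
        planted_annotations[pid] = per_cat

    # ---- repertoires --------------------------------------------------
    repertoires = []
    for pid, group in patients:
        alpha = config.power_exponents[group]
        n_clones = config.clones_per_patient
        freqs = np.arange(1, n_clones + 1, dtype=float) ** (-alpha)
        freqs /= freqs.sum()
        counts = rng.multinomial(config.total_templates, freqs)
        seen: set[str] = {c.cdr3_aa for c in planted_clones[pid]}
        clones = list(planted_clones[pid])
        for count in counts:
            if count == 0:
                continue
            cdr3 = _random_cdr3(rng)
            while cdr3 in seen:
                cdr3 = _random_cdr3(rng)
            seen.add(cdr3)
            clones.append(Clonotype(
                cdr3_aa=cdr3, v_gene=_random_v(rng), d_gene="unresolved",
                j_gene=_random_j(rng), templates=int(count), frame="in"))
        # a little nonproductive noise so the frame filter is exercised
        for frame in ("out", "stop"):
            clones.append(Clonotype(
                cdr3_aa=_random_cdr3(rng), v_gene=_random_v(rng),
                d_gene="unresolved", j_gene=_random_j(rng),
                templates=int(rng.integers(1, 5)), frame=frame))
        repertoires.append(Repertoire(patient_id=pid, clonotypes=clones))

    # ---- clinical / survival -----------------------------------------
    clin_rows = []
    for pid, group in patients:
        if group == "worst":
            rfs = float(rng.uniform(1.0, 5.5))
            responded = False
        elif group == "poor":
            rfs = float(rng.uniform(1.0, 5.5))
            responded = True
        elif group == "good":
            rfs = float(rng.uniform(6.0, 12.0))
            responded = True
        else:
            rfs = float(rng.uniform(12.5, 48.0))
            responded = True
        assert derive_prognosis_label(pid, rfs, responded).label == group
        hazard = config.survival_hazards[group]
        raw = float(rng.exponential(1.0 / hazard))
        event = raw <= config.censor_horizon
        os_months = min(raw, config.censor_horizon)
        clin_rows.append({
            "patient_id": pid, "rfs_months": round(rfs, 2),
            "responded": responded,
            "os_months": round(max(os_months, 0.1), 2), "os_event": event,
            "debulking": str(rng.choice(["optimal", "suboptimal"],
                                        p=[0.7, 0.3])),
        })
    clinical = pd.DataFrame(clin_rows)

    # ---- flow markers -------------------------------------------------
    base_means = {"cd8": 30.0, "cd4": 40.0, "cd4_foxp3": 5.0, "pd1": 10.0,
                  "icos": 5.0, "ki67": 8.0, "ctla4": 3.0}
    flow_rows = {}
    for pid, group in patients:
        row = {}
        for marker, mean in base_means.items():
            shift = config.flow_effects.get(marker, {}).get(group, 1.0)
            row[marker] = float(mean * shift * rng.lognormal(0.0, 0.3))
        flow_rows[pid] = row
    flow = pd.DataFrame(flow_rows).T
    flow.index.name = "patient_id"

    truth = PlantedTruth(
        labels=labels, clusters=truth_clusters,
        planted_annotations=planted_annotations,
        survival_hazards=dict(config.survival_hazards), seed=config.seed)
    return SyntheticCohort(
        repertoires=repertoires, clinical=clinical, flow=flow,
        reference_db=reference_db, cd4_reference=cd4_reference,
        cd8_reference=cd8_reference, truth=truth, config=config)


# ---------------------------------------------------------------------------
# recovery metrics

def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def truth_report(
    truth: PlantedTruth,
    clusters: Sequence[SpecificityCluster],
    associations: Mapping[str, Mapping[str, dict]],
    jaccard_min: float = 0.5,
    cox_hr: float | None = None,
) -> dict:
    """Match planted clusters to recovered clusters (member-set Jaccard
    >= ``jaccard_min``) and summarise recovery and association accuracy.

    ``associations`` maps cluster_id -> direction name ("excellent" /
    "poor_worst") -> association record from the contingency test.
    """
    known = set(truth.labels)
    for cluster in clusters:
        stray = {pid for pid, _ in cluster.members} - known
        if stray:
            raise ValidationError(f"cluster patients not in cohort: {sorted(stray)}")

    cluster_by_id = {c.cluster_id: c for c in clusters}
    per_planted = {}
    n_recovered = 0
    n_correct = 0
    for name, info in truth.clusters.items():
        planted_members = set(info["members"])
        best_id, best_j = None, 0.0
        for c in clusters:
            j = _jaccard(planted_members, c.members)
            if j > best_j:
                best_id, best_j = c.cluster_id, j
        recovered = best_j >= jaccard_min
        expected_dir = ("excellent" if set(info["groups"]) <= {"excellent", "good"}
                        else "poor_worst")
        correct = False
        if recovered:
            n_recovered += 1
            rec = associations.get(best_id, {}).get(expected_dir)
            correct = bool(rec and rec.get("associated"))
            if correct:
                n_correct += 1
        per_planted[name] = {"matched_cluster": best_id, "jaccard": best_j,
                             "recovered": recovered,
                             "associated_correctly": correct}

    matched_ids = set()
    for name, info in truth.clusters.items():
        planted_members = set(info["members"])
        for c in clusters:
            if _jaccard(planted_members, c.members) >= jaccard_min:
                matched_ids.add(c.cluster_id)

    associated_ids = {
        cid for cid, by_dir in associations.items()
        if any(rec.get("associated") for rec in by_dir.values())}
    evaluated_ids = {
        cid for cid, by_dir in associations.items()
        if any(rec.get("evaluated") for rec in by_dir.values())}
    false_pos = associated_ids - matched_ids
    n_planted = len(truth.clusters)
    report = {
        "n_planted": n_planted,
        "n_recovered": n_recovered,
        "sensitivity": (n_correct / n_planted) if n_planted else float("nan"),
        "recovery_rate": (n_recovered / n_planted) if n_planted else float("nan"),
        "n_evaluated": len(evaluated_ids),
        "n_associated": len(associated_ids),
        "n_false_positive": len(false_pos),
        "fdr": (len(false_pos) / len(associated_ids)) if associated_ids else 0.0,
        "per_planted": per_planted,
    }
    if cox_hr is not None:
        hazards = truth.survival_hazards
        true_hr = (np.mean([hazards["worst"], hazards["poor"]])
                   / np.mean([hazards["good"], hazards["excellent"]]))
        report["cox_hr_fitted"] = float(cox_hr)
        report["cox_hr_true"] = float(true_hr)
    return report
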