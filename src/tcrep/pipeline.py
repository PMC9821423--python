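"""End-to-end pipeline: repertoire stats, flow clustering, survival
screen, peptide association, annotation/enrichment, specificity-group
clustering per reference, cluster-prognosis association, association
networks, and (for synthetic cohorts) planted-truth recovery metrics.

Every stage writes its artifacts under the configured output directory
and contributes to a single machine-readable ``report.json``.  All
randomness derives from the configured seed, and floating-point output
is formatted at fixed precision, so re-running with the same
configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from . import annotation as ann
from . import motifs as mot
from . import network as net
from . import simulate as sim
from . import stats as cstats
from . import survival as surv
from .errors import TcrepError, ValidationError
from .repertoire import cohort_stats_table, parse_immunoseq_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

FLOAT_FORMAT = "%.10g"


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration.

    Exactly one of ``inputs`` (paths to real data) or ``synthetic``
    (cohort-generator overrides) must be provided.
    """

    outdir: str = "tcrep_out"
    seed: int = 0
    inputs: dict | None = None
    synthetic: dict | None = None
    thresholds: dict = field(default_factory=dict)

    DEFAULT_THRESHOLDS = {
        "levenshtein_max": 1,
        "read_cutoff": 2,          # templates required (strictly more than 1 read)
        "cluster_min_subjects": 4,
        "alpha": 0.05,
        "network_r": 0.60,
        "minprop": 0.1,
        "prevalence_cutoff": 0.75,
        "cutpoint_permutations": 200,
        "gap_b_refs": 25,
        "motif_resamples": 1000,
    }

    def __post_init__(self):
        if (self.inputs is None) == (self.synthetic is None):
            raise ValidationError(
                "exactly one of 'inputs' and 'synthetic' must be configured")
        unknown = set(self.thresholds) - set(self.DEFAULT_THRESHOLDS)
        if unknown:
            raise ValidationError(f"unknown threshold key(s): {sorted(unknown)}")
        merged = dict(self.DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        if not 0 < merged["alpha"] < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if not 0 < merged["minprop"] < 0.5:
            raise ValidationError("minprop must be in (0, 0.5)")
        if merged["levenshtein_max"] not in (0, 1):
            raise ValidationError("levenshtein_max must be 0 or 1")
        self.thresholds = merged

    @classmethod
    def from_dict(cls, payload: Mapping[str, Any]) -> "PipelineConfig":
        allowed = {"outdir", "seed", "inputs", "synthetic", "thresholds"}
        unknown = set(payload) - allowed
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**dict(payload))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                               default=_json_default) + "\n")


def _write_tsv(path: Path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def _load_inputs(config: PipelineConfig):
    paths = config.inputs
    required = {"repertoire_dir", "reference_db", "clinical", "flow",
                "cd4_reference", "cd8_reference"}
    missing = required - set(paths)
    if missing:
        raise ValidationError(f"inputs missing key(s): {sorted(missing)}")
    rep_dir = Path(paths["repertoire_dir"])
    reps = [parse_immunoseq_table(p, p.stem)
            for p in sorted(rep_dir.glob("*.tsv"))]
    if not reps:
        raise ValidationError(f"no repertoire TSVs under {rep_dir}")
    clinical = pd.read_csv(paths["clinical"])
    flow = pd.read_csv(paths["flow"], index_col="patient_id")
    db = ann.load_reference_db(paths["reference_db"])
    cd4 = Path(paths["cd4_reference"]).read_text().split()
    cd8 = Path(paths["cd8_reference"]).read_text().split()
    return reps, clinical, flow, db, cd4, cd8, None


def _load_synthetic(config: PipelineConfig):
    overrides = dict(config.synthetic)
    overrides.setdefault("seed", config.seed)
    known = {f.name for f in dataclasses.fields(sim.CohortConfig)}
    unknown = set(overrides) - known
    if unknown:
        raise ValidationError(f"unknown synthetic key(s): {sorted(unknown)}")
    cohort = sim.generate_cohort(sim.CohortConfig(**overrides))
    return (cohort.repertoires, cohort.clinical, cohort.flow,
            cohort.reference_db, cohort.cd4_reference, cohort.cd8_reference,
            cohort)


def _labels_from_clinical(clinical: pd.DataFrame) -> dict[str, str]:
    labels = {}
    for _, row in clinical.iterrows():
        lab = cstats.derive_prognosis_label(
            str(row["patient_id"]), float(row["rfs_months"]),
            bool(row["responded"]))
        labels[lab.patient_id] = lab.label
    return labels


def _stage_motifs(reps, labels, reference, ref_name, thresholds, seed, outdir):
    members = mot.clustering_input(reps, min_templates=thresholds["read_cutoff"])
    peptides = sorted({pep for _, pep in members})
    hits = mot.enriched_motifs(
        peptides, reference, n_resamples=thresholds["motif_resamples"],
        seed=seed)
    clusters = mot.build_specificity_clusters(members, hits)
    associations = {}
    rows = []
    for cluster in clusters:
        by_dir = {
            "excellent": mot.cluster_prognosis_association(
                cluster, labels, {"excellent"}, members,
                min_subjects=thresholds["cluster_min_subjects"],
                alpha=thresholds["alpha"]),
            "poor_worst": mot.cluster_prognosis_association(
                cluster, labels, {"poor", "worst"}, members,
                min_subjects=thresholds["cluster_min_subjects"],
                alpha=thresholds["alpha"]),
        }
        associations[cluster.cluster_id] = by_dir
        direction = None
        p_best = None
        for name, rec in by_dir.items():
            if rec.get("associated"):
                if p_best is None or rec["p_value"] < p_best:
                    direction, p_best = name, rec["p_value"]
        rows.append({
            "cluster_id": cluster.cluster_id,
            "pattern": cluster.pattern.pattern,
            "subjects": cluster.subjects,
            "n_members": len(cluster.members),
            "members": ";".join(f"{pid}:{pep}"
                                for pid, pep in sorted(cluster.members)),
            "evaluated": by_dir["excellent"]["evaluated"],
            "p_excellent": by_dir["excellent"].get("p_value"),
            "p_poor_worst": by_dir["poor_worst"].get("p_value"),
            "associated_direction": direction or "",
        })
    table = pd.DataFrame(rows, columns=[
        "cluster_id", "pattern", "subjects", "n_members", "members",
        "evaluated", "p_excellent", "p_poor_worst", "associated_direction"])
    _write_tsv(outdir / f"clusters_{ref_name}.tsv", table)

    associated = [c for c in clusters
                  if any(r.get("associated")
                         for r in associations[c.cluster_id].values())]
    tree_dir = outdir / f"clusters_{ref_name}_detail"
    tree_dir.mkdir(exist_ok=True)
    for cluster in associated[:10]:
        peps = sorted(cluster.peptides)
        if len(peps) >= 2:
            newick = mot.neighbor_joining_tree(peps)
            (tree_dir / f"{cluster.cluster_id}.nwk").write_text(newick + "\n")
        _, pfm = mot.cluster_pattern(peps)
        pfm_df = pd.DataFrame(pfm).fillna(0).astype(int).T
        pfm_df.index.name = "position"
        _write_tsv(tree_dir / f"{cluster.cluster_id}_pfm.tsv", pfm_df,
                   index=True)
    return members, clusters, associations, associated


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the aggregated report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = config.thresholds
    report: dict[str, Any] = {"seed": config.seed, "thresholds": thresholds}

    if config.synthetic is not None:
        reps, clinical, flow, db, cd4_ref, cd8_ref, cohort = \
            _load_synthetic(config)
    else:
        reps, clinical, flow, db, cd4_ref, cd8_ref, cohort = \
            _load_inputs(config)
    labels = _labels_from_clinical(clinical)
    _write_json(outdir / "resolved_config.json", {
        "seed": config.seed, "thresholds": thresholds,
        "mode": "synthetic" if config.synthetic is not None else "inputs"})

    # 1. repertoire stats -------------------------------------------------
    stats_table = cohort_stats_table(reps)
    _write_tsv(outdir / "cohort_stats.tsv", stats_table)
    report["n_patients"] = int(len(stats_table))

    # 2. flow clustering and marker tests --------------------------------
    flow_cd8treg = cstats.add_cd8_treg(flow)
    flow_result = cstats.cluster_flow_profiles(
        flow_cd8treg.drop(columns=["cd8_treg"]),
        b_refs=thresholds["gap_b_refs"], seed=config.seed + 11)
    _write_tsv(outdir / "flow_clusters.tsv",
               flow_result["labels"].to_frame(), index=True)
    marker_rows = []
    for marker in flow_cd8treg.columns:
        groups = [
            flow_cd8treg.loc[[p for p in flow_cd8treg.index
                              if labels[p] == g], marker].dropna().tolist()
            for g in cstats.GROUP_ORDER]
        groups = [g for g in groups if g]
        kw = cstats.kruskal_wallis(groups)
        marker_rows.append({"marker": marker, "kw_statistic": kw["statistic"],
                            "kw_p": kw["p_value"]})
    _write_tsv(outdir / "flow_marker_tests.tsv", pd.DataFrame(marker_rows))
    report["flow_k"] = int(flow_result["k"])

    # 3. survival screen --------------------------------------------------
    records = [
        surv.SurvivalRecord(
            patient_id=str(row["patient_id"]), time=float(row["os_months"]),
            event=bool(row["os_event"]),
            covariates={"debulking_suboptimal":
                        float(row["debulking"] == "suboptimal")})
        for _, row in clinical.iterrows()]
    km = surv.km_estimate(records, groups=labels)
    km_table = pd.concat(
        [df.assign(group=name) for name, df in sorted(km.items())],
        ignore_index=True)
    _write_tsv(outdir / "km_by_prognosis.tsv", km_table)
    logrank = surv.log_rank_test(records, labels)
    report["logrank_prognosis_p"] = logrank["p_value"]

    stats_by_pid = stats_table.set_index("patient_id")
    cutpoints = {}
    biomarkers = {
        "productive_entropy_bits":
            stats_by_pid["productive_entropy_bits"].to_dict(),
        "cd8_treg": flow_cd8treg["cd8_treg"].dropna().to_dict(),
    }
    for i, (name, values) in enumerate(sorted(biomarkers.items())):
        try:
            cutpoints[name] = surv.optimal_cutpoint(
                values, records, minprop=thresholds["minprop"],
                n_permutations=thresholds["cutpoint_permutations"],
                seed=config.seed + 23 + i)
        except ValidationError as exc:
            cutpoints[name] = {"error": str(exc)}
    _write_json(outdir / "cutpoints.json", cutpoints)

    cox_records = []
    for r in records:
        cov = dict(r.covariates)
        cov["entropy"] = float(stats_by_pid.loc[r.patient_id,
                                                "productive_entropy_bits"])
        cov["unfavorable"] = float(labels[r.patient_id] in
                                   cstats.UNFAVORABLE_GROUPS)
        cox_records.append(surv.SurvivalRecord(
            r.patient_id, r.time, r.event, cov))
    try:
        cox = surv.cox_ph_fit(cox_records,
                              ["unfavorable", "debulking_suboptimal"])
        _write_tsv(outdir / "cox_coefficients.tsv", cox["table"])
        report["cox_lr_p"] = cox["lr_p"]
        report["cox_hr_unfavorable"] = float(
            cox["table"].set_index("covariate").loc["unfavorable",
                                                    "hazard_ratio"])
    except TcrepError as exc:
        report["cox_error"] = str(exc)

    # 4. per-peptide prognosis association -------------------------------
    peptide_table = cstats.peptide_prognosis_association(
        reps, labels, alpha=thresholds["alpha"])
    _write_tsv(outdir / "peptide_associations.tsv", peptide_table)
    report["n_associated_peptides"] = int(peptide_table["associated"].sum())

    # 5. annotation and enrichment ---------------------------------------
    fuzzy_hits = ann.annotate_cohort(
        reps, db, mode="fuzzy", max_dist=thresholds["levenshtein_max"])
    exact_hits = ann.annotate_cohort(reps, db, mode="exact")
    hit_rows = [{
        "patient_id": h.patient_id, "cdr3_aa": h.cdr3_aa,
        "db_cdr3_aa": h.record.cdr3_aa, "category": h.record.category,
        "pathology": h.record.pathology, "epitope_gene": h.record.epitope_gene,
        "edit_distance": h.edit_distance, "mode": h.mode,
    } for h in fuzzy_hits + exact_hits]
    _write_tsv(outdir / "annotation_hits.tsv", pd.DataFrame(hit_rows))
    if fuzzy_hits:
        enrichment = ann.category_enrichment(fuzzy_hits)
        _write_json(outdir / "category_enrichment.json", enrichment)
        report["enrichment_p"] = enrichment["p_value"]
        report["cancer_proportion"] = \
            enrichment["observed_proportions"]["cancer"]
    conditions = ann.condition_prognosis_test(
        fuzzy_hits, reps, labels, alpha=thresholds["alpha"])
    _write_tsv(outdir / "condition_tests.tsv",
               conditions.drop(columns=["dunn"]))
    group_freq = ann.cancer_match_group_frequency(exact_hits, labels)
    _write_tsv(outdir / "cancer_group_frequency.tsv", group_freq)
    report["cancer_group_frequency"] = {
        row["group"]: row["frequency"] for _, row in group_freq.iterrows()}
    gene_matrix = ann.epitope_gene_matrix(
        exact_hits, labels, prevalence_cutoff=thresholds["prevalence_cutoff"])
    _write_tsv(outdir / "epitope_gene_matrix.tsv", gene_matrix, index=True)
    usage = ann.vj_usage(reps)
    _write_tsv(outdir / "v_usage.tsv", usage["v_gene"], index=True)
    _write_tsv(outdir / "j_usage.tsv", usage["j_gene"], index=True)

    # 6-7. specificity clustering and networks, per reference ------------
    report["references"] = {}
    truth_inputs = {}
    for ref_name, reference in (("cd4", cd4_ref), ("cd8", cd8_ref)):
        members, clusters, associations, associated = _stage_motifs(
            reps, labels, reference, ref_name, thresholds,
            seed=config.seed + 31, outdir=outdir)
        ref_report = {
            "n_clusters": len(clusters),
            "n_evaluated": sum(
                1 for by_dir in associations.values()
                if any(r.get("evaluated") for r in by_dir.values())),
            "n_associated": len(associated),
        }
        if associated:
            matrix = net.membership_matrix(associated, sorted(labels))
            graph = net.build_network(matrix, labels,
                                      r_threshold=thresholds["network_r"])
            edges = pd.DataFrame(
                [{"a": a, "b": b, "r": d["r"]}
                 for a, b, d in graph.edges(data=True)],
                columns=["a", "b", "r"]).sort_values(["a", "b"])
            _write_tsv(outdir / f"network_{ref_name}_edges.tsv", edges)
            nx.write_graphml(graph, outdir / f"network_{ref_name}.graphml")
            if graph.number_of_edges() > 0:
                ref_report["assortativity"] = net.prognosis_assortativity(graph)
        report["references"][ref_name] = ref_report
        truth_inputs[ref_name] = (clusters, associations)

    # 8. planted-truth recovery ------------------------------------------
    if cohort is not None:
        clusters, associations = truth_inputs["cd4"]
        recovery = sim.truth_report(
            cohort.truth, clusters, associations,
            cox_hr=report.get("cox_hr_unfavorable"))
        _write_json(outdir / "truth_report.json", recovery)
        report["truth"] = {k: recovery[k] for k in
                           ("sensitivity", "recovery_rate", "fdr",
                            "n_evaluated", "n_associated")}

    _write_json(outdir / "report.json", report)
    return report
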