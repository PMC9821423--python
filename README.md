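# tcrep

TCR-repertoire prognosis analysis toolkit for ascites/tumor cohorts:

- **Repertoire metrics** — parse immunoSEQ-style clonotype TSVs, restrict to
  productive rearrangements and compute productive rearrangements/templates,
  Shannon entropy (bits), clonality and max/top-10/top-100 productive
  frequencies (`tcrep.repertoire`).
- **Antigen annotation** — match cohort CDR3β peptides against a curated
  reference table (McPAS-like fuzzy matching at Levenshtein distance ≤ 1,
  VDJdb-like exact matching), with functional-category enrichment against a
  database background, per-condition Kruskal–Wallis/Dunn prognosis tests,
  per-group cancer-match frequencies, epitope-gene presence matrices and V/J
  usage (`tcrep.annotation`).
- **Specificity grouping** — GLIPH-style clustering of >1-read CDR3β peptides
  via enriched interior k-mers (size-matched reference resampling) plus
  equal-length Hamming-1 neighbours; wildcard patterns (e.g. `CA%SL%NTEAFF`),
  position-frequency matrices, neighbour-joining trees (uncorrected
  normalized edit distance, newick output) and 2×2 chi-square
  cluster–prognosis association for clusters with ≥ 4 subjects
  (`tcrep.motifs`).
- **Cohort statistics** — tie-corrected Kruskal–Wallis, Dunn post-hoc, Fisher
  exact (hypergeometric enumeration), chi-square goodness of fit, Pearson
  correlation, per-peptide prognosis association, and hierarchical clustering
  of log2/z-scored flow-marker profiles with gap-statistic model selection
  (`tcrep.stats`).
- **Survival** — Kaplan–Meier, k-sample log-rank, maximally selected
  log-rank cutpoints with permutation p-values, Cox proportional hazards
  (Breslow ties, Newton–Raphson) (`tcrep.survival`).
- **Association networks** — patient–patient networks from shared
  prognosis-associated clusters (Pearson r ≥ 0.60 on binary membership
  profiles) with label assortativity (`tcrep.network`).
- **Synthetic cohorts** — a fully seeded generator that emits all four input
  formats for a 47-patient cohort (groups 4/16/13/14) with planted ground
  truth: per-group power-law clone frequencies, group-exclusive motif
  clusters, reference-matching clones enriched in the excellent group,
  shifted flow markers and per-group survival hazards (`tcrep.simulate`).

## Tests

```bash
python -m pytest -q tests/                 # full suite incl. acceptance
python -m pytest -q tests/ --ignore=tests/test_acceptance.py   # fast subset
```

## CLI

```bash
# generate a synthetic cohort (repertoires/, clinical.csv, flow.csv,
# reference_db.tsv, cd4/cd8 reference lists, truth.json)
tcrep simulate --seed 1 --outdir sim/

# run the full pipeline on it (stats → flow clustering → survival screen →
# peptide association → annotation/enrichment → specificity clustering per
# reference → cluster association → networks → truth recovery report)
tcrep run --indir sim/ --seed 1 --outdir out/

# print the headline numbers from out/report.json
tcrep report --outdir out/
```

`tcrep run --config pipeline.yaml` accepts a YAML file with either an
`inputs:` block (paths to real repertoire/reference/clinical/flow files) or a
`synthetic:` block (generator overrides), plus a `thresholds:` block
(`levenshtein_max`, `read_cutoff`, `cluster_min_subjects`, `alpha`,
`network_r`, `minprop`, ...). Exit code 2 signals a configuration error.
Re-running with the same config and seed reproduces byte-identical outputs.

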