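# cogsvd

Comparative generalized-SVD analysis of patient-matched tumor/normal DNA
copy-number cohorts.

Given two copy-number matrices with matched patient columns but independent
probe rows (e.g. a tumor and a normal platform), `cogsvd`:

1. **decomposes** the pair as `D_i = U_i Σ_i Vᵀ` — one shared set of
   unit-norm *probelets* (patterns across patients) and per-dataset
   orthonormal *arraylets* (patterns across the genome) with generalized
   singular values `σ_{1,n}, σ_{2,n}`;
2. **ranks** components by the angular distance
   `θ = arctan(σ₁/σ₂) − π/4 ∈ [−π/4, π/4]` and labels them
   tumor-exclusive (`θ > 2π/15`), normal-exclusive, common (`|θ| < π/16`) or
   intermediate, alongside generalized fractions and normalized Shannon
   entropies;
3. **calls CNAs** (gain/loss) from an arraylet at chromosome, arm, segment
   and probe resolution using deviation rules against an autosomal genomic
   baseline with configurable outlier-region exclusions, plus a
   permutation-tested change-point segmentation for visualization;
4. **matches probes** one-to-one across platforms by ≥1-bp genomic overlap
   with a deterministic nearest-anchor tie-break, and extracts
   consistently-aberrated pairs;
5. **classifies patients** into low/high pattern-weight groups by probelet
   coefficient (discovery) or missing-aware Pearson correlation with the
   pattern (validation), with cutoffs scaled by the 2-norm of the score
   vector (base 0.15);
6. **evaluates survival**: Kaplan-Meier curves and medians, two-group
   log-rank tests, univariate/bivariate Cox proportional hazards (Efron
   ties, Wald CIs, via lifelines), Harrell's concordance index, exact
   upper-tail hypergeometric enrichment and Mann-Whitney tests;
7. **simulates** paired cohorts with planted ground truth (survival-linked
   tumor-exclusive pattern, shared male-specific X deletion, tumor-only
   batch effect, Gaussian noise) so every stage is testable end to end.

## CLI

```sh
cogsvd simulate --out cohort/ --seed 1            # synthetic paired cohort
cogsvd gsvd --tumor cohort/tumor.tsv --normal cohort/normal.tsv \
    --annotation cohort/tumor_annotation.tsv \
    --annotation cohort/normal_annotation.tsv \
    --centromeres cohort/centromeres.tsv --out model/
cogsvd call --pattern run/pattern.tsv --annotation cohort/tumor_annotation.tsv \
    --centromeres cohort/centromeres.tsv --exclude chr7 --exclude chr10 \
    --exclude chr9p --out calls.tsv
cogsvd match --annotation-a affy.tsv --annotation-b agilent.tsv --out pairs.tsv
cogsvd classify --pattern run/pattern.tsv --profiles validation.tsv \
    --annotation validation_annotation.tsv --out classification.tsv
cogsvd survival --clinical clinical.tsv --classification classification.tsv \
    --covariate chemotherapy --out survival.json
cogsvd discover --config run.toml                 # end-to-end discovery
cogsvd validate --config val.toml --pattern run/pattern.tsv
```

Exit codes: 0 ok, 1 user error, 2 internal error. `discover`/`validate` read
a TOML config whose keys mirror `cogsvd.pipeline.RunConfig`; every run
freezes a copy of the config next to its `report.json`, and reruns with the
same config are byte-identical.

## File formats

- **Copy-number matrix**: TSV, first column `probe_id`, one column per
  patient; empty cells or `NA` are missing (never imputed).
- **Probe annotation**: headerless 4-column TSV
  `probe_id  chromosome  start  end`, BED-style 0-based half-open.
- **Centromere table**: TSV with header
  `chromosome  centromere_start  centromere_end` (defines p/q arms).
- **Clinical table**: TSV with header; `patient_id`, `survival_time`
  (months), `event` (True/False), plus optional categorical columns
  (`chemotherapy`, `radiation`, `age_group`, `grade`, `mgmt_status`,
  `idh1_status`, `gender`, `batch`).
- **Segment table**: TSV with header `chromosome  start  end  probe_count`.
- **Pairs table**: TSV with header `probe_a  probe_b  chromosome overlap_bp`.

## Notes on conventions

- Median-centering is per patient column over non-missing entries.
- The canonical model orders components by decreasing θ and fixes probelet
  signs so the largest-magnitude entry is positive; the discovery pipeline
  afterwards orients the selected pattern so the "high" group is the
  hazard-increasing one.
- Call thresholds are strict inequalities; classification ties go to "low".
- The genomic baseline always excludes sex chromosomes; the default outlier
  exclusion list (`chr7`, `chr10`, `chr9p`) is pattern-specific and
  configurable.
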