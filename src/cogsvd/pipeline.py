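"""End-to-end discovery and validation flows with reproducible reports.

``run_discovery`` executes: median-center -> validate pair -> GSVD ->
canonicalize -> component classification -> pattern-of-interest selection
-> genomic baseline + CNA calls -> patient classification with the scaled
cutoff -> survival report. ``run_validation`` classifies an independent
cohort by correlation with a previously discovered pattern.

Reports are plain JSON/TSV with no timestamps, so a rerun with the same
config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from cogsvd import classification as cls
from cogsvd import cna_calling, data_io, gsvd_core, probe_matching, survival_stats

log = logging.getLogger(__name__)

BATCH_ENRICHMENT_ALPHA = 1e-3


@dataclasses.dataclass
class RunConfig:
    tumor_path: str
    normal_path: str
    tumor_annotation_path: str
    normal_annotation_path: str
    centromere_path: str
    clinical_path: str
    out_dir: str
    segments_path: str | None = None
    pairs_path: str | None = None
    excluded_regions: Sequence[str] = cna_calling.DEFAULT_EXCLUDED
    base_cutoff: float = cls.DEFAULT_BASE_CUTOFF
    cutoff: float | None = None  # fixed cutoff (validation); else scaled
    exclusive_min: float = gsvd_core.DEFAULT_EXCLUSIVE_MIN
    common_max: float = gsvd_core.DEFAULT_COMMON_MAX
    min_segment_probes: int = 5
    min_overlap_probes: int = cls.DEFAULT_MIN_OVERLAP
    component_index: int | None = None  # 0-based override of pattern choice
    batch_columns: Sequence[str] = ("batch",)
    covariates: Sequence[str] = ()
    seed: int = 0

    @classmethod
    def from_toml(cls_, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as handle:
            raw = tomllib.load(handle)
        known = {f.name for f in dataclasses.fields(cls_)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls_(**raw)

    def thresholds(self) -> gsvd_core.ExclusivityThresholds:
        return gsvd_core.ExclusivityThresholds(self.exclusive_min, self.common_max)

    def digest(self) -> str:
        payload = json.dumps(
            {k: list(v) if isinstance(v, tuple) else v
             for k, v in dataclasses.asdict(self).items()},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _require(path: str | None, label: str) -> Path:
    if path is None:
        raise ValueError(f"config lacks required path: {label}")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{label} not found: {p}")
    return p


def _load_pair(config: RunConfig):
    tumor = data_io.read_copy_number(
        _require(config.tumor_path, "tumor_path"),
        _require(config.tumor_annotation_path, "tumor_annotation_path"),
        _require(config.centromere_path, "centromere_path"),
    )
    normal = data_io.read_copy_number(
        _require(config.normal_path, "normal_path"),
        _require(config.normal_annotation_path, "normal_annotation_path"),
        config.centromere_path,
    )
    return tumor, normal


def select_pattern_component(
    model: gsvd_core.GSVDModel,
    clinical: pd.DataFrame,
    batch_columns: Sequence[str],
    alpha: float = BATCH_ENRICHMENT_ALPHA,
) -> tuple[int, list[dict]]:
    """Highest-angular-distance component whose probelet is not enriched in
    any batch annotation (heuristic; overridable via config).

    Components are scanned in canonical (theta-descending) order; one whose
    sign-split is enriched in a batch column at ``alpha`` is presumed to
    track an experimental batch effect and skipped.
    """
    patients = model.patients
    if patients is None:
        raise ValueError("model lacks patient ids")
    skipped = []
    for k in range(model.n_components):
        batch_p = None
        for column in batch_columns:
            if column not in clinical.columns:
                continue
            report = survival_stats.annotate_probelet(
                model.v[:, k], clinical, column, patients
            )
            p = float(report["p_hypergeometric"].min())
            if batch_p is None or p < batch_p:
                batch_p = p
        if batch_p is not None and batch_p < alpha:
            skipped.append({"component": k, "batch_p": batch_p})
            continue
        return k, skipped
    raise ValueError("every component is batch-enriched; no pattern candidate")


def _survival_report(
    clinical: pd.DataFrame,
    classification: cls.PatientClassification,
    covariates: Sequence[str],
) -> dict:
    groups = {
        p: lab
        for p, lab in zip(classification.patients, classification.labels)
        if lab is not None
    }
    patients = [p for p in classification.patients if p in groups]
    records = survival_stats.records_from_frame(clinical, patients, groups)
    by_label = {
        label: [r for r in records if r.group == label] for label in (cls.LOW, cls.HIGH)
    }
    report: dict = {"groups": {}}
    for label, recs in by_label.items():
        if not recs:
            report["groups"][label] = {"n": 0}
            continue
        km = survival_stats.km_curve(recs)
        report["groups"][label] = {
            "n": len(recs),
            "events": int(sum(r.event for r in recs)),
            "km_median": km.median,
        }
    if by_label[cls.LOW] and by_label[cls.HIGH]:
        lr = survival_stats.log_rank(by_label[cls.LOW], by_label[cls.HIGH])
        report["log_rank"] = {"statistic": lr.statistic, "p": lr.p_value}
        fit = survival_stats.cox_fit(records, ["group"])
        cox = fit["group=high"]
        report["cox"] = {
            "hazard_ratio": cox.hazard_ratio,
            "ci_low": cox.ci_low,
            "ci_high": cox.ci_high,
            "p": cox.p_value,
            "flagged": cox.flagged,
        }
        scores = [
            float(s)
            for p, s in zip(classification.patients, classification.scores)
            if p in groups
        ]
        report["concordance"] = survival_stats.concordance_index(records, scores)
        for covariate in covariates:
            try:
                bifit = survival_stats.cox_fit(records, ["group", covariate])
            except ValueError as exc:
                log.warning("bivariate fit with %s skipped: %s", covariate, exc)
                continue
            report.setdefault("bivariate", {})[covariate] = {
                name: dataclasses.asdict(res) for name, res in bifit.items()
            }
    return report


def _km_median_or_inf(value) -> float:
    return math.inf if value is None else float(value)


def _orient_classification(
    classification: cls.PatientClassification, clinical: pd.DataFrame
) -> tuple[cls.PatientClassification, bool]:
    """Flip the score sign if the 'high' group outlives the 'low' group, so
    that 'high' is always the hazard-increasing direction (post-hoc
    orientation of the sign-ambiguous pattern)."""
    medians = {}
    for label in (cls.LOW, cls.HIGH):
        members = classification.group_patients(label)
        if not members:
            return classification, False
        records = survival_stats.records_from_frame(clinical, members)
        medians[label] = _km_median_or_inf(survival_stats.km_curve(records).median)
    if medians[cls.HIGH] > medians[cls.LOW]:
        return cls.flip(classification), True
    return classification, False


def run_discovery(config: RunConfig) -> dict:
    """Full discovery flow; returns the report dict and persists all
    intermediates under ``config.out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    clinical = data_io.read_clinical(_require(config.clinical_path, "clinical_path"))

    tumor, normal = _load_pair(config)
    tumor = data_io.drop_incomplete_probes(data_io.median_center(tumor))
    normal = data_io.drop_incomplete_probes(data_io.median_center(normal))
    data_io.validate_pair(tumor, normal)

    model = gsvd_core.compute_gsvd(tumor, normal)
    thresholds = config.thresholds()
    labels = gsvd_core.classify_components(model, thresholds)
    gsvd_core.write_model(
        model,
        out_dir,
        tumor.probes["probe_id"],
        normal.probes["probe_id"],
        thresholds,
        write_arraylets=True,
    )

    if config.component_index is not None:
        selected, skipped = config.component_index, []
    else:
        selected, skipped = select_pattern_component(
            model, clinical, config.batch_columns
        )
    pattern = model.u1[:, selected].copy()

    # discovery classifies by the probelet coefficients (the pattern's
    # per-patient weights); the unit probelet norm makes the scaled cutoff
    # equal the base cutoff, consistent with correlation-mode cutoffs scaled
    # by the 2-norm of the discovery correlations
    correlations = cls.correlate_pattern(pattern, tumor, config.min_overlap_probes)
    scores = model.v[:, selected].copy()
    if config.cutoff is not None:
        cutoff = float(config.cutoff)
    else:
        cutoff = cls.scale_cutoff(config.base_cutoff, scores)
    patient_cls = cls.classify(tumor.patients, scores, cutoff, cls.MODE_COEFFICIENT)
    patient_cls, flipped = _orient_classification(patient_cls, clinical)
    if flipped:
        pattern = -pattern
        correlations = -correlations
    patient_cls.to_frame().assign(correlation=correlations).to_csv(
        out_dir / "classification.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {"probe_id": tumor.probes["probe_id"], "value": pattern}
    ).to_csv(out_dir / "pattern.tsv", sep="\t", index=False)

    baseline = cna_calling.compute_baseline(
        pattern, tumor.probes, config.excluded_regions
    )
    calls: list[cna_calling.CNACall] = []
    chromosomes = list(dict.fromkeys(tumor.probes["chromosome"]))
    for chrom in chromosomes:
        calls.append(
            cna_calling.call_chromosome_or_arm(pattern, tumor.probes, baseline, chrom)
        )
        for arm in ("p", "q"):
            sub = tumor.probes[
                (tumor.probes["chromosome"] == chrom) & (tumor.probes["arm"] == arm)
            ]
            if len(sub):
                calls.append(
                    cna_calling.call_chromosome_or_arm(
                        pattern, tumor.probes, baseline, f"{chrom}{arm}"
                    )
                )
    if config.segments_path is not None:
        segments = cna_calling.filter_segments(
            data_io.read_segments(config.segments_path), config.min_segment_probes
        )
        for row in segments.itertuples(index=False):
            calls.append(
                cna_calling.call_segment(
                    pattern,
                    tumor.probes,
                    baseline,
                    str(row.chromosome),
                    int(row.start),
                    int(row.end),
                )
            )
    cna_calling.calls_to_frame(calls).to_csv(
        out_dir / "calls.tsv", sep="\t", index=False
    )

    survival = _survival_report(clinical, patient_cls, config.covariates)

    report = {
        "flow": "discovery",
        "seed": config.seed,
        "config_digest": config.digest(),
        "n_patients": tumor.n_patients,
        "n_probes_tumor": tumor.n_probes,
        "n_probes_normal": normal.n_probes,
        "entropy_tumor": model.entropy(1),
        "entropy_normal": model.entropy(2),
        "component_labels": labels,
        "selected_component": int(selected),
        "selected_theta": float(model.theta[selected]),
        "skipped_batch_components": skipped,
        "pattern_flipped": flipped,
        "cutoff": cutoff,
        "correlation_cutoff": cls.scale_cutoff(
            config.base_cutoff, correlations[np.isfinite(correlations)]
        ),
        "n_low": len(patient_cls.group_patients(cls.LOW)),
        "n_high": len(patient_cls.group_patients(cls.HIGH)),
        "n_calls": {
            direction: sum(c.direction == direction for c in calls)
            for direction in (cna_calling.GAIN, cna_calling.LOSS, cna_calling.NONE)
        },
        "survival": survival,
    }
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report


def run_validation(
    config: RunConfig,
    pattern_path: str | Path,
) -> dict:
    """Classify an independent cohort by correlation with a saved pattern."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    clinical = data_io.read_clinical(_require(config.clinical_path, "clinical_path"))
    cohort = data_io.read_copy_number(
        _require(config.tumor_path, "tumor_path"),
        _require(config.tumor_annotation_path, "tumor_annotation_path"),
        config.centromere_path,
    )
    if cohort.n_patients == 0:
        raise ValueError("validation cohort has no patients")
    cohort = data_io.median_center(cohort)

    pattern_frame = pd.read_csv(pattern_path, sep="\t", dtype={"probe_id": str})
    pattern_ids = list(pattern_frame["probe_id"])
    pattern = pattern_frame["value"].to_numpy(dtype=float)

    cohort_ids = list(cohort.probes["probe_id"])
    if cohort_ids == pattern_ids:
        aligned_pattern, profiles = pattern, cohort
    elif set(cohort_ids) >= set(pattern_ids):
        index = {pid: i for i, pid in enumerate(cohort_ids)}
        rows = np.array([index[pid] for pid in pattern_ids])
        profiles = cohort.subset_probes(rows)
        aligned_pattern = pattern
    elif config.pairs_path is not None:
        pairs_frame = pd.read_csv(config.pairs_path, sep="\t")
        ann_a = pd.DataFrame({"probe_id": pattern_ids})
        pairs = probe_matching.pairs_from_frame(pairs_frame, ann_a, cohort.probes)
        aligned_pattern = probe_matching.project_profile(pattern, pairs, "a")
        rows = np.array([p.index_b for p in pairs])
        profiles = cohort.subset_probes(rows)
    else:
        raise ValueError(
            "probe spaces differ and no pairs_path given; cannot project pattern"
        )

    correlations = cls.correlate_pattern(
        aligned_pattern, profiles, config.min_overlap_probes
    )
    cutoff = (
        float(config.cutoff)
        if config.cutoff is not None
        else cls.scale_cutoff(
            config.base_cutoff, correlations[np.isfinite(correlations)]
        )
    )
    patient_cls = cls.classify(
        profiles.patients, correlations, cutoff, cls.MODE_CORRELATION
    )
    patient_cls.to_frame().to_csv(
        out_dir / "classification.tsv", sep="\t", index=False
    )
    survival = _survival_report(clinical, patient_cls, config.covariates)
    report = {
        "flow": "validation",
        "seed": config.seed,
        "config_digest": config.digest(),
        "n_patients": profiles.n_patients,
        "n_probes_used": profiles.n_probes,
        "cutoff": cutoff,
        "n_low": len(patient_cls.group_patients(cls.LOW)),
        "n_high": len(patient_cls.group_patients(cls.HIGH)),
        "survival": survival,
    }
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report
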