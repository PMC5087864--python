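"""Paired tumor/normal cohort generator with planted ground truth.

Each generated cohort contains, mirroring the structure the decomposition is
meant to separate:

* a tumor-exclusive genome-wide pattern whose per-patient weight defines a
  low/high group linked to survival through an exponential hazards model;
* a male-specific X-chromosome deletion shared by tumor and normal genomes;
* a tumor-only batch effect (deterministic +/- half-chromosome shape so it
  survives per-patient median centering) on a random patient subset;
* i.i.d. Gaussian probe noise.

Tumor and normal probe sets are independent: the normal platform covers the
same chromosomes with 80% of the probe density at staggered coordinates.
The planted pattern and batch shapes are deterministic given the genome, so
different seeds share the planted structure and differ only in noise and
patient assignments.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cogsvd.cna_calling import parse_region, _region_mask
from cogsvd.data_io import (
    CopyNumberDataset,
    is_autosome,
    write_annotation,
    write_copy_number,
)

PROBE_LENGTH = 25
PROBE_SPACING = 1000

DEFAULT_GENOME = {
    "chr1": 500,
    "chr2": 500,
    "chr3": 500,
    "chr4": 500,
    "chrX": 200,
}
DEFAULT_PATTERN_REGIONS = (("chr1", "gain"), ("chr2q", "loss"))


@dataclasses.dataclass
class SurvivalParams:
    median_low_months: float = 60.0
    hazard_ratio: float = 5.0
    censoring_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.median_low_months <= 0 or self.hazard_ratio <= 0:
            raise ValueError("survival parameters must be positive")
        if not 0.0 <= self.censoring_fraction < 1.0:
            raise ValueError("censoring fraction must be in [0, 1)")


@dataclasses.dataclass
class CohortParams:
    n_patients: int = 60
    n_probes: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_GENOME)
    )
    pattern_amplitude: float = 0.3
    pattern_regions: Sequence[tuple[str, str]] = DEFAULT_PATTERN_REGIONS
    fraction_high: float = 0.5
    x_deletion_amplitude: float = 1.0  # log2(1/2): loss of one of two copies
    male_fraction: float = 0.5
    batch_effect_amplitude: float = 0.1
    batch_fraction: float = 0.3
    noise_sd: float = 0.1
    survival: SurvivalParams = dataclasses.field(default_factory=SurvivalParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        for name, value in (
            ("pattern_amplitude", self.pattern_amplitude),
            ("x_deletion_amplitude", self.x_deletion_amplitude),
            ("batch_effect_amplitude", self.batch_effect_amplitude),
        ):
            if value < 0:
                raise ValueError(f"{name} must be >= 0")
        for name, value in (
            ("fraction_high", self.fraction_high),
            ("male_fraction", self.male_fraction),
            ("batch_fraction", self.batch_fraction),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")


@dataclasses.dataclass
class CohortTruth:
    planted_pattern: np.ndarray  # over the tumor probe set
    planted_x_tumor: np.ndarray  # X-deletion shape over tumor probes
    planted_x_normal: np.ndarray  # X-deletion shape over normal probes
    weights: np.ndarray  # per-patient pattern weight
    group: list[str]  # 'low' / 'high'
    gender: list[str]  # 'female' / 'male'
    batch: list[str]  # 'plate1' / 'plate2'
    survival: SurvivalParams
    hazard_times: np.ndarray
    events: np.ndarray


def build_probes(
    genome: Mapping[str, int], platform: str, density: float = 1.0
) -> pd.DataFrame:
    """Evenly spaced probe annotation with derived p/q arms (centromere at
    the chromosome midpoint).

    ``density`` thins the autosomal probes (different platform); the X
    chromosome keeps full density so the shared X-deletion has comparable
    weight in both datasets.
    """
    rows = []
    for chrom, count in genome.items():
        d = density if is_autosome(chrom) else 1.0
        n = max(2, int(round(count * d)))
        offset = 0 if d == 1.0 else PROBE_SPACING // 3
        for i in range(n):
            start = offset + i * int(PROBE_SPACING / d)
            rows.append(
                {
                    "probe_id": f"{platform}_{chrom}_{i:05d}",
                    "chromosome": chrom,
                    "start": start,
                    "end": start + PROBE_LENGTH,
                    "arm": "p" if i < n // 2 else "q",
                }
            )
    return pd.DataFrame(rows)


def centromere_table(genome: Mapping[str, int], density: float = 1.0) -> pd.DataFrame:
    rows = []
    for chrom, count in genome.items():
        d = density if is_autosome(chrom) else 1.0
        n = max(2, int(round(count * d)))
        mid = (n // 2) * int(PROBE_SPACING / d)
        rows.append(
            {
                "chromosome": chrom,
                "centromere_start": mid - PROBE_SPACING // 4,
                "centromere_end": mid,
            }
        )
    return pd.DataFrame(rows)


def _pattern_vector(
    probes: pd.DataFrame, regions: Sequence[tuple[str, str]]
) -> np.ndarray:
    pattern = np.zeros(len(probes))
    chromosomes = set(probes["chromosome"])
    for region, direction in regions:
        chrom, arm = parse_region(region, chromosomes)
        sign = {"gain": 1.0, "loss": -1.0}[direction]
        pattern[_region_mask(probes, chrom, arm)] = sign
    return pattern


def _batch_vector(probes: pd.DataFrame) -> np.ndarray:
    """Alternating +1/-1 over autosomal probes: zero-median within every
    patient (survives median centering) and orthogonal to any region-block
    pattern, so the batch component does not contaminate the planted CNA
    pattern."""
    autosomal = np.fromiter(
        (is_autosome(c) for c in probes["chromosome"]), bool, len(probes)
    )
    alternating = np.where(np.arange(len(probes)) % 2 == 0, 1.0, -1.0)
    return np.where(autosomal, alternating, 0.0)


def _x_vector(probes: pd.DataFrame) -> np.ndarray:
    return np.where([not is_autosome(c) for c in probes["chromosome"]], -1.0, 0.0)


def simulate_survival(
    group: Sequence[str],
    params: SurvivalParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential survival with group-specific rates and administrative
    censoring at the horizon where the expected surviving fraction equals
    the requested censoring fraction. Returns (times, events)."""
    from scipy.optimize import brentq

    group = np.asarray(group)
    rate_low = math.log(2.0) / params.median_low_months
    rates = np.where(group == "high", rate_low * params.hazard_ratio, rate_low)
    times = rng.exponential(1.0 / rates)
    events = np.ones(times.size, dtype=bool)
    if params.censoring_fraction > 0:
        p_high = float(np.mean(group == "high"))

        def surviving(horizon: float) -> float:
            return (
                (1.0 - p_high) * math.exp(-rate_low * horizon)
                + p_high * math.exp(-rate_low * params.hazard_ratio * horizon)
                - params.censoring_fraction
            )

        horizon = brentq(surviving, 1e-9, 1e9)
        events = times <= horizon
        times = np.minimum(times, horizon)
    return np.maximum(times, 1e-3), events


def generate_cohort(
    params: CohortParams,
) -> tuple[CopyNumberDataset, CopyNumberDataset, pd.DataFrame, CohortTruth]:
    """Generate (tumor, normal, clinical, truth); reproducible from the seed."""
    rng = np.random.default_rng(params.seed)
    n = params.n_patients

    tumor_probes = build_probes(params.n_probes, "affy", density=1.0)
    normal_probes = build_probes(params.n_probes, "agil", density=0.8)

    pattern = _pattern_vector(tumor_probes, params.pattern_regions)
    batch_shape = _batch_vector(tumor_probes)
    x_tumor = _x_vector(tumor_probes)
    x_normal = _x_vector(normal_probes)

    n_high = int(round(params.fraction_high * n))
    group = np.array(["low"] * n, dtype=object)
    group[rng.permutation(n)[:n_high]] = "high"
    weights = np.where(
        group == "high",
        rng.normal(1.0, 0.1, n),
        rng.normal(0.0, 0.05, n),
    )

    n_male = int(round(params.male_fraction * n))
    male = np.zeros(n, dtype=bool)
    male[rng.permutation(n)[:n_male]] = True
    gender = np.where(male, "male", "female")

    n_batch = int(round(params.batch_fraction * n))
    in_batch = np.zeros(n, dtype=bool)
    in_batch[rng.permutation(n)[:n_batch]] = True
    batch = np.where(in_batch, "plate2", "plate1")

    tumor_values = (
        params.pattern_amplitude * np.outer(pattern, weights)
        + params.x_deletion_amplitude * np.outer(x_tumor, male.astype(float))
        + params.batch_effect_amplitude * np.outer(batch_shape, in_batch.astype(float))
        + rng.normal(0.0, params.noise_sd, (len(tumor_probes), n))
    )
    normal_values = params.x_deletion_amplitude * np.outer(
        x_normal, male.astype(float)
    ) + rng.normal(0.0, params.noise_sd, (len(normal_probes), n))

    patients = [f"patient_{j + 1:03d}" for j in range(n)]
    tumor = CopyNumberDataset(tumor_values, tumor_probes, patients)
    normal = CopyNumberDataset(normal_values, normal_probes, patients)

    times, events = simulate_survival(group, params.survival, rng)
    clinical = pd.DataFrame(
        {
            "patient_id": patients,
            "survival_time": times,
            "event": events,
            "chemotherapy": rng.random(n) < 0.5,
            "radiation": rng.random(n) < 0.5,
            "age_group": np.where(rng.random(n) < 0.5, "under50", "over50"),
            "grade": np.where(rng.random(n) < 0.5, "II", "III"),
            "mgmt_status": np.where(
                rng.random(n) < 0.5, "methylated", "unmethylated"
            ),
            "idh1_status": np.where(rng.random(n) < 0.5, "mutated", "wildtype"),
            "gender": gender,
            "batch": batch,
        }
    ).set_index("patient_id")

    truth = CohortTruth(
        planted_pattern=pattern,
        planted_x_tumor=x_tumor,
        planted_x_normal=x_normal,
        weights=weights,
        group=list(group),
        gender=list(gender),
        batch=list(batch),
        survival=params.survival,
        hazard_times=times,
        events=events,
    )
    return tumor, normal, clinical, truth


def evaluate_recovery(
    model,
    classification,
    truth: CohortTruth,
    thresholds=None,
) -> dict:
    """Compare a fitted model + classification against the planted truth.

    Reports the absolute correlation of the best-matching tumor arraylet
    with the planted pattern, that component's angular distance and
    exclusivity label, the label-agreement accuracy (maximized over the
    sign-ambiguous polarity), and the angular distance/label of the tumor
    arraylet best matching the planted X-deletion shape.
    """
    from cogsvd.gsvd_core import classify_components

    if model.u1.shape[0] != truth.planted_pattern.size:
        raise ValueError("model and truth disagree on the tumor probe count")
    labels = classify_components(model, thresholds)

    def best_match(target: np.ndarray, basis: np.ndarray) -> tuple[int, float]:
        t = target - target.mean()
        tn = np.linalg.norm(t)
        cors = []
        for k in range(basis.shape[1]):
            u = basis[:, k] - basis[:, k].mean()
            denom = tn * np.linalg.norm(u)
            cors.append(abs(float(t @ u)) / denom if denom > 0 else 0.0)
        k = int(np.argmax(cors))
        return k, cors[k]

    k_pat, r_pat = best_match(truth.planted_pattern, model.u1)
    k_x, r_x = best_match(truth.planted_x_tumor, model.u1)

    agreements = [
        lab == grp
        for lab, grp in zip(classification.labels, truth.group)
        if lab is not None
    ]
    accuracy = float(np.mean(agreements)) if agreements else float("nan")
    accuracy = max(accuracy, 1.0 - accuracy)

    return {
        "pattern_component": k_pat,
        "pattern_correlation": r_pat,
        "pattern_theta": float(model.theta[k_pat]),
        "pattern_label": labels[k_pat],
        "x_component": k_x,
        "x_correlation": r_x,
        "x_theta": float(model.theta[k_x]),
        "x_label": labels[k_x],
        "label_accuracy": accuracy,
    }


def write_cohort(
    out_dir: str | Path,
    tumor: CopyNumberDataset,
    normal: CopyNumberDataset,
    clinical: pd.DataFrame,
    truth: CohortTruth | None = None,
    genome: Mapping[str, int] | None = None,
) -> None:
    """Write the TSV files the pipeline readers consume, plus truth files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_copy_number(tumor, out_dir / "tumor.tsv")
    write_copy_number(normal, out_dir / "normal.tsv")
    write_annotation(tumor.probes, out_dir / "tumor_annotation.tsv")
    write_annotation(normal.probes, out_dir / "normal_annotation.tsv")
    clinical.reset_index().to_csv(out_dir / "clinical.tsv", sep="\t", index=False)
    centromere_table(genome or DEFAULT_GENOME).to_csv(
        out_dir / "centromeres.tsv", sep="\t", index=False
    )
    if truth is not None:
        pd.DataFrame(
            {
                "probe_id": tumor.probes["probe_id"],
                "planted_pattern": truth.planted_pattern,
            }
        ).to_csv(out_dir / "truth_pattern.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "patient_id": tumor.patients,
                "weight": truth.weights,
                "group": truth.group,
                "gender": truth.gender,
                "batch": truth.batch,
            }
        ).to_csv(out_dir / "truth_patients.tsv", sep="\t", index=False)
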