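"""Binary low/high patient classification by pattern weight or correlation.

Discovery cohorts are classified by the probelet coefficient of the pattern
of interest; validation and cross-cohort classification correlates each
(median-centered) tumor profile with the arraylet pattern, skipping missing
probes per profile. The correlation cutoff is the base cutoff scaled by the
2-norm of the discovery correlations, so thresholds carry across cohorts of
different correlation scales. Boundary ties go to "low".
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from cogsvd.data_io import CopyNumberDataset

log = logging.getLogger(__name__)

LOW = "low"
HIGH = "high"

MODE_COEFFICIENT = "coefficient"
MODE_CORRELATION = "correlation"

DEFAULT_BASE_CUTOFF = 0.15
DEFAULT_MIN_OVERLAP = 100


@dataclasses.dataclass
class PatientClassification:
    patients: list[str]
    scores: np.ndarray  # NaN = missing score (patient excluded)
    labels: list[str | None]  # 'low' / 'high' / None for missing
    cutoff: float
    mode: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patients,
                "score": self.scores,
                "label": [lab if lab is not None else "NA" for lab in self.labels],
                "mode": self.mode,
                "cutoff": self.cutoff,
            }
        )

    def group_patients(self, label: str) -> list[str]:
        return [p for p, lab in zip(self.patients, self.labels) if lab == label]


def correlate_pattern(
    pattern: np.ndarray,
    profiles: CopyNumberDataset,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> np.ndarray:
    """Pearson correlation of the pattern with each patient profile.

    Each correlation uses only the probes non-missing in that patient's
    profile; patients with fewer than ``min_overlap`` usable probes, or a
    zero-variance profile or pattern restriction, receive NaN (warned).
    """
    pattern = np.asarray(pattern, dtype=float)
    if pattern.size != profiles.n_probes:
        raise ValueError(
            f"pattern length {pattern.size} != {profiles.n_probes} profile probes"
        )
    out = np.full(profiles.n_patients, np.nan)
    for j, patient in enumerate(profiles.patients):
        column = profiles.values[:, j]
        use = np.isfinite(column) & np.isfinite(pattern)
        if use.sum() < min_overlap:
            log.warning(
                "patient %s: only %d usable probes (< %d); score missing",
                patient,
                int(use.sum()),
                min_overlap,
            )
            continue
        x = pattern[use]
        y = column[use]
        sx = x.std()
        sy = y.std()
        if sx == 0.0 or sy == 0.0:
            log.warning("patient %s: zero variance; score missing", patient)
            continue
        out[j] = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return out


def scale_cutoff(base_cutoff: float, correlations: np.ndarray) -> float:
    """Scale a base cutoff by the Euclidean norm of the discovery
    correlations."""
    correlations = np.asarray(correlations, dtype=float)
    if correlations.size == 0:
        raise ValueError("empty correlation vector")
    if np.isnan(correlations).any():
        raise ValueError("correlations contain missing values")
    return float(base_cutoff * np.linalg.norm(correlations))


def classify(
    patients: list[str],
    scores: np.ndarray,
    cutoff: float,
    mode: str,
) -> PatientClassification:
    """Label ``high`` iff score strictly exceeds the cutoff; missing scores
    are excluded with their ids logged."""
    if mode not in (MODE_COEFFICIENT, MODE_CORRELATION):
        raise ValueError(f"unknown mode {mode!r}")
    scores = np.asarray(scores, dtype=float)
    if scores.size != len(patients):
        raise ValueError("scores and patients differ in length")
    labels: list[str | None] = []
    skipped = []
    for patient, score in zip(patients, scores):
        if not np.isfinite(score):
            labels.append(None)
            skipped.append(patient)
        else:
            labels.append(HIGH if score > cutoff else LOW)
    if skipped:
        log.warning("%d patients without scores excluded: %s", len(skipped), skipped)
    if all(lab is None for lab in labels):
        log.warning("all scores missing: empty classification")
    return PatientClassification(list(patients), scores, labels, float(cutoff), mode)


def flip(classification: PatientClassification) -> PatientClassification:
    """Re-classify with negated scores (used to orient a sign-ambiguous
    pattern so that 'high' is the hazard-increasing direction)."""
    return classify(
        classification.patients,
        -classification.scores,
        classification.cutoff,
        classification.mode,
    )
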