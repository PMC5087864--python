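"""Survival and enrichment statistics for pattern-based stratification.

Kaplan-Meier curves, two-group log-rank tests, univariate/bivariate Cox
proportional-hazards fits (delegated to lifelines, Efron ties, Wald CIs),
Harrell's concordance index, exact upper-tail hypergeometric enrichment and
Mann-Whitney-Wilcoxon tests. Conventions: KM median is the first event time
where the survival estimate drops to <= 0.5; score ties contribute 0.5 to
the concordance numerator; the log-rank statistic has one degree of freedom
with no continuity correction.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclasses.dataclass
class SurvivalRecord:
    patient_id: str
    time: float  # months, > 0
    event: bool  # death observed
    group: str | None = None
    covariates: Mapping[str, object] = dataclasses.field(default_factory=dict)


@dataclasses.dataclass(frozen=True)
class EnrichmentInput:
    """k of K annotated patients observed in a subset of n out of N."""

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        ok = (
            0 <= self.k <= min(self.n, self.K)
            and self.n <= self.N
            and self.K <= self.N
            and self.n >= 0
            and self.K >= 0
        )
        if not ok:
            raise ValueError(f"invalid enrichment counts {self}")


@dataclasses.dataclass
class KMEstimate:
    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    median: float | None  # None when S never reaches 0.5

    def step_function(self):
        def s(t: float) -> float:
            idx = np.searchsorted(self.times, t, side="right")
            return 1.0 if idx == 0 else float(self.survival[idx - 1])

        return s


def _arrays(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([bool(r.event) for r in records])
    if times.size == 0:
        raise ValueError("no survival records")
    if np.any(times <= 0) or not np.all(np.isfinite(times)):
        raise ValueError("survival times must be positive and finite")
    return times, events


def km_curve(records: Sequence[SurvivalRecord]) -> KMEstimate:
    """Product-limit estimator; median = first event time with S(t) <= 0.5."""
    times, events = _arrays(records)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    distinct = np.unique(times[events])
    survival = []
    s = 1.0
    median = None
    for t in distinct:
        at_risk = int(np.sum(times >= t))
        deaths = int(np.sum((times == t) & events))
        s *= 1.0 - deaths / at_risk
        survival.append(s)
        if median is None and s <= 0.5:
            median = float(t)
    return KMEstimate(distinct, np.array(survival), median)


@dataclasses.dataclass
class LogRankResult:
    statistic: float
    p_value: float
    observed: float  # events in group A
    expected: float  # expected events in group A under the null


def log_rank(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> LogRankResult:
    """Standard two-group log-rank test (1 df, no continuity correction)."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    ta, ea = _arrays(group_a)
    tb, eb = _arrays(group_b)
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    in_a = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])

    observed = expected = variance = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & in_a).sum())
        dying = (times == t) & events
        d = int(dying.sum())
        d1 = int((dying & in_a).sum())
        observed += d1
        expected += d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1.0 - n1 / n) * (n - d) / (n - 1)
    if variance == 0.0:
        log.warning("log-rank variance is zero (no informative events); P = 1")
        return LogRankResult(0.0, 1.0, observed, expected)
    statistic = (observed - expected) ** 2 / variance
    return LogRankResult(
        float(statistic),
        float(stats.chi2.sf(statistic, df=1)),
        observed,
        expected,
    )


@dataclasses.dataclass
class CoxResult:
    covariate: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    coef: float
    flagged: bool = False  # convergence / monotone-likelihood warning raised


def _design_frame(
    records: Sequence[SurvivalRecord], covariate_names: Sequence[str]
) -> pd.DataFrame:
    times, events = _arrays(records)
    data: dict[str, np.ndarray] = {"time": times, "event": events.astype(float)}
    columns: list[str] = []
    for name in covariate_names:
        if name == "group":
            raw = [r.group for r in records]
        else:
            raw = [r.covariates.get(name) for r in records]
        if any(v is None for v in raw):
            raise ValueError(f"covariate {name!r} missing for some records")
        values = pd.Series(raw)
        if values.dtype == bool or set(values.unique()) <= {0, 1, True, False}:
            data[name] = values.astype(float).to_numpy()
            columns.append(name)
        else:
            levels = sorted(map(str, values.unique()))
            if set(levels) == {"low", "high"}:
                levels = ["low", "high"]  # hazard ratio of high vs low
            if len(levels) < 2:
                raise ValueError(f"covariate {name!r} has a single level")
            for level in levels[1:]:  # first level is the reference
                col = f"{name}={level}"
                data[col] = (values.astype(str) == level).astype(float).to_numpy()
                columns.append(col)
    frame = pd.DataFrame(data)
    frame.attrs["covariate_columns"] = columns
    return frame


def cox_fit(
    records: Sequence[SurvivalRecord], covariate_names: Sequence[str]
) -> dict[str, CoxResult]:
    """Univariate (1 name) or bivariate (2 names) Cox PH fit via lifelines.

    Categorical covariates are dummy-coded against their first sorted level.
    Non-convergence or monotone-likelihood warnings flag the result rather
    than raising.
    """
    if not 1 <= len(covariate_names) <= 2:
        raise ValueError("cox_fit supports one or two covariates")
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceWarning

    frame = _design_frame(records, covariate_names)
    columns = frame.attrs["covariate_columns"]
    fitter = CoxPHFitter()
    flagged = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fitter.fit(frame, duration_col="time", event_col="event")
        except Exception as exc:  # complete separation etc.
            log.warning("Cox fit failed: %s", exc)
            return {
                col: CoxResult(col, np.nan, np.nan, np.nan, np.nan, np.nan, True)
                for col in columns
            }
        flagged = any(issubclass(w.category, ConvergenceWarning) for w in caught)
    summary = fitter.summary
    out = {}
    for col in columns:
        row = summary.loc[col]
        with np.errstate(over="ignore"):  # inf CI bound under separation is fine
            out[col] = CoxResult(
            covariate=col,
            hazard_ratio=float(np.exp(row["coef"])),
            ci_low=float(np.exp(row["coef lower 95%"])),
            ci_high=float(np.exp(row["coef upper 95%"])),
            p_value=float(row["p"]),
            coef=float(row["coef"]),
            flagged=flagged,
        )
    return out


def concordance_index(
    records: Sequence[SurvivalRecord], scores: Sequence[float]
) -> float | None:
    """Harrell's C: fraction of comparable pairs where the higher risk score
    fails first; score ties count 0.5. A pair is comparable when the shorter
    time carries an event. Returns None (warned) with no comparable pairs."""
    times, events = _arrays(records)
    scores = np.asarray(scores, dtype=float)
    if scores.size != times.size:
        raise ValueError("scores must cover all records")
    concordant = 0.0
    comparable = 0
    n = times.size
    for i in range(n):
        for j in range(i + 1, n):
            if times[i] == times[j]:
                continue
            short, long_ = (i, j) if times[i] < times[j] else (j, i)
            if not events[short]:
                continue
            comparable += 1
            if scores[short] > scores[long_]:
                concordant += 1.0
            elif scores[short] == scores[long_]:
                concordant += 0.5
    if comparable == 0:
        log.warning("no comparable pairs; concordance undefined")
        return None
    return concordant / comparable


def hypergeometric_enrichment(enrichment: EnrichmentInput) -> float:
    """Exact upper-tail hypergeometric probability
    P = C(N,n)^-1 * sum_{i=k}^{n} C(K,i) C(N-K,n-i) (impossible summands 0)."""
    if enrichment.k == 0:
        return 1.0
    return float(
        stats.hypergeom.sf(
            enrichment.k - 1, enrichment.N, enrichment.K, enrichment.n
        )
    )


def mann_whitney(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney-Wilcoxon U (of the first sample) and two-sided P.

    Exact null distribution for combined n <= 20 without ties, otherwise the
    tie-corrected normal approximation.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
    result = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(result.statistic), float(result.pvalue)


def annotate_probelet(
    probelet: np.ndarray,
    clinical: pd.DataFrame,
    annotation_name: str,
    patients: Sequence[str],
    split: str = "sign",
    quantile: float = 0.5,
) -> pd.DataFrame:
    """Enrichment report for one probelet against one clinical annotation.

    Patients are split into high/low subsets by probelet sign (default) or
    by a quantile of the coefficients. For every annotation level the exact
    hypergeometric upper-tail P of its count within each subset is computed,
    together with a Mann-Whitney P comparing coefficients of that level
    against the rest. Patients with a missing annotation are excluded.
    """
    probelet = np.asarray(probelet, dtype=float)
    if probelet.size != len(patients):
        raise ValueError("probelet length must equal the patient count")
    if annotation_name not in clinical.columns:
        raise ValueError(f"annotation {annotation_name!r} absent from clinical table")
    anno = clinical[annotation_name].reindex(list(patients))
    known = anno.notna().to_numpy()
    anno = anno[known]
    coef = probelet[known]
    if split == "sign":
        in_high = coef > 0
    elif split == "quantile":
        in_high = coef > np.quantile(coef, quantile)
    else:
        raise ValueError(f"unknown split {split!r}")

    total = int(known.sum())
    rows = []
    for level in sorted(map(str, anno.unique())):
        member = (anno.astype(str) == level).to_numpy()
        K = int(member.sum())
        for subset_name, subset in (("high", in_high), ("low", ~in_high)):
            n = int(subset.sum())
            k = int((member & subset).sum())
            p_hyper = hypergeometric_enrichment(EnrichmentInput(total, K, n, k))
            rows.append(
                {
                    "annotation": annotation_name,
                    "level": level,
                    "subset": subset_name,
                    "N": total,
                    "K": K,
                    "n": n,
                    "k": k,
                    "p_hypergeometric": p_hyper,
                }
            )
        if 0 < K < total:
            _, p_mw = mann_whitney(coef[member], coef[~member])
        else:
            p_mw = 1.0
        for row in rows[-2:]:
            row["p_mannwhitney"] = p_mw
    return pd.DataFrame(rows)


def records_from_frame(
    clinical: pd.DataFrame,
    patients: Sequence[str],
    groups: Mapping[str, str] | None = None,
    time_col: str = "survival_time",
    event_col: str = "event",
) -> list[SurvivalRecord]:
    """Build survival records for ``patients`` from a clinical table indexed
    by patient id; ``groups`` optionally attaches a label per patient."""
    records = []
    for patient in patients:
        if patient not in clinical.index:
            raise ValueError(f"patient {patient} absent from clinical table")
        row = clinical.loc[patient]
        covariates = {
            c: row[c] for c in clinical.columns if c not in (time_col, event_col)
        }
        records.append(
            SurvivalRecord(
                patient_id=patient,
                time=float(row[time_col]),
                event=bool(row[event_col]),
                group=None if groups is None else groups.get(patient),
                covariates=covariates,
            )
        )
    return records
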