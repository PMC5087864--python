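"""Gain/loss calling on an arraylet pattern by baseline deviation.

Call rules (all deviations are from means, so calls are invariant to an
additive offset of the whole pattern and, because thresholds scale with the
standard deviations, to positive rescaling):

* chromosome / arm: gain (loss) when the region mean deviates from the
  genomic mean by strictly more than twice the genomic standard deviation;
* segment / probe: the same genomic rule, or a deviation from the
  chromosomal mean strictly greater than one chromosomal standard deviation
  provided its sign agrees with the (nonzero) deviation from the genomic
  mean.

The genomic baseline is computed over autosomal probes only, minus a
configurable exclusion list of outlying chromosomes/arms (default chr7,
chr10 and 9p, matching a glioma-type pattern).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from cogsvd.data_io import is_autosome

log = logging.getLogger(__name__)

DEFAULT_EXCLUDED = ("chr7", "chr10", "chr9p")

GAIN = "gain"
LOSS = "loss"
NONE = "none"

RULE_GENOMIC = "genomic"
RULE_CHROMOSOMAL = "chromosomal"
RULE_NONE = "none"


def parse_region(name: str, chromosomes: Iterable[str]) -> tuple[str, str | None]:
    """Parse ``"chr7"`` -> (chr7, None) or ``"chr9p"``/``"9p"`` -> (chr9, p)."""
    chromosomes = set(chromosomes)
    if name in chromosomes:
        return name, None
    if name and name[-1] in "pq":
        stem = name[:-1]
        if stem in chromosomes:
            return stem, name[-1]
        if "chr" + stem in chromosomes:
            return "chr" + stem, name[-1]
    if "chr" + name in chromosomes:
        return "chr" + name, None
    raise ValueError(f"unknown region {name!r}")


@dataclasses.dataclass
class GenomicBaseline:
    """Genomic and per-chromosome location/scale of a pattern."""

    genomic_mean: float
    genomic_std: float
    per_chromosome: dict[str, tuple[float, float]]
    excluded_regions: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genomic_std > 0:
            raise ValueError("degenerate baseline: genomic standard deviation is 0")


@dataclasses.dataclass
class CNACall:
    region_kind: str  # chromosome | arm | segment | probe
    region: str
    chromosome: str
    start: int
    end: int
    direction: str  # gain | loss | none
    genomic_deviation: float  # multiples of genomic std
    chromosomal_deviation: float  # multiples of chromosomal std (NaN if n/a)
    rule_fired: str  # genomic | chromosomal | none


def _check_pattern(pattern: np.ndarray, probes: pd.DataFrame) -> np.ndarray:
    pattern = np.asarray(pattern, dtype=float)
    if pattern.ndim != 1 or pattern.size != len(probes):
        raise ValueError(
            f"pattern length {pattern.size} does not match {len(probes)} probes"
        )
    return pattern


def _region_mask(probes: pd.DataFrame, chromosome: str, arm: str | None) -> np.ndarray:
    mask = (probes["chromosome"] == chromosome).to_numpy()
    if arm is not None:
        if "arm" not in probes.columns:
            raise ValueError("arm-level regions need an 'arm' annotation column")
        mask &= (probes["arm"] == arm).to_numpy()
    return mask


def compute_baseline(
    pattern: np.ndarray,
    probes: pd.DataFrame,
    excluded: Sequence[str] = DEFAULT_EXCLUDED,
    strict_excluded: bool = False,
) -> GenomicBaseline:
    """Autosomal genomic mean/std outside the excluded regions, plus
    per-chromosome statistics over every chromosome's full probe set.

    Excluded regions naming chromosomes absent from the annotation are
    skipped with a warning unless ``strict_excluded``.
    """
    probes = probes.reset_index(drop=True)
    pattern = _check_pattern(pattern, probes)
    chromosomes = set(probes["chromosome"])
    keep = np.fromiter(
        (is_autosome(c) for c in probes["chromosome"]), bool, len(probes)
    )
    applied = []
    for name in excluded:
        try:
            chrom, arm = parse_region(name, chromosomes)
        except ValueError:
            if strict_excluded:
                raise
            log.warning("excluded region %r not in annotation; skipped", name)
            continue
        keep &= ~_region_mask(probes, chrom, arm)
        applied.append(name)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 probes remain for the genomic baseline")
    genomic = pattern[keep]
    genomic_std = float(np.std(genomic, ddof=1))
    per_chromosome = {}
    for chrom, idx in probes.groupby("chromosome", sort=False).groups.items():
        values = pattern[np.asarray(idx)]
        std = float(np.std(values, ddof=1)) if values.size > 1 else float("nan")
        per_chromosome[str(chrom)] = (float(np.mean(values)), std)
    return GenomicBaseline(
        genomic_mean=float(np.mean(genomic)),
        genomic_std=genomic_std,
        per_chromosome=per_chromosome,
        excluded_regions=tuple(applied),
    )


def _genomic_rule(mean: float, baseline: GenomicBaseline) -> tuple[str, float]:
    dev = mean - baseline.genomic_mean
    gdev = dev / baseline.genomic_std
    if dev > 2.0 * baseline.genomic_std:
        return GAIN, gdev
    if dev < -2.0 * baseline.genomic_std:
        return LOSS, gdev
    return NONE, gdev


def call_chromosome_or_arm(
    pattern: np.ndarray,
    probes: pd.DataFrame,
    baseline: GenomicBaseline,
    region: str,
) -> CNACall:
    """Two-genomic-sigma rule on a whole chromosome or arm mean."""
    pattern = _check_pattern(pattern, probes)
    chrom, arm = parse_region(region, set(probes["chromosome"]))
    mask = _region_mask(probes, chrom, arm)
    if not mask.any():
        raise ValueError(f"region {region!r} covers no probes")
    direction, gdev = _genomic_rule(float(pattern[mask].mean()), baseline)
    sub = probes.loc[mask]
    return CNACall(
        region_kind="arm" if arm else "chromosome",
        region=region,
        chromosome=chrom,
        start=int(sub["start"].min()),
        end=int(sub["end"].max()),
        direction=direction,
        genomic_deviation=gdev,
        chromosomal_deviation=float("nan"),
        rule_fired=RULE_GENOMIC if direction != NONE else RULE_NONE,
    )


def _two_rule_call(
    mean: float, chromosome: str, baseline: GenomicBaseline
) -> tuple[str, float, float, str]:
    """Shared segment/probe logic; returns (direction, gdev, cdev, rule)."""
    direction, gdev = _genomic_rule(mean, baseline)
    chrom_mean, chrom_std = baseline.per_chromosome.get(
        chromosome, (float("nan"), float("nan"))
    )
    dev_c = mean - chrom_mean
    cdev = dev_c / chrom_std if chrom_std and np.isfinite(chrom_std) else float("nan")
    if direction != NONE:
        return direction, gdev, cdev, RULE_GENOMIC
    dev_g = mean - baseline.genomic_mean
    if (
        np.isfinite(cdev)
        and abs(dev_c) > chrom_std
        and dev_g != 0.0
        and np.sign(dev_c) == np.sign(dev_g)
    ):
        return (GAIN if dev_c > 0 else LOSS), gdev, cdev, RULE_CHROMOSOMAL
    return NONE, gdev, cdev, RULE_NONE


def segment_probe_mask(
    probes: pd.DataFrame, chromosome: str, start: int, end: int
) -> np.ndarray:
    """A segment's probes are those whose interval midpoint lies in the
    half-open segment."""
    mid = 0.5 * (probes["start"] + probes["end"])
    return (
        (probes["chromosome"] == chromosome) & (mid >= start) & (mid < end)
    ).to_numpy()


def call_segment(
    pattern: np.ndarray,
    probes: pd.DataFrame,
    baseline: GenomicBaseline,
    chromosome: str,
    start: int,
    end: int,
    name: str | None = None,
) -> CNACall:
    pattern = _check_pattern(pattern, probes)
    mask = segment_probe_mask(probes, chromosome, start, end)
    label = name or f"{chromosome}:{start}-{end}"
    if not mask.any():
        raise ValueError(f"segment {label} covers no probes")
    direction, gdev, cdev, rule = _two_rule_call(
        float(pattern[mask].mean()), chromosome, baseline
    )
    return CNACall(
        region_kind="segment",
        region=label,
        chromosome=chromosome,
        start=int(start),
        end=int(end),
        direction=direction,
        genomic_deviation=gdev,
        chromosomal_deviation=cdev,
        rule_fired=rule,
    )


def call_probes(
    pattern: np.ndarray, probes: pd.DataFrame, baseline: GenomicBaseline
) -> list[CNACall]:
    """Per-probe calls under the segment rules with single-probe regions."""
    pattern = _check_pattern(pattern, probes)
    calls = []
    for i in range(len(probes)):
        row = probes.iloc[i]
        direction, gdev, cdev, rule = _two_rule_call(
            float(pattern[i]), str(row["chromosome"]), baseline
        )
        calls.append(
            CNACall(
                region_kind="probe",
                region=str(row["probe_id"]),
                chromosome=str(row["chromosome"]),
                start=int(row["start"]),
                end=int(row["end"]),
                direction=direction,
                genomic_deviation=gdev,
                chromosomal_deviation=cdev,
                rule_fired=rule,
            )
        )
    return calls


def probe_directions(calls: Sequence[CNACall]) -> np.ndarray:
    """Vector of {-1, 0, +1} per probe call."""
    code = {GAIN: 1, NONE: 0, LOSS: -1}
    return np.array([code[c.direction] for c in calls], dtype=int)


def filter_segments(segments: pd.DataFrame, min_probes: int = 5) -> pd.DataFrame:
    """Keep segments spanning at least ``min_probes`` probes."""
    if "probe_count" not in segments.columns:
        raise ValueError("segment table lacks a probe_count column")
    return segments.loc[segments["probe_count"] >= min_probes].reset_index(drop=True)


def calls_to_frame(calls: Sequence[CNACall]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(c) for c in calls])


# ---------------------------------------------------------------------------
# change-point segmentation (visualization aid; permutation-tested recursive
# binary splitting, not an exact reimplementation of published CBS)


def _best_split(x: np.ndarray, min_size: int) -> tuple[int, float]:
    n = x.size
    if n < 2 * min_size:
        return -1, 0.0
    cs = np.cumsum(x)
    i = np.arange(min_size, n - min_size + 1)
    mean_l = cs[i - 1] / i
    mean_r = (cs[-1] - cs[i - 1]) / (n - i)
    stat = np.abs(mean_l - mean_r) * np.sqrt(i * (n - i) / n)
    k = int(np.argmax(stat))
    return int(i[k]), float(stat[k])


def _segment_recursive(
    x: np.ndarray,
    offset: int,
    alpha: float,
    n_permutations: int,
    min_size: int,
    rng: np.random.Generator,
    out: list[int],
) -> None:
    split, stat = _best_split(x, min_size)
    if split < 0 or stat == 0.0:
        return
    exceed = 0
    for _ in range(n_permutations):
        _, perm_stat = _best_split(rng.permutation(x), min_size)
        if perm_stat >= stat:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    if p >= alpha:
        return
    out.append(offset + split)
    _segment_recursive(x[:split], offset, alpha, n_permutations, min_size, rng, out)
    _segment_recursive(
        x[split:], offset + split, alpha, n_permutations, min_size, rng, out
    )


def segment_arraylet(
    pattern: np.ndarray,
    probes: pd.DataFrame,
    alpha: float = 0.01,
    n_permutations: int = 1000,
    min_size: int = 5,
    seed: int | None = 0,
) -> list[int]:
    """Change points (global probe indices) that never cross chromosome
    boundaries; each accepted split passes a permutation test at ``alpha``."""
    probes = probes.reset_index(drop=True)
    pattern = _check_pattern(pattern, probes)
    rng = np.random.default_rng(seed)
    change_points: list[int] = []
    for _, idx in probes.groupby("chromosome", sort=False).groups.items():
        idx = np.asarray(idx)
        _segment_recursive(
            pattern[idx],
            int(idx[0]),
            alpha,
            n_permutations,
            min_size,
            rng,
            change_points,
        )
    return sorted(change_points)
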