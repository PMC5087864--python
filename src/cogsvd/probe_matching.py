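"""One-to-one matching of probes across platforms by genomic overlap.

Two probes match when their half-open intervals share the same chromosome
and overlap by at least one base pair. Conflicts are resolved greedily
scanning platform A in genome order: each A probe takes the not-yet-matched
overlapping B probe whose anchor coordinate (start by default, end behind a
config switch) is nearest its own, residual ties broken by smaller genomic
start and then by smaller index. The result is deterministic and one-to-one.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from cogsvd.data_io import chromosome_sort_key


@dataclasses.dataclass(frozen=True)
class ProbePair:
    index_a: int
    index_b: int
    chromosome: str
    overlap: int

    def __post_init__(self) -> None:
        if self.overlap < 1:
            raise ValueError("matched probes must overlap by at least 1 bp")


def _check_sorted(annotation: pd.DataFrame, label: str) -> None:
    keys = [
        (chromosome_sort_key(c), s)
        for c, s in zip(annotation["chromosome"], annotation["start"])
    ]
    if any(keys[i] > keys[i + 1] for i in range(len(keys) - 1)):
        raise ValueError(f"annotation {label} is not genome-sorted")


def match_probes(
    annotation_a: pd.DataFrame,
    annotation_b: pd.DataFrame,
    anchor: str = "start",
) -> list[ProbePair]:
    """Greedy one-to-one overlap matching of two genome-sorted annotations."""
    if anchor not in ("start", "end"):
        raise ValueError("anchor must be 'start' or 'end'")
    annotation_a = annotation_a.reset_index(drop=True)
    annotation_b = annotation_b.reset_index(drop=True)
    _check_sorted(annotation_a, "A")
    _check_sorted(annotation_b, "B")

    b_by_chrom: dict[str, np.ndarray] = {
        str(chrom): np.asarray(idx)
        for chrom, idx in annotation_b.groupby("chromosome", sort=False).groups.items()
    }
    a_start = annotation_a["start"].to_numpy()
    a_end = annotation_a["end"].to_numpy()
    b_start = annotation_b["start"].to_numpy()
    b_end = annotation_b["end"].to_numpy()

    taken_b: set[int] = set()
    pairs: list[ProbePair] = []
    for ia in range(len(annotation_a)):
        chrom = str(annotation_a["chromosome"].iloc[ia])
        cand = b_by_chrom.get(chrom)
        if cand is None:
            continue
        overlap = np.minimum(a_end[ia], b_end[cand]) - np.maximum(
            a_start[ia], b_start[cand]
        )
        hits = cand[overlap >= 1]
        if hits.size == 0:
            continue
        best = None
        for ib in hits:
            ib = int(ib)
            if ib in taken_b:
                continue
            if anchor == "start":
                dist = abs(int(b_start[ib]) - int(a_start[ia]))
            else:
                dist = abs(int(b_end[ib]) - int(a_end[ia]))
            key = (dist, int(b_start[ib]), ib)
            if best is None or key < best[0]:
                best = (key, ib)
        if best is None:
            continue
        ib = best[1]
        taken_b.add(ib)
        pairs.append(
            ProbePair(
                index_a=ia,
                index_b=ib,
                chromosome=chrom,
                overlap=int(
                    min(a_end[ia], b_end[ib]) - max(a_start[ia], b_start[ib])
                ),
            )
        )
    return pairs


def consistent_pairs(
    pairs: Sequence[ProbePair],
    directions_a: np.ndarray,
    directions_b: np.ndarray,
) -> list[ProbePair]:
    """Pairs whose probes are aberrated in the same direction on both
    platforms (gain/gain or loss/loss); unaberrated and discordant pairs are
    dropped. Directions are {-1, 0, +1} vectors indexed like the annotations
    (see :func:`cogsvd.cna_calling.probe_directions`)."""
    directions_a = np.asarray(directions_a)
    directions_b = np.asarray(directions_b)
    for pair in pairs:
        if pair.index_a >= directions_a.size or pair.index_b >= directions_b.size:
            raise ValueError("call vector shorter than the annotation it describes")
    return [
        p
        for p in pairs
        if directions_a[p.index_a] != 0
        and directions_a[p.index_a] == directions_b[p.index_b]
    ]


def project_profile(
    profile: np.ndarray, pairs: Sequence[ProbePair], side: str
) -> np.ndarray:
    """Restrict a patient profile to the paired probes, in pair order.

    Missing entries (NaN) are preserved.
    """
    if side not in ("a", "b"):
        raise ValueError("side must be 'a' or 'b'")
    profile = np.asarray(profile, dtype=float)
    idx = np.array(
        [p.index_a if side == "a" else p.index_b for p in pairs], dtype=int
    )
    if idx.size and (idx.max() >= profile.size or idx.min() < 0):
        raise ValueError("pair index out of range for the given profile")
    return profile[idx]


def pairs_to_frame(
    pairs: Sequence[ProbePair],
    annotation_a: pd.DataFrame,
    annotation_b: pd.DataFrame,
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probe_a": [annotation_a["probe_id"].iloc[p.index_a] for p in pairs],
            "probe_b": [annotation_b["probe_id"].iloc[p.index_b] for p in pairs],
            "chromosome": [p.chromosome for p in pairs],
            "overlap_bp": [p.overlap for p in pairs],
        }
    )


def pairs_from_frame(
    frame: pd.DataFrame,
    annotation_a: pd.DataFrame,
    annotation_b: pd.DataFrame,
) -> list[ProbePair]:
    """Inverse of :func:`pairs_to_frame` against the same annotations."""
    index_a = {pid: i for i, pid in enumerate(annotation_a["probe_id"])}
    index_b = {pid: i for i, pid in enumerate(annotation_b["probe_id"])}
    pairs = []
    for row in frame.itertuples(index=False):
        pairs.append(
            ProbePair(
                index_a=index_a[row.probe_a],
                index_b=index_b[row.probe_b],
                chromosome=str(row.chromosome),
                overlap=int(row.overlap_bp),
            )
        )
    return pairs
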