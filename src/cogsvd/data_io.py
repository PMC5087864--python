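"""Reading, writing and validation of copy-number cohort files.

File conventions
----------------
* Copy-number matrix: TSV; first column ``probe_id``, remaining columns one
  per patient; empty cells or ``NA`` denote missing values (never imputed).
* Probe annotation: headerless 4-column TSV ``(probe_id, chromosome, start,
  end)`` with BED-style 0-based half-open coordinates.
* Centromere table: TSV with header ``chromosome\tcentromere_start\t
  centromere_end``; used to derive chromosome arms.
* Clinical table: TSV with header, one row per patient, ``patient_id`` column
  required.
* Segment table: TSV with header ``chromosome\tstart\tend\tprobe_count``.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING_TOKEN = "NA"

ANNOTATION_COLUMNS = ("probe_id", "chromosome", "start", "end")

_SEX_CHROM_RE = re.compile(r"^(chr)?[xy]$", re.IGNORECASE)


def chromosome_sort_key(chromosome: str) -> tuple[int, float, str]:
    """Genome-order sort key: chr1..chr22 numerically, then chrX, chrY, rest."""
    name = chromosome[3:] if chromosome.lower().startswith("chr") else chromosome
    if name.isdigit():
        return (0, int(name), "")
    if name.upper() == "X":
        return (1, 0, "")
    if name.upper() == "Y":
        return (1, 1, "")
    return (2, 0, name)


def is_autosome(chromosome: str) -> bool:
    return not _SEX_CHROM_RE.match(chromosome)


@dataclasses.dataclass(frozen=True)
class ProbeLocus:
    """A probe's genomic interval (0-based, half-open) and derived arm."""

    probe_id: str
    chromosome: str
    start: int
    end: int
    arm: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"probe {self.probe_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.start < 0:
            raise ValueError(f"probe {self.probe_id}: negative start {self.start}")
        if self.arm is not None and self.arm not in ("p", "q"):
            raise ValueError(f"probe {self.probe_id}: invalid arm {self.arm!r}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclasses.dataclass
class CopyNumberDataset:
    """Probes x patients matrix of log2 relative copy numbers.

    ``values`` is an ``(M, N)`` float array with ``NaN`` marking missing
    cells; ``probes`` is a DataFrame with columns ``probe_id, chromosome,
    start, end`` (and optionally ``arm``) in the same row order as
    ``values``; ``patients`` is the ordered list of patient ids.
    """

    values: np.ndarray
    probes: pd.DataFrame
    patients: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        self.patients = [str(p) for p in self.patients]
        if self.values.shape != (len(self.probes), len(self.patients)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape}, "
                f"{len(self.probes)} probes, {len(self.patients)} patients"
            )
        if len(set(self.patients)) != len(self.patients):
            raise ValueError("duplicate patient ids")
        ids = self.probes["probe_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].tolist()[:5]
            raise ValueError(f"duplicate probe ids, e.g. {dupes}")
        bad = self.probes["end"] <= self.probes["start"]
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} probes with end <= start, "
                f"e.g. {self.probes.loc[bad, 'probe_id'].iloc[0]}"
            )

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_patients(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "CopyNumberDataset":
        return CopyNumberDataset(
            self.values.copy(), self.probes.copy(), list(self.patients)
        )

    def sort_genomic(self) -> "CopyNumberDataset":
        """Return a copy sorted by (chromosome in genome order, start)."""
        key = self.probes["chromosome"].map(chromosome_sort_key)
        frame = self.probes.assign(_key=key).sort_values(
            ["_key", "start"], kind="stable"
        )
        order = frame.index.to_numpy()
        probes = frame.drop(columns="_key").reset_index(drop=True)
        return CopyNumberDataset(self.values[order], probes, list(self.patients))

    def subset_probes(self, mask: np.ndarray) -> "CopyNumberDataset":
        mask = np.asarray(mask)
        return CopyNumberDataset(
            self.values[mask],
            self.probes.loc[mask].reset_index(drop=True),
            list(self.patients),
        )


# ---------------------------------------------------------------------------
# readers / writers


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a headerless BED-like probe annotation TSV."""
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=list(ANNOTATION_COLUMNS),
        dtype={"probe_id": str, "chromosome": str, "start": np.int64, "end": np.int64},
    )
    if frame["probe_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate probe ids in annotation")
    if (frame["end"] <= frame["start"]).any():
        raise ValueError(f"{path}: annotation intervals with end <= start")
    if (frame["start"] < 0).any():
        raise ValueError(f"{path}: negative start coordinates")
    return frame


def write_annotation(probes: pd.DataFrame, path: str | Path) -> None:
    probes[list(ANNOTATION_COLUMNS)].to_csv(path, sep="\t", header=False, index=False)


def read_centromeres(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    required = {"chromosome", "centromere_start", "centromere_end"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: centromere table missing columns {sorted(missing)}")
    return frame


def assign_arms(probes: pd.DataFrame, centromeres: pd.DataFrame) -> pd.DataFrame:
    """Attach an ``arm`` column: p before, q after the centromere midpoint."""
    cen = centromeres.set_index("chromosome")
    mid = 0.5 * (probes["start"] + probes["end"])
    arms = []
    for chrom, m in zip(probes["chromosome"], mid):
        if chrom not in cen.index:
            arms.append(None)
            continue
        row = cen.loc[chrom]
        if m < row["centromere_start"]:
            arms.append("p")
        elif m >= row["centromere_end"]:
            arms.append("q")
        else:
            cmid = 0.5 * (row["centromere_start"] + row["centromere_end"])
            arms.append("p" if m < cmid else "q")
    out = probes.copy()
    out["arm"] = arms
    return out


def read_copy_number(
    path: str | Path,
    annotation_path: str | Path,
    centromere_path: str | Path | None = None,
    max_unannotated_fraction: float = 0.5,
) -> CopyNumberDataset:
    """Read a copy-number matrix plus probe annotation into a dataset.

    Probes lacking annotation are dropped (count logged); probes annotated
    but absent from the matrix are ignored. If more than
    ``max_unannotated_fraction`` of the matrix probes lack annotation the
    id universes are considered mismatched and a hard error is raised.
    """
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
    raw_patients = header[1:]
    if len(set(raw_patients)) != len(raw_patients):  # pandas mangles duplicates
        raise ValueError(f"{path}: duplicate patient column ids")
    frame = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[MISSING_TOKEN], keep_default_na=True
    )
    frame.index = frame.index.astype(str)
    if frame.index.duplicated().any():
        raise ValueError(f"{path}: duplicate probe ids")
    patients = [str(c) for c in frame.columns]

    annotation = read_annotation(annotation_path)
    annotated = annotation.set_index("probe_id")
    in_both = frame.index.intersection(annotated.index)
    n_dropped = len(frame.index) - len(in_both)
    if len(frame.index) and n_dropped / len(frame.index) > max_unannotated_fraction:
        raise ValueError(
            f"{path}: {n_dropped}/{len(frame.index)} probes lack annotation "
            f"(> {max_unannotated_fraction:.0%}); matrix/annotation mismatch"
        )
    if n_dropped:
        log.warning("%s: dropped %d probes without annotation", path, n_dropped)

    frame = frame.loc[in_both]
    probes = annotated.loc[in_both].reset_index()[list(ANNOTATION_COLUMNS)]
    if centromere_path is not None:
        probes = assign_arms(probes, read_centromeres(centromere_path))
    dataset = CopyNumberDataset(frame.to_numpy(dtype=float), probes, patients)
    return dataset.sort_genomic()


def write_copy_number(dataset: CopyNumberDataset, path: str | Path) -> None:
    frame = pd.DataFrame(
        dataset.values,
        index=pd.Index(dataset.probes["probe_id"], name="probe_id"),
        columns=dataset.patients,
    )
    frame.to_csv(path, sep="\t", na_rep=MISSING_TOKEN)


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV indexed by ``patient_id``."""
    frame = pd.read_csv(
        path, sep="\t", dtype={"patient_id": str}, na_values=[MISSING_TOKEN]
    )
    if "patient_id" not in frame.columns:
        raise ValueError(f"{path}: clinical table lacks a patient_id column")
    if frame["patient_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate patients in clinical table")
    return frame.set_index("patient_id")


def read_segments(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    required = {"chromosome", "start", "end"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: segment table missing columns {sorted(missing)}")
    return frame


# ---------------------------------------------------------------------------
# transformations / validation


def median_center(dataset: CopyNumberDataset) -> CopyNumberDataset:
    """Center every patient column at zero median over its non-missing cells."""
    values = dataset.values.copy()
    for j, patient in enumerate(dataset.patients):
        column = values[:, j]
        finite = np.isfinite(column)
        if not finite.any():
            raise ValueError(f"patient {patient}: all values missing")
        column[finite] -= np.median(column[finite])
    return CopyNumberDataset(values, dataset.probes.copy(), list(dataset.patients))


def drop_incomplete_probes(dataset: CopyNumberDataset) -> CopyNumberDataset:
    """Drop probes missing in any patient (logged), as required by the GSVD."""
    complete = np.isfinite(dataset.values).all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.warning("dropped %d probes with missing values", n_dropped)
    return dataset.subset_probes(complete)


def numerical_rank(matrix: np.ndarray, tol: float | None = None) -> int:
    s = np.linalg.svd(matrix, compute_uv=False)
    if s.size == 0:
        return 0
    if tol is None:
        tol = min(matrix.shape) * np.finfo(float).eps * s[0]
    return int((s > tol).sum())


def validate_pair(
    tumor: CopyNumberDataset,
    normal: CopyNumberDataset,
    rank_tol: float | None = None,
) -> tuple[CopyNumberDataset, CopyNumberDataset]:
    """Check the column-matched full-rank structure the GSVD requires.

    Patient lists must be identical and identically ordered; each matrix
    must have numerical column rank N (missing cells are treated as rank
    failure since the decomposition cannot run on them anyway). Probe sets
    may differ freely.
    """
    if tumor.patients != normal.patients:
        sym = set(tumor.patients) ^ set(normal.patients)
        if sym:
            raise ValueError(
                f"patient mismatch between tumor and normal: {sorted(sym)}"
            )
        raise ValueError("patient columns are permuted between tumor and normal")
    for name, ds in (("tumor", tumor), ("normal", normal)):
        if ds.n_probes < ds.n_patients:
            raise ValueError(
                f"{name}: fewer probes ({ds.n_probes}) than patients ({ds.n_patients})"
            )
        values = ds.values
        if not np.isfinite(values).all():
            values = np.nan_to_num(values)  # missing cells void rank anyway
        if numerical_rank(values, rank_tol) < ds.n_patients:
            raise ValueError(f"{name}: matrix is not of full column rank")
    return tumor, normal


def align_patients(
    dataset: CopyNumberDataset, patients: Sequence[str]
) -> CopyNumberDataset:
    """Reorder patient columns to match ``patients`` (all must be present)."""
    index = {p: j for j, p in enumerate(dataset.patients)}
    missing = [p for p in patients if p not in index]
    if missing:
        raise ValueError(f"patients absent from dataset: {missing}")
    cols = [index[p] for p in patients]
    return CopyNumberDataset(
        dataset.values[:, cols], dataset.probes.copy(), list(patients)
    )
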