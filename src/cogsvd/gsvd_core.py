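"""Comparative generalized SVD of a tumor/normal copy-number pair.

Given two full-column-rank matrices ``D1`` (M1 x N) and ``D2`` (M2 x N) with
matched columns, the decomposition

    ``D_i = U_i @ diag(sigma_i) @ V.T``        (i = 1, 2)

shares a single set of unit-norm (not necessarily orthogonal) right basis
vectors — the *probelets*, patterns of variation across patients — while the
left basis vectors (*arraylets*, patterns across the genome) are orthonormal
within each dataset. The ratio ``sigma1/sigma2`` measures how exclusive a
probelet is to the first dataset; the angular distance maps it onto
``[-pi/4, pi/4]``.

The implementation takes a thin QR of the stacked ``(M1+M2) x N`` matrix and
computes the thin cosine-sine decomposition of the partitioned orthonormal
factor via an SVD of its upper block, which is stable for M >> N.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import xlogy

from cogsvd.data_io import CopyNumberDataset, numerical_rank

DEFAULT_EXCLUSIVE_MIN = 2.0 * math.pi / 15.0
DEFAULT_COMMON_MAX = math.pi / 16.0

LABEL_TUMOR = "tumor_exclusive"
LABEL_NORMAL = "normal_exclusive"
LABEL_COMMON = "common"
LABEL_INTERMEDIATE = "intermediate"


@dataclasses.dataclass(frozen=True)
class ExclusivityThresholds:
    """Angular-distance bands separating exclusive from common components."""

    exclusive_min: float = DEFAULT_EXCLUSIVE_MIN
    common_max: float = DEFAULT_COMMON_MAX

    def __post_init__(self) -> None:
        if not (0.0 < self.common_max < self.exclusive_min <= math.pi / 4 + 1e-15):
            raise ValueError(
                "thresholds must satisfy 0 < common_max < exclusive_min <= pi/4"
            )


@dataclasses.dataclass
class GSVDModel:
    """Paired decomposition D_i = U_i diag(sigma_i) V^T."""

    u1: np.ndarray  # (M1, N), orthonormal columns (tumor arraylets)
    u2: np.ndarray  # (M2, N), orthonormal columns (normal arraylets)
    sigma1: np.ndarray  # (N,), non-negative
    sigma2: np.ndarray  # (N,), non-negative
    v: np.ndarray  # (N, N), unit-2-norm columns (probelets)
    theta: np.ndarray  # (N,), angular distances in [-pi/4, pi/4]
    patients: list[str] | None = None

    @property
    def n_components(self) -> int:
        return self.v.shape[1]

    def fractions(self, dataset: int) -> np.ndarray:
        return generalized_fractions(self.sigma1 if dataset == 1 else self.sigma2)

    def entropy(self, dataset: int) -> float:
        return generalized_entropy(self.fractions(dataset))

    def reconstruct(self, dataset: int) -> np.ndarray:
        u, s = (self.u1, self.sigma1) if dataset == 1 else (self.u2, self.sigma2)
        return (u * s) @ self.v.T

    def copy(self) -> "GSVDModel":
        return GSVDModel(
            self.u1.copy(),
            self.u2.copy(),
            self.sigma1.copy(),
            self.sigma2.copy(),
            self.v.copy(),
            self.theta.copy(),
            None if self.patients is None else list(self.patients),
        )


def angular_distance(sigma1_n, sigma2_n):
    """theta = arctan(sigma1/sigma2) - pi/4, with the sigma2=0 limit +pi/4.

    Accepts scalars or arrays; both-zero pairs are an error since the
    component would be absent from both datasets.
    """
    s1 = np.asarray(sigma1_n, dtype=float)
    s2 = np.asarray(sigma2_n, dtype=float)
    if np.any(s1 < 0) or np.any(s2 < 0):
        raise ValueError("generalized singular values must be non-negative")
    if np.any((s1 == 0) & (s2 == 0)):
        raise ValueError("angular distance undefined for sigma1 = sigma2 = 0")
    out = np.arctan2(s1, s2) - math.pi / 4
    return float(out) if out.ndim == 0 else out


def generalized_fractions(sigma: np.ndarray) -> np.ndarray:
    """p_n = sigma_n^2 / sum(sigma^2): the share of a dataset's information
    captured by each component."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("generalized singular values must be non-negative")
    total = float(np.sum(sigma**2))
    if total == 0.0:
        raise ValueError("all-zero singular value vector")
    return sigma**2 / total


def generalized_entropy(fractions: np.ndarray) -> float:
    """Shannon entropy of the fraction distribution, normalized to [0, 1]."""
    p = np.asarray(fractions, dtype=float)
    if p.size < 2:
        raise ValueError("entropy requires at least two components")
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("fractions must form a probability vector")
    p = np.clip(p, 0.0, 1.0)
    return float(-np.sum(xlogy(p, p)) / math.log(p.size))


def _complete_orthonormal(u: np.ndarray, undefined: np.ndarray, rng_seed: int = 0):
    """Fill columns flagged ``undefined`` with an orthonormal completion."""
    if not undefined.any():
        return u
    m, n = u.shape
    rng = np.random.default_rng(rng_seed)
    basis = u[:, ~undefined]
    for j in np.flatnonzero(undefined):
        for _ in range(50):
            cand = rng.standard_normal(m)
            cand -= basis @ (basis.T @ cand)
            norm = np.linalg.norm(cand)
            if norm > 1e-8:
                u[:, j] = cand / norm
                basis = np.hstack([basis, u[:, j : j + 1]])
                break
        else:  # pragma: no cover - would need m < n
            raise np.linalg.LinAlgError("cannot complete orthonormal basis")
    return u


def gsvd_matrices(
    d1: np.ndarray, d2: np.ndarray, rank_tol: float | None = None
) -> GSVDModel:
    """Comparative GSVD of two raw arrays (see :func:`compute_gsvd`)."""
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.ndim != 2 or d2.ndim != 2 or d1.shape[1] != d2.shape[1]:
        raise ValueError("inputs must be 2-D with equal column counts")
    if np.isnan(d1).any() or np.isnan(d2).any():
        raise ValueError("missing values: drop or complete probes before the GSVD")
    m1, n = d1.shape
    m2 = d2.shape[0]
    if m1 < n or m2 < n:
        raise ValueError("each matrix needs at least as many rows as columns")
    for name, d in (("first", d1), ("second", d2)):
        if numerical_rank(d, rank_tol) < n:
            raise ValueError(f"{name} matrix is rank deficient")

    q, r = np.linalg.qr(np.vstack([d1, d2]))
    q1, q2 = q[:m1], q[m1:]

    # thin CS decomposition of [Q1; Q2]: SVD of Q1 gives the cosines, and
    # Q2 W has orthogonal columns of norm sin (since Q1'Q1 + Q2'Q2 = I)
    u1, cos, wt = np.linalg.svd(q1, full_matrices=False)
    cos = np.clip(cos, 0.0, 1.0)
    w = wt.T
    b2 = q2 @ w
    sin = np.linalg.norm(b2, axis=0)
    defined = sin > 1e-12
    u2 = np.zeros_like(b2)
    u2[:, defined] = b2[:, defined] / sin[defined]
    u2 = _complete_orthonormal(u2, ~defined)

    v_raw = r.T @ w  # columns are the unnormalized probelets
    norms = np.linalg.norm(v_raw, axis=0)
    if np.any(norms <= 0):
        raise ValueError("degenerate probelet with zero norm")
    v = v_raw / norms
    sigma1 = cos * norms
    sigma2 = sin * norms
    theta = angular_distance(sigma1, sigma2)

    model = GSVDModel(u1, u2, sigma1, sigma2, v, np.asarray(theta))
    return canonicalize(model)


def compute_gsvd(
    tumor: CopyNumberDataset,
    normal: CopyNumberDataset,
    rank_tol: float | None = None,
) -> GSVDModel:
    """Comparative GSVD of a validated tumor/normal dataset pair.

    The returned model is canonicalized: components in decreasing angular
    distance, probelet signs fixed by the largest-magnitude-entry-positive
    convention.
    """
    if tumor.patients != normal.patients:
        raise ValueError("datasets must share an identical patient list")
    model = gsvd_matrices(tumor.values, normal.values, rank_tol)
    model.patients = list(tumor.patients)
    return model


def canonicalize(model: GSVDModel) -> GSVDModel:
    """Deterministic ordering and signs; idempotent.

    Components are sorted by (theta desc, sigma1 desc, original index asc);
    each probelet is flipped (jointly with both arraylets) so that its entry
    of largest absolute value is positive.
    """
    n = model.n_components
    order = np.lexsort((np.arange(n), -model.sigma1, -model.theta))
    out = GSVDModel(
        model.u1[:, order].copy(),
        model.u2[:, order].copy(),
        model.sigma1[order].copy(),
        model.sigma2[order].copy(),
        model.v[:, order].copy(),
        model.theta[order].copy(),
        None if model.patients is None else list(model.patients),
    )
    peaks = np.abs(out.v).argmax(axis=0)
    flip = out.v[peaks, np.arange(n)] < 0
    out.v[:, flip] *= -1
    out.u1[:, flip] *= -1
    out.u2[:, flip] *= -1
    return out


def classify_components(
    model: GSVDModel, thresholds: ExclusivityThresholds | None = None
) -> list[str]:
    """Label each component by exclusivity band of its angular distance."""
    thresholds = thresholds or ExclusivityThresholds()
    labels = []
    for theta in model.theta:
        if theta > thresholds.exclusive_min:
            labels.append(LABEL_TUMOR)
        elif theta < -thresholds.exclusive_min:
            labels.append(LABEL_NORMAL)
        elif abs(theta) < thresholds.common_max:
            labels.append(LABEL_COMMON)
        else:
            labels.append(LABEL_INTERMEDIATE)
    return labels


def check_model(
    model: GSVDModel,
    d1: np.ndarray,
    d2: np.ndarray,
    rtol: float = 1e-8,
) -> None:
    """Raise if the factorization invariants fail at relative tolerance."""
    for name, d, u, s in (
        ("first", d1, model.u1, model.sigma1),
        ("second", d2, model.u2, model.sigma2),
    ):
        recon = (u * s) @ model.v.T
        err = np.linalg.norm(recon - d) / max(np.linalg.norm(d), 1e-300)
        if err > rtol:
            raise AssertionError(f"{name} reconstruction error {err:.2e} > {rtol}")
        gram = u.T @ u
        dev = np.abs(gram - np.eye(gram.shape[0])).max()
        if dev > rtol:
            raise AssertionError(f"{name} arraylets not orthonormal (dev {dev:.2e})")
    norms = np.linalg.norm(model.v, axis=0)
    if np.abs(norms - 1.0).max() > rtol:
        raise AssertionError("probelets not unit norm")


# ---------------------------------------------------------------------------
# serialization


def model_summary(
    model: GSVDModel, thresholds: ExclusivityThresholds | None = None
) -> pd.DataFrame:
    labels = classify_components(model, thresholds)
    return pd.DataFrame(
        {
            "n": np.arange(1, model.n_components + 1),
            "sigma1": model.sigma1,
            "sigma2": model.sigma2,
            "theta": model.theta,
            "fraction1": model.fractions(1),
            "fraction2": model.fractions(2),
            "label": labels,
        }
    )


def write_model(
    model: GSVDModel,
    out_dir: str | Path,
    tumor_probe_ids=None,
    normal_probe_ids=None,
    thresholds: ExclusivityThresholds | None = None,
    write_arraylets: bool = True,
) -> None:
    """Write summary, probelet and (optionally) arraylet TSVs to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    component_names = [f"component_{k + 1}" for k in range(model.n_components)]
    model_summary(model, thresholds).to_csv(
        out_dir / "summary.tsv", sep="\t", index=False
    )
    patients = model.patients or [f"patient_{j + 1}" for j in range(model.v.shape[0])]
    pd.DataFrame(model.v, index=patients, columns=component_names).to_csv(
        out_dir / "probelets.tsv", sep="\t", index_label="patient_id"
    )
    if write_arraylets:
        for name, u, ids in (
            ("arraylets_tumor.tsv", model.u1, tumor_probe_ids),
            ("arraylets_normal.tsv", model.u2, normal_probe_ids),
        ):
            index = (
                pd.Index(ids, name="probe_id")
                if ids is not None
                else pd.RangeIndex(u.shape[0], name="row")
            )
            pd.DataFrame(u, index=index, columns=component_names).to_csv(
                out_dir / name, sep="\t"
            )
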