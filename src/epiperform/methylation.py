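"""Beta/M-value computation, probe QC and quantile normalization.

Methylation at a CpG is summarized as a beta value
``β = meth / (meth + unmeth + offset)`` in [0, 1], or on the log2-odds
scale as an M-value ``M = log2(β / (1 − β))``, the preferred scale for
regression.  Probe reliability is judged by a detection p-value — the
upper-tail probability of the observed intensity under a normal background
model estimated from negative-control probes — and probes failing the
threshold in too many samples are dropped.  Samples are then forced onto a
common empirical distribution by quantile normalization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BetaMatrix",
    "QcReport",
    "BETA_CLIP_EPS",
    "beta_from_intensities",
    "m_from_beta",
    "detection_p",
    "filter_probes",
    "quantile_normalize",
    "global_mean_beta",
]

#: clipping half-width applied to betas before the logit, keeps M finite
BETA_CLIP_EPS = 1e-3


@dataclass
class BetaMatrix:
    """CpG × sample methylation fractions with an optional detection-p matrix.

    ``values`` is a DataFrame with CpG ids as the index and sample ids as
    columns, entries in [0, 1].  ``detection_p`` (if given) shares both axes.
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ValueError("duplicate CpG ids")
        if v.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        arr = v.to_numpy(dtype=float)
        if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
            raise ValueError("beta values must lie in [0, 1]")
        if self.detection_p is not None:
            d = self.detection_p
            if d.shape != v.shape or list(d.index) != list(v.index) or \
                    list(d.columns) != list(v.columns):
                raise ValueError("detection_p axes must match the beta matrix")

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="cpg_id")

    @classmethod
    def from_tsv(cls, path: str | Path,
                 detection_p_path: str | Path | None = None) -> "BetaMatrix":
        values = pd.read_csv(path, sep="\t", index_col="cpg_id")
        values.index.name = None
        detp = None
        if detection_p_path is not None:
            detp = pd.read_csv(detection_p_path, sep="\t", index_col="cpg_id")
            detp.index.name = None
        return cls(values=values, detection_p=detp)


@dataclass(frozen=True)
class QcReport:
    """Per-probe detection failure fractions and the removal tally."""

    fail_fraction: pd.Series
    probes_removed: int
    threshold: float
    max_fail_fraction: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "probes_removed": self.probes_removed,
            "threshold": self.threshold,
            "max_fail_fraction": self.max_fail_fraction,
            "probes_tested": int(len(self.fail_fraction)),
        }, indent=1) + "\n")


def beta_from_intensities(meth, unmeth, offset: float = 100.0):
    """β = meth / (meth + unmeth + offset); array-friendly."""
    meth = np.asarray(meth, dtype=float)
    unmeth = np.asarray(unmeth, dtype=float)
    if np.any(meth < 0) or np.any(unmeth < 0):
        raise ValueError("intensities must be non-negative")
    denom = meth + unmeth + offset
    with np.errstate(invalid="ignore"):
        beta = np.where(denom > 0, meth / denom, 0.0)
    return beta if beta.ndim else float(beta)


def m_from_beta(beta, eps: float = BETA_CLIP_EPS):
    """M = log2(β/(1−β)) with β clipped into [eps, 1−eps] first."""
    beta = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    m = np.log2(beta / (1.0 - beta))
    return m if m.ndim else float(m)


def detection_p(signal, bg_mean: float, bg_sd: float):
    """Upper-tail probability of the signal under normal(bg_mean, bg_sd)."""
    if bg_sd <= 0:
        raise ValueError("background sd must be positive")
    p = stats.norm.sf(np.asarray(signal, dtype=float), loc=bg_mean, scale=bg_sd)
    return p if p.ndim else float(p)


def filter_probes(matrix: BetaMatrix, threshold: float = 0.01,
                  max_fail_fraction: float = 0.0) -> tuple[BetaMatrix, QcReport]:
    """Drop probes whose detection-p failure fraction exceeds the cap.

    A sample "fails" a probe when its detection p exceeds ``threshold``;
    a probe is removed when its failing-sample fraction exceeds
    ``max_fail_fraction`` (default 0: any failure drops the probe).
    """
    if matrix.detection_p is None:
        raise ValueError("probe filtering requires a detection_p matrix")
    fail = (matrix.detection_p > threshold).mean(axis=1)
    keep = fail <= max_fail_fraction
    report = QcReport(
        fail_fraction=fail,
        probes_removed=int((~keep).sum()),
        threshold=threshold,
        max_fail_fraction=max_fail_fraction,
    )
    filtered = BetaMatrix(
        values=matrix.values.loc[keep],
        detection_p=matrix.detection_p.loc[keep],
    )
    return filtered, report


def _qn_array(x: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns of a 2-D array.

    Every column's sorted vector becomes the rank-wise mean of all sorted
    columns; within-column ties receive the mean of the reference values at
    their tied ranks, preserving the tie.
    """
    n_rows, _ = x.shape
    order = np.argsort(x, axis=0, kind="stable")
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x, dtype=float)
    for j in range(x.shape[1]):
        col = x[:, j]
        idx = order[:, j]
        mapped = np.empty(n_rows)
        mapped[idx] = reference
        # average the reference over runs of tied input values
        sorted_col = col[idx]
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        stops = np.concatenate((boundaries, [n_rows]))
        for a, b in zip(starts, stops):
            if b - a > 1:
                mapped[idx[a:b]] = reference[a:b].mean()
        out[:, j] = mapped
    return out


def quantile_normalize(matrix: BetaMatrix | pd.DataFrame) -> BetaMatrix | pd.DataFrame:
    """Force all samples (columns) onto the rank-wise mean distribution."""
    values = matrix.values if isinstance(matrix, BetaMatrix) else matrix
    if values.size == 0:
        raise ValueError("cannot normalize an empty matrix")
    if values.isna().any().any():
        raise ValueError("missing values present; run QC first")
    normed = pd.DataFrame(
        _qn_array(values.to_numpy(dtype=float)),
        index=values.index, columns=values.columns,
    )
    if isinstance(matrix, BetaMatrix):
        return BetaMatrix(values=normed, detection_p=matrix.detection_p)
    return normed


def global_mean_beta(matrix: BetaMatrix | pd.DataFrame) -> pd.Series:
    """Per-sample mean beta over all retained CpGs (global methylation)."""
    values = matrix.values if isinstance(matrix, BetaMatrix) else matrix
    if len(values.index) == 0:
        raise ValueError("no probes left to average")
    return values.mean(axis=0)
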