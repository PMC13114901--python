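"""Linear epigenetic-clock application and age calibration.

An epigenetic clock is a linear combination of CpG beta values plus an
intercept; the linear predictor is either already in years (``identity``
calibration) or passed through the piecewise log-linear transform used by
several published blood/skin clocks::

    age(lp) = (adult_age + 1) * exp(lp) - 1        if lp < 0
            = (adult_age + 1) * lp + adult_age     otherwise

which inverts F(age) = log(age+1) - log(adult_age+1) below the adult-age
knot and (age - adult_age)/(adult_age+1) above it.

The per-sample age delta is defined as chronological minus clock age, so a
positive delta means the sample looks biologically *younger* than its
chronological age.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .methylation import BetaMatrix

__all__ = [
    "ClockDefinition",
    "ClockEstimate",
    "MissingCpGError",
    "load_clock_definition",
    "linear_predictor",
    "calibrate_age",
    "estimate_cohort",
    "delta_summary",
]

INTERCEPT_ID = "(Intercept)"


class MissingCpGError(KeyError):
    """A clock CpG is absent from the beta matrix under policy 'error'."""


@dataclass(frozen=True)
class ClockDefinition:
    """Intercept + CpG coefficient map + calibration mode for one clock."""

    name: str
    intercept: float
    coefficients: pd.Series  # index: cpg_id, values: weights
    calibration: str = "identity"
    adult_age: float = 20.0

    def __post_init__(self) -> None:
        if len(self.coefficients) == 0:
            raise ValueError(f"clock {self.name}: empty coefficient map")
        if self.coefficients.index.has_duplicates:
            raise ValueError(f"clock {self.name}: duplicate CpG ids")
        if self.calibration not in ("identity", "log_linear"):
            raise ValueError(f"clock {self.name}: unknown calibration "
                             f"{self.calibration!r}")
        if self.calibration == "log_linear" and self.adult_age <= 0:
            raise ValueError(f"clock {self.name}: adult_age must be positive")

    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        rows = pd.DataFrame({
            "cpg_id": [INTERCEPT_ID, *self.coefficients.index],
            "coefficient": [self.intercept, *self.coefficients.to_numpy()],
        })
        rows.to_csv(path, index=False)
        if sidecar is not None:
            Path(sidecar).write_text(json.dumps({
                "name": self.name,
                "calibration": self.calibration,
                "adult_age": self.adult_age,
            }, indent=1) + "\n")


def load_clock_definition(path: str | Path,
                          sidecar: str | Path | None = None) -> ClockDefinition:
    """Parse a clock CSV (``cpg_id,coefficient`` with one intercept row).

    The optional JSON sidecar carries ``{name, calibration, adult_age}``;
    without it the clock is named after the file and assumed identity-
    calibrated (with a warning).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if not {"cpg_id", "coefficient"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns cpg_id, coefficient")
    if not np.issubdtype(df["coefficient"].dtype, np.number):
        bad = df[pd.to_numeric(df["coefficient"], errors="coerce").isna()]
        raise ValueError(f"{path}: unparseable coefficient rows: "
                         f"{bad['cpg_id'].tolist()[:5]}")
    is_intercept = df["cpg_id"] == INTERCEPT_ID
    if is_intercept.sum() != 1:
        raise ValueError(f"{path}: exactly one {INTERCEPT_ID} row required, "
                         f"found {int(is_intercept.sum())}")
    intercept = float(df.loc[is_intercept, "coefficient"].iloc[0])
    coefs = df.loc[~is_intercept].set_index("cpg_id")["coefficient"]
    if coefs.index.has_duplicates:
        dups = coefs.index[coefs.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated CpG rows: {dups[:5]}")
    meta = {"name": path.stem, "calibration": "identity", "adult_age": 20.0}
    if sidecar is not None and Path(sidecar).exists():
        meta.update(json.loads(Path(sidecar).read_text()))
    else:
        default_sidecar = path.with_suffix(".json")
        if default_sidecar.exists():
            meta.update(json.loads(default_sidecar.read_text()))
        else:
            warnings.warn(f"{path}: no calibration metadata, assuming identity",
                          stacklevel=2)
    return ClockDefinition(
        name=str(meta["name"]),
        intercept=intercept,
        coefficients=coefs.astype(float),
        calibration=str(meta["calibration"]),
        adult_age=float(meta.get("adult_age", 20.0)),
    )


def linear_predictor(beta_column: pd.Series, clock: ClockDefinition,
                     missing_policy: str = "error") -> tuple[float, int]:
    """Intercept + Σ wⱼ·βⱼ over the clock's CpGs for one sample.

    Returns ``(lp, n_missing)``.  Missing CpGs raise under policy
    ``"error"`` (the default: silent gaps hide array/definition
    mismatches) or impute β = 0.5 under ``"mean_impute"``.
    """
    if missing_policy not in ("error", "mean_impute"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    betas = beta_column.reindex(clock.coefficients.index)
    missing = betas.isna()
    n_missing = int(missing.sum())
    if n_missing and missing_policy == "error":
        absent = betas.index[missing].tolist()
        raise MissingCpGError(
            f"clock {clock.name}: {n_missing} CpGs absent from the matrix "
            f"(first: {absent[:5]})"
        )
    filled = betas.fillna(0.5).to_numpy(dtype=float)
    lp = clock.intercept + float(clock.coefficients.to_numpy() @ filled)
    return lp, n_missing


def calibrate_age(lp, calibration: str = "identity",
                  adult_age: float = 20.0):
    """Map a linear predictor to years under the clock's calibration."""
    if calibration == "identity":
        out = np.asarray(lp, dtype=float)
    elif calibration == "log_linear":
        lp = np.asarray(lp, dtype=float)
        out = np.where(
            lp < 0,
            (adult_age + 1.0) * np.exp(lp) - 1.0,
            (adult_age + 1.0) * lp + adult_age,
        )
    else:
        raise ValueError(f"unknown calibration {calibration!r}")
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ClockEstimate:
    sample_id: str
    clock: str
    dnam_age: float
    chronological_age: float | None
    delta: float | None  # chronological - dnam_age; positive = younger
    cpgs_used: int
    cpgs_missing: int


def estimate_cohort(matrix: BetaMatrix,
                    clocks: list[ClockDefinition] | ClockDefinition,
                    ages: pd.Series | None = None,
                    missing_policy: str = "error") -> list[ClockEstimate]:
    """Apply each clock to each sample; attach deltas where ages are given."""
    if isinstance(clocks, ClockDefinition):
        clocks = [clocks]
    if ages is not None:
        unknown = set(ages.index) - set(matrix.sample_ids)
        if unknown:
            raise ValueError(f"ages given for unknown samples: "
                             f"{sorted(unknown)[:5]}")
    estimates = []
    for sample in matrix.sample_ids:
        column = matrix.values[sample]
        for clock in clocks:
            try:
                lp, n_missing = linear_predictor(column, clock, missing_policy)
            except MissingCpGError as exc:
                raise MissingCpGError(f"sample {sample}: {exc}") from exc
            age_est = calibrate_age(lp, clock.calibration, clock.adult_age)
            chron = float(ages[sample]) if ages is not None and sample in ages.index else None
            estimates.append(ClockEstimate(
                sample_id=sample,
                clock=clock.name,
                dnam_age=float(age_est),
                chronological_age=chron,
                delta=None if chron is None else chron - float(age_est),
                cpgs_used=len(clock.coefficients) - n_missing,
                cpgs_missing=n_missing,
            ))
    return estimates


def estimates_table(estimates: list[ClockEstimate]) -> pd.DataFrame:
    """Wide samples × clocks layout (one chronological column, one per clock)."""
    long = pd.DataFrame([{
        "sample_id": e.sample_id, "clock": e.clock, "dnam_age": e.dnam_age,
        "chronological_age": e.chronological_age,
    } for e in estimates])
    wide = long.pivot(index="sample_id", columns="clock", values="dnam_age")
    chron = long.groupby("sample_id")["chronological_age"].first()
    wide.insert(0, "chronological_age", chron)
    return wide


def delta_summary(estimates: list[ClockEstimate]) -> pd.DataFrame:
    """Per-clock mean, SD and SEM of the age delta, sorted by mean delta.

    The dispersion printed alongside a mean delta is ambiguous in small
    cohorts, so both the sample SD and the standard error are reported.
    """
    rows = [(e.clock, e.delta) for e in estimates if e.delta is not None]
    if not rows:
        raise ValueError("no deltas available (chronological ages missing)")
    df = pd.DataFrame(rows, columns=["clock", "delta"])
    out = df.groupby("clock")["delta"].agg(
        mean_delta="mean", sd_delta=lambda d: d.std(ddof=1), n="count",
    )
    out["sem_delta"] = out["sd_delta"] / np.sqrt(out["n"])
    return out.sort_values("mean_delta", ascending=False)
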