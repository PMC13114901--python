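"""Synthetic aging-cohort generator.

Emulates a small community-dwelling adult cohort (default n = 24, ages
drawn from a truncated normal with mean 58.67 and SD 9.22 on [35, 70])
whose motor-test performance declines linearly with age, together with a
CpG beta matrix in which a designated subset of "clock" CpGs varies
linearly with age plus Gaussian noise.  The generator also returns the
ground truth — each participant's age and each CpG's intercept/slope —
and the linear clock definition implied by that truth, which inverts
noise-free betas back to age exactly.

Every output is deterministic given the config seed, so the full analysis
pipeline is testable without any external download.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .clocks import ClockDefinition
from .methylation import BetaMatrix
from .performance import (
    NormativeTable,
    ParticipantRecord,
    SLS_CAP_SECONDS,
    NORMED_TESTS,
    write_participants,
)

__all__ = [
    "TestModel",
    "CohortConfig",
    "SyntheticTruth",
    "generate_participants",
    "generate_normative_table",
    "generate_methylation",
    "write_fixture_dir",
]

#: age at which per-test baselines are anchored (cohort inclusion floor)
BASELINE_AGE = 35.0


@dataclass(frozen=True)
class TestModel:
    """Linear-in-age generative model for one motor test.

    ``trial mean = baseline + slope * (age - 35)``, truncated to
    ``[minimum, maximum]``; two i.i.d. trials per participant with
    ``noise_sd`` around that mean.
    """

    baseline: float
    slope: float  # units per year, negative for age-declining tests
    noise_sd: float
    minimum: float = 0.0
    maximum: float = float("inf")

    def mean_at(self, age) -> np.ndarray:
        raw = self.baseline + self.slope * (np.asarray(age, dtype=float) - BASELINE_AGE)
        return np.clip(raw, self.minimum, self.maximum)


def _default_test_models() -> dict[str, TestModel]:
    # baselines anchored at age 35 so cohort means at the default mean age
    # (58.67 y) land near: gait 1.26 m/s (0.74 height-adjusted), grip
    # 30.8 kgF, SLS 22.4 s (30 s cap), 30CST 14.3 reps, 2MST 63 steps
    return {
        "gait_normal": TestModel(baseline=1.45, slope=-0.008, noise_sd=0.08),
        "grip": TestModel(baseline=38.0, slope=-0.31, noise_sd=6.0),
        "sls": TestModel(baseline=32.0, slope=-0.40, noise_sd=6.0,
                         maximum=SLS_CAP_SECONDS),
        "cst30": TestModel(baseline=17.0, slope=-0.11, noise_sd=3.0),
        "step2min": TestModel(baseline=80.0, slope=-0.72, noise_sd=15.0),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition knobs for the synthetic cohort.

    Defaults reproduce the cohort shape the analysis assumes: 24 adults,
    age ~ truncated normal(58.67, 9.22) on [35, 70], 62.5% female,
    dual-task gait-speed cost ~ normal(15.47%, 17.94%) truncated at 0,
    and 200 CpGs of which 50 carry a linear age signal.
    """

    n_participants: int = 24
    age_mean: float = 58.67
    age_sd: float = 9.22
    age_min: float = 35.0
    age_max: float = 70.0
    female_proportion: float = 15 / 24
    test_models: dict[str, TestModel] = field(default_factory=_default_test_models)
    dual_task_cost_mean: float = 15.47  # percent
    dual_task_cost_sd: float = 17.94
    n_cpgs: int = 200
    n_clock_cpgs: int = 50
    beta_age_slope_range: tuple[float, float] = (0.002, 0.006)
    beta_noise_sd: float = 0.01
    height_mean_f: float = 1.62
    height_mean_m: float = 1.76
    height_sd: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if not isinstance(self.seed, (int, np.integer)) or isinstance(self.seed, bool):
            raise TypeError("seed must be an integer")
        if self.age_min >= self.age_max:
            raise ValueError("age_min must be below age_max")
        if self.n_clock_cpgs > self.n_cpgs:
            raise ValueError("n_clock_cpgs cannot exceed n_cpgs")
        for name, value in (("age_sd", self.age_sd),
                            ("dual_task_cost_sd", self.dual_task_cost_sd),
                            ("beta_noise_sd", self.beta_noise_sd),
                            ("height_sd", self.height_sd)):
            if value < 0:
                raise ValueError(f"{name} must be non-negative")
        lo, hi = self.beta_age_slope_range
        if not (0 < lo <= hi):
            raise ValueError("beta_age_slope_range must be 0 < low <= high")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind one generated dataset."""

    ages: pd.Series                  # per-participant true age
    cpg_intercepts: pd.Series        # a_j: beta at age 0
    cpg_slopes: pd.Series            # b_j: beta-units per year (0 off-clock)
    clock: ClockDefinition

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "ages": self.ages.round(6).to_dict(),
            "cpg_intercepts": self.cpg_intercepts.round(8).to_dict(),
            "cpg_slopes": self.cpg_slopes.round(8).to_dict(),
            "clock_name": self.clock.name,
        }, indent=1) + "\n")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def generate_participants(config: CohortConfig) -> list[ParticipantRecord]:
    """Draw a cohort of participants with age-declining motor performance.

    Each motor test yields two i.i.d. trials around the participant's
    age-dependent mean; dual-task gait speed is the normal-pace trial
    scaled by ``1 − cost/100`` with the cost drawn per participant from a
    normal truncated at zero.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    ages = _truncated_normal(rng, config.age_mean, config.age_sd,
                             config.age_min, config.age_max, n)
    n_female = int(round(config.female_proportion * n))
    sexes = np.array(["F"] * n_female + ["M"] * (n - n_female))
    rng.shuffle(sexes)
    heights = np.where(
        sexes == "F",
        rng.normal(config.height_mean_f, config.height_sd, n),
        rng.normal(config.height_mean_m, config.height_sd, n),
    ).clip(1.30, 2.10)
    activity = rng.choice(["low", "moderate", "high"], size=n,
                          p=[0.5, 0.375, 0.125])
    costs = _truncated_normal(rng, config.dual_task_cost_mean,
                              config.dual_task_cost_sd, 0.0, np.inf, n)

    trial_draws: dict[str, np.ndarray] = {}
    for key, model in config.test_models.items():
        mean = model.mean_at(ages)
        draws = mean[:, None] + rng.normal(0.0, model.noise_sd, (n, 2))
        trial_draws[key] = np.clip(draws, model.minimum, model.maximum)

    participants = []
    for i in range(n):
        gait = trial_draws["gait_normal"][i]
        factor = 1.0 - costs[i] / 100.0
        trials = {
            "gait_normal": (float(gait[0]), float(gait[1])),
            "gait_dual": (float(max(gait[0] * factor, 0.0)),
                          float(max(gait[1] * factor, 0.0))),
        }
        for key in ("grip", "sls", "cst30", "step2min"):
            t = trial_draws[key][i]
            trials[key] = (float(t[0]), float(t[1]))
        participants.append(ParticipantRecord(
            id=f"S{i + 1:03d}",
            age=float(ages[i]),
            sex=str(sexes[i]),
            height=float(round(heights[i], 3)),
            activity_level=str(activity[i]),
            trials=trials,
        ))
    return participants


# One broad adult band by default: cutoffs anchored at the mid-adult mean
# leave the age-related decline visible in the composite score, matching
# the negative age-performance association the analysis is built to
# detect.  Finer bands (e.g. decadal) progressively age-normalize the
# score away; they remain available via the age_bands argument.
DEFAULT_AGE_BANDS = ((35, 74),)


def generate_normative_table(config: CohortConfig, k: float = 0.5,
                             age_bands=DEFAULT_AGE_BANDS) -> NormativeTable:
    """Build normative cutoffs from the generative model itself.

    For each test × age band × sex the cutoffs bracket the generative mean
    at the band midpoint: ``mean ∓ k·sd``.  Gait cutoffs are expressed in
    height-adjusted units (divided by the sex's mean height), matching how
    gait is compared during scoring.
    """
    if not age_bands:
        raise ValueError("age_bands must be non-empty")
    rows = []
    for test in NORMED_TESTS:
        model_key = "gait_normal" if test == "gait_speed" else test
        model = config.test_models[model_key]
        for (lo_age, hi_age) in age_bands:
            mid = (lo_age + hi_age) / 2.0
            mean = float(model.mean_at(mid))
            sd = model.noise_sd
            for sex in ("F", "M"):
                lower, upper = mean - k * sd, mean + k * sd
                if test == "gait_speed":
                    h = config.height_mean_f if sex == "F" else config.height_mean_m
                    lower, upper = lower / h, upper / h
                rows.append({"test": test, "sex": sex,
                             "age_low": lo_age, "age_high": hi_age,
                             "lower": lower, "upper": upper})
    return NormativeTable(pd.DataFrame(rows))


def generate_methylation(participants: list[ParticipantRecord],
                         config: CohortConfig,
                         ) -> tuple[BetaMatrix, SyntheticTruth, ClockDefinition]:
    """Simulate betas linear in age at clock CpGs, plus the implied clock.

    β_ij = clip(a_j + b_j·age_i + ε, 0.001, 0.999), ε ~ N(0, beta_noise_sd).
    Clock CpGs draw |b_j| uniformly from ``beta_age_slope_range`` with a
    random sign; other CpGs are flat (b_j = 0).  The returned clock has
    weights w_j = 1/(n_clock·b_j) and intercept −Σ a_j/(n_clock·b_j), so on
    noise-free betas it returns each true age exactly.
    """
    if not participants:
        raise ValueError("participants list is empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ages = np.array([p.age for p in participants])
    sample_ids = [p.id for p in participants]
    n_cpgs, n_clock = config.n_cpgs, config.n_clock_cpgs
    cpg_ids = [f"cg{j:08d}" for j in range(1, n_cpgs + 1)]

    lo, hi = config.beta_age_slope_range
    signs = rng.choice([-1.0, 1.0], size=n_clock)
    b = np.zeros(n_cpgs)
    b[:n_clock] = signs * rng.uniform(lo, hi, n_clock)
    # anchor each CpG's beta at the age-range midpoint so the noise-free
    # trajectory stays inside the clip interval for all cohort ages
    mid_age = (config.age_min + config.age_max) / 2.0
    half_span = (config.age_max - config.age_min) / 2.0
    margin = np.abs(b) * half_span
    mid_beta = rng.uniform(0.05 + margin, 0.95 - margin)
    a = mid_beta - b * mid_age

    clean = a[:, None] + b[:, None] * ages[None, :]
    noisy = clean + rng.normal(0.0, config.beta_noise_sd, (n_cpgs, len(ages)))
    clipped = np.clip(noisy, 0.001, 0.999)
    if np.mean(clipped != noisy) > 0.5:
        warnings.warn("beta noise so large that clipping saturates more than "
                      "half the matrix", stacklevel=2)

    w = 1.0 / (n_clock * b[:n_clock])
    intercept = -float(np.sum(a[:n_clock] * w))
    clock = ClockDefinition(
        name="synthetic_truth_clock",
        intercept=intercept,
        coefficients=pd.Series(w, index=cpg_ids[:n_clock]),
        calibration="identity",
    )
    matrix = BetaMatrix(values=pd.DataFrame(clipped, index=cpg_ids,
                                            columns=sample_ids))
    truth = SyntheticTruth(
        ages=pd.Series(ages, index=sample_ids),
        cpg_intercepts=pd.Series(a, index=cpg_ids),
        cpg_slopes=pd.Series(b, index=cpg_ids),
        clock=clock,
    )
    return matrix, truth, clock


def write_fixture_dir(outdir: str | Path, config: CohortConfig | None = None,
                      ) -> dict[str, Path]:
    """Generate a full fixture set on disk; returns the paths written."""
    config = config or CohortConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    participants = generate_participants(config)
    norms = generate_normative_table(config)
    matrix, truth, clock = generate_methylation(participants, config)
    paths = {
        "participants": outdir / "participants.csv",
        "normative": outdir / "normative.json",
        "betas": outdir / "betas.tsv",
        "clock": outdir / "clock_true.csv",
        "clock_meta": outdir / "clock_true.json",
        "truth": outdir / "truth.json",
    }
    write_participants(participants, paths["participants"])
    norms.to_json(paths["normative"])
    matrix.to_tsv(paths["betas"])
    clock.to_csv(paths["clock"], sidecar=paths["clock_meta"])
    truth.to_json(paths["truth"])
    return paths
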