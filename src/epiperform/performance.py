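"""Composite physical-performance scoring against normative cutoffs.

A motor-test battery of six components — usual-pace gait speed, dual-task
gait speed, dominant-hand grip strength, single-limb stance (SLS), the 30-s
chair-stand test (30CST) and the 2-minute step test (2MST) — is reduced to a
single cumulative score from 0 to 12.  Five of the components are rated
against a normative table (0 = below the normative range, 1 = within,
2 = above); the dual-task component is rated by the percent reduction in
gait speed relative to the participant's own usual pace (reduction > 25%
scores 0, 10–25% scores 1, < 10% scores 2).  The six category ratings are
summed.

Each test is performed twice and the two trials are averaged before any
categorization.  Gait speed is divided by body height before the normative
comparison, so gait cutoffs are expressed in height-adjusted units
(m/s per m of height).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TESTS",
    "NORMED_TESTS",
    "TRIAL_KEYS",
    "ParticipantRecord",
    "NormativeTable",
    "ComponentCategory",
    "CompositeScore",
    "MissingDataError",
    "NormativeGapError",
    "average_trials",
    "height_adjust_gait",
    "categorize_component",
    "dual_task_category",
    "composite_score",
    "score_cohort",
    "read_participants",
]

#: the six scored components, in canonical order
TESTS = ("gait_speed", "dual_task", "grip", "sls", "cst30", "step2min")
#: the five components rated against the normative table
NORMED_TESTS = ("gait_speed", "grip", "sls", "cst30", "step2min")
#: raw trial keys carried on a participant record
TRIAL_KEYS = ("gait_normal", "gait_dual", "grip", "sls", "cst30", "step2min")

SLS_CAP_SECONDS = 30.0


class MissingDataError(ValueError):
    """A participant is missing a trial needed for scoring."""


class NormativeGapError(KeyError):
    """No normative row covers a (test, sex, age) combination."""


@dataclass(frozen=True)
class ParticipantRecord:
    """One subject: demographics plus two raw trials per motor test.

    ``trials`` maps each key in :data:`TRIAL_KEYS` to a ``(trial1, trial2)``
    pair in that test's units (gait speeds m/s, grip kgF, SLS seconds,
    30CST repetitions, 2MST steps).
    """

    id: str
    age: float
    sex: str
    height: float
    activity_level: str
    trials: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"participant {self.id}: age must be positive")
        if self.height <= 0:
            raise ValueError(f"participant {self.id}: height must be positive")
        if self.sex not in ("F", "M"):
            raise ValueError(f"participant {self.id}: sex must be 'F' or 'M'")
        if self.activity_level not in ("low", "moderate", "high"):
            raise ValueError(
                f"participant {self.id}: unknown activity level "
                f"{self.activity_level!r}"
            )
        for test, pair in self.trials.items():
            for v in pair:
                if v < 0:
                    raise ValueError(
                        f"participant {self.id}: negative value for {test}"
                    )
            if test == "sls" and max(pair) > SLS_CAP_SECONDS:
                raise ValueError(
                    f"participant {self.id}: SLS trial exceeds the "
                    f"{SLS_CAP_SECONDS:.0f} s test cap"
                )

    def trial_pair(self, key: str) -> tuple[float, float]:
        try:
            return self.trials[key]
        except KeyError:
            raise MissingDataError(
                f"participant {self.id}: missing trials for {key}"
            ) from None


class NormativeTable:
    """Cutoffs mapping a test value to a 0/1/2 category given age and sex.

    Rows carry ``(test, sex, age_low, age_high, lower, upper)`` with closed
    age bands.  ``lower < upper`` is enforced per row; bands for a
    (test, sex) pair must not overlap.
    """

    COLUMNS = ("test", "sex", "age_low", "age_high", "lower", "upper")

    def __init__(self, rows: pd.DataFrame):
        rows = rows.reset_index(drop=True)
        missing = set(self.COLUMNS) - set(rows.columns)
        if missing:
            raise ValueError(f"normative table missing columns: {sorted(missing)}")
        if len(rows) == 0:
            raise ValueError("normative table is empty")
        bad = rows[rows["lower"] >= rows["upper"]]
        if len(bad):
            first = bad.iloc[0]
            raise ValueError(
                "normative cutoffs must satisfy lower < upper; violated for "
                f"test={first['test']} sex={first['sex']} band="
                f"[{first['age_low']}, {first['age_high']}]"
            )
        for (test, sex), grp in rows.groupby(["test", "sex"]):
            bands = grp.sort_values("age_low")[["age_low", "age_high"]].to_numpy()
            for (lo1, hi1), (lo2, _) in zip(bands, bands[1:]):
                if lo2 <= hi1:
                    raise ValueError(
                        f"overlapping age bands for test={test} sex={sex}"
                    )
        self._rows = rows[list(self.COLUMNS)]

    @property
    def rows(self) -> pd.DataFrame:
        return self._rows.copy()

    def lookup(self, test: str, sex: str, age: float) -> tuple[float, float]:
        """Return the (lower, upper) cutoff pair covering (test, sex, age).

        Bands are whole-year closed intervals; a fractional age is matched
        by age at last birthday (floor), the usual normative-table rule.
        """
        band_age = float(np.floor(age))
        r = self._rows
        hit = r[
            (r["test"] == test)
            & (r["sex"] == sex)
            & (r["age_low"] <= band_age)
            & (band_age <= r["age_high"])
        ]
        if len(hit) == 0:
            raise NormativeGapError(
                f"no normative band covers test={test} sex={sex} age={age}"
            )
        row = hit.iloc[0]
        return float(row["lower"]), float(row["upper"])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self._rows.to_dict(orient="records"), indent=1) + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "NormativeTable":
        records = json.loads(Path(path).read_text())
        return cls(pd.DataFrame.from_records(records))


@dataclass(frozen=True)
class ComponentCategory:
    test: str
    category: int

    def __post_init__(self) -> None:
        if self.test not in TESTS:
            raise ValueError(f"unknown test {self.test!r}")
        if self.category not in (0, 1, 2):
            raise ValueError("category must be 0, 1 or 2")


@dataclass(frozen=True)
class CompositeScore:
    participant_id: str
    total: int


def average_trials(trial1: float | None, trial2: float | None,
                   *, participant: str = "?", test: str = "?") -> float:
    """Arithmetic mean of the two trials; missing trials are a hard error."""
    if trial1 is None or trial2 is None:
        raise MissingDataError(
            f"participant {participant}: missing trial for {test}"
        )
    if trial1 < 0 or trial2 < 0:
        raise ValueError(f"negative trial value for {test}")
    return (trial1 + trial2) / 2.0


def height_adjust_gait(speed: float, height: float) -> float:
    """Gait speed divided by body height (m/s per m of height)."""
    if height <= 0:
        raise ValueError("height must be positive")
    return speed / height


def categorize_component(value: float, test: str, age: float, sex: str,
                         table: NormativeTable) -> ComponentCategory:
    """Rate a test value against the normative band covering (test, sex, age).

    Values exactly at a cutoff rate 1 ("within"), so the three categories
    partition the value axis.
    """
    lower, upper = table.lookup(test, sex, age)
    if value < lower:
        cat = 0
    elif value > upper:
        cat = 2
    else:
        cat = 1
    return ComponentCategory(test=test, category=cat)


def dual_task_category(normal_speed: float, dual_speed: float) -> ComponentCategory:
    """Rate the dual-task cost: percent gait-speed reduction vs usual pace.

    reduction > 25% → 0, 10–25% (inclusive) → 1, < 10% → 2.  A speed-up
    (negative reduction) rates 2.
    """
    if normal_speed <= 0:
        raise ValueError("normal-pace speed must be positive")
    reduction = 100.0 * (normal_speed - dual_speed) / normal_speed
    eps = 1e-9  # keep speeds landing exactly on a boundary in "between"
    if reduction > 25.0 + eps:
        cat = 0
    elif reduction >= 10.0 - eps:
        cat = 1
    else:
        cat = 2
    return ComponentCategory(test="dual_task", category=cat)


def composite_score(components: Sequence[ComponentCategory],
                    participant_id: str = "?") -> CompositeScore:
    """Sum the six component categories into the 0–12 cumulative score."""
    seen = [c.test for c in components]
    if sorted(seen) != sorted(TESTS):
        raise ValueError(
            f"participant {participant_id}: need exactly one category per "
            f"test {TESTS}, got {seen}"
        )
    return CompositeScore(
        participant_id=participant_id,
        total=int(sum(c.category for c in components)),
    )


def _participant_categories(p: ParticipantRecord,
                            table: NormativeTable) -> dict[str, int]:
    gait_normal = average_trials(*p.trial_pair("gait_normal"),
                                 participant=p.id, test="gait_normal")
    gait_dual = average_trials(*p.trial_pair("gait_dual"),
                               participant=p.id, test="gait_dual")
    values = {
        "gait_speed": height_adjust_gait(gait_normal, p.height),
        "grip": average_trials(*p.trial_pair("grip"), participant=p.id,
                               test="grip"),
        "sls": average_trials(*p.trial_pair("sls"), participant=p.id,
                              test="sls"),
        "cst30": average_trials(*p.trial_pair("cst30"), participant=p.id,
                                test="cst30"),
        "step2min": average_trials(*p.trial_pair("step2min"),
                                   participant=p.id, test="step2min"),
    }
    cats = {
        test: categorize_component(values[test], test, p.age, p.sex, table).category
        for test in NORMED_TESTS
    }
    cats["dual_task"] = dual_task_category(gait_normal, gait_dual).category
    return cats


def score_cohort(participants: Sequence[ParticipantRecord],
                 table: NormativeTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every participant and summarize category frequencies per test.

    Returns ``(scores, summary)``: *scores* has one row per participant with
    the six component categories and the composite total; *summary* has one
    row per test with the percentage of the cohort rated below / within /
    above the norm.
    """
    if not participants:
        raise ValueError("no participants to score")
    rows = []
    for p in participants:
        try:
            cats = _participant_categories(p, table)
        except (MissingDataError, NormativeGapError) as exc:
            raise type(exc)(f"scoring participant {p.id}: {exc}") from exc
        rows.append({"id": p.id, **cats,
                     "total": sum(cats[t] for t in TESTS)})
    scores = pd.DataFrame(rows).set_index("id")
    n = len(scores)
    summary = pd.DataFrame(
        {
            "test": list(TESTS),
            "below_norm_pct": [100.0 * (scores[t] == 0).sum() / n for t in TESTS],
            "within_norm_pct": [100.0 * (scores[t] == 1).sum() / n for t in TESTS],
            "above_norm_pct": [100.0 * (scores[t] == 2).sum() / n for t in TESTS],
        }
    ).set_index("test")
    return scores, summary


def read_participants(path: str | Path) -> list[ParticipantRecord]:
    """Read a participants CSV (trial columns suffixed ``_t1``/``_t2``)."""
    df = pd.read_csv(path)
    required = {"id", "age", "sex", "height", "activity_level"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"participants file missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        trials = {}
        for key in TRIAL_KEYS:
            c1, c2 = f"{key}_t1", f"{key}_t2"
            if c1 in df.columns and c2 in df.columns:
                trials[key] = (float(row[c1]), float(row[c2]))
        out.append(
            ParticipantRecord(
                id=str(row["id"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                height=float(row["height"]),
                activity_level=str(row["activity_level"]),
                trials=trials,
            )
        )
    return out


def write_participants(participants: Sequence[ParticipantRecord],
                       path: str | Path) -> None:
    rows = []
    for p in participants:
        row: dict[str, object] = {
            "id": p.id, "age": p.age, "sex": p.sex, "height": p.height,
            "activity_level": p.activity_level,
        }
        for key in TRIAL_KEYS:
            t1, t2 = p.trial_pair(key)
            row[f"{key}_t1"] = t1
            row[f"{key}_t2"] = t2
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
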