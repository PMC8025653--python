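"""Field-trial scoring rules and the non-inferiority analysis.

A two-arm swine-respiratory-disease (SRD) trial scores every animal daily
(day 0 enrolment to day 10) on depression (0–3), respiratory signs (0–3)
and rectal temperature. The rules implemented here:

* enrolment: depression >= 2 AND respiratory >= 2 AND temperature > 40.0 °C;
* on-study removal: (depression == 3 OR respiratory == 3) AND temperature
  >= 40.0 °C — removed animals confirmed SRD-positive count as treatment
  failures; removals for non-SRD reasons leave the analysis population;
* day-10 outcome: failure iff (depression >= 1 AND temperature > 40.0) OR
  (respiratory >= 1 AND temperature > 40.0), success otherwise;
* per-sign dichotomization: a score of 0 or 1 is acceptable, and a
  temperature <= 40.0 °C is acceptable.

Treatment success and the three per-sign acceptabilities are compared
between arms with a two-proportion non-inferiority test: the two-sided
95% CI on p1 − p2 is (p1−p2) ± 1.960·sqrt((1/n1 + 1/n2)·p̄(1−p̄)) with p̄
the pooled proportion, and the test arm is non-inferior when the lower
limit exceeds −margin (margin 0.10). Decisions always use unrounded
values; rounding to 2 decimals happens only when a report is rendered.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

#: 97.5th percentile of the standard normal, as used in the trial's
#: published CI formula (3-decimal convention)
Z_975 = 1.960

DEFAULT_MARGIN = 0.10

ENDPOINTS = ("overall", "depression", "respiration", "temperature")

OBSERVATION_COLUMNS = ["site", "animal_id", "arm", "day", "depression", "respiratory", "temp_c"]
EXIT_COLUMNS = ["animal_id", "day", "reason"]


class Arm(str, enum.Enum):
    GAM = "GAM"  # gamithromycin (test)
    TIL = "TIL"  # tildipirosin (reference)


class OutcomeStatus(str, enum.Enum):
    SUCCESS = "success"
    FAILURE_DAY10 = "failure_day10"
    REMOVED_SRD = "removed_srd"
    REMOVED_NON_SRD = "removed_non_srd"


class TrialDataError(ValueError):
    """Inconsistent or malformed trial records, naming the animal."""


@dataclass(frozen=True)
class ClinicalObservation:
    """One animal-day of SRD scores and rectal temperature."""

    site: str
    animal_id: str
    arm: Arm
    day: int
    depression: int
    respiratory: int
    temperature: float  # °C

    def __post_init__(self) -> None:
        if self.depression not in (0, 1, 2, 3):
            raise ValueError(f"depression score must be 0-3, got {self.depression}")
        if self.respiratory not in (0, 1, 2, 3):
            raise ValueError(f"respiratory score must be 0-3, got {self.respiratory}")
        if not 35.0 <= self.temperature <= 43.0:
            raise ValueError(
                f"temperature {self.temperature} outside plausibility band [35, 43] °C"
            )
        if not 0 <= self.day <= 10:
            raise ValueError(f"day must be 0-10, got {self.day}")
        if not isinstance(self.arm, Arm):
            object.__setattr__(self, "arm", Arm(self.arm))


@dataclass(frozen=True)
class AnimalOutcome:
    animal_id: str
    arm: Arm
    status: OutcomeStatus
    day_of_exit: int


@dataclass(frozen=True)
class NonInferiorityResult:
    """Difference of two proportions with its pooled-variance 95% CI."""

    p1: float
    p2: float
    n1: int
    n2: int
    diff: float
    ci_lower: float
    ci_upper: float
    margin: float
    non_inferior: bool


@dataclass(frozen=True)
class TrialReport:
    """Analysis-population accounting plus per-endpoint results."""

    n_enrolled: dict
    n_removed_srd: dict
    n_removed_non_srd: dict
    n_analyzed: dict
    successes: dict  # endpoint -> {arm: count}
    endpoints: dict  # endpoint -> NonInferiorityResult
    outcomes: list  # AnimalOutcome per analyzed animal


# ---------------------------------------------------------------------------
# classification rules


def classify_enrolment(obs: ClinicalObservation) -> bool:
    """Inclusion: both scores >= 2 and temperature strictly above 40.0 °C."""
    return obs.depression >= 2 and obs.respiratory >= 2 and obs.temperature > 40.0


def classify_removal(obs: ClinicalObservation, *, temp_threshold: float = 40.0) -> bool:
    """Removal: either score at 3 with temperature at/above the threshold."""
    return (obs.depression == 3 or obs.respiratory == 3) and obs.temperature >= temp_threshold


def classify_final_outcome(obs: ClinicalObservation) -> str:
    """Day-10 outcome: 'failure' iff a sign >= 1 coincides with fever > 40.0 °C."""
    if obs.day != 10:
        raise TrialDataError(
            f"{obs.animal_id}: final outcome requires a day-10 observation, got day {obs.day}"
        )
    febrile = obs.temperature > 40.0
    if (obs.depression >= 1 and febrile) or (obs.respiratory >= 1 and febrile):
        return "failure"
    return "success"


def dichotomize(obs: ClinicalObservation) -> tuple[bool, bool, bool]:
    """(depression, respiratory, temperature) acceptability booleans."""
    return (
        obs.depression <= 1,
        obs.respiratory <= 1,
        obs.temperature <= 40.0,
    )


# ---------------------------------------------------------------------------
# non-inferiority of two proportions


def noninferiority_analysis(
    x1: int, n1: int, x2: int, n2: int, margin: float = DEFAULT_MARGIN
) -> NonInferiorityResult:
    """Two-proportion non-inferiority CI from success counts.

    Pooled proportion p̄ = (x1+x2)/(n1+n2) feeds the variance term; the
    non-inferiority call requires the lower CI limit to exceed −margin.
    A degenerate p̄ of 0 or 1 produces a zero-width CI with a warning.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("noninferiority_analysis: both arms need n >= 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("noninferiority_analysis: counts must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    p_ave = (x1 + x2) / (n1 + n2)
    if p_ave in (0.0, 1.0):
        warnings.warn(
            "pooled proportion is degenerate (0 or 1); CI has zero width",
            RuntimeWarning,
            stacklevel=2,
        )
    half_width = Z_975 * math.sqrt((1.0 / n1 + 1.0 / n2) * p_ave * (1.0 - p_ave))
    diff = p1 - p2
    lower, upper = diff - half_width, diff + half_width
    return NonInferiorityResult(
        p1=p1,
        p2=p2,
        n1=n1,
        n2=n2,
        diff=diff,
        ci_lower=lower,
        ci_upper=upper,
        margin=margin,
        non_inferior=lower > -margin,
    )


# ---------------------------------------------------------------------------
# trial-level analysis


def read_observations(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TrialDataError(f"{path}: file not found")
    df = pd.read_csv(path)
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise TrialDataError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def read_exits(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TrialDataError(f"{path}: file not found")
    df = pd.read_csv(path)
    missing = [c for c in EXIT_COLUMNS if c not in df.columns]
    if missing:
        raise TrialDataError(f"{path}: missing column(s) {', '.join(missing)}")
    bad = set(df["reason"].unique()) - {"srd", "non_srd"}
    if bad:
        raise TrialDataError(f"{path}: unknown exit reason(s) {sorted(bad)}")
    return df


def _row_obs(row) -> ClinicalObservation:
    """Build an observation from a day-10 table row (itertuples record)."""
    return ClinicalObservation(
        site=str(row.site),
        animal_id=str(row.animal_id),
        arm=Arm(str(row.arm)),
        day=int(row.day),
        depression=int(row.depression),
        respiratory=int(row.respiratory),
        temperature=float(row.temp_c),
    )


def analyze_trial(
    observations: pd.DataFrame,
    exits: Optional[pd.DataFrame] = None,
    margin: float = DEFAULT_MARGIN,
) -> TrialReport:
    """Pooled-sites analysis of the four trial endpoints.

    The analysis population excludes non-SRD removals entirely; SRD
    removals stay in every denominator and count as failures (overall) and
    as not-acceptable (each sign). Every other animal must contribute a
    day-10 observation, which is classified by the day-10 rules above.
    """
    if exits is None:
        exits = pd.DataFrame(columns=EXIT_COLUMNS)

    removed_non_srd = {
        str(r["animal_id"]): int(r["day"])
        for _, r in exits.iterrows()
        if r["reason"] == "non_srd"
    }
    removed_srd = {
        str(r["animal_id"]): int(r["day"])
        for _, r in exits.iterrows()
        if r["reason"] == "srd"
    }

    arms = {
        str(animal): Arm(str(arm))
        for animal, arm in observations.groupby("animal_id", sort=False)["arm"]
        .first()
        .items()
    }

    day10 = observations[observations["day"] == 10]
    day10_by_animal = {str(r.animal_id): r for r in day10.itertuples()}

    n_enrolled = {a: 0 for a in Arm}
    n_rm_srd = {a: 0 for a in Arm}
    n_rm_non = {a: 0 for a in Arm}
    successes = {e: {a: 0 for a in Arm} for e in ENDPOINTS}
    n_analyzed = {a: 0 for a in Arm}
    outcomes: list[AnimalOutcome] = []

    for animal_id in sorted(arms):
        arm = arms[animal_id]
        n_enrolled[arm] += 1
        if animal_id in removed_non_srd:
            n_rm_non[arm] += 1
            outcomes.append(
                AnimalOutcome(animal_id, arm, OutcomeStatus.REMOVED_NON_SRD, removed_non_srd[animal_id])
            )
            continue
        n_analyzed[arm] += 1
        if animal_id in removed_srd:
            n_rm_srd[arm] += 1
            # failure for the overall endpoint, not-acceptable for each sign
            outcomes.append(
                AnimalOutcome(animal_id, arm, OutcomeStatus.REMOVED_SRD, removed_srd[animal_id])
            )
            continue
        if animal_id not in day10_by_animal:
            raise TrialDataError(
                f"animal {animal_id}: neither a day-10 observation nor an exit record"
            )
        obs = _row_obs(day10_by_animal[animal_id])
        outcome = classify_final_outcome(obs)
        dep_ok, resp_ok, temp_ok = dichotomize(obs)
        if outcome == "success":
            successes["overall"][arm] += 1
        successes["depression"][arm] += int(dep_ok)
        successes["respiration"][arm] += int(resp_ok)
        successes["temperature"][arm] += int(temp_ok)
        outcomes.append(
            AnimalOutcome(
                animal_id,
                arm,
                OutcomeStatus.SUCCESS if outcome == "success" else OutcomeStatus.FAILURE_DAY10,
                10,
            )
        )

    endpoints = {
        e: noninferiority_analysis(
            successes[e][Arm.GAM],
            n_analyzed[Arm.GAM],
            successes[e][Arm.TIL],
            n_analyzed[Arm.TIL],
            margin=margin,
        )
        for e in ENDPOINTS
    }
    return TrialReport(
        n_enrolled={a.value: n_enrolled[a] for a in Arm},
        n_removed_srd={a.value: n_rm_srd[a] for a in Arm},
        n_removed_non_srd={a.value: n_rm_non[a] for a in Arm},
        n_analyzed={a.value: n_analyzed[a] for a in Arm},
        successes={e: {a.value: successes[e][a] for a in Arm} for e in ENDPOINTS},
        endpoints=endpoints,
        outcomes=outcomes,
    )


def declaration_rate(
    p1: float,
    p2: float,
    n1: int,
    n2: int,
    *,
    margin: float = DEFAULT_MARGIN,
    replicates: int = 10_000,
    rng,
) -> float:
    """Monte-Carlo probability of declaring non-inferiority.

    Draws independent binomial success counts per arm and runs
    :func:`noninferiority_analysis` on each replicate.
    """
    x1 = rng.binomial(n1, p1, size=replicates)
    x2 = rng.binomial(n2, p2, size=replicates)
    declared = 0
    for a, b in zip(x1, x2):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = noninferiority_analysis(int(a), n1, int(b), n2, margin=margin)
        declared += int(res.non_inferior)
    return declared / replicates
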