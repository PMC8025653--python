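"""Synthetic plasma profiles and field-trial outcomes.

The PK generator emulates a single-dose macrolide study in fattening
swine: two-compartment linear disposition with very fast first-order
intramuscular absorption, the study's sampling schedule (5 min to day
10), multiplicative assay noise and censoring at the 2.0 ng/ml LLOQ. The
default disposition is constrained so the population-typical IV profile
has CL = 1.03 L/hr/kg, Vss = 39.2 L/kg and a terminal half-life of ~76 hr
(the free choice, V1 = 2.0 L/kg, sets how sharply concentrations fall
after the early peak). Between-animal variability is log-normal on each
disposition parameter and on ka; residual error is log-normal per sample.

The trial generator emulates a two-arm multicentre study: animals are
allocated 1:1 in blocks of two within site, every enrolment-day record
meets the inclusion rule, latent treatment outcomes are Bernoulli per
arm, a fraction of failures exit early through the removal rule, and
day-10 scores are drawn from per-state emission distributions constrained
(by rejection) so the day-10 classifier reproduces the latent status
exactly. All randomness flows from a single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .clinical_trial import (
    EXIT_COLUMNS,
    OBSERVATION_COLUMNS,
    Arm,
    ClinicalObservation,
    classify_final_outcome,
    classify_removal,
)
from .pk_data import ConcentrationRecord, DoseEvent, PKProfile, Route, Sex

#: nominal post-dose sampling times (hr): 5, 10, 15, 30 min; 1-24 hr; days 2-10
DEFAULT_SCHEDULE: tuple[float, ...] = (
    0.083, 0.167, 0.25, 0.5, 1.0, 2.0, 3.0, 6.0, 10.0, 24.0,
    48.0, 72.0, 96.0, 120.0, 144.0, 168.0, 192.0, 216.0, 240.0,
)

#: dosing design: route, dose (mg/kg) for the four treated groups
DEFAULT_DOSES: tuple[tuple[str, float], ...] = (
    ("IV", 6.0), ("IM", 3.0), ("IM", 6.0), ("IM", 12.0),
)


@dataclass(frozen=True)
class Disposition:
    """Two-compartment macro parameters, all per kg body weight."""

    cl: float = 1.03  # L/hr/kg
    v1: float = 2.0  # L/kg
    q: float = 0.509  # L/hr/kg, inter-compartmental clearance
    v2: float = 37.2  # L/kg

    def __post_init__(self) -> None:
        for name in ("cl", "v1", "q", "v2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def vss(self) -> float:
        return self.v1 + self.v2


@dataclass
class PKSimConfig:
    """Configuration of the synthetic single-dose PK study."""

    n_per_group: int = 6
    group_sizes: Optional[Sequence[int]] = (8, 6, 6, 6)  # matches the study design
    doses: Sequence[tuple[str, float]] = DEFAULT_DOSES
    disposition: Disposition = field(default_factory=Disposition)
    ka: float = 28.0  # 1/hr, IM absorption (Tmax ~8 min)
    f_im: float = 0.92  # IM bioavailable fraction for doses not listed below
    #: apparent bioavailable fraction per IM dose, reproducing the observed
    #: dose-dependent exposure (the 3 mg/kg value exceeds 1 as reported;
    #: it is an apparent, estimation-borne quantity, not a true fraction).
    #: Set to None for an idealized dose-linear study.
    f_im_by_dose: Optional[dict] = field(
        default_factory=lambda: {3.0: 1.07, 6.0: 0.922, 12.0: 0.814}
    )
    residual_cv: float = 0.05  # assay-level multiplicative error
    bsv_cv: float = 0.15  # between-animal CV on CL, V1, Q, V2
    ka_cv: float = 0.25  # between-animal CV on ka
    lloq: float = 2.0  # ng/ml
    schedule: Sequence[float] = DEFAULT_SCHEDULE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ka <= 0 or not 0 < self.f_im <= 1:
            raise ValueError("ka must be positive and f_im in (0, 1]")
        for name in ("residual_cv", "bsv_cv", "ka_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.group_sizes is not None and len(self.group_sizes) != len(self.doses):
            raise ValueError("group_sizes must match doses in length")

    def bioavailable_fraction(self, dose: float) -> float:
        if self.f_im_by_dose is not None and dose in self.f_im_by_dose:
            return self.f_im_by_dose[dose]
        return self.f_im


def _micro_rates(d: Disposition) -> tuple[float, float, float, float, float]:
    """(k10, k12, k21, alpha, beta) from macro parameters."""
    k10 = d.cl / d.v1
    k12 = d.q / d.v1
    k21 = d.q / d.v2
    s = k10 + k12 + k21
    disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    alpha = (s + disc) / 2.0
    beta = (s - disc) / 2.0
    return k10, k12, k21, alpha, beta


def _separate(ka: float, alpha: float, beta: float) -> float:
    """Nudge ka off a disposition eigenvalue (limit handled by perturbation)."""
    for lam in (alpha, beta):
        if abs(ka - lam) < 1e-9 * max(ka, lam):
            return ka * (1.0 + 1e-6)
    return ka


def simulate_disposition(
    config: PKSimConfig,
    route: str | Route,
    dose: float,
    times: Sequence[float],
    *,
    disposition: Optional[Disposition] = None,
    ka: Optional[float] = None,
) -> np.ndarray:
    """Noiseless concentration curve (ng/ml) at ``times`` (hr).

    IV bolus gives the bi-exponential closed form; IM adds first-order
    absorption (tri-exponential), scaled by the bioavailable fraction.
    Concentrations are linear in dose.
    """
    d = disposition or config.disposition
    ka_val = ka if ka is not None else config.ka
    route = Route(route)
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    _, _, k21, alpha, beta = _micro_rates(d)
    if route is Route.IV:
        c0 = dose / d.v1  # mg/L == µg/ml
        a = c0 * (alpha - k21) / (alpha - beta)
        b = c0 * (k21 - beta) / (alpha - beta)
        conc = a * np.exp(-alpha * t) + b * np.exp(-beta * t)
    else:
        ka_val = _separate(ka_val, alpha, beta)
        scale = config.bioavailable_fraction(dose) * dose * ka_val / d.v1
        coef_a = (k21 - alpha) / ((ka_val - alpha) * (beta - alpha))
        coef_b = (k21 - beta) / ((ka_val - beta) * (alpha - beta))
        coef_k = (k21 - ka_val) / ((alpha - ka_val) * (beta - ka_val))
        conc = scale * (
            coef_a * np.exp(-alpha * t)
            + coef_b * np.exp(-beta * t)
            + coef_k * np.exp(-ka_val * t)
        )
    return np.maximum(conc, 0.0) * 1000.0  # µg/ml -> ng/ml


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative log-normal deviate with median 1 and the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(0.0, sigma, size=size))


def simulate_pk_study(config: PKSimConfig) -> list[PKProfile]:
    """Per-animal profiles with between-animal and residual variability.

    Measurements below the LLOQ keep their simulated value but are
    flagged BLOQ. Identical seeds give identical output.
    """
    rng = np.random.default_rng(config.seed)
    sizes = (
        list(config.group_sizes)
        if config.group_sizes is not None
        else [config.n_per_group] * len(config.doses)
    )
    profiles: list[PKProfile] = []
    times = np.asarray(config.schedule, dtype=float)
    d0 = config.disposition
    for (route, dose), n_animals in zip(config.doses, sizes):
        for i in range(n_animals):
            f_cl, f_v1, f_q, f_v2 = (
                float(_lognormal_factor(rng, config.bsv_cv)) for _ in range(4)
            )
            disp = Disposition(d0.cl * f_cl, d0.v1 * f_v1, d0.q * f_q, d0.v2 * f_v2)
            ka_i = config.ka * float(_lognormal_factor(rng, config.ka_cv))
            curve = simulate_disposition(
                config, route, dose, times, disposition=disp, ka=ka_i
            )
            noise = _lognormal_factor(rng, config.residual_cv, size=len(times))
            observed = curve * noise
            records = [
                ConcentrationRecord(float(t), float(c), bool(c < config.lloq))
                for t, c in zip(times, observed)
            ]
            animal_id = f"{Route(route).value}{dose:g}-{i + 1:02d}"
            sex = Sex.MALE_CASTRATE if i % 2 == 0 else Sex.FEMALE
            profiles.append(
                PKProfile(DoseEvent(animal_id, Route(route), dose), sex, records, config.lloq)
            )
    return profiles


# ---------------------------------------------------------------------------
# field trial


@dataclass(frozen=True)
class StateEmission:
    """Day-10 score/temperature distribution for one latent state."""

    dep_probs: tuple[float, float, float, float]
    resp_probs: tuple[float, float, float, float]
    temp_mean: float
    temp_sd: float


@dataclass(frozen=True)
class ScoreModel:
    """Latent two-state (cured / not cured) emission model."""

    success: StateEmission = StateEmission(
        (0.78, 0.18, 0.03, 0.01), (0.70, 0.22, 0.06, 0.02), 39.4, 0.45
    )
    failure: StateEmission = StateEmission(
        (0.10, 0.30, 0.40, 0.20), (0.10, 0.30, 0.40, 0.20), 40.7, 0.5
    )


@dataclass
class TrialSimConfig:
    """Configuration of the synthetic two-arm field trial."""

    n_sites: int = 6
    n_per_arm: int = 152
    p_success: tuple[float, float] = (0.967, 0.934)  # (test arm, reference arm)
    p_removal_srd: float = 0.5  # P(early SRD removal | latent failure)
    p_removal_non_srd: float = 0.013
    score_model: ScoreModel = field(default_factory=ScoreModel)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (*self.p_success, self.p_removal_srd, self.p_removal_non_srd):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_sites < 1 or self.n_per_arm < 1:
            raise ValueError("n_sites and n_per_arm must be >= 1")


def _draw_temp(rng, mean, sd, lo=35.0, hi=43.0):
    # tables carry one decimal; round here so classification on the drawn
    # value and on the serialized value can never disagree
    return round(float(np.clip(rng.normal(mean, sd), lo, hi)), 1)


def _emit_day10(rng, em: StateEmission, want_failure: bool, site, animal_id, arm):
    """Rejection-sample a day-10 observation matching the latent state."""
    for _ in range(10_000):
        obs = ClinicalObservation(
            site=site,
            animal_id=animal_id,
            arm=arm,
            day=10,
            depression=int(rng.choice(4, p=em.dep_probs)),
            respiratory=int(rng.choice(4, p=em.resp_probs)),
            temperature=_draw_temp(rng, em.temp_mean, em.temp_sd),
        )
        if (classify_final_outcome(obs) == "failure") == want_failure:
            return obs
    raise RuntimeError("day-10 emission rejection sampling did not converge")


def _interp_score(day: int, start: int, end: int, last_day: int = 10) -> int:
    frac = day / last_day
    return int(round(start + (end - start) * frac))


def simulate_trial(config: TrialSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (observations, exits) tables for a synthetic trial.

    Animals are allocated to arms in blocks of two within site. Each
    animal's enrolment-day record satisfies the inclusion rule; SRD exits
    satisfy the removal rule on their exit day; other on-study days never
    trigger removal; and the day-10 record classifies to the animal's
    latent outcome. Seeded and reproducible.
    """
    rng = np.random.default_rng(config.seed)
    sm = config.score_model

    base, rem = divmod(config.n_per_arm, config.n_sites)
    blocks_per_site = [base + (1 if i < rem else 0) for i in range(config.n_sites)]

    obs_rows: list[dict] = []
    exit_rows: list[dict] = []
    counter = 0
    for site_idx, n_blocks in enumerate(blocks_per_site):
        site = f"site{site_idx + 1}"
        for _ in range(n_blocks):
            order = [Arm.GAM, Arm.TIL]
            if rng.random() < 0.5:
                order.reverse()
            for arm in order:
                counter += 1
                animal_id = f"A{counter:03d}"
                p_succ = config.p_success[0 if arm is Arm.GAM else 1]
                latent_success = rng.random() < p_succ
                non_srd_exit = rng.random() < config.p_removal_non_srd
                srd_exit = (not latent_success) and rng.random() < config.p_removal_srd

                # enrolment day: both scores >= 2, fever strictly above 40.0
                dep0 = int(rng.choice([2, 3], p=[0.7, 0.3]))
                resp0 = int(rng.choice([2, 3], p=[0.7, 0.3]))
                temp0 = round(float(min(43.0, 40.1 + abs(rng.normal(0.5, 0.35)))), 1)
                obs_rows.append(
                    dict(site=site, animal_id=animal_id, arm=arm.value, day=0,
                         depression=dep0, respiratory=resp0, temp_c=temp0)
                )

                if non_srd_exit:
                    exit_day = int(rng.integers(1, 10))
                    for day in range(1, exit_day):
                        obs_rows.append(
                            _mid_day(rng, sm, site, animal_id, arm, day,
                                     dep0, resp0, temp0, recovering=True)
                        )
                    exit_rows.append(dict(animal_id=animal_id, day=exit_day, reason="non_srd"))
                    continue

                if srd_exit:
                    exit_day = int(rng.integers(2, 10))
                    for day in range(1, exit_day):
                        obs_rows.append(
                            _mid_day(rng, sm, site, animal_id, arm, day,
                                     dep0, resp0, temp0, recovering=False)
                        )
                    # exit-day record must satisfy the removal rule
                    which_three = rng.random() < 0.5
                    exit_obs = ClinicalObservation(
                        site=site, animal_id=animal_id, arm=arm, day=exit_day,
                        depression=3 if which_three else int(rng.choice([1, 2])),
                        respiratory=3 if not which_three else int(rng.choice([1, 2])),
                        temperature=min(43.0, max(40.0, _draw_temp(rng, 40.8, 0.4))),
                    )
                    assert classify_removal(exit_obs)
                    obs_rows.append(
                        dict(site=site, animal_id=animal_id, arm=arm.value, day=exit_day,
                             depression=exit_obs.depression, respiratory=exit_obs.respiratory,
                             temp_c=exit_obs.temperature)
                    )
                    exit_rows.append(dict(animal_id=animal_id, day=exit_day, reason="srd"))
                    continue

                day10 = _emit_day10(
                    rng,
                    sm.success if latent_success else sm.failure,
                    want_failure=not latent_success,
                    site=site, animal_id=animal_id, arm=arm,
                )
                for day in range(1, 10):
                    obs_rows.append(
                        _mid_day(rng, sm, site, animal_id, arm, day,
                                 dep0, resp0, temp0,
                                 recovering=latent_success,
                                 end=(day10.depression, day10.respiratory, day10.temperature))
                    )
                obs_rows.append(
                    dict(site=site, animal_id=animal_id, arm=arm.value, day=10,
                         depression=day10.depression, respiratory=day10.respiratory,
                         temp_c=round(day10.temperature, 1))
                )

    observations = pd.DataFrame(obs_rows, columns=OBSERVATION_COLUMNS)
    exits = pd.DataFrame(exit_rows, columns=EXIT_COLUMNS)
    return observations, exits


def _mid_day(rng, sm: ScoreModel, site, animal_id, arm, day,
             dep0, resp0, temp0, *, recovering: bool, end=None) -> dict:
    """An intermediate follow-up day: interpolated severity, never a removal."""
    if end is None:
        end = (0, 0, 39.2) if recovering else (2, 2, 40.6)
    dep = _interp_score(day, dep0, end[0])
    resp = _interp_score(day, resp0, end[1])
    temp = temp0 + (end[2] - temp0) * day / 10.0 + float(rng.normal(0.0, 0.2))
    temp = round(float(np.clip(temp, 35.0, 43.0)), 1)
    # a non-removed animal must never meet the removal rule mid-study
    if temp >= 40.0:
        dep = min(dep, 2)
        resp = min(resp, 2)
    obs = ClinicalObservation(site=site, animal_id=animal_id, arm=arm, day=day,
                              depression=dep, respiratory=resp, temperature=temp)
    assert not classify_removal(obs)
    return dict(site=site, animal_id=animal_id, arm=arm.value, day=day,
                depression=obs.depression, respiratory=obs.respiratory,
                temp_c=obs.temperature)
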