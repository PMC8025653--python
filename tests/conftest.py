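"""Shared fixtures: profile builders and a count-matched trial dataset."""

from __future__ import annotations

import itertools

import pandas as pd
import pytest

from gampk.pk_data import ConcentrationRecord, DoseEvent, PKProfile, Route, Sex


def make_profile(
    times,
    concs,
    *,
    route: str = "IV",
    dose: float = 6.0,
    lloq: float = 2.0,
    bloq=None,
    animal_id: str = "A1",
    sex: str = "female",
) -> PKProfile:
    """Build a PKProfile from parallel time/concentration sequences."""
    flags = bloq if bloq is not None else [False] * len(times)
    records = [
        ConcentrationRecord(float(t), float(c), bool(b))
        for t, c, b in zip(times, concs, flags)
    ]
    return PKProfile(DoseEvent(animal_id, Route(route), dose), Sex(sex), records, lloq=lloq)


@pytest.fixture
def profile_builder():
    return make_profile


def build_trial_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """A trial dataset whose endpoint counts equal the published field study.

    Per arm the day-10 score/temperature patterns are chosen so that the
    overall evaluation and the three dichotomized signs reproduce the
    reported successes exactly: GAM 145/143/139/139 of 150 and TIL
    141/144/142/137 of 151, with 3 and 5 SRD removals respectively plus a
    handful of excluded non-SRD removals.
    """
    obs_rows: list[dict] = []
    exit_rows: list[dict] = []
    ids = itertools.count(1)

    def add_animal(arm, day10=None, exit_reason=None, exit_day=5):
        animal = f"T{next(ids):03d}"
        obs_rows.append(
            dict(site="site1", animal_id=animal, arm=arm, day=0,
                 depression=2, respiratory=2, temp_c=40.5)
        )
        if exit_reason is not None:
            if exit_reason == "srd":
                obs_rows.append(
                    dict(site="site1", animal_id=animal, arm=arm, day=exit_day,
                         depression=3, respiratory=3, temp_c=40.8)
                )
            exit_rows.append(dict(animal_id=animal, day=exit_day, reason=exit_reason))
        else:
            dep, resp, temp = day10
            obs_rows.append(
                dict(site="site1", animal_id=animal, arm=arm, day=10,
                     depression=dep, respiratory=resp, temp_c=temp)
            )

    # GAM: 150 analyzed = 3 SRD removals + 147 day-10 animals
    for _ in range(3):
        add_animal("GAM", exit_reason="srd")
    gam_day10 = (
        [(2, 2, 40.5)] * 2       # day-10 failures
        + [(2, 0, 39.5)] * 2     # success, depression not acceptable
        + [(0, 2, 39.5)] * 6     # success, respiration not acceptable
        + [(0, 0, 40.5)] * 6     # success, temperature not acceptable
        + [(0, 0, 39.0)] * 131   # clean successes
    )
    for pattern in gam_day10:
        add_animal("GAM", day10=pattern)
    # excluded from analysis entirely
    for _ in range(3):
        add_animal("GAM", exit_reason="non_srd")

    # TIL: 151 analyzed = 5 SRD removals + 146 day-10 animals
    for _ in range(5):
        add_animal("TIL", exit_reason="srd")
    til_day10 = (
        [(2, 2, 40.6)] * 2       # failures, both signs involved
        + [(0, 2, 40.6)] * 2     # failures via respiration
        + [(1, 1, 40.8)] * 1     # failure with per-sign scores still acceptable
        + [(0, 0, 40.5)] * 4     # success, temperature not acceptable
        + [(0, 0, 39.0)] * 137   # clean successes
    )
    for pattern in til_day10:
        add_animal("TIL", day10=pattern)
    add_animal("TIL", exit_reason="non_srd")

    return pd.DataFrame(obs_rows), pd.DataFrame(exit_rows)


@pytest.fixture(scope="session")
def trial_tables():
    return build_trial_tables()
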