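"""Domain types and delimited-text I/O for concentration–time data.

Internal units are hours and ng/ml throughout; doses are mg per kg body
weight. Areas under the curve are converted to µg·hr/ml only in the report
layer (exactly once, on output).

Below-LOQ policy: measurements under the lower limit of quantitation
(LLOQ, default 2.0 ng/ml) are flagged and excluded from every downstream
computation — they are not imputed to zero or LLOQ/2, and no pre-dose zero
record is fabricated. A value exactly at the LLOQ is quantifiable by
default (it is, by definition, quantitated); a strict-``>`` mode is
available for sensitivity checks.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

DEFAULT_LLOQ = 2.0  # ng/ml

CONCENTRATION_COLUMNS = [
    "animal_id",
    "sex",
    "route",
    "dose_mg_per_kg",
    "time_hr",
    "conc_ng_per_ml",
]

NCA_TABLE_COLUMNS = [
    "animal_id",
    "group",
    "n",
    "auc_last",
    "auc_inf",
    "cmax",
    "tmax",
    "t_half",
    "vss",
    "cl",
    "f_pct",
]


class Route(str, enum.Enum):
    IV = "IV"
    IM = "IM"


class Sex(str, enum.Enum):
    MALE_CASTRATE = "male_castrate"
    FEMALE = "female"


class ParseError(ValueError):
    """Raised for malformed concentration input, naming the offending row."""


@dataclass(frozen=True)
class DoseEvent:
    """A single bolus administration: route and dose in mg/kg body weight."""

    animal_id: str
    route: Route
    dose: float  # mg/kg
    dose_time: float = 0.0  # hr, 0 by convention

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ValueError(f"dose must be positive, got {self.dose}")
        if not isinstance(self.route, Route):
            object.__setattr__(self, "route", Route(self.route))


@dataclass(frozen=True)
class ConcentrationRecord:
    """One plasma measurement: time since dose (hr) and concentration (ng/ml)."""

    time: float
    concentration: float
    bloq: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"time must be >= 0, got {self.time}")
        if self.concentration < 0:
            raise ValueError(f"concentration must be >= 0, got {self.concentration}")


@dataclass
class PKProfile:
    """One animal's dosing record plus its time-ordered plasma measurements."""

    dose_event: DoseEvent
    sex: Sex
    records: list[ConcentrationRecord] = field(default_factory=list)
    lloq: float = DEFAULT_LLOQ

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"profile {self.dose_event.animal_id}: no records")
        if not isinstance(self.sex, Sex):
            self.sex = Sex(self.sex)
        self.records = sorted(self.records, key=lambda r: r.time)
        times = [r.time for r in self.records]
        if len(set(times)) != len(times):
            dup = next(t for i, t in enumerate(times) if t in times[:i])
            raise ValueError(
                f"profile {self.dose_event.animal_id}: duplicate time {dup}"
            )

    @property
    def animal_id(self) -> str:
        return self.dose_event.animal_id


def quantifiable_records(
    profile: PKProfile, *, lloq_inclusive: bool = True
) -> list[ConcentrationRecord]:
    """Records usable for NCA: not flagged BLOQ and at/above the LLOQ.

    Idempotent and order-preserving. ``lloq_inclusive`` controls whether a
    value exactly at the LLOQ counts as quantifiable (default yes).
    """
    out = []
    for rec in profile.records:
        if rec.bloq:
            continue
        if lloq_inclusive:
            if rec.concentration >= profile.lloq:
                out.append(rec)
        elif rec.concentration > profile.lloq:
            out.append(rec)
    return out


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")


def read_concentrations(
    path: str | Path,
    lloq: float = DEFAULT_LLOQ,
    *,
    lloq_inclusive: bool = True,
) -> list[PKProfile]:
    """Read a concentration CSV into one :class:`PKProfile` per animal.

    Expected columns: animal_id, sex, route, dose_mg_per_kg, time_hr,
    conc_ng_per_ml, and optionally bloq (0/1). Rows with concentration
    below the LLOQ (or at it, in strict mode) are flagged BLOQ in addition
    to any explicit marker.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    df = pd.read_csv(path)
    _require_columns(df, CONCENTRATION_COLUMNS, path)

    for col in ("time_hr", "conc_ng_per_ml", "dose_mg_per_kg"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(df.index[coerced.isna()][0]) + 2  # 1-based incl. header
            raise ParseError(f"{path}: non-numeric value in '{col}' at line {row}")
        df[col] = coerced

    dup = df.duplicated(subset=["animal_id", "time_hr"], keep=False)
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise ParseError(
            f"{path}: duplicate time {bad['time_hr']} hr for animal "
            f"{bad['animal_id']}"
        )

    profiles: list[PKProfile] = []
    for animal_id, sub in df.groupby("animal_id", sort=True):
        first = sub.iloc[0]
        try:
            route = Route(str(first["route"]).strip().upper())
        except ValueError as exc:
            raise ParseError(
                f"{path}: unknown route {first['route']!r} for animal {animal_id}"
            ) from exc
        try:
            sex = Sex(str(first["sex"]).strip().lower())
        except ValueError as exc:
            raise ParseError(
                f"{path}: unknown sex {first['sex']!r} for animal {animal_id}"
            ) from exc
        dose_event = DoseEvent(str(animal_id), route, float(first["dose_mg_per_kg"]))
        records = []
        for _, row in sub.iterrows():
            conc = float(row["conc_ng_per_ml"])
            flagged = bool(int(row["bloq"])) if "bloq" in sub.columns and pd.notna(
                row.get("bloq")
            ) else False
            below = conc < lloq if lloq_inclusive else conc <= lloq
            records.append(
                ConcentrationRecord(float(row["time_hr"]), conc, flagged or below)
            )
        profiles.append(PKProfile(dose_event, sex, records, lloq=lloq))
    return profiles


def profiles_to_frame(profiles: Sequence[PKProfile]) -> pd.DataFrame:
    """Flatten profiles back into the concentration CSV dialect."""
    rows = []
    for p in profiles:
        for r in p.records:
            rows.append(
                {
                    "animal_id": p.animal_id,
                    "sex": p.sex.value,
                    "route": p.dose_event.route.value,
                    "dose_mg_per_kg": p.dose_event.dose,
                    "time_hr": r.time,
                    "conc_ng_per_ml": r.concentration,
                    "bloq": int(r.bloq),
                }
            )
    return pd.DataFrame(rows, columns=CONCENTRATION_COLUMNS + ["bloq"])


def write_concentrations(profiles: Sequence[PKProfile], path: str | Path) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)


def write_nca_table(results: Sequence, path: str | Path) -> None:
    """Write per-animal NCA results as CSV (report units: AUC in µg·hr/ml).

    ``results`` are :class:`gampk.nca.NCAResult`; the µg conversion happens
    here and nowhere else. IV-only parameters are blank for IM animals.
    """
    if not len(results):
        raise ValueError("write_nca_table: empty result list")
    rows = []
    for r in results:
        rows.append(
            {
                "animal_id": r.animal_id,
                "group": f"{r.route.value}-{r.dose:g}",
                "n": r.lambda_fit.n_points,
                "auc_last": r.auc_last / 1000.0,  # ng·hr/ml -> µg·hr/ml
                "auc_inf": r.auc_inf / 1000.0,
                "cmax": r.cmax,
                "tmax": r.tmax,
                "t_half": r.lambda_fit.t_half,
                "vss": r.vss if r.vss is not None else "",
                "cl": r.cl_obs if r.cl_obs is not None else "",
                "f_pct": r.f_pct if r.f_pct is not None else "",
            }
        )
    pd.DataFrame(rows, columns=NCA_TABLE_COLUMNS).to_csv(path, index=False)


def read_nca_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_nca_table`."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    df = pd.read_csv(path)
    _require_columns(df, NCA_TABLE_COLUMNS, path)
    return df
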