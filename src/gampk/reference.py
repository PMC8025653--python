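"""Published summary results of the original gamithromycin swine studies.

These are the group-level numbers reported for the single-dose PK study
(group mean ± SD per route/dose) and the multicentre SRD field trial
(per-endpoint success counts per arm). They are inputs for re-deriving
the study's secondary quantities — bioavailability ratios, dose
normalization, the group-mean dose-proportionality fit and the
non-inferiority confidence intervals — since per-animal raw data were
never published.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PKGroupReference:
    route: str
    dose: float  # mg/kg
    n: int
    auc_last: float  # µg·hr/ml, group mean
    auc_inf: float  # µg·hr/ml, group mean
    cmax: float | None  # ng/ml, group mean (not reported for IV)
    t_half: float  # hr, group mean


#: group means of the single-dose PK study (IV 6 and IM 3/6/12 mg/kg)
PK_GROUPS: tuple[PKGroupReference, ...] = (
    PKGroupReference("IV", 6.0, 8, 5.65, 5.89, None, 76.1),
    PKGroupReference("IM", 3.0, 6, 2.90, 3.15, 843.0, 79.5),
    PKGroupReference("IM", 6.0, 6, 5.13, 5.43, 960.0, 94.1),
    PKGroupReference("IM", 12.0, 6, 9.35, 9.60, 1390.0, 74.2),
)

#: IV reference values used to parameterize the synthetic study
IV_CL_ML_HR_KG = 1030.0
IV_VSS_L_KG = 39.2
IV_T_HALF_HR = 76.1

#: field-trial endpoint counts: (successes GAM, n GAM, successes TIL, n TIL)
FIELD_TRIAL_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "overall": (145, 150, 141, 151),
    "depression": (143, 150, 144, 151),
    "respiration": (139, 150, 142, 151),
    "temperature": (139, 150, 137, 151),
}

#: non-inferiority margin used in the field trial
FIELD_TRIAL_MARGIN = 0.10


def im_groups() -> list[PKGroupReference]:
    return [g for g in PK_GROUPS if g.route == "IM"]


def iv_group() -> PKGroupReference:
    return next(g for g in PK_GROUPS if g.route == "IV")
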