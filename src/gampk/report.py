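"""Pipeline drivers and report rendering.

Ties the stages together into the two study analyses:

* PK pipeline: concentration CSV → per-animal NCA table, group summary
  (mean ± SD), bioavailability / dose-normalization table, sex and
  dose-group t-tests, power-model fit with a log-log figure;
* trial pipeline: observation + exit CSVs → per-endpoint proportions,
  non-inferiority CIs and decisions, analysis-population accounting.

Reports are pure functions of (inputs, configuration): no timestamps or
environment state are written, so identical inputs give identical bytes.
All decision thresholds in force are echoed into the run log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import nca as nca_mod
from ._format import round_half_away, sigfig_str
from .clinical_trial import (
    DEFAULT_MARGIN,
    analyze_trial,
    read_exits,
    read_observations,
)
from .dose_proportionality import fit_power_model, two_sample_ttest
from .nca import NCAResult, analyze_study, bioavailability, dose_normalize, summarize_group
from .pk_data import DEFAULT_LLOQ, PKProfile, Route, read_concentrations, write_nca_table


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and context."""


@dataclass
class RunConfig:
    """Run configuration shared by the CLI and the analysis drivers."""

    mode: str = "pk"  # pk | trial | simulate-pk | simulate-trial
    input: Optional[Path] = None
    exits: Optional[Path] = None
    out: Path = Path("results")
    lloq: float = DEFAULT_LLOQ
    lloq_inclusive: bool = True
    margin: float = DEFAULT_MARGIN
    lambda_z_selection: str = "best_fit"
    ttest_welch: bool = False
    seed: int = 0
    report_sigfigs: int = 3
    make_plot: bool = True
    log_lines: list = field(default_factory=list)

    def log(self, line: str) -> None:
        self.log_lines.append(line)


def _group_label(r: NCAResult) -> str:
    return f"{r.route.value}-{r.dose:g}"


def _fmt(x: float, sig: int = 3) -> str:
    return sigfig_str(x, sig)


def run_pk_pipeline(config: RunConfig, profiles: Optional[Sequence[PKProfile]] = None) -> dict:
    """Execute the full PK analysis; returns the computed objects.

    ``profiles`` may be passed directly (e.g. fresh from the simulator);
    otherwise they are read from ``config.input``.
    """
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    config.log(f"lloq = {config.lloq} ng/ml (boundary inclusive: {config.lloq_inclusive})")
    config.log(f"lambda_z selection = {config.lambda_z_selection}")
    config.log(f"t-test variant = {'welch' if config.ttest_welch else 'pooled'}")

    if profiles is None:
        if config.input is None:
            raise PipelineError("input stage: no concentration file given")
        try:
            profiles = read_concentrations(
                config.input, lloq=config.lloq, lloq_inclusive=config.lloq_inclusive
            )
        except Exception as exc:
            raise PipelineError(f"input stage: {exc}") from exc

    n_bloq = sum(sum(r.bloq for r in p.records) for p in profiles)
    config.log(f"profiles read: {len(profiles)}; BLOQ measurements excluded: {n_bloq}")

    try:
        results = analyze_study(profiles, selection=config.lambda_z_selection)
    except Exception as exc:
        raise PipelineError(f"nca stage: {exc}") from exc
    for r in results:
        config.log(
            f"lambda_z[{r.animal_id}]: n={r.lambda_fit.n_points} points from "
            f"t={r.lambda_fit.window_start:g} hr, adjR2={r.lambda_fit.r_squared_adj:.4f}"
        )

    write_nca_table(results, out / "nca_animals.csv")

    # ---- group summary (Table-4 style: mean ± SD per route/dose group)
    groups: dict[str, list[NCAResult]] = {}
    for r in results:
        groups.setdefault(_group_label(r), []).append(r)

    summary_rows = []
    for label, rs in groups.items():
        params = {
            "auc_last_ug_hr_ml": [r.auc_last / 1000.0 for r in rs],
            "auc_inf_ug_hr_ml": [r.auc_inf / 1000.0 for r in rs],
            "cmax_ng_ml": [r.cmax for r in rs],
            "t_half_hr": [r.lambda_fit.t_half for r in rs],
            "extrap_frac": [r.extrap_frac for r in rs],
        }
        if rs[0].route is Route.IV:
            params["vss_l_kg"] = [r.vss for r in rs]
            params["cl_ml_hr_kg"] = [r.cl_obs for r in rs]
        else:
            params["f_pct"] = [r.f_pct for r in rs if r.f_pct is not None]
        tmaxes = [r.tmax for r in rs]
        summary_rows.append(
            {
                "group": label,
                "parameter": "tmax_hr",
                "mean": float(np.mean(tmaxes)),
                "sd": float(np.std(tmaxes, ddof=1)) if len(tmaxes) > 1 else "",
                "n": len(tmaxes),
                "formatted": f"{min(tmaxes):g} to {max(tmaxes):g}",
            }
        )
        for name, values in params.items():
            if not values:
                continue
            s = summarize_group(values, label, name)
            summary_rows.append(
                {
                    "group": label,
                    "parameter": name,
                    "mean": s.mean,
                    "sd": s.sd if s.sd is not None else "",
                    "n": s.n,
                    "formatted": s.formatted,
                }
            )
    summary_df = pd.DataFrame(summary_rows)
    summary_df.to_csv(out / "nca_group_summary.csv", index=False)

    # ---- bioavailability and dose normalization
    iv = [r for r in results if r.route is Route.IV]
    im = [r for r in results if r.route is Route.IM]
    bio_rows = []
    if iv and im:
        iv_dose = iv[0].dose
        iv_mean_auc = float(np.mean([r.auc_inf for r in iv]))
        im_by_dose: dict[float, list[NCAResult]] = {}
        for r in im:
            im_by_dose.setdefault(r.dose, []).append(r)
        for dose in sorted(im_by_dose):
            rs = im_by_dose[dose]
            mean_auc = float(np.mean([r.auc_inf for r in rs]))
            mean_cmax = float(np.mean([r.cmax for r in rs]))
            f_group = bioavailability(mean_auc, dose, iv_mean_auc, iv_dose)
            f_animal = float(np.mean([r.f_pct for r in rs]))
            bio_rows.append(
                {
                    "dose_mg_per_kg": dose,
                    "n": len(rs),
                    "f_group_mean_pct": f_group,
                    "f_group_mean_pct_fmt": _fmt(f_group, config.report_sigfigs),
                    "f_per_animal_mean_pct": f_animal,
                    "dose_norm_cmax": dose_normalize(mean_cmax, dose),
                    "dose_norm_auc_inf_ug": dose_normalize(mean_auc / 1000.0, dose),
                }
            )
    bio_df = pd.DataFrame(bio_rows)
    bio_df.to_csv(out / "bioavailability.csv", index=False)

    # ---- t-tests: sex difference; dose-normalized AUC 6 vs 3 / 6 vs 12
    ttest_rows = []
    sexes = {p.animal_id: p.sex.value for p in profiles}
    for param, getter in (
        ("t_half_hr", lambda r: r.lambda_fit.t_half),
        ("auc_inf_ng_hr_ml", lambda r: r.auc_inf),
    ):
        a = [getter(r) for r in results if sexes[r.animal_id] == "male_castrate"]
        b = [getter(r) for r in results if sexes[r.animal_id] == "female"]
        if len(a) >= 2 and len(b) >= 2:
            t = two_sample_ttest(a, b, welch=config.ttest_welch)
            ttest_rows.append(
                {"comparison": f"sex:{param}", "t": t.t_statistic, "df": t.degrees_of_freedom,
                 "p": t.p_value, "significant_95": t.significant_at_95}
            )
    im_by_dose = {}
    for r in im:
        im_by_dose.setdefault(r.dose, []).append(r.auc_inf / r.dose)
    doses_sorted = sorted(im_by_dose)
    if len(doses_sorted) == 3:
        mid = doses_sorted[1]
        for other in (doses_sorted[0], doses_sorted[2]):
            t = two_sample_ttest(im_by_dose[mid], im_by_dose[other], welch=config.ttest_welch)
            ttest_rows.append(
                {"comparison": f"dose_norm_auc:{mid:g}v{other:g}", "t": t.t_statistic,
                 "df": t.degrees_of_freedom, "p": t.p_value,
                 "significant_95": t.significant_at_95}
            )
    pd.DataFrame(ttest_rows).to_csv(out / "ttests.csv", index=False)

    # ---- dose-proportionality power model on per-animal IM AUCinf
    power = None
    if len({r.dose for r in im}) >= 2 and len(im) >= 3:
        obs = [(r.dose, r.auc_inf) for r in im]
        power = fit_power_model(obs)
        pd.DataFrame(
            [
                {"coefficient": "beta0", "estimate": power.beta0,
                 "ci_lower": power.ci_beta0[0], "ci_upper": power.ci_beta0[1],
                 "p_value": power.p_value_beta0},
                {"coefficient": "beta1", "estimate": power.beta1,
                 "ci_lower": power.ci_beta1[0], "ci_upper": power.ci_beta1[1],
                 "p_value": power.p_value_beta1},
            ]
        ).to_csv(out / "power_model.csv", index=False)
        config.log(
            f"power model: ln AUCinf = {power.beta0:.4f} + {power.beta1:.4f} ln Dose, "
            f"R2 = {power.r_squared:.4f}, n = {power.n}, weights 1/dose"
        )
        if config.make_plot:
            _plot_power_model(obs, power, out / "dose_proportionality.png")

    (out / "run_log.txt").write_text("\n".join(config.log_lines) + "\n")
    return {
        "results": results,
        "summary": summary_df,
        "bioavailability": bio_df,
        "power_model": power,
        "ttests": ttest_rows,
    }


def _plot_power_model(obs, power, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    doses = np.array([d for d, _ in obs])
    aucs = np.array([a for _, a in obs]) / 1000.0  # µg·hr/ml for display
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(np.log(doses), np.log(aucs * 1000.0), color="tab:blue", label="animals")
    grid = np.linspace(np.log(doses.min()), np.log(doses.max()), 50)
    ax.plot(grid, power.beta0 + power.beta1 * grid, color="tab:red",
            label=f"ln AUC = {power.beta0:.3f} + {power.beta1:.3f} ln dose")
    ax.set_xlabel("ln dose (mg/kg)")
    ax.set_ylabel("ln AUCinf (ng·hr/ml)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# trial pipeline


def run_trial_pipeline(
    config: RunConfig,
    observations: Optional[pd.DataFrame] = None,
    exits: Optional[pd.DataFrame] = None,
) -> dict:
    """Execute the field-trial analysis; returns the report objects."""
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    config.log(f"non-inferiority margin = {config.margin}")
    config.log("enrolment rule: dep>=2 & resp>=2 & T>40.0; removal: score==3 & T>=40.0")
    config.log("day-10 failure: (dep>=1 & T>40.0) | (resp>=1 & T>40.0); acceptable: score<=1, T<=40.0")

    if observations is None:
        if config.input is None:
            raise PipelineError("input stage: no observation file given")
        try:
            observations = read_observations(config.input)
            exits = read_exits(config.exits) if config.exits else None
        except Exception as exc:
            raise PipelineError(f"input stage: {exc}") from exc

    try:
        report = analyze_trial(observations, exits, margin=config.margin)
    except Exception as exc:
        raise PipelineError(f"trial stage: {exc}") from exc

    rows = []
    for name, res in report.endpoints.items():
        rows.append(
            {
                "endpoint": name,
                "gam_pct": round_half_away(res.p1 * 100.0, 0),
                "gam_counts": f"{report.successes[name]['GAM']}/{res.n1}",
                "til_pct": round_half_away(res.p2 * 100.0, 0),
                "til_counts": f"{report.successes[name]['TIL']}/{res.n2}",
                "ci_lower": round_half_away(res.ci_lower, 2),
                "ci_upper": round_half_away(res.ci_upper, 2),
                "threshold": -res.margin,
                "non_inferior": res.non_inferior,
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(out / "trial_endpoints.csv", index=False)

    lines = [
        f"{'endpoint':<14}{'GAM':>16}{'TIL':>16}{'CI lower':>10}{'CI upper':>10}"
        f"{'threshold':>11}{'non-inferior':>14}"
    ]
    for row in rows:
        gam_cell = "{:.0f}% ({})".format(row["gam_pct"], row["gam_counts"])
        til_cell = "{:.0f}% ({})".format(row["til_pct"], row["til_counts"])
        lines.append(
            f"{row['endpoint']:<14}{gam_cell:>16}{til_cell:>16}"
            f"{row['ci_lower']:>10.2f}{row['ci_upper']:>10.2f}"
            f"{row['threshold']:>11.2f}{str(row['non_inferior']):>14}"
        )
    lines.append("")
    lines.append("analysis population:")
    for key, d in (
        ("enrolled", report.n_enrolled),
        ("removed (SRD, failures)", report.n_removed_srd),
        ("removed (non-SRD, excluded)", report.n_removed_non_srd),
        ("analyzed", report.n_analyzed),
    ):
        lines.append(f"  {key}: GAM {d['GAM']}, TIL {d['TIL']}")
    (out / "trial_report.txt").write_text("\n".join(lines) + "\n")
    (out / "run_log.txt").write_text("\n".join(config.log_lines) + "\n")
    return {"report": report, "table": table}
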