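"""Non-inferiority evaluation: published counts and the synthetic trial.

First re-derives the four per-endpoint confidence intervals from the
published success counts; then runs the full scoring pipeline on the
synthetic trial from step 04 and writes the endpoint table and report.
"""

from pathlib import Path

from gampk.clinical_trial import noninferiority_analysis
from gampk.reference import FIELD_TRIAL_COUNTS
from gampk.report import RunConfig, run_trial_pipeline

IN = Path("results/trial_sim")
OUT = Path("results/trial")


def main() -> None:
    print("published counts -> 95% CI on the success-proportion difference:")
    for name, (x1, n1, x2, n2) in FIELD_TRIAL_COUNTS.items():
        res = noninferiority_analysis(x1, n1, x2, n2)
        verdict = "non-inferior" if res.non_inferior else "NOT non-inferior"
        print("  %-12s %3.0f%% (%d/%d) vs %3.0f%% (%d/%d): (%.2f, %.2f) -> %s"
              % (name, res.p1 * 100, x1, n1, res.p2 * 100, x2, n2,
                 res.ci_lower, res.ci_upper, verdict))

    obs_path = IN / "observations.csv"
    if not obs_path.exists():
        raise SystemExit(f"{obs_path} missing - run analysis/04_simulate_field_trial.py first")
    config = RunConfig(mode="trial", input=obs_path, exits=IN / "exits.csv", out=OUT)
    outputs = run_trial_pipeline(config)
    print(f"\nsynthetic trial -> {OUT}")
    print((OUT / "trial_report.txt").read_text())


if __name__ == "__main__":
    main()
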