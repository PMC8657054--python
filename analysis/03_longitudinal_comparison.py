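"""Longitudinal model comparison: predicting one-year loneliness change.

Same catalogue, but the follow-up outcome is modelled with the baseline
outcome as a freely estimated covariate (so every K grows by one), and
persons missing the follow-up stay in the AICc sample size while dropping out
of the conditional likelihood.  A failed gate is reported as a decision, the
way a high-attrition cohort can end this analysis.

Run analysis/01_simulate_cohorts.py first.
"""

from pathlib import Path

from polycompare import RunConfig, run_analysis

ROOT = Path(__file__).resolve().parents[1]
COHORTS = ROOT / "results" / "cohorts"
OUT = ROOT / "results" / "longitudinal"


def main() -> None:
    for name in ("panel_346", "multiitem_237"):
        csv = COHORTS / f"{name}.csv"
        if not csv.exists():
            raise SystemExit(f"{csv} missing -- run analysis/01_simulate_cohorts.py first")
        result = run_analysis(
            RunConfig(input_path=str(csv), mode="longitudinal",
                      output_dir=str(OUT / name))
        )
        print(f"\n=== {name} (longitudinal) ===")
        g = result.gate
        print(f"LR gate: chi2({g.df}) = {g.statistic:.2f}, p = {g.p:.3g}, proceed = {g.proceed}")
        if result.gate_stopped:
            print("traits explain no added variance beyond baseline loneliness; stopping")
            continue
        t = result.table.table
        in_set = t.loc[t["in_confidence_set"], ["model", "K", "LL", "AICc", "weight"]]
        print("95% confidence set:")
        print(in_set.to_string(index=False, float_format=lambda v: f"{v:.3f}"))


if __name__ == "__main__":
    main()
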