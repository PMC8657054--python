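"""Cross-sectional model comparison on both synthetic cohorts.

For each cohort: preprocess, screen influence, apply the full-vs-null LR gate,
fit the 19-model catalogue, prune redundant models, and report the 95%
confidence set with Akaike weights.  Outputs land in
results/cross_sectional/<cohort>/ (comparison.csv, fits.json, gate.json, ...).

Run analysis/01_simulate_cohorts.py first.
"""

from pathlib import Path

from polycompare import RunConfig, run_analysis

ROOT = Path(__file__).resolve().parents[1]
COHORTS = ROOT / "results" / "cohorts"
OUT = ROOT / "results" / "cross_sectional"


def main() -> None:
    for name in ("panel_346", "multiitem_237"):
        csv = COHORTS / f"{name}.csv"
        if not csv.exists():
            raise SystemExit(f"{csv} missing -- run analysis/01_simulate_cohorts.py first")
        result = run_analysis(
            RunConfig(input_path=str(csv), mode="cross_sectional",
                      output_dir=str(OUT / name))
        )
        print(f"\n=== {name} ===")
        g = result.gate
        print(f"LR gate: chi2({g.df}) = {g.statistic:.2f}, p = {g.p:.2e}, proceed = {g.proceed}")
        if result.gate_stopped:
            print("gate stopped the analysis; no comparison performed")
            continue
        t = result.table.table
        cols = ["model", "K", "LL", "AICc", "weight", "adj_R2"]
        in_set = t.loc[t["in_confidence_set"], cols]
        print("95% confidence set:")
        print(in_set.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        if result.table.exclusions:
            print(f"redundancy-pruned models: {len(result.table.exclusions)}")


if __name__ == "__main__":
    main()
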