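"""Response-surface interpretation of the fitted full models.

Reads the cross-sectional fits, re-derives the auxiliary response-surface
coefficients (a1..a4 along the congruence and incongruence lines), classifies
each trait's effect shape over the observed range, and writes a 50x50
prediction grid masked to the convex hull of the observed trait pairs.

Run analysis/02_cross_sectional_comparison.py first.
"""

import json
from pathlib import Path

import pandas as pd

from polycompare import classify_shape, predict_grid, rsa_coefficients
from polycompare.preprocess import PreparedData, RangeBox

ROOT = Path(__file__).resolve().parents[1]
CS = ROOT / "results" / "cross_sectional"
OUT = ROOT / "results" / "surfaces"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name in ("panel_346", "multiitem_237"):
        run_dir = CS / name
        fits_path = run_dir / "fits.json"
        if not fits_path.exists():
            raise SystemExit(f"{fits_path} missing -- run analysis/02 first")
        fits = json.loads(fits_path.read_text())
        beta = next(d["beta"] for d in fits if d["spec"] == "Full Model")
        frame = pd.read_csv(run_dir / "prepared.csv")
        box = RangeBox(frame["E"].min(), frame["E"].max(), frame["N"].min(), frame["N"].max())
        prepared = PreparedData(frame=frame, range_box=box, trait_means=(0.0, 0.0))

        a = rsa_coefficients(beta)
        shape = classify_shape(beta, box, prepared)
        grid = predict_grid(beta, box, resolution=50, points=frame[["E", "N"]].to_numpy())
        grid.to_csv(OUT / f"{name}_grid.csv")
        (OUT / f"{name}_shape.json").write_text(json.dumps(shape, indent=2, default=list))

        print(f"\n=== {name}: full-model surface ===")
        print(f"a1 (slope along E=N)      = {a.a1:+.3f}")
        print(f"a2 (curvature along E=N)  = {a.a2:+.3f}")
        print(f"a3 (slope along E=-N)     = {a.a3:+.3f}")
        print(f"a4 (curvature along E=-N) = {a.a4:+.3f}")
        print(f"shape: E effect {shape['E']}, N effect {shape['N']}, "
              f"interaction {shape['interaction']}")
        if "N_positive_slope_fraction" in shape:
            print(f"fraction of persons with rising N-slope: "
                  f"{100 * shape['N_positive_slope_fraction']:.2f}%")
        print(f"in-region grid nodes: {int(grid.frame['in_region'].sum())}/2500")


if __name__ == "__main__":
    main()
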