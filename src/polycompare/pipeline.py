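"""End-to-end orchestration: ingest -> preprocess -> gate -> catalogue -> report.

The stages run in the order the analysis prescribes: preprocess and screen the
cohort, estimate the full and null models, apply the chi-square
likelihood-ratio gate, and only when it passes fit the whole catalogue, prune
redundant models, compute Akaike weights and the confidence set, and -- when
the full model makes the confidence set -- interpret it as a response surface.
A failed gate is a recorded decision, not an error; the run stops there and
says so.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from . import catalog as cat
from .cohort import SynthConfig, generate
from .comparison import ComparisonTable, build_comparison_table
from .fitting import FitResult, GateResult, fit, fit_catalog, lr_gate
from .preprocess import Cohort, InfluenceReport, PreparedData, build_design, flag_influential, load_cohort
from .surface import SurfaceGrid, classify_shape, predict_grid

__all__ = ["RunConfig", "RunResult", "run_analysis"]

log = logging.getLogger("polycompare")


@dataclass
class RunConfig:
    input_path: str | None = None
    ingest_config: dict | str | None = None
    synth: SynthConfig | None = None
    mode: str = "cross_sectional"  # or "longitudinal"
    rescale: bool = True
    confidence_level: float = 0.95
    redundancy_threshold: float = 1.0
    alpha: float = 0.05
    renormalize_within_set: bool = False
    output_dir: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synth is None):
            raise ValueError("exactly one of input_path or synth must be given")
        if not 0.0 < self.confidence_level < 1.0:
            raise ValueError("confidence level must lie in (0, 1)")
        if self.mode not in ("cross_sectional", "longitudinal"):
            raise ValueError(f"unknown mode '{self.mode}'")


@dataclass
class RunResult:
    gate: GateResult
    gate_stopped: bool
    table: ComparisonTable | None
    fits: list[FitResult] = field(default_factory=list)
    influence: InfluenceReport | None = None
    surface_grid: SurfaceGrid | None = None
    surface_shape: dict | None = None
    prepared: PreparedData | None = None
    manifest: dict = field(default_factory=dict)


def _manifest(config: RunConfig, cohort: Cohort) -> dict:
    cfg = dataclasses.asdict(config)
    if config.synth is not None:
        cfg["synth"] = dataclasses.asdict(config.synth)
    return {
        "polycompare_version": __version__,
        "numpy_version": np.__version__,
        "config": cfg,
        "n_rows": cohort.n,
        "cohort_meta": {k: v for k, v in cohort.meta.items() if not isinstance(v, dict)},
    }


def run_analysis(config: RunConfig) -> RunResult:
    """Run the full pipeline; see the module docstring for the stage order."""
    if config.synth is not None:
        synth = config.synth
        if synth.seed is None and config.seed is not None:
            synth = dataclasses.replace(synth, seed=config.seed)
        cohort = generate(synth)
        log.info("generated synthetic cohort: n=%d, model=%s", cohort.n, synth.model)
    else:
        cohort = load_cohort(config.input_path, config.ingest_config)
        log.info("loaded cohort from %s: n=%d", config.input_path, cohort.n)

    prepared = build_design(cohort, rescale=config.rescale)
    influence = flag_influential(prepared, outcome="L1")
    if len(influence.flagged):
        log.warning("influential cases flagged (not removed): %s",
                    influence.flagged["row"].tolist())

    longitudinal = config.mode == "longitudinal"
    outcome = "L2" if longitudinal else "L1"
    covariate = "L1" if longitudinal else None
    specs = cat.build_catalog(prepared.range_box, longitudinal=longitudinal)
    by_name = {s.name: s for s in specs}

    full_fit = fit(by_name[cat.FULL_MODEL], prepared, outcome, covariate)
    null_fit = fit(by_name[cat.NULL_MODEL], prepared, outcome, covariate)
    gate = lr_gate(full_fit, null_fit, alpha=config.alpha)
    log.info("LR gate: chi2(%d)=%.2f, p=%.4g, proceed=%s", gate.df, gate.statistic, gate.p,
             gate.proceed)

    result = RunResult(gate=gate, gate_stopped=not gate.proceed, table=None,
                       influence=influence, prepared=prepared,
                       manifest=_manifest(config, cohort))
    if not gate.proceed:
        log.info("full model adds no significant variance over the null; stopping here")
        _write_outputs(config, result)
        return result

    fits = fit_catalog(specs, prepared, outcome, covariate)
    nesting_pairs = cat.catalog_nesting(longitudinal=longitudinal)
    table = build_comparison_table(
        fits,
        nesting_pairs,
        level=config.confidence_level,
        threshold=config.redundancy_threshold,
        renormalize_within_set=config.renormalize_within_set,
    )
    result.fits = fits
    result.table = table
    log.info("best model: %s; confidence set: %s", table.best_model, table.confidence_models)

    if cat.FULL_MODEL in table.confidence_models:
        full = next(f for f in fits if f.spec_name == cat.FULL_MODEL)
        pts = prepared.frame[["E", "N"]].to_numpy()
        result.surface_grid = predict_grid(full.beta, prepared.range_box, points=pts)
        result.surface_shape = classify_shape(full.beta, prepared.range_box, prepared)
        log.info("full model in confidence set; surface shape: %s", result.surface_shape)

    _write_outputs(config, result)
    return result


def _write_outputs(config: RunConfig, result: RunResult) -> None:
    if config.output_dir is None:
        return
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.prepared.to_csv(out / "prepared.csv")
    result.influence.table.to_csv(out / "influence.csv", index=False)
    gate = dataclasses.asdict(result.gate) | {"gate_stopped": result.gate_stopped}
    (out / "gate.json").write_text(json.dumps(gate, indent=2))
    if result.table is not None:
        result.table.to_csv(out / "comparison.csv")
        (out / "exclusions.json").write_text(json.dumps(result.table.exclusions, indent=2))
        (out / "fits.json").write_text(
            json.dumps([f.to_dict() for f in result.fits], indent=2)
        )
    if result.surface_grid is not None:
        result.surface_grid.to_csv(out / "surface_grid.csv")
        (out / "surface_shape.json").write_text(
            json.dumps(result.surface_shape, indent=2, default=list)
        )
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2, default=str))
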