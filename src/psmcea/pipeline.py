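"""End-to-end orchestration: survival inputs -> fits -> traces -> results.

Stages (run in dependency order): ``base`` (survival fitting + both cohort
traces + incremental results), ``scenario`` (reduced bevacizumab-biosimilar
dose, efficacy unchanged), ``dsa`` (one-way tornado), ``psa`` (Monte Carlo
acceptability analysis). All tabular outputs are written as CSV; plots are
optional PNG analogues of the tornado, cost-effectiveness plane and CEAC.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import (
    ConfigError,
    apply_overrides,
    build_settings,
    build_strategies,
    parameter_specs,
)
from .engine import CEAResult, CohortTrace, compare, run_trace
from .survival import (
    ParametricFit,
    fit_all_families,
    fit_report,
    km_estimate,
    reconstruct_ipd,
    select_best,
)
from .synthetic import CohortSpec, DigitizedCurve, SurvivalDataset, simulate_ipd
from .uncertainty import PSAResult, one_way_dsa, run_psa

STAGES = ("base", "scenario", "dsa", "psa")
ENDPOINTS = ("PFS", "OS")


@dataclass
class PipelineResult:
    """Everything one run produced, for programmatic use or export."""

    config: dict
    datasets: dict[str, SurvivalDataset]
    fits: dict[str, list[ParametricFit]]
    selected: dict[str, ParametricFit]
    base: CEAResult | None = None
    traces: dict[str, CohortTrace] = field(default_factory=dict)
    scenario: CEAResult | None = None
    dsa: pd.DataFrame | None = None
    psa: PSAResult | None = None
    log: list[str] = field(default_factory=list)


def load_survival_datasets(
    config: dict, seed: int | None = None
) -> dict[str, SurvivalDataset]:
    """Obtain the reference arm's PFS and OS datasets per the config source:
    synthetic cohorts, patient-level CSVs, or digitized-curve reconstruction.
    """
    surv = config["survival"]
    source = surv.get("source", "synthetic")
    datasets: dict[str, SurvivalDataset] = {}
    if source == "synthetic":
        syn = surv["synthetic"]
        base_seed = int(syn["seed"]) if seed is None else int(seed)
        for i, endpoint in enumerate(ENDPOINTS):
            cal = syn[endpoint.lower()]
            params = (math.log(float(cal["median_months"])), float(cal["sigma"])) \
                if cal["family"] in ("log-normal", "lognormal") \
                else tuple(cal["params"])
            spec = CohortSpec(
                n_patients=int(syn["n_patients"]),
                endpoint=endpoint,
                family=cal["family"],
                params=params,
                accrual_months=float(syn["accrual_months"]),
                followup_months=float(syn["followup_months"]),
                seed=base_seed + i,
            )
            datasets[endpoint] = simulate_ipd(spec)
    elif source == "ipd":
        for endpoint in ENDPOINTS:
            path = surv["ipd"][endpoint.lower()]
            if path is None:
                raise ConfigError(
                    f"survival.source is 'ipd' but no {endpoint} CSV is set"
                )
            datasets[endpoint] = SurvivalDataset.from_csv(path, endpoint=endpoint)
    elif source == "digitized":
        for endpoint in ENDPOINTS:
            entry = surv["digitized"][endpoint.lower()]
            if entry.get("curve") is None or entry.get("risk") is None:
                raise ConfigError(
                    f"survival.source is 'digitized' but {endpoint} curve/risk "
                    "CSVs are not set"
                )
            curve = DigitizedCurve.from_csv(entry["curve"], entry["risk"])
            datasets[endpoint] = reconstruct_ipd(curve)
    else:
        raise ConfigError(f"unknown survival source {source!r}")
    return datasets


def fit_survival(
    config: dict, datasets: dict[str, SurvivalDataset]
) -> tuple[dict[str, list[ParametricFit]], dict[str, ParametricFit]]:
    """Fit the six families per endpoint and select by AIC (BIC tie-break)."""
    floor = float(config["settings"].get("gompertz_plateau_floor", 0.05))
    fits = {ep: fit_all_families(ds) for ep, ds in datasets.items()}
    selected = {
        ep: select_best(fs, gompertz_plateau_floor=floor)
        for ep, fs in fits.items()
    }
    return fits, selected


def make_evaluator(config: dict, fits: dict[str, ParametricFit]):
    """A closure mapping parameter overrides to a full two-arm model run.

    The survival fits stay fixed (curve uncertainty enters through the
    hazard-ratio parameters only); everything else is rebuilt from the
    overridden configuration.
    """

    def evaluate(overrides: dict[str, float]) -> CEAResult:
        cfg = apply_overrides(config, overrides) if overrides else config
        settings = build_settings(cfg)
        intervention, comparator = build_strategies(cfg, fits)
        return compare(
            run_trace(intervention, settings), run_trace(comparator, settings)
        )

    return evaluate


def _echo_assumptions(config: dict, log: list[str]) -> None:
    s = config["settings"]
    log.append(
        f"assumption: body weight {s['body_weight_kg']} kg for weight-based dosing"
    )
    log.append(
        f"assumption: horizon {s['horizon_cycles']} cycles of "
        f"{s['cycle_length_weeks']} weeks (lifetime operationalisation)"
    )
    log.append(
        "assumption: full follow-up panel per cycle while alive; "
        "administration bundle per on-treatment cycle"
    )
    caps = {
        arm: r.get("treatment_cap_cycles")
        for arm, r in config["regimens"].items()
    }
    log.append(f"assumption: treatment caps (cycles): {caps}")
    if config["survival"].get("source", "synthetic") == "synthetic":
        log.append(
            "survival inputs are SYNTHETIC cohorts calibrated to printed "
            "medians; sigma and the OS median are declared assumptions"
        )


def run_pipeline(
    config: dict,
    stages: set[str] | None = None,
    seed: int | None = None,
    outdir: str | Path | None = None,
    make_plots: bool = False,
) -> PipelineResult:
    """Execute the requested stages and (optionally) write all outputs."""
    stages = set(STAGES) if stages is None else set(stages)
    unknown = stages - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")

    log: list[str] = [f"psmcea {__version__}", f"seed: {seed}"]
    _echo_assumptions(config, log)

    datasets = load_survival_datasets(config, seed=seed)
    fits, selected = fit_survival(config, datasets)
    for ep in ENDPOINTS:
        log.append(
            f"{ep}: selected {selected[ep].family} "
            f"(AIC {selected[ep].aic:.1f}) from {len(fits[ep])} families"
        )

    result = PipelineResult(
        config=config, datasets=datasets, fits=fits, selected=selected, log=log
    )
    evaluate = make_evaluator(config, selected)

    settings = build_settings(config)
    intervention, comparator = build_strategies(config, selected)
    trace_i = run_trace(intervention, settings)
    trace_c = run_trace(comparator, settings)
    result.traces = {intervention.name: trace_i, comparator.name: trace_c}
    for tr in result.traces.values():
        log.extend(tr.warnings)
    if "base" in stages or "scenario" in stages:
        result.base = compare(trace_i, trace_c)
        icer = result.base.icer
        log.append(
            f"base case: dC={result.base.delta_cost:.0f} "
            f"dQ={result.base.delta_qaly:.3f} "
            + (f"ICER={icer:.0f}" if icer is not None else result.base.label)
        )

    if "scenario" in stages:
        scen_intervention, _ = build_strategies(config, selected, scenario=True)
        scen_trace = run_trace(scen_intervention, settings)
        result.scenario = compare(scen_trace, trace_c)
        result.traces[f"{intervention.name}_scenario"] = scen_trace

    specs = parameter_specs(config)
    if "dsa" in stages:
        result.dsa = one_way_dsa(specs, evaluate)

    if "psa" in stages:
        n_iter = int(config.get("psa", {}).get("n_iterations", 5000))
        s = config["settings"]
        wtp_grid = np.arange(
            0.0, float(s["wtp_grid_max"]) + 1, float(s["wtp_grid_step"])
        )
        psa_seed = (seed if seed is not None else 0) + 7919
        result.psa = run_psa(
            evaluate, specs, n_iterations=n_iter, seed=psa_seed, wtp_grid=wtp_grid
        )
        if result.psa.n_failures:
            log.append(f"psa: {result.psa.n_failures} failed iterations skipped")

    if outdir is not None:
        write_outputs(result, Path(outdir), make_plots=make_plots)
    return result


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def results_table(result: PipelineResult) -> pd.DataFrame:
    """Base-case (and scenario) per-strategy totals with the ICER."""
    frames = []
    if result.base is not None:
        df = result.base.to_frame()
        df.insert(0, "analysis", "base")
        frames.append(df)
    if result.scenario is not None:
        df = result.scenario.to_frame()
        df.insert(0, "analysis", "scenario")
        frames.append(df)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def write_outputs(
    result: PipelineResult, outdir: Path, make_plots: bool = False
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for ep, ds in result.datasets.items():
        ds.to_csv(outdir / f"ipd_{ep.lower()}.csv")
        fit_report(result.fits[ep]).to_csv(
            outdir / f"fit_report_{ep.lower()}.csv", index=False
        )
    table = results_table(result)
    if not table.empty:
        table.to_csv(outdir / "results.csv", index=False)
    for name, trace in result.traces.items():
        trace.to_frame().to_csv(outdir / f"trace_{name}.csv", index=False)
    if result.dsa is not None:
        result.dsa.to_csv(outdir / "dsa_tornado.csv", index=False)
    if result.psa is not None:
        result.psa.draws.to_csv(outdir / "psa_draws.csv", index_label="iteration")
        result.psa.ceac().to_csv(outdir / "ceac.csv", index=False)
        summary = {
            "n_iterations": result.psa.n_iterations,
            "crossover_wtp": result.psa.crossover_wtp(),
            "probability_cost_effective": {
                str(int(w)): result.psa.probability_cost_effective(w)
                for w in build_settings(result.config).wtp_thresholds
            },
        }
        (outdir / "psa_summary.json").write_text(json.dumps(summary, indent=2))
    (outdir / "run_log.txt").write_text("\n".join(result.log) + "\n")
    if make_plots:
        from . import plots

        if result.dsa is not None:
            plots.tornado(result.dsa, outdir / "tornado.png")
        if result.psa is not None:
            plots.ce_plane(
                result.psa,
                build_settings(result.config).wtp_thresholds,
                outdir / "ce_plane.png",
            )
            plots.ceac(result.psa, outdir / "ceac.png")
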