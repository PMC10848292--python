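"""End-to-end genotype assessment pipeline.

generate -> scale & filter -> close composition -> delivered cost ->
convert -> MFSP -> LCA -> summarize.  Each stage is the corresponding
module; this file only wires them together and handles I/O.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import analysis, conversion, lca, logistics, tea, yield_scaling
from .composition import close_mass_balance, fcmf, to_whole_biomass
from .synthetic_cohort import CohortConfig, GenotypeRecord, default_config, generate_cohort

log = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "results_for_records"]


@dataclass(frozen=True)
class PipelineResult:
    estimates: pd.DataFrame  # all genotypes with filter verdicts
    results: pd.DataFrame  # passed genotypes, one row of metrics each
    summary: analysis.CohortSummary
    impact_results: dict[str, lca.ImpactResult]


def results_for_records(
    records: Sequence[GenotypeRecord],
    sites,
    scaling: yield_scaling.ScalingFactors = yield_scaling.ScalingFactors(),
    cost_params: logistics.CostParams | None = None,
    conv_params: conversion.ConversionParams = conversion.ConversionParams(),
    economics: tea.EconomicAssumptions = tea.EconomicAssumptions(),
    factor_table: lca.ImpactFactorTable | None = None,
) -> PipelineResult:
    """Run every stage for a cohort of records."""
    cost_params = cost_params or logistics.default_cost_params()
    factor_table = factor_table or lca.load_default_table()
    per_mg_inputs = factor_table.biorefinery_per_mg()

    estimates = []
    rows = []
    impact_results: dict[str, lca.ImpactResult] = {}
    tally: dict[str, int] = {}
    for rec in records:
        est = yield_scaling.estimate_commercial_yield(rec, sites, scaling)
        estimates.append(est)
        tally[est.failure_reason.value] = tally.get(est.failure_reason.value, 0) + 1
        if not est.passed:
            continue
        closed = close_mass_balance(to_whole_biomass(rec.raw_composition))
        conv = conversion.convert(closed, conv_params, per_mg_inputs)
        cost = logistics.delivered_cost(est.commercial_yield, cost_params)
        mfsp = tea.solve_mfsp(economics, conv, cost.total)
        inventory = lca.assemble_inventory(
            est.commercial_yield,
            conv.process_yield,
            conv.excess_electricity,
            factor_table,
        )
        alloc = lca.allocation_fraction(
            conv_params.ethanol_lhv, conv.excess_electricity
        )
        impact = lca.characterize(inventory, factor_table, alloc)
        impact_results[rec.genotype_id] = impact
        rows.append(
            {
                "genotype_id": rec.genotype_id,
                "commercial_yield_Mg_ha": est.commercial_yield,
                "fcmf": fcmf(closed),
                "process_yield_L_Mg": conv.process_yield,
                "field_yield_L_ha": conversion.field_ethanol_yield(
                    conv.process_yield, est.commercial_yield
                ),
                "excess_kwh_L": conv.excess_electricity,
                "delivered_cost_usd_Mg": cost.total,
                "mfsp_usd_L": mfsp.mfsp,
                "mfsp_feedstock": mfsp.breakdown["feedstock"],
                "mfsp_capital": mfsp.breakdown["capital"],
                "mfsp_opex": mfsp.breakdown["opex"],
                "mfsp_coproduct_credit": mfsp.breakdown["coproduct_credit"],
                "gwp_g_L": impact.gwp,
                "ced_MJ_L": impact.ced,
                "aware_m3_L": impact.aware,
            }
        )
    est_frame = pd.DataFrame(
        {
            "genotype_id": [e.genotype_id for e in estimates],
            "commercial_yield_Mg_ha": [e.commercial_yield for e in estimates],
            "passed": [e.passed for e in estimates],
            "failure_reason": [e.failure_reason.value for e in estimates],
        }
    )
    results = pd.DataFrame(rows)
    log.info("filter tally: %s", tally)
    summary = analysis.summarize_cohort(results, tally)
    return PipelineResult(est_frame, results, summary, impact_results)


def run_pipeline(
    config: CohortConfig | None = None,
    seed: int | None = None,
    outdir: str | Path | None = None,
    **stage_kwargs,
) -> PipelineResult:
    """Generate the (default) cohort and run all stages.

    ``seed`` overrides the config seed.  When ``outdir`` is given, the
    estimates/results CSVs and a JSON summary are written there.
    """
    config = config or default_config()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    records = generate_cohort(config)
    out = results_for_records(records, config.sites, **stage_kwargs)
    if outdir is not None:
        write_outputs(out, outdir)
    return out


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.estimates.to_csv(outdir / "estimates.csv", index=False)
    result.results.to_csv(outdir / "results.csv", index=False)
    summary = {
        "n": result.summary.n,
        "filter_tally": dict(result.summary.filter_tally),
        "metrics": json.loads(result.summary.metrics.to_json(orient="index")),
        "regressions": [dataclasses.asdict(r) for r in result.summary.regressions],
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
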