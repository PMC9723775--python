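"""End-to-end orchestration: simulate -> quantify -> priming -> SIP ->
indicator analysis -> qPCR -> report.

Every stochastic stage draws its generator from the single global seed via
``numpy.random.default_rng([stage_index, seed])``, so a fixed seed yields
byte-identical report bundles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import gcms, indval, priming, qpcr, sip
from .io import write_config, write_feature_table, write_tsv
from .simulate import (
    GeneratorConfig,
    default_microcosm_config,
    simulate_gradient,
    simulate_microcosm,
    simulate_qpcr,
)

log = logging.getLogger("isoprime")

ALL_STAGES = ("simulate", "flux", "priming", "sip", "indval", "qpcr")

#: keys the JSON summary must carry for each enabled stage
REPORT_SCHEMA = {
    "meta": ("seed", "stages", "parameters"),
    "flux": ("n_measurements",),
    "priming": ("per_treatment",),
    "sip": ("n_enriched", "enriched_phylotypes"),
    "indval": ("n_significant",),
    "qpcr": ("per_sample",),
}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Run configuration for the full synthetic-analysis chain."""

    outdir: str | Path = "isoprime_out"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    generator: GeneratorConfig | None = None
    heavy_window: tuple = sip.DEFAULT_HEAVY_WINDOW
    fold_threshold: float = sip.DEFAULT_FOLD_THRESHOLD
    pseudocount: float = sip.DEFAULT_PSEUDOCOUNT
    rarefaction_depth: int = sip.DEFAULT_RAREFACTION_DEPTH
    n_permutations: int = 999
    detection_limit: float = qpcr.DEFAULT_DETECTION_LIMIT
    control_treatment: str = "water"
    log_level: str = "INFO"

    def resolved_generator(self) -> GeneratorConfig:
        cfg = self.generator or default_microcosm_config(self.seed)
        return replace(cfg, seed=self.seed)


def _stage_rng(stage: str, seed: int) -> np.random.Generator:
    return np.random.default_rng([ALL_STAGES.index(stage), seed])


def validate_report(summary: dict) -> None:
    """Check the JSON summary against the bundled stage-key schema."""
    for stage in summary.get("meta", {}).get("stages", ()):
        if stage not in summary and stage in REPORT_SCHEMA:
            raise PipelineError(f"summary missing stage key: {stage}")
    for stage, keys in REPORT_SCHEMA.items():
        if stage in summary:
            missing = [k for k in keys if k not in summary[stage]]
            if missing:
                raise PipelineError(f"summary[{stage!r}] missing keys: {missing}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order and write the report.

    Returns the machine-readable summary dict (also written to
    ``<outdir>/summary.json``).  A stage failure raises with the stage
    name; outputs of completed stages remain on disk.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = tuple(s for s in ALL_STAGES if s in config.stages)
    gen = config.resolved_generator()
    summary: dict = {
        "meta": {
            "seed": config.seed,
            "stages": list(stages),
            "parameters": {
                "heavy_window": list(config.heavy_window),
                "fold_threshold": config.fold_threshold,
                "pseudocount": config.pseudocount,
                "rarefaction_depth": config.rarefaction_depth,
                "n_permutations": config.n_permutations,
                "detection_limit": config.detection_limit,
            },
        }
    }
    state: dict = {}

    for stage in stages:
        try:
            _STAGE_FUNCS[stage](config, gen, state, summary, outdir)
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    write_report(summary, outdir)
    return summary


def write_report(summary: dict, outdir) -> Path:
    """Validate and write the machine-readable JSON summary.

    Stage TSV tables are written by the stages themselves; this emits the
    schema-checked `summary.json` at full numeric precision and returns its
    path.
    """
    if not any(k in summary for k in REPORT_SCHEMA if k != "meta"):
        raise PipelineError("no stage results to report")
    validate_report(summary)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "summary.json"
    path.write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_json_default)
    )
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (np.ndarray,)):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(config, gen, state, summary, outdir):
    rng = _stage_rng("simulate", config.seed)
    readings, truth = simulate_microcosm(gen, rng=rng)
    table, gtruth = simulate_gradient(gen, rng=rng)
    state.update(readings=readings, truth=truth, table=table, gtruth=gtruth)
    write_tsv(readings, outdir / "headspace.tsv")
    write_feature_table(table, outdir / "feature_table.tsv",
                        outdir / "sample_sheet.tsv")
    write_tsv(truth.summary, outdir / "truth_microcosm.tsv")
    write_tsv(gtruth.taxa.reset_index(), outdir / "truth_gradient.tsv")
    write_config(gen, outdir / "generator_config.yaml")
    summary["simulate"] = {
        "n_vials": int(readings["vial_id"].nunique()),
        "n_libraries": int(len(table.libraries)),
        "truth": {
            "cum_primed_c": {
                t: float(g["cum_primed_c"].iloc[0])
                for t, g in truth.summary.groupby("treatment")
            },
            "n_labeled_taxa": int(gtruth.taxa["labeled"].sum()),
        },
    }


def _stage_flux(config, gen, state, summary, outdir):
    if "readings" not in state:
        raise PipelineError("flux stage requires simulate outputs")
    geom = gen.geometry
    cal = gcms.CalibrationCurve.identity(44), gcms.CalibrationCurve.identity(45)
    measured = gcms.quantify_table(state["readings"], cal[0], cal[1], geom)
    state["measurements"] = measured
    write_tsv(measured, outdir / "measurements.tsv")
    summary["flux"] = {
        "n_measurements": int(len(measured)),
        "n_clipped": int(measured["clipped"].sum()),
    }


def _stage_priming(config, gen, state, summary, outdir):
    measured = state["measurements"]
    ctrl_name = config.control_treatment
    controls = measured.loc[measured["treatment"] == ctrl_name]
    if controls.empty:
        raise PipelineError(f"no control treatment {ctrl_name!r}")
    f_nat = priming.natural_abundance_baseline(controls, strata=("ecoplot",))
    per_treatment = {}
    frames = []
    doses = {t.name: (t.dose_c, t.substrate_atom_fraction_13c, t.labeled)
             for t in gen.treatments}
    # controls receive no labeled substrate: all respired C is SOC-derived
    control_part = controls.copy()
    control_part["total_c"] = control_part["umol12_per_g"] + control_part["umol13_per_g"]
    control_part["c_soc"] = control_part["total_c"]
    control_part["c_sub"] = 0.0
    cum_ctrl = priming.accumulate_series(control_part)
    for name, (dose, f_sub, labeled) in doses.items():
        if name == ctrl_name or not labeled:
            continue
        sub = measured.loc[measured["treatment"] == name]
        part = priming.partition_table(sub, f_sub=f_sub, f_nat=f_nat,
                                       strata=("ecoplot",))
        cum = priming.accumulate_series(part)
        frames.append(cum)
        series = priming.primed_soc(part, control_part, treatment=name)
        per_vial = cum.groupby("vial_id").tail(1)
        recovery = [
            priming.substrate_recovery(v, dose)[0]
            for v in per_vial["cum_c_sub"]
        ]
        per_treatment[name] = {
            "cumulative_primed_c": series.cumulative_primed_c,
            "percent_priming": series.percent_priming,
            "substrate_recovery_pct_mean": float(np.mean(recovery)),
            "significant_timepoints": int(series.per_time["significant"].sum()),
        }
        write_tsv(series.per_time, outdir / f"priming_{name}.tsv")
    # Tukey HSD on per-vial cumulative SOC-derived C across all arms
    groups = {}
    for name in doses:
        source = cum_ctrl if name == ctrl_name else \
            next((f for f in frames if (f["treatment"] == name).any()), None)
        if source is None:
            continue
        vals = source.loc[source["treatment"] == name].groupby("vial_id")[
            "cum_c_soc"].last()
        if len(vals) >= 2:
            groups[name] = vals.to_numpy()
    comparison = None
    if len(groups) >= 2:
        comparison = priming.compare_treatments(groups)
        per_treatment["_tukey_letters"] = comparison.letters
    if frames:
        write_tsv(pd.concat(frames, ignore_index=True), outdir / "partitions.tsv")
    state["priming"] = per_treatment
    summary["priming"] = {"per_treatment": per_treatment,
                          "f_nat": {str(k): float(v) for k, v in f_nat.items()}}


def _stage_sip(config, gen, state, summary, outdir):
    table = state["table"]
    filtered, ledger = sip.filter_phylotypes(table)
    fc = sip.heavy_window_fold_change(
        filtered, window=config.heavy_window, pseudocount=config.pseudocount,
        fold_threshold=config.fold_threshold,
    )
    rng = _stage_rng("sip", config.seed)
    depth = min(config.rarefaction_depth,
                int(filtered.library_totals().min()))
    rare, dropped = sip.rarefy(filtered, depth=depth, rng=rng)
    div = sip.diversity_metrics(rare)
    share = sip.taxon_group_share(
        filtered, ["Paraburkholderia", "Caballeronia"])
    enriched = fc.index[fc["enriched"]].tolist()
    state["sip_fc"] = fc
    state["sip_filtered"] = filtered
    write_tsv(fc.reset_index(), outdir / "enrichment.tsv")
    write_tsv(div.reset_index(), outdir / "diversity.tsv")
    write_tsv(ledger, outdir / "filter_ledger.tsv")
    truth_block = {}
    if "gtruth" in state:
        labeled = set(state["gtruth"].taxa.index[state["gtruth"].taxa["labeled"]])
        called = set(enriched)
        truth_block = {
            "true_labeled": len(labeled),
            "true_positives": len(called & labeled),
            "false_positives": len(called - labeled),
        }
    summary["sip"] = {
        "n_enriched": len(enriched),
        "enriched_phylotypes": enriched,
        "n_filtered_out": int(len(ledger)),
        "rarefaction_depth_used": int(depth),
        "degrader_share_13c_range": [
            float(share[table.samples.loc[share.index, "isotope"] == "13C"].min()),
            float(share[table.samples.loc[share.index, "isotope"] == "13C"].max()),
        ],
        "truth": truth_block,
    }


def _stage_indval(config, gen, state, summary, outdir):
    filtered = state.get("sip_filtered", state["table"])
    heavy = sip.select_heavy_window(filtered.samples, config.heavy_window)
    sub = filtered.subset_libraries(heavy)
    groups = sub.samples["isotope"]
    rng_seed = int(_stage_rng("indval", config.seed).integers(0, 2**31 - 1))
    res = indval.indval_permutation_test(
        sub, groups, n_permutations=config.n_permutations, seed=rng_seed)
    res = res.sort_values(["p_value", "indval"], ascending=[True, False])
    write_tsv(res.reset_index(), outdir / "indicators.tsv")
    summary["indval"] = {
        "n_significant": int((res["p_value"] < 0.05).sum()),
        "n_significant_bh": int((res["q_value"] < 0.05).sum()),
        "n_permutations": int(res["n_permutations"].iloc[0]),
        "seed": rng_seed,
    }


def _stage_qpcr(config, gen, state, summary, outdir):
    rng = _stage_rng("qpcr", config.seed)
    # transcript truth mirrors the flux dynamics: pobA is abundant while the
    # substrate is being respired (day 1) and falls below detection once the
    # amendment is exhausted (day 7); 16S is a stable reference
    rows = []
    for trt in gen.treatments:
        active = trt.dose_c > 0
        for rep in range(1, gen.n_replicates + 1):
            sid = f"{trt.name}.r{rep}"
            rows.append({"sample_id": f"{sid}.d1", "target": "pobA",
                         "copies": 5e4 if active else 50.0})
            rows.append({"sample_id": f"{sid}.d1", "target": "16S",
                         "copies": 2.5e6})
            rows.append({"sample_id": f"{sid}.d7", "target": "pobA",
                         "copies": 50.0})
            rows.append({"sample_id": f"{sid}.d7", "target": "16S",
                         "copies": 2.5e6})
    true_copies = pd.DataFrame(rows)
    plate = simulate_qpcr(gen, true_copies, rng=rng)
    quantified, curves = qpcr.quantify_plate(plate, config.detection_limit)
    poba = quantified.loc[quantified["target"] == "pobA"]
    ref = quantified.loc[quantified["target"] == "16S"]
    expr = qpcr.relative_expression(poba, ref)
    write_tsv(plate, outdir / "qpcr_plate.tsv")
    write_tsv(expr, outdir / "expression.tsv")
    summary["qpcr"] = {
        "per_sample": {
            r["sample_id"]: (None if r["censored"] else float(r["ratio"]))
            for _, r in expr.iterrows()
        },
        "efficiency": {t: float(c.efficiency) for t, c in curves.items()},
        "n_censored": int(expr["censored"].sum()),
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "flux": _stage_flux,
    "priming": _stage_priming,
    "sip": _stage_sip,
    "indval": _stage_indval,
    "qpcr": _stage_qpcr,
}
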