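"""End-to-end orchestration: simulate -> normalize -> calibrate -> bridge ->
estimate -> rank -> composition -> survival.

Each stage derives its own seed deterministically from the single global
seed (hash of stage name + seed), so stages are individually reproducible.
A JSON manifest records the stages run, their seeds, and a SHA-256 hash of
every output file; two runs with the same configuration produce identical
manifests apart from the timestamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import bridge as bridge_mod
from . import composition as comp_mod
from . import io as io_mod
from . import survival as surv_mod
from . import targets as targets_mod
from .flow import fit_standard_curve, summarize_flow_sample
from .preprocess import (
    DSBNormalizer,
    ProfileQuantileNormalizer,
    clr_normalize,
    qc_filter_cells,
)
from .synthetic import SyntheticConfig, derive_seed, generate_cohort, generate_expression

logger = logging.getLogger(__name__)

__all__ = [
    "STAGES",
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "prepare_bridging_inputs",
]

STAGES: tuple[str, ...] = (
    "simulate",
    "qc",
    "normalize",
    "flowquant",
    "bridge",
    "estimate",
    "rank",
    "composition",
    "survival",
)

_DEPENDENCIES = {
    "qc": ("simulate",),
    "normalize": ("qc",),
    "flowquant": ("simulate",),
    "bridge": ("normalize", "flowquant"),
    "estimate": ("bridge",),
    "rank": ("estimate",),
    "composition": ("simulate",),
    "survival": ("composition",),
}

#: Number of genes in the synthetic stemness gene set used for the LSC gate.
_N_STEM_GENES = 17


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Configuration for an end-to-end run on a synthetic cohort."""

    outdir: str = "citequant_run"
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    stages: tuple[str, ...] = STAGES
    positivity_min: float = 0.8
    count_min: float = 1000.0
    quantile_grid: tuple[float, ...] = bridge_mod.DEFAULT_QUANTILE_GRID
    pseudocount: float = 10.0
    lsc_params: targets_mod.LscGateParams = field(default_factory=targets_mod.LscGateParams)
    bootstrap_n: int = 344
    bootstrap_reps: int = 50
    cv_repeats: int = 10

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        synth = SyntheticConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("synthetic", {}).items()
        })
        lsc = targets_mod.LscGateParams(**raw.pop("lsc_params", {}))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "quantile_grid" in raw:
            raw["quantile_grid"] = tuple(raw["quantile_grid"])
        return cls(synthetic=synth, lsc_params=lsc, **raw)

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [convert(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return convert(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, through: Optional[str] = None) -> dict:
    """Run the configured stages in order and return the manifest.

    ``through`` truncates the stage list at the named stage.  A stage whose
    prerequisite is not scheduled raises :class:`PipelineError`.
    """
    stages = list(config.stages)
    if through is not None:
        if through not in STAGES:
            raise PipelineError(f"unknown stage {through!r}")
        stages = [s for s in stages if STAGES.index(s) <= STAGES.index(through)]
    for stage in stages:
        missing = [d for d in _DEPENDENCIES.get(stage, ()) if d not in stages]
        if missing:
            raise PipelineError(
                f"stage {stage!r} requires {missing} which are not scheduled; "
                "enable them or drop the dependent stage"
            )

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = {stage: derive_seed(config.seed, stage) for stage in stages}
    outputs: list[Path] = []
    state: dict = {}

    for stage in stages:
        t0 = time.monotonic()
        handler = _STAGE_HANDLERS[stage]
        handler(config, seeds[stage], outdir, state, outputs)
        logger.info("stage %-11s done in %.1fs", stage, time.monotonic() - t0)

    manifest = {
        "package": "citequant",
        "stages": stages,
        "seeds": seeds,
        "config": config.to_dict(),
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(outputs))
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    io_mod.write_json(manifest, outdir / "manifest.json")
    return manifest


def prepare_bridging_inputs(cohort, grid=bridge_mod.DEFAULT_QUANTILE_GRID):
    """QC-filter, normalize (DSB + cell-profile quantile), bead-calibrate
    and quantile-map a synthetic cohort; returns everything the bridging
    model consumes.

    Returns a dict with ``maps`` (QuantileMap list), ``qc`` (per-sample QC
    metric Series), ``normalized`` (per-sample normalized ADT matrices) and
    ``flow_mean_abc`` (per (sample, antigen) flow-measured mean ABC).
    """
    curves = {
        batch: fit_standard_curve(beads)
        for batch, beads in cohort.bead_standards.items()
    }
    maps, qc, normalized, flow_mean = [], {}, {}, {}
    for sample in cohort.samples:
        adt = qc_filter_cells(sample.adt)
        dsb = DSBNormalizer(isotype_controls=adt.isotype_controls)
        dsb.fit(adt.counts, background=adt.background)
        values = dsb.transform(adt.counts)[adt.antigens]
        matrix = ProfileQuantileNormalizer().fit(values).transform(values)
        normalized[sample.sample_id] = matrix
        qc[sample.sample_id] = sample.adt.qc_metrics
        curve = curves[sample.timepoint]
        for antigen in cohort.config.bridge_antigens:
            abc = np.asarray(curve.abc(sample.flow[antigen].gated("blast")))
            flow_mean[(sample.sample_id, antigen)] = float(abc.mean())
            maps.append(
                bridge_mod.build_quantile_map(
                    abc, matrix[antigen].to_numpy(), grid,
                    sample_id=sample.sample_id, antigen=antigen,
                )
            )
    return {
        "maps": maps,
        "qc": qc,
        "normalized": normalized,
        "flow_mean_abc": flow_mean,
        "curves": curves,
    }


# ---------------------------------------------------------------------------
# stage handlers


def _stage_simulate(config, seed, outdir, state, outputs):
    synth = dataclasses.replace(config.synthetic, seed=seed)
    cohort = generate_cohort(synth)
    state["cohort"] = cohort
    sample_dir = outdir / "samples"
    for sample in cohort.samples:
        written = io_mod.write_adt_sample(sample.adt, sample_dir / sample.sample_id)
        outputs.extend(written)
        truth_path = sample_dir / sample.sample_id / "truth_abc.csv"
        sample.truth_abc.to_csv(truth_path, index_label="barcode")
        outputs.append(truth_path)
        labels_path = sample_dir / sample.sample_id / "lineage_labels.csv"
        pd.DataFrame(
            {"barcode": sample.adt.counts.index, "state": sample.lineage_labels}
        ).to_csv(labels_path, index=False)
        outputs.append(labels_path)
        outputs.append(
            io_mod.write_flow_csv(
                sample.flow.values(), sample_dir / sample.sample_id / "flow_events.csv"
            )
        )
    for batch, beads in cohort.bead_standards.items():
        outputs.append(io_mod.write_bead_csv(beads, outdir / f"beads_{batch}.csv"))
    surv_path = outdir / "survival_records.csv"
    cohort.survival.to_csv(surv_path)
    outputs.append(surv_path)
    logger.info("simulate: %d samples x %d cells", len(cohort.samples),
                synth.n_cells_per_sample)


def _stage_qc(config, seed, outdir, state, outputs):
    cohort = state["cohort"]
    filtered = {}
    for sample in cohort.samples:
        kept = qc_filter_cells(sample.adt)
        filtered[sample.sample_id] = kept
        logger.info("qc: %s %d -> %d cells", sample.sample_id,
                    sample.adt.n_cells, kept.n_cells)
    state["filtered"] = filtered


def _stage_normalize(config, seed, outdir, state, outputs):
    cohort = state["cohort"]
    normalized = {}
    clr = {}
    norm_dir = outdir / "normalized"
    norm_dir.mkdir(exist_ok=True)
    for sample_id, adt in state["filtered"].items():
        if adt.n_cells == 0:
            raise PipelineError(f"{sample_id}: no cells left after QC filtering")
        dsb = DSBNormalizer(isotype_controls=adt.isotype_controls)
        dsb.fit(adt.counts, background=adt.background)
        dsb_values = dsb.transform(adt.counts)[adt.antigens]
        qn = ProfileQuantileNormalizer().fit(dsb_values)
        normalized[sample_id] = qn.transform(dsb_values)
        clr[sample_id] = clr_normalize(adt.counts)
        path = norm_dir / f"{sample_id}.csv"
        normalized[sample_id].to_csv(path, index_label="barcode")
        outputs.append(path)
    state["normalized"] = normalized
    state["clr"] = clr
    recipe = outdir / "normalization_recipe.json"
    io_mod.write_json(
        {
            "steps": ["dsb(background=empty_droplets, isotype technical factor)",
                      "cell-profile quantile normalization (antigen columns)"],
            "log": "ln(x+1)",
        },
        recipe,
    )
    outputs.append(recipe)


def _stage_flowquant(config, seed, outdir, state, outputs):
    cohort = state["cohort"]
    curves = {
        batch: fit_standard_curve(beads)
        for batch, beads in cohort.bead_standards.items()
    }
    rows = []
    flow_abc: dict[tuple[str, str], np.ndarray] = {}
    flow_mean: dict[tuple[str, str], float] = {}
    for sample in cohort.samples:
        curve = curves[sample.timepoint]
        for antigen, fs in sample.flow.items():
            rows.append(summarize_flow_sample(fs, curve))
            abc = np.asarray(curve.abc(fs.gated("blast")))
            flow_abc[(sample.sample_id, antigen)] = abc
            flow_mean[(sample.sample_id, antigen)] = float(abc.mean())
    table = pd.DataFrame(rows)
    path = outdir / "flow_quant.csv"
    table.to_csv(path, index=False)
    outputs.append(path)
    state["curves"] = curves
    state["flow_abc"] = flow_abc
    state["flow_mean_abc"] = flow_mean


def _stage_bridge(config, seed, outdir, state, outputs):
    cohort = state["cohort"]
    maps = []
    for sample in cohort.samples:
        matrix = state["normalized"][sample.sample_id]
        for antigen in cohort.config.bridge_antigens:
            abc = state["flow_abc"][(sample.sample_id, antigen)]
            maps.append(
                bridge_mod.build_quantile_map(
                    abc, matrix[antigen].to_numpy(), config.quantile_grid,
                    sample_id=sample.sample_id, antigen=antigen,
                )
            )
    qc = {s.sample_id: s.adt.qc_metrics for s in cohort.samples}
    table = bridge_mod.build_training_table(maps, qc)
    table_path = outdir / "training_table.csv"
    table.to_csv(table_path, index=False)
    outputs.append(table_path)
    model = bridge_mod.train_model(table, seed=seed, cv_repeats=config.cv_repeats)
    model_path = outdir / "bridge_model.pkl"
    bridge_mod.save_model(model, model_path)
    outputs.append(model_path)
    maps_path = outdir / "quantile_maps.csv"
    pd.DataFrame(
        [
            {
                "sample_id": qm.sample_id,
                "antigen": qm.antigen,
                "level": lv,
                "adt_quantile": aq,
                "abc_log10_quantile": bq,
            }
            for qm in maps
            for lv, aq, bq in zip(qm.levels, qm.adt_quantiles, qm.abc_log10_quantiles)
        ]
    ).to_csv(maps_path, index=False)
    outputs.append(maps_path)
    state["maps"] = maps
    state["qc_metrics"] = qc
    state["model"] = model
    logger.info("bridge: %d training rows, CV RMSE %.3f +/- %.3f",
                len(table), model.cv_rmse_mean_, model.cv_rmse_sd_)


def _stage_estimate(config, seed, outdir, state, outputs):
    cohort = state["cohort"]
    est_dir = outdir / "estimates"
    est_dir.mkdir(exist_ok=True)
    estimates = {}
    for sample in cohort.samples:
        matrix = state["normalized"][sample.sample_id]
        est = bridge_mod.predict_cell_abc(
            state["model"], matrix, sample.adt.qc_metrics
        )
        estimates[sample.sample_id] = est
        path = est_dir / f"{sample.sample_id}.csv"
        est.to_csv(path, index_label="barcode", float_format="%.4f")
        outputs.append(path)
    state["estimates"] = estimates


def _stage_rank(config, seed, outdir, state, outputs):
    cohort = state["cohort"]
    rng_seed = seed
    summaries_blast, summaries_lsc = [], []
    coexpr_rows = []
    bridge_pair = cohort.config.bridge_antigens[:2]
    for sample in cohort.samples:
        est = state["estimates"][sample.sample_id]
        clr = state["clr"][sample.sample_id]
        # blast population = all QC-passing cells
        for antigen in est.columns:
            summaries_blast.append(
                targets_mod.positivity_and_intensity(
                    est, antigen, config.count_min,
                    sample_id=sample.sample_id, population="blast",
                    timepoint=sample.timepoint,
                )
            )
        coexpr_rows.append(
            {
                "sample_id": sample.sample_id,
                "antigen_a": bridge_pair[0],
                "antigen_b": bridge_pair[1],
                "threshold": config.count_min,
                "fraction_dual_positive": targets_mod.co_expression_fraction(
                    est, bridge_pair[0], bridge_pair[1], config.count_min
                ),
            }
        )
        # LSC-enriched population via stemness module score + CD34/CD38 CLR
        if {"CD34", "CD38"} <= set(clr.columns):
            expr = generate_expression(est.shape[0], seed=rng_seed)
            expr.index = est.index
            gene_set = list(expr.columns[:_N_STEM_GENES])
            scores = targets_mod.module_score(expr, gene_set, seed=rng_seed)
            mask = targets_mod.lsc_gate(
                scores.to_numpy(),
                clr.loc[est.index, "CD34"].to_numpy(),
                clr.loc[est.index, "CD38"].to_numpy(),
                config.lsc_params,
            )
            if mask.any():
                lsc_est = est.loc[mask]
                for antigen in lsc_est.columns:
                    summaries_lsc.append(
                        targets_mod.positivity_and_intensity(
                            lsc_est, antigen, config.count_min,
                            sample_id=sample.sample_id, population="lsc",
                            timepoint=sample.timepoint,
                        )
                    )
    for name, summaries in (("blast", summaries_blast), ("lsc", summaries_lsc)):
        if not summaries:
            continue
        ranked = targets_mod.rank_targets(
            summaries, config.positivity_min, config.count_min
        )
        path = outdir / f"ranking_{name}.csv"
        ranked.to_csv(path, index=False)
        outputs.append(path)
    coexpr_path = outdir / "co_expression.csv"
    pd.DataFrame(coexpr_rows).to_csv(coexpr_path, index=False)
    outputs.append(coexpr_path)
    state["ranking"] = summaries_blast


def _stage_composition(config, seed, outdir, state, outputs):
    cohort = state["cohort"]
    rows = []
    for pair in cohort.pairs:
        dist = comp_mod.aitchison_distance(
            pair.diagnosis, pair.relapse, config.pseudocount
        )
        rows.append(
            {
                "patient_id": pair.patient_id,
                "shannon_diagnosis": comp_mod.shannon_index(pair.diagnosis),
                "shannon_relapse": comp_mod.shannon_index(pair.relapse),
                "aitchison_distance": dist,
            }
        )
    metrics = pd.DataFrame(rows).set_index("patient_id")
    path = outdir / "composition_metrics.csv"
    metrics.to_csv(path)
    outputs.append(path)
    boot = comp_mod.fixed_size_bootstrap(
        cohort.pairs, n=config.bootstrap_n, reps=config.bootstrap_reps,
        seed=seed, pseudocount=config.pseudocount,
    )
    boot_path = outdir / "bootstrap_distances.csv"
    boot.to_csv(boot_path, index=False)
    outputs.append(boot_path)
    state["composition_metrics"] = metrics


def _stage_survival(config, seed, outdir, state, outputs):
    cohort = state["cohort"]
    metrics = state["composition_metrics"]
    df = cohort.survival.join(metrics["aitchison_distance"]).rename(
        columns={"aitchison_distance": "distance"}
    )
    logrank = surv_mod.mean_split_logrank(df)
    rows = [
        {
            "analysis": "mean_split_logrank",
            "statistic": logrank["statistic"],
            "p_value": logrank["p_value"],
            "n_high": logrank["n_high"],
            "n_low": logrank["n_low"],
        }
    ]
    # tiny or degenerate cohorts can defeat the partial-likelihood fit;
    # record the failure instead of aborting the whole run
    try:
        cox = surv_mod.cox_fit(df)
        rows.append(
            {
                "analysis": "cox_distance_sex",
                "statistic": cox["hazard_ratio"],
                "p_value": cox["p_value"],
                "ci_lower": cox["ci_lower"],
                "ci_upper": cox["ci_upper"],
            }
        )
    except Exception as exc:  # noqa: BLE001 - diagnostic, not control flow
        logger.warning("survival: Cox fit failed (%s)", exc)
        cox = None
        rows.append(
            {"analysis": "cox_distance_sex", "note": f"fit failed: {exc}"}
        )
    summary_path = outdir / "survival_summary.csv"
    pd.DataFrame(rows).to_csv(summary_path, index=False)
    outputs.append(summary_path)
    km_path = outdir / "km_curves.csv"
    pd.concat(
        [c.assign(group=name) for name, c in logrank["km_curves"].items()],
        ignore_index=True,
    ).to_csv(km_path, index=False)
    outputs.append(km_path)
    state["logrank"] = logrank
    state["cox"] = cox


_STAGE_HANDLERS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "normalize": _stage_normalize,
    "flowquant": _stage_flowquant,
    "bridge": _stage_bridge,
    "estimate": _stage_estimate,
    "rank": _stage_rank,
    "composition": _stage_composition,
    "survival": _stage_survival,
}
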