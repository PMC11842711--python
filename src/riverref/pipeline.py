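"""End-to-end driver: simulate → prep → human-effect → fit → enrich →
classify → summarise.

Each stage reads its inputs from, and writes its outputs to, a single run
directory, so the stages can be run one at a time from the CLI or chained
with :func:`run_pipeline`.  All randomness derives from the config seed,
making a re-run with identical settings byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from . import concentration_models as cm
from . import human_effect as he
from . import periphyton_class as pc
from . import reference_enrichment as re_
from . import sample_prep as sp
from . import synthetic_catchments as sc
from .config import PipelineConfig
from .io import read_catchments, read_discharge, read_samples, write_table

log = logging.getLogger(__name__)

STAGES = (
    "simulate", "prep", "human_effect", "fit",
    "enrich", "classify", "summarise",
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def derive_seed(seed: int, *tags: int) -> int:
    """Deterministic child seed (< 2**31) for a pipeline stage."""
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, *tags])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _truth(cfg: PipelineConfig) -> sc.TruthParams:
    return sc.TruthParams(
        human_effect_slope=cfg.human_effect_slope,
        noise_sd_log=cfg.noise_sd_log,
        baseflow_index=cfg.baseflow_index,
        storm_frequency=cfg.storm_frequency,
        seed=cfg.seed,
    )


def _grid(cfg: PipelineConfig) -> cm.TuningGrid:
    return cm.TuningGrid(
        n_estimators=cfg.grid_trees,
        max_features=cfg.grid_max_features,
        min_samples_leaf=cfg.grid_min_leaf,
        cv_folds=cfg.cv_folds,
    )


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    truth = _truth(cfg)
    catchments = sc.generate_catchments(
        cfg.n_catchments, truth, mdc_fraction=cfg.mdc_fraction
    )
    discharge_parts, sample_parts, truth_rows = [], [], []
    for _, catchment in catchments.iterrows():
        d = sc.generate_discharge(catchment, cfg.n_days, truth)
        d.insert(0, "site_id", catchment["id"])
        discharge_parts.append(d)
        for analyte in cfg.analytes:
            s = sc.generate_samples(
                catchment, d, truth, analyte,
                samples_per_month=cfg.samples_per_month,
            )
            sample_parts.append(s)
            truth_rows.append(
                {
                    "id": catchment["id"],
                    "analyte": analyte,
                    "true_median": s.attrs["true_median"],
                }
            )
    paths = {
        "catchments": write_table(catchments, outdir / "catchments.csv"),
        "discharge": write_table(
            pd.concat(discharge_parts, ignore_index=True), outdir / "discharge.csv"
        ),
        "samples": write_table(
            pd.concat(sample_parts, ignore_index=True), outdir / "samples.csv"
        ),
        "true_medians": write_table(
            pd.DataFrame(truth_rows), outdir / "true_medians.csv"
        ),
    }
    return {k: str(v) for k, v in paths.items()}


def stage_prep(cfg: PipelineConfig, outdir: Path) -> dict:
    catchments = read_catchments(outdir / "catchments.csv")
    discharge = read_discharge(outdir / "discharge.csv")
    samples = read_samples(outdir / "samples.csv")

    filtered_parts = []
    for site, site_q in discharge.groupby("site_id", sort=True):
        sep = sp.separate_baseflow(
            site_q.reset_index(drop=True), cfg.filter_alpha, cfg.filter_passes
        )
        site_samples = samples.loc[samples["site_id"] == site]
        if site_samples.empty:
            continue
        filtered_parts.append(
            sp.filter_stormflow_samples(site_samples, sep, cfg.storm_threshold)
        )
    filtered = pd.concat(filtered_parts, ignore_index=True)
    lat = catchments.set_index("id")["latitude"]
    medians = sp.site_medians(filtered, lat, cfg.tropic_latitude)
    paths = {
        "filtered_samples": write_table(filtered, outdir / "filtered_samples.csv"),
        "medians": write_table(medians, outdir / "medians.csv"),
    }
    return {
        **{k: str(v) for k, v in paths.items()},
        "n_samples_in": len(samples),
        "n_samples_retained": len(filtered),
    }


def stage_human_effect(cfg: PipelineConfig, outdir: Path) -> dict:
    catchments = read_catchments(outdir / "catchments.csv")
    medians = pd.read_csv(outdir / "medians.csv")
    components = he.transform_components(catchments)
    ref_components = he.transform_components(re_.reference_inputs(catchments))

    weights_out: dict[str, dict] = {}
    he_rows = []
    for analyte in cfg.analytes:
        if cfg.weights_source == "published":
            weights = he.published_weights(analyte)
        else:
            med = medians.loc[medians["analyte"] == analyte].set_index("site_id")
            idx = catchments["id"].isin(med.index)
            X = components.loc[idx.to_numpy()]
            y = np.log(
                med.loc[catchments.loc[idx.to_numpy(), "id"], "median_conc"]
            ).to_numpy()
            weights = he.fit_first_pls_component(X, y, analyte=analyte)
        weights_out[analyte] = {
            "coefficients": {k: float(v) for k, v in weights.coefficients.items()},
            "correlation_with_response": weights.correlation_with_response,
            "source": weights.source,
        }
        he_rows.append(
            pd.DataFrame(
                {
                    "id": catchments["id"],
                    "analyte": analyte,
                    "human_effect": he.apply_weights(weights, components),
                    "human_effect_reference": he.apply_weights(
                        weights, ref_components
                    ),
                }
            )
        )
    (outdir / "weights.json").write_text(json.dumps(weights_out, indent=1))
    path = write_table(pd.concat(he_rows, ignore_index=True), outdir / "human_effect.csv")
    return {"weights": str(outdir / "weights.json"), "human_effect": str(path)}


def _modeling_table(
    catchments: pd.DataFrame,
    medians: pd.DataFrame,
    human: pd.DataFrame,
    analyte: str,
) -> pd.DataFrame:
    med = medians.loc[medians["analyte"] == analyte, ["site_id", "median_conc", "n_obs"]]
    hum = human.loc[human["analyte"] == analyte, ["id", "human_effect", "human_effect_reference"]]
    table = (
        catchments.merge(med.rename(columns={"site_id": "id"}), on="id", how="inner")
        .merge(hum, on="id", how="left")
    )
    table["ln_median"] = np.log(table["median_conc"])
    return table


def stage_fit(cfg: PipelineConfig, outdir: Path) -> dict:
    catchments = read_catchments(outdir / "catchments.csv")
    medians = pd.read_csv(outdir / "medians.csv")
    human = pd.read_csv(outdir / "human_effect.csv")
    grid = _grid(cfg)

    info = {}
    for k, analyte in enumerate(cfg.analytes):
        table = _modeling_table(catchments, medians, human, analyte)
        seed = derive_seed(cfg.seed, 10, k)
        train, test = cm.split_train_test(table, cfg.train_frac, seed)
        levels = tuple(sorted(catchments["biome"].unique()))
        candidates = cm.backward_eliminate(
            train, list(cfg.predictors), grid, seed=seed, biome_levels=levels
        )
        bundle = cm.select_model(
            candidates, test, rel_tol=cfg.select_rel_tol,
            analyte=analyte, seed=seed, train=train,
        )
        table = table.assign(split=np.where(table["id"].isin(train["id"]), "train", "test"))
        write_table(table, outdir / f"modeling_{analyte}.csv")
        joblib.dump(bundle, outdir / f"model_{analyte}.joblib")
        info[analyte] = bundle.summary()
        info[analyte]["n_candidates"] = len(candidates)
    (outdir / "models.json").write_text(json.dumps(info, indent=1))
    return {"models": str(outdir / "models.json")}


def _percentile_ci(draws: np.ndarray, point: np.ndarray, level: float) -> pd.DataFrame:
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(draws, alpha, axis=0)
    upper = np.quantile(draws, 1.0 - alpha, axis=0)
    return pd.DataFrame(
        {
            "lower": np.minimum(lower, point),
            "point": point,
            "upper": np.maximum(upper, point),
        }
    )


def stage_enrich(cfg: PipelineConfig, outdir: Path) -> dict:
    catchments = read_catchments(outdir / "catchments.csv")
    medians = pd.read_csv(outdir / "medians.csv")
    human = pd.read_csv(outdir / "human_effect.csv")

    enrich_parts, mdc_parts = [], []
    for k, analyte in enumerate(cfg.analytes):
        bundle = joblib.load(outdir / f"model_{analyte}.joblib")
        table = pd.read_csv(outdir / f"modeling_{analyte}.csv")
        train = table.loc[table["split"] == "train"]

        hum = human.loc[human["analyte"] == analyte].set_index("id")
        current = catchments.copy()
        current["human_effect"] = hum.loc[current["id"], "human_effect"].to_numpy()
        reference = re_.reference_inputs(catchments)
        reference["human_effect"] = hum.loc[
            reference["id"], "human_effect_reference"
        ].to_numpy()

        draws = cm.bootstrap_predictions(
            bundle, train, [current, reference],
            reps=cfg.bootstrap_reps, seed=derive_seed(cfg.seed, 20, k),
        )
        cur_ci = _percentile_ci(
            np.exp(draws[0]), np.exp(bundle.predict(current)), cfg.ci_level
        )
        ref_ci = _percentile_ci(
            np.exp(draws[1]), np.exp(bundle.predict(reference)), cfg.ci_level
        )
        enrich_parts.append(
            re_.enrichment_table(catchments["id"], analyte, cur_ci, ref_ci)
        )
        ref_preds = ref_ci.assign(id=catchments["id"].to_numpy())
        obs = medians.loc[medians["analyte"] == analyte]
        report = re_.mdc_validation(
            ref_preds, catchments, obs,
            olsen_max=cfg.mdc_olsen_max, pop_max=cfg.mdc_pop_max,
            natural_min=cfg.mdc_natural_min,
        )
        report.insert(0, "analyte", analyte)
        mdc_parts.append(report)

    paths = {
        "enrichment": write_table(
            pd.concat(enrich_parts, ignore_index=True), outdir / "enrichment.csv"
        ),
        "mdc_validation": write_table(
            pd.concat(mdc_parts, ignore_index=True), outdir / "mdc_validation.csv"
        ),
    }
    return {k: str(v) for k, v in paths.items()}


def stage_classify(cfg: PipelineConfig, outdir: Path) -> dict:
    catchments = read_catchments(outdir / "catchments.csv")
    enrichment = pd.read_csv(outdir / "enrichment.csv")
    th = pc.Thresholds(
        tn_threshold=cfg.tn_threshold, tp_threshold=cfg.tp_threshold,
        np_low=cfg.np_low, np_high=cfg.np_high,
    )
    wide = enrichment.pivot(index="id", columns="analyte",
                            values=["current", "reference"])
    wide = wide.loc[catchments["id"]]
    parts = []
    for scenario in ("current", "reference"):
        parts.append(
            pc.class_table(
                catchments,
                wide[(scenario, "TN")].to_numpy(),
                wide[(scenario, "TP")].to_numpy(),
                scenario,
                th,
            )
        )
    path = write_table(pd.concat(parts, ignore_index=True), outdir / "classes.csv")
    return {"classes": str(path)}


def stage_summarise(cfg: PipelineConfig, outdir: Path) -> dict:
    catchments = read_catchments(outdir / "catchments.csv")
    enrichment = pd.read_csv(outdir / "enrichment.csv")
    classes = pd.read_csv(outdir / "classes.csv")

    summary = pd.concat(
        [
            re_.summarise(enrichment, catchments, "continent"),
            re_.summarise(enrichment, catchments, "world"),
        ],
        ignore_index=True,
    )
    shares = pc.aggregate(catchments, classes)
    paths = {
        "enrichment_summary": write_table(summary, outdir / "enrichment_summary.csv"),
        "periphyton_shares": write_table(shares, outdir / "periphyton_shares.csv"),
    }
    return {k: str(v) for k, v in paths.items()}


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "prep": stage_prep,
    "human_effect": stage_human_effect,
    "fit": stage_fit,
    "enrich": stage_enrich,
    "classify": stage_classify,
    "summarise": stage_summarise,
}


def run_stage(name: str, cfg: PipelineConfig, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        return _STAGE_FUNCS[name](cfg, outdir)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(name, exc) from exc


def run_pipeline(cfg: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run every stage; returns (and writes) the run manifest.

    On a stage failure the partial manifest is still written, and a
    :class:`StageError` naming the stage is raised.
    """
    outdir = Path(outdir if outdir is not None else cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "outdir": str(outdir), "stages": {}}
    try:
        for name in STAGES:
            t0 = time.monotonic()
            log.info("stage %s ...", name)
            manifest["stages"][name] = run_stage(name, cfg, outdir)
            manifest["stages"][name]["elapsed_s"] = round(time.monotonic() - t0, 2)
    except StageError:
        manifest["failed_stage"] = name
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
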