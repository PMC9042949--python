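"""End-to-end orchestration: landmarks -> superimposition -> scores ->
reliability -> colour decision -> standardisation -> path-model fits ->
summaries, plots and a run report.

A pipeline run is driven by a plain config mapping (or YAML file) that
either names input files or requests a simulation preset. Every stage is
logged; any stage failure aborts with a stage-named diagnostic and leaves a
``failed_<stage>`` marker next to any partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import landmarks as lio
from . import measures, shape_scores
from .diagnostics import vif_table
from .pathmodel import (
    PathModelSpec, PosteriorDraws, build_model, fit, standardize, summarize,
)
from .plots import forest_and_density_plots
from .procrustes import gpa
from .simulate import (
    PRESET_SAMPLE_SIZES, preset_truth, simulate_study, write_study,
)

__all__ = ["PipelineRun", "run_pipeline", "load_config"]

log = logging.getLogger(__name__)


@dataclass
class PipelineRun:
    """Record of one pipeline execution."""

    config: dict
    seed: int
    input_manifest: dict[str, str] = field(default_factory=dict)
    stage_log: list[str] = field(default_factory=list)
    output_paths: dict[str, str] = field(default_factory=dict)
    icc: dict[str, float] = field(default_factory=dict)
    colour_mode: str = "channels"
    analysis_table: pd.DataFrame | None = None
    fits: dict[str, PosteriorDraws] = field(default_factory=dict)
    summaries: dict[str, pd.DataFrame] = field(default_factory=dict)
    vif: pd.Series | None = None


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage(run: PipelineRun, name: str, out_dir: Path | None):
    """Context manager logging a stage and marking failures."""
    class _Ctx:
        def __enter__(self):
            run.stage_log.append(f"stage {name}: start")
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                run.stage_log.append(f"stage {name}: FAILED ({exc})")
                if out_dir is not None:
                    out_dir.mkdir(parents=True, exist_ok=True)
                    (out_dir / f"failed_{name}").write_text(str(exc) + "\n")
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") \
                    from exc
            run.stage_log.append(f"stage {name}: ok")
    return _Ctx()


def run_pipeline(config: dict | str | Path,
                 out_dir: str | Path | None = None) -> PipelineRun:
    """Execute the full analysis described by ``config``.

    Config keys (all optional unless noted):

    * ``simulate``: {preset, n_per_sex, seed} — generate the study; or
    * ``inputs``: {tps, scheme, specimens, ratings_sextypicality,
      ratings_dominance} — read it from files (one of the two required);
    * ``focal_sex``: which sex carries the analysed ratings;
    * ``slide``: slide semi-landmarks during superimposition (default true);
    * ``colour``: 'auto' (parallel-analysis decision), 'channels', 'factor';
    * ``variants``: list of model variants to fit (default ['default']);
    * ``n_draws``, ``chains``, ``seed``: sampling configuration;
    * ``plots``: write forest/density figures (default true when out_dir).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out_path = Path(out_dir) if out_dir is not None else None
    seed = int(config.get("seed", 0))
    run = PipelineRun(config=json.loads(json.dumps(config, default=str)),
                      seed=seed)

    # --- inputs -----------------------------------------------------------
    with _stage(run, "inputs", out_path):
        if "simulate" in config:
            sim = config["simulate"]
            preset = sim.get("preset", "custom")
            truth = preset_truth(preset, seed=int(sim.get("seed", seed)))
            n_per_sex = int(sim.get("n_per_sex",
                                    PRESET_SAMPLE_SIZES.get(preset, 50)))
            study = simulate_study(truth, n_per_sex)
            if out_path is not None:
                paths = write_study(study, out_path / "study")
                run.input_manifest = {k: _hash_file(p)
                                      for k, p in paths.items()}
                run.output_paths.update(
                    {f"study_{k}": str(p) for k, p in paths.items()})
            configs, scheme = study.configs, study.scheme
            specimens = study.specimens
            ratings_st = study.ratings_sextypicality
            ratings_do = study.ratings_dominance
            focal_sex = config.get("focal_sex", truth.focal_sex)
        elif "inputs" in config:
            files = {k: Path(v) for k, v in config["inputs"].items()}
            run.input_manifest = {k: _hash_file(p) for k, p in files.items()}
            configs = lio.read_tps(files["tps"])
            scheme = lio.read_scheme(files["scheme"])
            specimens = lio.read_specimen_table(files["specimens"])
            ratings_st = lio.read_ratings(files["ratings_sextypicality"])
            ratings_do = lio.read_ratings(files["ratings_dominance"])
            focal_sex = config.get("focal_sex", "female")
        else:
            raise ValueError("config needs either 'simulate' or 'inputs'")

    # --- superimposition --------------------------------------------------
    with _stage(run, "gpa", out_path):
        slide = bool(config.get("slide", True))
        aligned = gpa(configs, scheme=scheme, slide=slide)
        run.stage_log.append(
            f"gpa: {aligned.n_specimens} specimens, "
            f"{aligned.iterations} iterations, converged={aligned.converged}, "
            f"slide={slide}")

    # --- shape scores -----------------------------------------------------
    with _stage(run, "scores", out_path):
        id_order = [c.specimen_id for c in configs]
        spec_df = specimens.set_index("id").loc[id_order].reset_index()
        sex = spec_df["sex"].to_numpy()
        sshd = shape_scores.sshd_scores(aligned, sex)
        dist = shape_scores.distinctiveness(aligned)
        spec_df["sshd"] = sshd
        spec_df["dist"] = dist

    # --- reliability and rating aggregation --------------------------------
    with _stage(run, "reliability", out_path):
        run.icc["sextypicality"] = measures.icc_3k(ratings_st)
        run.icc["dominance"] = measures.icc_3k(ratings_do)
        mean_st = measures.mean_ratings(ratings_st)
        mean_do = measures.mean_ratings(ratings_do)
        spec_df["perceived_sextypicality"] = \
            mean_st.reindex(spec_df["id"]).to_numpy()
        spec_df["perceived_dominance"] = \
            mean_do.reindex(spec_df["id"]).to_numpy()

    # --- anthropometrics ---------------------------------------------------
    with _stage(run, "anthro", out_path):
        width = measures.repeatability_gate(spec_df["width1"].to_numpy(),
                                            spec_df["width2"].to_numpy())
        height_px = measures.repeatability_gate(spec_df["height1"].to_numpy(),
                                                spec_df["height2"].to_numpy())
        spec_df["fwhr"] = measures.fwhr(width, height_px)
        if "bmi" not in spec_df.columns:
            spec_df["bmi"] = measures.bmi(spec_df["weight"].to_numpy(),
                                          spec_df["height"].to_numpy())

    # --- focal subset and shape-trait scores -------------------------------
    with _stage(run, "shape_traits", out_path):
        focal_idx = np.flatnonzero(sex == focal_sex)
        focal = spec_df.iloc[focal_idx].reset_index(drop=True)
        focal["shape_sextypicality"] = shape_scores.shape_trait_scores(
            aligned, focal["perceived_sextypicality"].to_numpy(),
            indices=focal_idx)
        focal["shape_dominance"] = shape_scores.shape_trait_scores(
            aligned, focal["perceived_dominance"].to_numpy(),
            indices=focal_idx)

    # --- colour decision ----------------------------------------------------
    with _stage(run, "colour", out_path):
        mode = config.get("colour", "auto")
        chan = focal[["L", "a", "b"]].to_numpy()
        if mode == "auto":
            mode = ("factor" if measures.use_colour_factor(chan, seed=seed)
                    else "channels")
        if mode == "factor":
            loadings, scores, r2 = measures.extract_colour_factor(chan)
            focal["colour"] = scores
            run.stage_log.append(
                "colour: single-factor mode, loadings="
                + np.array2string(loadings, precision=3)
                + ", r2=" + np.array2string(r2, precision=3))
        run.colour_mode = mode

    # --- standardisation ----------------------------------------------------
    with _stage(run, "standardize", out_path):
        variables = ["age", "bmi", "fwhr", "sshd", "dist",
                     "perceived_sextypicality", "perceived_dominance",
                     "shape_sextypicality", "shape_dominance"]
        variables += (["colour"] if run.colour_mode == "factor"
                      else ["L", "a", "b"])
        analysis, _ = standardize(focal, variables)
        run.analysis_table = analysis

    # --- model fits ---------------------------------------------------------
    with _stage(run, "fit", out_path):
        variants = config.get("variants", ["default"])
        n_draws = int(config.get("n_draws", 2000))
        chains = int(config.get("chains", 2))
        prior_keys = ("prior_intercept_sd", "prior_slope_sd", "lkj_eta",
                      "sd_rate")
        priors = {k: float(config[k]) for k in prior_keys if k in config}
        for variant in variants:
            spec = PathModelSpec(variant=variant, colour_mode=run.colour_mode,
                                 n_draws=n_draws, **priors)
            manifest = build_model(spec)
            draws = fit(manifest, analysis, seed=seed, chains=chains)
            run.fits[variant] = draws
            run.summaries[variant] = summarize(draws)

    # --- diagnostics --------------------------------------------------------
    with _stage(run, "vif", out_path):
        ext = PathModelSpec(variant="extended", colour_mode=run.colour_mode)
        predictors = [m for m in ext.mediators if m in analysis.columns]
        run.vif = vif_table(analysis[predictors])

    # --- outputs ------------------------------------------------------------
    if out_path is not None:
        with _stage(run, "report", out_path):
            out_path.mkdir(parents=True, exist_ok=True)
            (out_path / "config.json").write_text(
                json.dumps(run.config, indent=1) + "\n")
            analysis.to_csv(out_path / "analysis_table.csv", index=False)
            run.output_paths["analysis_table"] = str(
                out_path / "analysis_table.csv")
            for variant, draws in run.fits.items():
                draws.to_frame().to_csv(out_path / f"draws_{variant}.csv",
                                        index=False)
                run.summaries[variant].to_csv(
                    out_path / f"summary_{variant}.csv")
                draws.diagnostics_frame().to_csv(
                    out_path / f"diagnostics_{variant}.csv", index=False)
                if config.get("plots", True):
                    figs = forest_and_density_plots(
                        run.summaries[variant], draws, out_path / "figures",
                        prefix=variant)
                    run.output_paths.update(
                        {f"{variant}_{k}": str(p) for k, p in figs.items()})
            report = [
                f"seed: {seed}",
                f"inputs: {run.input_manifest}",
                f"icc3k: { {k: round(v, 4) for k, v in run.icc.items()} }",
                f"colour mode: {run.colour_mode}",
                f"vif: { {k: round(v, 3) for k, v in run.vif.items()} }",
                "stages:",
            ] + [f"  {line}" for line in run.stage_log]
            (out_path / "run_report.txt").write_text("\n".join(report) + "\n")
            run.output_paths["report"] = str(out_path / "run_report.txt")
    return run
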