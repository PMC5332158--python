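"""Shared plumbing: config parsing, table I/O, pipeline orchestration.

The run configuration is a flat-sectioned YAML file (``mortality``,
``growth``, ``phenotype``, ``imaging``, ``simulate``, ``fit``, ``report``
plus a top-level ``master_seed``).  Unknown keys are hard errors so typos
cannot silently fall back to defaults, and every section validates its
type invariants before any computation runs.

``run_pipeline`` chains the four stages (simulate, quantify, fit, report),
writing versioned CSV/JSON outputs plus a manifest listing every file with
its SHA-256 hash, the seed, and the cohort sizes.  Re-running with the
same config and seed reproduces identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, quantify, simulate, survival
from .simulate import (GrowthParams, ImagingParams, MortalityModel,
                       PhenotypeProbs)

__all__ = [
    "RunConfig",
    "ConfigError",
    "DataError",
    "load_config",
    "save_config",
    "run_pipeline",
    "write_lifespans",
    "read_lifespans",
    "write_trajectories",
    "read_stack",
    "write_stack",
]

log = logging.getLogger("replispan")

STAGES = ("simulate", "quantify", "fit", "report")


class ConfigError(ValueError):
    pass


class DataError(RuntimeError):
    pass


_DEFAULTS = {
    "master_seed": 0,
    "mortality": {"kind": "exponential", "alpha": 0.02, "beta": 0.0},
    "growth": {f.name: f.default for f in dataclasses.fields(GrowthParams)},
    "phenotype": {
        "p_short_death": 0.72,
        "p_elongated_death": 0.28,
        "sibling_fate_probs": [0.66, 0.14, 0.20],
        "defect_class_probs": [0.9256, 0.0085, 0.0330, 0.0329],
        "defect_class_probs_dying": [0.6028, 0.1134, 0.1419, 0.1419],
    },
    "imaging": {
        "pixel_size": 0.2,
        "frame_shape": [64, 384],
        "rotation_deg": 0.0,
        "max_jitter": 0,
        "noise_sd": 0.0,
        "psf_sigma": 1.0,
        "channel_center_row": 32,
        "notch_col": 24,
    },
    "simulate": {"n_cells": 200, "render_stacks": 0},
    "fit": {"model": "auto", "n_boot": 1000, "weighting": "inverse_survival"},
    "report": {"k_max": 5, "age_bins": None, "contour_resolution": 80},
}


@dataclasses.dataclass
class RunConfig:
    master_seed: int
    mortality: MortalityModel
    growth: GrowthParams
    phenotype: PhenotypeProbs
    imaging: ImagingParams
    n_cells: int
    render_stacks: int
    fit_model: str
    n_boot: int
    weighting: str
    k_max: int
    age_bins: list | None
    contour_resolution: int
    raw: dict = dataclasses.field(default_factory=dict, repr=False)


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = {}
    for key, default in defaults.items():
        if isinstance(default, dict):
            out[key] = _merge(default, user.get(key, {}) or {},
                              f"{path}{key}.")
        else:
            out[key] = user.get(key, default)
    unknown = set(user) - set(defaults)
    if unknown:
        raise ConfigError(
            f"unknown config key(s): {sorted(path + k for k in unknown)}")
    return out


def _build(config: dict) -> RunConfig:
    def section(name, cls, **coerce):
        params = dict(config[name])
        for key, fn in coerce.items():
            params[key] = fn(params[key])
        try:
            return cls(**params)
        except (ValueError, TypeError) as err:
            raise ConfigError(f"invalid [{name}] section: {err}") from err

    mortality = section("mortality", MortalityModel)
    growth = section("growth", GrowthParams)
    phenotype = section("phenotype", PhenotypeProbs,
                        sibling_fate_probs=tuple,
                        defect_class_probs=tuple,
                        defect_class_probs_dying=tuple)
    imaging = section("imaging", ImagingParams, frame_shape=tuple)
    if config["fit"]["model"] not in ("auto", "exponential", "gompertz"):
        raise ConfigError("fit.model must be auto|exponential|gompertz")
    if config["simulate"]["n_cells"] < 1:
        raise ConfigError("simulate.n_cells must be >= 1")
    return RunConfig(
        master_seed=int(config["master_seed"]),
        mortality=mortality, growth=growth, phenotype=phenotype,
        imaging=imaging,
        n_cells=int(config["simulate"]["n_cells"]),
        render_stacks=int(config["simulate"]["render_stacks"]),
        fit_model=config["fit"]["model"],
        n_boot=int(config["fit"]["n_boot"]),
        weighting=config["fit"]["weighting"],
        k_max=int(config["report"]["k_max"]),
        age_bins=config["report"]["age_bins"],
        contour_resolution=int(config["report"]["contour_resolution"]),
        raw=config,
    )


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML run config; missing keys take defaults."""
    user: dict = {}
    if path is not None:
        text = Path(path).read_text()
        user = yaml.safe_load(text) or {}
        if not isinstance(user, dict):
            raise ConfigError("config file must contain a YAML mapping")
    if overrides:
        user = {**user, **overrides}
    return _build(_merge(_DEFAULTS, user))


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.raw, sort_keys=False))


# --------------------------------------------------------------------------
# table and image I/O (plain CSV, multi-frame grayscale TIFF)
# --------------------------------------------------------------------------

def write_lifespans(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_lifespans(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(simulate.LIFESPAN_COLUMNS[:3]) - set(table.columns)
    if missing:
        raise DataError(f"lifespan table missing columns: {sorted(missing)}")
    return table


def write_trajectories(trajectories, path) -> None:
    """Long-format CSV: one row per (cell, time point); lengths in um."""
    frames = [
        pd.DataFrame({"cell_id": traj.cell_id, "time_h": traj.times,
                      "length_um": traj.lengths})
        for traj in trajectories
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_stack(stack: simulate.KymographStack, path) -> None:
    import tifffile

    tifffile.imwrite(path, stack.frames.astype(np.float32))
    sidecar = Path(path).with_suffix(".truth.csv")
    truth = stack.truth or {}
    shifts = truth.get("shifts", np.zeros((len(stack.timestamps), 2), int))
    pd.DataFrame({
        "time_h": stack.timestamps,
        "shift_row": shifts[:, 0],
        "shift_col": shifts[:, 1],
    }).to_csv(sidecar, index=False)


def read_stack(path) -> simulate.KymographStack:
    import tifffile

    frames = tifffile.imread(path)
    sidecar = Path(path).with_suffix(".truth.csv")
    truth = None
    if sidecar.exists():
        df = pd.read_csv(sidecar)
        timestamps = df["time_h"].to_numpy()
        truth = {"shifts": df[["shift_row", "shift_col"]].to_numpy()}
    else:
        timestamps = np.arange(frames.shape[0], dtype=float)
    return simulate.KymographStack(frames=frames.astype(np.float32),
                                   timestamps=timestamps, truth=truth)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(stage_dir: Path, stage: str, seed: int, extra: dict) -> None:
    files = sorted(p for p in stage_dir.iterdir()
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "stage": stage,
        "seed": seed,
        "outputs": {p.name: _sha256(p) for p in files},
        **extra,
    }
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def run_pipeline(config: RunConfig, stages, out_dir) -> Path:
    """Run the requested stages in order, writing one directory per stage.

    ``quantify`` needs stacks from ``simulate`` (render_stacks > 0);
    ``fit`` needs a lifespan table; ``report`` needs lifespans and
    trajectories.  Missing upstream artifacts raise :class:`DataError`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ConfigError(f"unknown stage(s): {bad}")
    stages = [s for s in STAGES if s in stages]
    seed = config.master_seed

    if "simulate" in stages:
        stage_dir = out / "simulate"
        stage_dir.mkdir(exist_ok=True)
        table, trajectories = simulate.simulate_cohort(
            config.mortality, config.growth, config.phenotype,
            config.n_cells, seed)
        write_lifespans(table, stage_dir / "lifespans.csv")
        write_trajectories(trajectories, stage_dir / "trajectories.csv")
        pd.DataFrame([
            {"cell_id": t.cell_id, "generation": i + 1,
             "division_time_h": dt, "division_length_um": dl}
            for t in trajectories
            for i, (dt, dl) in enumerate(zip(t.division_times,
                                             t.division_lengths))
        ]).to_csv(stage_dir / "divisions_truth.csv", index=False)
        n_stacks = min(config.render_stacks, len(trajectories))
        for i in range(n_stacks):
            stack = simulate.render_kymograph_stack(
                trajectories[i], config.imaging, seed + 1000 + i)
            write_stack(stack, stage_dir / f"stack_{i:04d}.tif")
        log.info("simulate: n=%d cells, %d stacks, seed=%d",
                 config.n_cells, n_stacks, seed)
        _write_manifest(stage_dir, "simulate", seed,
                        {"n_cells": config.n_cells, "n_stacks": n_stacks})

    if "quantify" in stages:
        stage_dir = out / "quantify"
        stage_dir.mkdir(exist_ok=True)
        stack_paths = sorted((out / "simulate").glob("stack_*.tif"))
        if not stack_paths:
            raise DataError("quantify: no image stacks found "
                            "(run simulate with render_stacks > 0)")
        im = config.imaging
        trace_rows, div_rows, life_rows = [], [], []
        for path in stack_paths:
            stack = read_stack(path)
            trace, divisions = quantify.quantify_stack(
                stack, im.pixel_size, im.notch_col, im.channel_center_row,
                rotation_deg=im.rotation_deg)
            cell_id = path.stem
            if trace.ejection_suspected:
                log.warning("quantify: %s excluded (reason=ejection t=%.2f h)",
                            cell_id, trace.ejection_time)
                life_rows.append({"cell_id": cell_id, "generations_at_death": 0,
                                  "status": "ejected"})
                continue
            trace_rows.append(pd.DataFrame({
                "cell_id": cell_id, "time_h": trace.times,
                "length_um": trace.lengths}))
            for g, (t, l) in enumerate(zip(divisions.division_times,
                                           divisions.division_lengths), 1):
                div_rows.append({"cell_id": cell_id, "generation": g,
                                 "division_time_h": t,
                                 "division_length_um": l})
            life_rows.append({"cell_id": cell_id,
                              "generations_at_death": divisions.generation_count,
                              "status": "died"})
        pd.concat(trace_rows, ignore_index=True).to_csv(
            stage_dir / "traces.csv", index=False)
        pd.DataFrame(div_rows).to_csv(stage_dir / "divisions.csv", index=False)
        life = pd.DataFrame(life_rows)
        for col in ("terminal_phenotype", "sibling_fate", "defect_class"):
            life[col] = "none"
        write_lifespans(life, stage_dir / "lifespans_quantified.csv")
        _write_manifest(stage_dir, "quantify", seed,
                        {"n_stacks": len(stack_paths)})

    if "fit" in stages:
        stage_dir = out / "fit"
        stage_dir.mkdir(exist_ok=True)
        lifespan_path = out / "simulate" / "lifespans.csv"
        if not lifespan_path.exists():
            raise DataError("fit: no lifespan table found (run simulate first)")
        table = read_lifespans(lifespan_path)
        curve = survival.km_estimate(table)
        if config.fit_model == "auto":
            fit = survival.select_model(curve, config.weighting)
        else:
            fit = survival.fit_survival(curve, config.fit_model,
                                        config.weighting)
        fit = survival.attach_bootstrap(fit, table, config.n_boot, seed + 7)
        haz = survival.empirical_hazard(curve)
        pd.DataFrame({"generation": curve.generations,
                      "survival": curve.survival,
                      "at_risk": curve.at_risk}).to_csv(
            stage_dir / "survival.csv", index=False)
        pd.DataFrame({"generation": haz.generations,
                      "hazard": haz.hazard}).to_csv(
            stage_dir / "hazard.csv", index=False)
        (stage_dir / "fit.json").write_text(json.dumps({
            "model": fit.model.kind,
            "alpha": fit.model.alpha,
            "beta": fit.model.effective_beta,
            "adjusted_r2": fit.adjusted_r2,
            "rls": fit.rls,
            "rls_ci": list(fit.rls_ci),
            "alpha_ci": list(fit.coef_cis["alpha"]),
            "beta_ci": list(fit.coef_cis["beta"]),
            "n_cells": fit.n_cells,
            "weighting": fit.weighting,
        }, indent=2))
        from . import plots
        plots.survival_plot(curve, fit, stage_dir / "survival.png")
        plots.hazard_plot(haz, fit, stage_dir / "hazard.png")
        log.info("fit: model=%s alpha=%.4f rls=%.1f", fit.model.kind,
                 fit.model.alpha, fit.rls)
        _write_manifest(stage_dir, "fit", seed,
                        {"n_cells": int(fit.n_cells)})

    if "report" in stages:
        stage_dir = out / "report"
        stage_dir.mkdir(exist_ok=True)
        lifespan_path = out / "simulate" / "lifespans.csv"
        if not lifespan_path.exists():
            raise DataError("report: no lifespan table found")
        table = read_lifespans(lifespan_path)
        curve = survival.km_estimate(table)
        fit_exp = survival.fit_survival(curve, "exponential", config.weighting)
        try:
            fit_gom = survival.fit_survival(curve, "gompertz", config.weighting)
            fit_gom = survival.attach_bootstrap(fit_gom, table,
                                                max(100, config.n_boot // 2),
                                                seed + 11)
            verdict = analysis.classify_aging(fit_exp, fit_gom)
        except survival.FitError:
            verdict = {"verdict": "non_aging",
                       "note": "Gompertz fit failed; exponential retained"}
        (stage_dir / "aging_verdict.json").write_text(
            json.dumps(verdict, indent=2, default=float))

        # death-aligned distributions need per-generation truth
        _, records = simulate.sample_cell_records(
            config.mortality, config.growth, config.n_cells, seed)
        dists = analysis.post_synchronize_to_death(records, config.k_max)
        analysis.ks_generation_comparison(dists).to_csv(
            stage_dir / "ks_comparisons.csv", index=False)

        fates = analysis.sibling_fate_by_age(
            table, config.age_bins, n_boot=min(config.n_boot, 500),
            seed=seed + 13)
        pd.DataFrame([
            {"age_bin": str(b), "fate": f, "proportion": p,
             "bootstrap_sd": fates["bootstrap_sd"][b][f]}
            for b, fp in fates["proportions"].items() for f, p in fp.items()
        ]).to_csv(stage_dir / "sibling_fates.csv", index=False)

        grid = analysis.rls_contour_grid(
            (0.001, 0.2), (0.0, 0.5), config.contour_resolution)
        pd.DataFrame(grid.rls_matrix, index=grid.alpha_values,
                     columns=grid.beta_values).to_csv(
            stage_dir / "rls_contours.csv")
        from . import plots
        plots.contour_plot(grid, stage_dir / "rls_contours.png")
        plots.ring_chart(table, stage_dir / "defect_rings.png")
        _write_manifest(stage_dir, "report", seed, {})

    return out
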