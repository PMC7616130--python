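"""End-to-end orchestration.

Generates (or ingests) a multi-condition cohort, runs the four analysis
stages (arbor morphometry, growth-cone densitometry, AFM mechanics,
kymograph transport), applies the statistics layer to the study's fixed
readouts, and writes per-stage CSVs, statistics tables with significance
tiers, minimal summary plots and a replayable run manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthgen, arbor, fluorquant, afm, kymo, stats

__all__ = ["validate_config", "run_pipeline", "arbor_stage_trial"]

_DEFAULTS = {
    "conditions": ["control", "treated"],
    "n_per_condition": 5,
    "seed": 0,
    "curves_per_cell": 10,
    "stages": ["arbor", "image", "afm", "kymo"],
    "turn_threshold_deg": 270.0,
    "simple_threshold": 1.4,
    "nu": 0.5,
    "hertz_window": [0.05, 0.20],
    "linewidth_px": 20,
    "fps": 2.0,
    "height_threshold_m": 150e-9,
    "mask_method": "threshold",
    "arbor_params": {},
    "image_params": {},
    "force_params": {},
    "granule_params": {},
    "effects": {},
    "plots": True,
}

_METRICS = {
    "arbor": ["ACI", "N1", "N2", "N3", "mean_primary_length_um", "total_length_um"],
    "image": ["density", "area_um2"],
    "afm": ["E_apparent_Pa"],
    "kymo": ["density_per_um", "mean_frame_disp_um"],
}


class ConfigError(ValueError):
    pass


def validate_config(config: dict | str | Path) -> dict:
    """Fill defaults and reject unknown or invalid keys.

    Accepts a dict or a path to a YAML/JSON file; returns a normalised
    config dict.  Errors name the offending key.
    """
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        config = yaml.safe_load(text) or {}
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(config) - set(_DEFAULTS)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    merged = {**_DEFAULTS, **config}
    if merged["n_per_condition"] < 1:
        raise ConfigError("n_per_condition: must be >= 1")
    if len(set(merged["conditions"])) != len(merged["conditions"]):
        raise ConfigError("conditions: labels must be unique")
    lo, hi = merged["hertz_window"]
    if not (0 <= lo < hi <= 1):
        raise ConfigError("hertz_window: need 0 <= lo < hi <= 1")
    if merged["simple_threshold"] <= 1:
        raise ConfigError("simple_threshold: must exceed 1")
    for block, cls in (("arbor_params", synthgen.ArborParams),
                       ("image_params", synthgen.GrowthConeImageParams),
                       ("force_params", synthgen.ForceCurveParams),
                       ("granule_params", synthgen.GranuleMovieParams)):
        fields = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore
        bad = set(merged[block]) - fields
        if bad:
            raise ConfigError(f"{block}: unknown fields {sorted(bad)}")
    return merged


def _cohort_config(cfg: dict) -> synthgen.CohortConfig:
    def build(cls, block):
        kw = {k: (tuple(v) if isinstance(v, list) else v)
              for k, v in cfg[block].items()}
        return cls(**kw)
    gran = dict(cfg["granule_params"])
    gran.setdefault("fps", cfg["fps"])
    return synthgen.CohortConfig(
        conditions=tuple(cfg["conditions"]),
        n_per_condition=cfg["n_per_condition"],
        seed=cfg["seed"],
        arbor=build(synthgen.ArborParams, "arbor_params"),
        image=build(synthgen.GrowthConeImageParams, "image_params"),
        force=build(synthgen.ForceCurveParams, "force_params"),
        granule=synthgen.GranuleMovieParams(**gran),
        curves_per_cell=cfg["curves_per_cell"],
        effects=cfg["effects"],
    )


def run_pipeline(config: dict | str | Path, out_dir: str | Path,
                 synthetic: bool = True, input_dir: str | Path | None = None,
                 overwrite: bool = False) -> Path:
    """Run the full pipeline; returns the report directory.

    With ``synthetic`` a cohort is generated under ``<out>/cohort`` from the
    config seed; otherwise ``input_dir`` must point at an existing cohort
    with the generator's layout.  Each stage is re-runnable from its
    on-disk inputs alone; a failing stage aborts with a stage-scoped error.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg["stages"]

    if synthetic:
        cohort_dir = out / "cohort"
        synthgen.generate_cohort(_cohort_config(cfg), cohort_dir,
                                 overwrite=overwrite, stages=tuple(stages))
    else:
        if input_dir is None:
            raise ConfigError("input_dir required when synthetic=False")
        cohort_dir = Path(input_dir)

    tables: dict[str, pd.DataFrame] = {}
    stat_tables = []

    def run_stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    if "arbor" in stages:
        def _arbor():
            df = arbor.analyze_swc_dir(
                cohort_dir, turn_threshold_deg=cfg["turn_threshold_deg"],
                simple_threshold=cfg["simple_threshold"])
            df["condition"] = df["axon_id"].str.rsplit("_", n=1).str[0]
            return df
        tables["arbor"] = run_stage("arbor", _arbor)
    if "image" in stages:
        tables["image"] = run_stage("image", lambda: fluorquant.analyze_image_dir(
            cohort_dir, method=cfg["mask_method"]))
    if "afm" in stages:
        def _afm():
            df = afm.analyze_curve_dir(cohort_dir, nu=cfg["nu"],
                                       window_lo=cfg["hertz_window"][0],
                                       window_hi=cfg["hertz_window"][1])
            return df[(df["error"] == "") & df["height_pass"]]
        tables["afm"] = run_stage("afm", _afm)
    if "kymo" in stages:
        def _kymo():
            axons, tracks = kymo.analyze_kymo_dir(cohort_dir)
            return axons.merge(tracks.groupby("axon_id")["mean_frame_disp_um"]
                               .mean().rename("mean_frame_disp_um"),
                               on="axon_id", how="left")
        tables["kymo"] = run_stage("kymo", _kymo)

    for stage, df in tables.items():
        df.to_csv(out / f"{stage}_metrics.csv", index=False)
        for metric in _METRICS[stage]:
            if metric not in df.columns:
                continue
            sub = df.dropna(subset=[metric])
            if sub["condition"].nunique() < 2 or len(sub) < 4:
                continue
            res = stats.run_metric_tests(sub, metric)
            res.insert(0, "stage", stage)
            stat_tables.append(res)

    # looping frequency: Fisher's exact test of each condition vs the first
    if "arbor" in tables and tables["arbor"]["condition"].nunique() >= 2:
        adf = tables["arbor"]
        conds = list(dict.fromkeys(adf["condition"]))
        ref = conds[0]
        rows = []
        for cond in conds[1:]:
            a = int(adf.loc[adf.condition == cond, "looping"].sum())
            b = int((adf.condition == cond).sum()) - a
            c = int(adf.loc[adf.condition == ref, "looping"].sum())
            d = int((adf.condition == ref).sum()) - c
            try:
                r = stats.fisher_exact_2x2(stats.ContingencyTable2x2(a, b, c, d))
            except ValueError:
                continue
            rows.append({"stage": "arbor", "metric": "looping",
                         "comparison": f"{cond} vs {ref}", "statistic": r.statistic,
                         "p_raw": r.p_raw, "p_adjusted": r.p_adjusted,
                         "tier": r.tier})
        if rows:
            stat_tables.append(pd.DataFrame(rows))

    if stat_tables:
        pd.concat(stat_tables, ignore_index=True).to_csv(
            out / "statistics.csv", index=False)

    if cfg["plots"]:
        _summary_plots(tables, out)

    manifest = {
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
        "master_seed": cfg["seed"],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "cohort_dir": str(cohort_dir),
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      default=str))
    return out


def _summary_plots(tables: dict[str, pd.DataFrame], out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for stage, df in tables.items():
        metrics = [m for m in _METRICS[stage] if m in df.columns]
        if not metrics or "condition" not in df.columns:
            continue
        fig, axes = plt.subplots(1, len(metrics),
                                 figsize=(3 * len(metrics), 3), squeeze=False)
        for ax, metric in zip(axes[0], metrics):
            groups = [(c, g[metric].dropna().to_numpy())
                      for c, g in df.groupby("condition", sort=False)]
            ax.boxplot([v for _, v in groups], tick_labels=[c for c, _ in groups])
            ax.set_ylabel(metric)
            ax.tick_params(axis="x", rotation=45)
        fig.tight_layout()
        fig.savefig(out / f"{stage}_summary.png", dpi=100)
        plt.close(fig)


def arbor_stage_trial(conditions: dict[str, tuple | None], n_per_condition: int,
                      seed: int, params: synthgen.ArborParams | None = None,
                      loop_probability: dict[str, float] | None = None) -> pd.DataFrame:
    """In-memory arbor cohort + morphometry, for power / calibration studies.

    ``conditions`` maps label -> per-order branch-mean multipliers (or None
    for baseline).  Returns the per-axon metric table with a condition
    column; no files are written.
    """
    params = params or synthgen.ArborParams()
    rows = []
    for ci, (label, mult) in enumerate(conditions.items()):
        p = params
        if loop_probability and label in loop_probability:
            from dataclasses import replace
            p = replace(params, loop_probability=loop_probability[label])
        for i in range(n_per_condition):
            s = synthgen._sub_seed(seed, label, "arbor", i)
            tree = synthgen.generate_arbor(p, mult, seed=s)
            row = arbor.analyze_tree(tree)
            row["condition"] = label
            rows.append(row)
    return pd.DataFrame(rows)
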