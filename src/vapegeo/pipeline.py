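"""End-to-end analysis pipeline and privacy suppression.

Stages (in order): generate or ingest the study tables; scale survey
weights; fit the random-intercepts multilevel logistic model per
outcome; shrink and standardize division estimates; suppress or merge
small cells; select the spatial weight specification by Monte Carlo
Moran trials; run the Lee's L correlation sweep; export everything with
a run manifest (config echo, seeds, versions, convergence flags, chosen
weights, suppression log, output checksums).  All randomness derives
from the single configured seed, so identical runs are byte-identical.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as vio
from .lee import correlate_all
from .mixedlogit import SIGMA2_E0_LOGISTIC, fit_multilevel_logistic, scale_weights
from .shrinkage import apply_shrinkage, standardize_prevalence
from .spatial import SpatialWeights, knn_weights, select_weights
from .synthetic import ScenarioConfig, simulate_scenario

logger = logging.getLogger(__name__)

STAGES = ("simulate", "fit", "estimate", "spatial", "correlate")

DEFAULT_CONFIG: dict = {
    "mode": "synthetic",  # or "real"
    "seed": 0,
    "scenario": {},  # ScenarioConfig overrides (synthetic mode)
    "inputs": {  # real mode
        "respondents": None,
        "covariates": None,
        "geography": None,
        "adjacency": None,  # optional edge-list; replaces k-NN trials
    },
    "weights": {"method": "A", "use_in_fit": True},
    "model": {"sigma2_e0": SIGMA2_E0_LOGISTIC, "method": "laplace", "n_quad": 1},
    "outcomes": {"ends": "y_ends", "smoke": "y_smoke"},
    "estimation": {"n_draws": 1000},
    "suppression": {"min_n": 10, "strategy": "suppress"},
    "spatial": {"candidate_ks": [1, 2, 3, 4, 5, 6, 7, 8], "n_sims": 999},
    "correlation": {"n_perm": 999},
}


def load_config(path_or_dict) -> dict:
    """Merge a YAML config file (or dict) over the defaults and validate."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path_or_dict is not None:
        if isinstance(path_or_dict, (str, Path)):
            with open(path_or_dict) as fh:
                user = yaml.safe_load(fh) or {}
        else:
            user = copy.deepcopy(dict(path_or_dict))
        for key, val in user.items():
            if key not in cfg:
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(cfg[key], dict) and isinstance(val, dict):
                unknown = set(val) - set(cfg[key]) if key != "scenario" else set()
                if unknown:
                    raise ValueError(f"unknown config key(s) {key}.{sorted(unknown)}")
                cfg[key].update(val)
            else:
                cfg[key] = val
    if cfg["mode"] not in {"synthetic", "real"}:
        raise ValueError("mode must be 'synthetic' or 'real'")
    if cfg["mode"] == "real":
        for name in ("respondents", "covariates", "geography"):
            p = cfg["inputs"].get(name)
            if not p:
                raise ValueError(f"real-data mode requires inputs.{name}")
            if not Path(p).exists():
                raise FileNotFoundError(f"inputs.{name} does not exist: {p}")
    if cfg["suppression"]["strategy"] not in {"suppress", "merge-nearest"}:
        raise ValueError("suppression.strategy must be suppress or merge-nearest")
    return cfg


def _subseed(master: int, tag: int) -> int:
    return int(np.random.SeedSequence([int(master), tag]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# privacy suppression
# ---------------------------------------------------------------------------

def suppress_small_cells(
    estimates: pd.DataFrame,
    min_n: int,
    strategy: str = "suppress",
    geography: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Withhold or merge divisions with fewer than ``min_n`` respondents.

    ``suppress``: flag the division and withhold its estimate columns.
    ``merge-nearest``: pool each under-threshold division into its
    nearest neighbour by centroid distance (smallest n first, ties by
    id), recompute the absorbing division's estimate as the
    count-weighted mean, and drop the absorbed row; iterates until every
    remaining division meets the threshold or one row remains.  The
    step-by-step log is attached as ``df.attrs['suppression_log']``.
    Divisions never flagged or absorbed are returned unchanged.
    """
    out = estimates.copy()
    log: list[dict] = []
    if min_n <= 0:
        out.attrs["suppression_log"] = log
        return out
    value_cols = [c for c in ("prevalence", "ci_low", "ci_high", "u_hat") if c in out.columns]
    if strategy == "suppress":
        mask = out["n_j"] < min_n
        out.loc[mask, "suppressed"] = True
        out.loc[mask, value_cols] = np.nan
        for d in out.loc[mask, "division_id"]:
            log.append({"action": "suppress", "division": d})
    elif strategy == "merge-nearest":
        if geography is None:
            raise ValueError("merge-nearest requires the division geography")
        geo = geography.set_index("division_id")[["x", "y"]]
        out.index = pd.Index(out["division_id"].to_numpy())  # unnamed, avoids ambiguity
        while len(out) > 1:
            small = out[out["n_j"] < min_n]
            if small.empty:
                break
            row = small.sort_values(["n_j", "division_id"]).iloc[0]
            src = row["division_id"]
            others = out.index[out.index != src]
            d = ((geo.loc[others] - geo.loc[src]) ** 2).sum(axis=1)
            tgt = d.sort_values(kind="stable").index[0]
            n_src, n_tgt = float(row["n_j"]), float(out.at[tgt, "n_j"])
            for c in value_cols:
                a, b = row[c], out.at[tgt, c]
                if pd.notna(a) and pd.notna(b):
                    out.at[tgt, c] = (n_src * a + n_tgt * b) / (n_src + n_tgt)
            out.at[tgt, "n_j"] = n_src + n_tgt
            out = out.drop(index=src)
            log.append(
                {"action": "merge", "division": src, "into": tgt,
                 "pooled_n": int(n_src + n_tgt)}
            )
        out = out.reset_index(drop=True)
    else:
        raise ValueError(f"unknown suppression strategy {strategy!r}")
    out.attrs["suppression_log"] = log
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _setup_logging(outdir: Path, level: str = "INFO") -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    handlers.append(logging.FileHandler(outdir / "run.log", mode="w"))
    fmt = logging.Formatter("%(levelname)s %(name)s: %(message)s")
    root = logging.getLogger("vapegeo")
    root.setLevel(level)
    root.handlers = []
    for h in handlers:
        h.setFormatter(fmt)
        root.addHandler(h)


def run_pipeline(
    config=None,
    outdir="vapegeo_out",
    stop_after: str = "correlate",
    log_level: str = "INFO",
) -> dict:
    """Execute the pipeline and return the run manifest.

    ``config`` is a YAML path, a dict of overrides, or None for the
    default synthetic scenario.  ``stop_after`` truncates the stage
    chain (one of ``simulate, fit, estimate, spatial, correlate``).  All
    outputs plus ``manifest.json`` land in ``outdir``.
    """
    if stop_after not in STAGES:
        raise ValueError(f"stop_after must be one of {STAGES}")
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir, log_level)
    seed = int(cfg["seed"])
    manifest: dict = {
        "package": "vapegeo",
        "config": cfg,
        "seed": seed,
        "versions": _versions(),
        "stages_run": [],
        "complete": False,
    }
    outputs: dict[str, Path] = {}
    try:
        _run_stages(cfg, outdir, stop_after, seed, manifest, outputs)
        manifest["complete"] = True
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        logger.error("pipeline failed: %s", manifest["error"])
        _finalize(manifest, outdir, outputs)
        raise
    _finalize(manifest, outdir, outputs)
    return manifest


def _versions() -> dict:
    import scipy
    import statsmodels

    from . import __version__

    return {
        "vapegeo": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _to_py(obj):
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def _finalize(manifest: dict, outdir: Path, outputs: dict[str, Path]) -> None:
    manifest["outputs"] = {
        name: vio.sha256_file(path) for name, path in sorted(outputs.items())
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_to_py)


def _run_stages(cfg, outdir, stop_after, seed, manifest, outputs):
    stop_idx = STAGES.index(stop_after)

    # -- stage: simulate / ingest ---------------------------------------
    if cfg["mode"] == "synthetic":
        scen = ScenarioConfig(**{**cfg["scenario"], "seed": seed})
        manifest["scenario"] = scen.to_dict()
        world = simulate_scenario(scen)
        geography, respondents, covariates = (
            world.geography, world.respondents, world.covariates,
        )
        for name, df in [
            ("respondents.csv", world.respondents),
            ("covariates.csv", world.covariates),
            ("truth.csv", world.truth),
        ]:
            vio.write_table(df, outdir / name)
            outputs[name] = outdir / name
        vio.write_geojson(geography, outdir / "geography.geojson")
        outputs["geography.geojson"] = outdir / "geography.geojson"
    else:
        respondents = vio.read_table(cfg["inputs"]["respondents"], "respondents")
        covariates = vio.read_table(cfg["inputs"]["covariates"], "covariates")
        geography = vio.read_geojson(cfg["inputs"]["geography"])
        missing = set(respondents["division_id"]) - set(geography["division_id"])
        if missing:
            raise vio.SchemaError(
                f"respondent divisions missing from geography: {sorted(missing)[:5]}"
            )
    logger.info(
        "study tables ready: %d respondents, %d divisions",
        len(respondents), geography["division_id"].nunique(),
    )
    manifest["stages_run"].append("simulate")
    if stop_idx < 1:
        return

    # -- stage: weight scaling + model fits ------------------------------
    respondents = scale_weights(respondents, method=cfg["weights"]["method"])
    fits = {}
    for label, col in cfg["outcomes"].items():
        if col is None or col not in respondents.columns:
            logger.info("outcome %s (%s) absent; skipped", label, col)
            continue
        res = fit_multilevel_logistic(
            respondents,
            outcome=col,
            use_weights=cfg["weights"]["use_in_fit"],
            sigma2_e0=cfg["model"]["sigma2_e0"],
            method=cfg["model"]["method"],
            n_quad=cfg["model"]["n_quad"],
        )
        fits[label] = res
        logger.info(
            "fit %s: llf=%.2f sigma2_u0=%.4f converged=%s",
            label, res.llf, res.sigma2_u0, res.converged,
        )
        re_path = outdir / f"residuals_{label}.csv"
        vio.write_table(res.random_effects, re_path)
        outputs[re_path.name] = re_path
    if "ends" not in fits:
        raise ValueError("the ENDS outcome is required")
    manifest["fits"] = {k: v.to_manifest() for k, v in fits.items()}
    manifest["stages_run"].append("fit")
    if stop_idx < 2:
        return

    # -- stage: shrinkage + standardization + suppression -----------------
    estimates = {}
    for i, (label, res) in enumerate(fits.items()):
        est = apply_shrinkage(res)
        est = standardize_prevalence(
            res, est,
            n_draws=int(cfg["estimation"]["n_draws"]),
            seed=_subseed(seed, 10 + i),
        )
        est = suppress_small_cells(
            est,
            min_n=int(cfg["suppression"]["min_n"]),
            strategy=cfg["suppression"]["strategy"],
            geography=geography,
        )
        manifest.setdefault("suppression", {})[label] = est.attrs.get(
            "suppression_log", []
        )
        estimates[label] = est
        path = outdir / f"estimates_{label}.csv"
        vio.write_table(est, path)
        outputs[path.name] = path
    vio.write_geojson(
        geography, outdir / "estimates_ends.geojson", estimates=estimates["ends"]
    )
    outputs["estimates_ends.geojson"] = outdir / "estimates_ends.geojson"
    manifest["stages_run"].append("estimate")
    if stop_idx < 3:
        return

    # -- stage: spatial weight selection ----------------------------------
    ends = estimates["ends"]
    ok = ends[~ends["suppressed"].astype(bool) & np.isfinite(ends["prevalence"])]
    geo_ok = geography[geography["division_id"].isin(ok["division_id"])]
    if cfg["inputs"].get("adjacency"):
        chosen = SpatialWeights.from_edgelist(cfg["inputs"]["adjacency"])
        chosen = chosen.subset(sorted(ok["division_id"]))
        trials = []
    else:
        candidates = [knn_weights(geo_ok, k) for k in cfg["spatial"]["candidate_ks"]]
        chosen, trials = select_weights(
            candidates[0].align(ok, "prevalence"),
            candidates,
            n_sims=int(cfg["spatial"]["n_sims"]),
            seed=_subseed(seed, 20),
        )
    trial_df = pd.DataFrame([dataclasses.asdict(t) for t in trials])
    trial_df.to_csv(outdir / "weight_trials.csv", index=False)
    outputs["weight_trials.csv"] = outdir / "weight_trials.csv"
    chosen.to_edgelist(outdir / "weights_edgelist.tsv")
    outputs["weights_edgelist.tsv"] = outdir / "weights_edgelist.tsv"
    manifest["weight_selection"] = {
        "chosen": chosen.spec,
        "n_sims": int(cfg["spatial"]["n_sims"]),
        "trials": trial_df.to_dict("records"),
    }
    logger.info("selected spatial weights: %s", chosen.spec)
    manifest["stages_run"].append("spatial")
    if stop_idx < 4:
        return

    # -- stage: correlation sweep ------------------------------------------
    corr = correlate_all(
        estimates["ends"],
        estimates.get("smoke"),
        covariates,
        chosen,
        n_perm=int(cfg["correlation"]["n_perm"]),
        seed=_subseed(seed, 30),
    )
    corr.to_csv(outdir / "correlations.csv", index=False)
    outputs["correlations.csv"] = outdir / "correlations.csv"
    manifest["correlations"] = corr[["x", "y", "L", "p"]].to_dict("records")
    manifest["stages_run"].append("correlate")
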