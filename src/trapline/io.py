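"""Trial-table I/O, validation and study orchestration.

The on-disk interchange format is a flat CSV with one row per trial:
``experiment, species, individual, trial, sequence, source, distance`` where
``sequence`` joins platform labels with ``-``.  The loader validates labels
against the named array, collapses consecutive duplicate visits (recording
artifacts with zero distance), recomputes distances, and flags trials that
did not visit every platform.

``run_simulation_study`` and ``run_empirical_study`` chain the stages:
simulate (or load) trials, compute recurrence tables, fit the learning and
DET models, and write summary CSVs plus a manifest carrying the config hash
and seed for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from ._mcmc import McmcSettings
from .arrays import get_array
from .detmodel import fit_det_model, prepare_det_data
from .geometry import PlatformArray, optimal_open_path, route_distance
from .learning import fit_learning_model, prepare_learning_data
from .records import SEQ_DELIMITER, TRIALS_COLUMNS, TrialRecord, factor_label
from .recurrence import collapse_consecutive, det_table
from .simulator import convergence_trial, run_cohort

__all__ = [
    "read_trials_csv",
    "write_trials_csv",
    "trials_to_records",
    "load_config",
    "run_simulation_study",
    "run_empirical_study",
]

logger = logging.getLogger(__name__)

#: default simulation grid, matching the study conditions
DEFAULT_FACTORS = (1.0, 1.2, 2.0)
DEFAULT_N_AGENTS = 100
DEFAULT_N_TRIALS = 120


def read_trials_csv(
    path: str | Path,
    arrays: Mapping[str, PlatformArray] | None = None,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Load and validate a trials CSV.

    ``arrays`` maps experiment names to :class:`PlatformArray`; built-in
    fixtures are used for any experiment name not supplied.  ``column_map``
    renames foreign column headers onto the canonical schema, so deposited
    datasets with different spellings can be adapted.

    Consecutive duplicate visits are collapsed (and logged), distances are
    recomputed from the collapsed sequences, and a boolean ``complete``
    column marks trials that visited every platform.  Unknown platform
    labels or malformed trial numbers raise with the offending row number.
    """
    df = pd.read_csv(path, dtype=str)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = {"experiment", "species", "individual", "trial", "sequence"} - set(
        df.columns
    )
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    try:
        trials = df["trial"].astype(int)
    except (TypeError, ValueError) as e:
        raise ValueError(f"{path}: malformed trial numbers ({e})") from None
    if (trials < 1).any():
        row = int(df.index[trials < 1][0])
        raise ValueError(f"{path}: trial number < 1 at row {row}")
    df["trial"] = trials
    if "source" not in df.columns:
        df["source"] = "empirical"

    resolved: dict[str, PlatformArray] = {}
    seqs, dists, complete = [], [], []
    n_collapsed = 0
    for rownum, rec in enumerate(df.itertuples()):
        name = str(rec.experiment)
        arr = (arrays or {}).get(name) or resolved.get(name)
        if arr is None:
            arr = get_array(name)
        resolved[name] = arr
        raw = tuple(str(rec.sequence).split(SEQ_DELIMITER))
        seq = collapse_consecutive(raw)
        if len(seq) < len(raw):
            n_collapsed += 1
        try:
            d = route_distance(arr, seq)
        except KeyError as e:
            raise ValueError(f"{path}: row {rownum}: {e.args[0]}") from None
        seqs.append(SEQ_DELIMITER.join(seq))
        dists.append(d)
        complete.append(set(seq) == set(arr.labels))
    if n_collapsed:
        logger.info("collapsed consecutive duplicate visits in %d trials", n_collapsed)
    out = df.copy()
    out["sequence"] = seqs
    out["distance"] = dists
    out["complete"] = complete
    dup = out.duplicated(subset=["experiment", "individual", "trial"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (experiment, individual, trial) at rows "
            f"{list(out.index[dup])[:5]}"
        )
    n_inc = int((~out["complete"]).sum())
    if n_inc:
        logger.warning("%d incomplete trials flagged (kept, marked)", n_inc)
    out.attrs["counts"] = (
        out.groupby(["experiment", "species"]).size().to_dict()
    )
    return out


def write_trials_csv(trials: pd.DataFrame, path: str | Path) -> Path:
    """Write a trials table in the canonical column order."""
    path = Path(path)
    cols = [c for c in TRIALS_COLUMNS if c in trials.columns]
    trials.to_csv(path, index=False, columns=cols)
    return path


def trials_to_records(trials: pd.DataFrame) -> list[TrialRecord]:
    """Convert a trials table to :class:`TrialRecord` objects."""
    return [
        TrialRecord(
            experiment=str(r.experiment),
            species=str(r.species),
            individual=str(r.individual),
            trial=int(r.trial),
            sequence=tuple(str(r.sequence).split(SEQ_DELIMITER)),
            source=str(r.source),
            distance=float(getattr(r, "distance", math.nan)),
        )
        for r in trials.itertuples()
    ]


def load_config(path: str | Path) -> dict:
    """Read a YAML study configuration."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def _config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _mcmc_from_config(config: Mapping, seed: int) -> McmcSettings:
    m = config.get("mcmc", {})
    return McmcSettings(
        n_walkers=m.get("n_walkers"),
        n_steps=m.get("n_steps", 1500),
        burn_steps=m.get("burn_steps"),
        thin=m.get("thin", 1),
        seed=seed,
    )


def run_simulation_study(config: Mapping, outdir: str | Path) -> dict:
    """Simulate cohorts on each configured array and fit both models.

    Config keys (all optional): ``arrays`` (names), ``factors``,
    ``n_agents``, ``n_trials``, ``start_mode``, ``seed``, ``det_mode``,
    ``mcmc`` (sampler settings).  Defaults follow the study conditions:
    factors 1/1.2/2, 100 agents, 120 trials, uniform starts.

    Writes per-array trial tables, recurrence tables, posterior summaries
    and a convergence-trial summary, plus a manifest with the config hash.
    Deterministic under a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = dict(config)
    seed = int(config.get("seed", 0))
    factors = tuple(config.get("factors", DEFAULT_FACTORS))
    n_agents = int(config.get("n_agents", DEFAULT_N_AGENTS))
    n_trials = int(config.get("n_trials", DEFAULT_N_TRIALS))
    det_mode = config.get("det_mode", "per_trial")
    artifacts: dict[str, object] = {"config_hash": _config_hash(config), "seed": seed}
    files = []
    for name in config.get("arrays", ("double_trapezoid",)):
        arr = get_array(name)
        trials = run_cohort(
            arr,
            factors,
            n_agents,
            n_trials,
            start_mode=config.get("start_mode", "uniform"),
            seed=seed,
        )
        files.append(write_trials_csv(trials, outdir / f"trials_{name}.csv"))

        rec = det_table(trials, mode=det_mode)
        rec.to_csv(outdir / f"recurrence_{name}.csv", index=False)
        files.append(outdir / f"recurrence_{name}.csv")

        ldata = prepare_learning_data(trials, array=arr, group_col="source")
        lpost = fit_learning_model(ldata, _mcmc_from_config(config, seed))
        lpost.summary().to_csv(outdir / f"learning_{name}.csv", index=False)
        files.append(outdir / f"learning_{name}.csv")

        ddata = prepare_det_data(rec)
        dpost = fit_det_model(ddata, _mcmc_from_config(config, seed + 1))
        dpost.cell_summary().to_csv(outdir / f"det_{name}.csv", index=False)
        files.append(outdir / f"det_{name}.csv")

        opt = optimal_open_path(arr).length
        conv_rows = []
        for (src, ind), grp in trials.groupby(["source", "individual"]):
            recs = trials_to_records(grp)
            conv_rows.append(
                {
                    "array": name,
                    "source": src,
                    "individual": ind,
                    "convergence_trial": convergence_trial(recs, opt),
                }
            )
        pd.DataFrame(conv_rows).to_csv(
            outdir / f"convergence_{name}.csv", index=False
        )
        files.append(outdir / f"convergence_{name}.csv")

        artifacts[name] = {
            "trials": trials,
            "recurrence": rec,
            "learning": lpost,
            "det": dpost,
        }
    manifest = {
        "config": {k: v for k, v in config.items()},
        "config_hash": artifacts["config_hash"],
        "seed": seed,
        "files": [f.name for f in files],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return artifacts


def run_empirical_study(
    data_path: str | Path, config: Mapping | None = None, outdir: str | Path = "."
) -> dict:
    """Fit both models to an empirical-format trials CSV, per array.

    Incomplete trials are excluded from the learning-model distances (they
    have no defined completion distance) but retained in the raw table.
    """
    config = dict(config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data_path = Path(data_path)
    if not data_path.exists():
        raise FileNotFoundError(
            f"{data_path} not found; the deposited dataset is available at "
            "the study's public repository"
        )
    seed = int(config.get("seed", 0))
    trials = read_trials_csv(data_path, column_map=config.get("column_map"))
    artifacts: dict[str, object] = {"trials": trials}
    for name, sub in trials.groupby("experiment"):
        arr = get_array(str(name))
        fit_sub = sub[sub["complete"]]
        ldata = prepare_learning_data(fit_sub, array=arr, group_col="species")
        lpost = fit_learning_model(ldata, _mcmc_from_config(config, seed))
        lpost.summary().to_csv(outdir / f"learning_{name}.csv", index=False)
        rec = det_table(sub, mode=config.get("det_mode", "per_trial"))
        ddata = prepare_det_data(rec)
        dpost = fit_det_model(ddata, _mcmc_from_config(config, seed + 1))
        dpost.cell_summary().to_csv(outdir / f"det_{name}.csv", index=False)
        artifacts[str(name)] = {"learning": lpost, "det": dpost, "recurrence": rec}
    return artifacts
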