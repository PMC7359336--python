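"""End-to-end pipeline: simulate/load -> preprocess -> effects -> prevalence
-> reliability -> group statistics, with a reproducibility manifest.

Driven by a plain dict (typically parsed from YAML).  Every stage writes its
output under the run directory; reruns with the same config and seeds are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .effects import fit_all_participants
from .group_stats import fisher_exact_rxc, jzs_anova_bf, oneway_anova, table1_report
from .io import ColumnMap, read_trials, write_trials
from .preprocess import preprocess
from .prevalence import LABELS, classify_cohort, prevalence_table
from .reliability import split_half_reliability
from .synthetic import SimConfig, generate_experiment

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},              # SimConfig overrides; set to None to load a CSV
    "input": None,               # path to a trial CSV (used when simulate is None)
    "preprocess": {"error_threshold": 0.40, "min_rt_ms": 200.0,
                   "k": 3.0, "trim_mode": "recursive"},
    "effects": {"min_cell": 5, "include_snarc": False,
                "include_standardized": False},
    "prevalence": {"n_iter": 5000, "set_size": 60, "ci": 0.90, "min_pool": 50},
    "reliability": {"n_splits": 200, "effects": ["nde", "nse"]},
}


def _merge(base: dict, override: dict | None) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


class _JSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_JSONEncoder)
                    + "\n", encoding="utf-8")


def _group_level(slopes: pd.DataFrame, classifications: pd.DataFrame,
                 mc_seed: int) -> dict:
    out: dict = {}
    multi_group = slopes["group"].nunique() >= 2 and \
        slopes.groupby("group").size().min() >= 2
    for effect, col in (("nde", "nde_slope"), ("nse", "nse_slope")):
        entry: dict = {}
        if multi_group:
            an = oneway_anova(slopes[col], slopes["group"])
            entry["anova"] = asdict(an)
            entry["anova_bf"] = jzs_anova_bf(slopes[col], slopes["group"])
            counts = (
                classifications[classifications["effect"] == effect]
                .groupby(["group", "label"]).size()
                .unstack(fill_value=0)
                .reindex(columns=list(LABELS), fill_value=0)
            )
            counts = counts.loc[:, counts.sum(axis=0) > 0]  # drop empty labels
            if counts.shape[1] >= 2:
                fres = fisher_exact_rxc(counts.to_numpy(), method="enumerate",
                                        seed=mc_seed)
                entry["fisher"] = {"p": fres.p, "method": fres.method,
                                   "n_tables": fres.n_tables}
        out[effect] = entry
    if multi_group:
        an = oneway_anova(slopes["mean_rt"], slopes["group"])
        out["mean_rt"] = {"anova": asdict(an),
                          "anova_bf": jzs_anova_bf(slopes["mean_rt"],
                                                   slopes["group"])}
    return out


def run_pipeline(config: dict | None = None, out_dir=None) -> dict:
    """Run every stage; returns a dict of in-memory results.

    When `out_dir` is given, all artefacts (CSVs, JSON reports, manifest)
    are written there.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    seed = int(cfg["seed"])
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    truth = None
    if cfg.get("simulate") is not None:
        sim_cfg = SimConfig.from_dict(_merge({"seed": seed}, cfg["simulate"]))
        trials, truth = generate_experiment(sim_cfg)
        if out is not None:
            write_trials(trials, out / "trials.csv")
            truth.to_csv(out / "ground_truth.csv", index=False)
    elif cfg.get("input"):
        trials = read_trials(cfg["input"], ColumnMap(**cfg.get("colmap", {})))
    else:
        raise ValueError("config must provide either 'simulate' or 'input'")

    retained, report = preprocess(trials, **cfg["preprocess"])
    slopes = fit_all_participants(retained, **cfg["effects"])
    classifications = classify_cohort(retained, slopes, seed=seed,
                                      **cfg["prevalence"])
    rel_cfg = cfg["reliability"]
    reliability = {
        eff: asdict(split_half_reliability(retained, effect=eff,
                                           n_splits=rel_cfg["n_splits"],
                                           seed=seed))
        for eff in rel_cfg["effects"]
    }
    table1 = table1_report(slopes, classifications)
    group = _group_level(slopes, classifications, mc_seed=seed)
    prev = {eff: prevalence_table(classifications, eff) for eff in ("nde", "nse")}

    results = {
        "config": cfg,
        "trials": trials,
        "ground_truth": truth,
        "retained": retained,
        "preprocess_report": report,
        "slopes": slopes,
        "classifications": classifications,
        "reliability": reliability,
        "table1": table1,
        "group_stats": group,
        "prevalence": prev,
    }

    if out is not None:
        _dump_json(report.to_dict(), out / "preprocess_report.json")
        slopes.to_csv(out / "slopes.csv", index=False)
        classifications.to_csv(out / "classifications.csv", index=False)
        for eff, tab in prev.items():
            tab.to_csv(out / f"prevalence_{eff}.csv", index=False)
        _dump_json(reliability, out / "reliability.json")
        table1.to_csv(out / "table1.csv", index=False)
        _dump_json(group, out / "group_stats.json")
        manifest = {
            "package": "magclass",
            "version": __version__,
            "seed": seed,
            "config": cfg,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg, sort_keys=True, default=str).encode()
            ).hexdigest(),
        }
        _dump_json(manifest, out / "manifest.json")
    return results
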