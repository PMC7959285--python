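"""Config-driven orchestration of the full workflow.

simulate (or load) -> preprocess -> peak features + ANOVA top-k -> LOPO
classification (both tree ensembles) -> per-band statistics -> report.

A single global seed fans out to per-stage seeds through a fixed derivation
(``numpy.random.SeedSequence([seed, stage_index])``), so every stage can be
re-run in isolation and still reproduce the full-pipeline result.  Stage
wall-times are logged, never stored in the report, so that reruns with the
same seed and config produce byte-identical reports.
"""

from __future__ import annotations

import json
import logging
import time
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import band_stats as bs
from . import classify as cl
from . import peak_features as pf
from . import preprocess as pp
from . import spectra_io as sio
from . import synthetic_data as sd

log = logging.getLogger("gliospec")

STAGE_IDS = {"simulate": 0, "classify_rf": 1, "classify_gb": 2, "stats": 3}


def derive_seed(seed: int, stage: str) -> int:
    """Stage seed from the global seed via a fixed SeedSequence derivation."""
    return int(
        np.random.SeedSequence([seed, STAGE_IDS[stage]]).generate_state(1)[0]
        % 2**31
    )


def load_study_cohort() -> pd.DataFrame:
    """The study's cohort composition table (samples and spectra per histology)."""
    src = resources.files("gliospec.data").joinpath("study_cohort.csv")
    with resources.as_file(src) as p:
        return pd.read_csv(p, keep_default_na=False)


def summarize_cohort(meta: pd.DataFrame) -> pd.DataFrame:
    """Per-histology sample/spectra counts with within-glioma percentages.

    Percentages are count / total glioma samples x 100, one decimal, as in a
    cohort composition table; rows for each class total plus a grand total
    are appended.
    """
    meta = pd.DataFrame(meta)
    if "histology" not in meta.columns:
        meta = meta.assign(histology="")
    rows = []
    n_tumor_samples = meta.loc[meta["label"] == "Tumor", "sample_id"].nunique()
    for (label, hist), grp in meta.groupby(["label", "histology"], sort=True):
        row = {
            "group": hist or label,
            "label": label,
            "n_samples": grp["sample_id"].nunique(),
            "n_spectra": len(grp),
        }
        if label == "Tumor" and n_tumor_samples:
            row["pct_of_glioma"] = round(
                row["n_samples"] / n_tumor_samples * 100, 1
            )
        rows.append(row)
    for label, grp in meta.groupby("label"):
        rows.append(
            {
                "group": f"{label} total",
                "label": label,
                "n_samples": grp["sample_id"].nunique(),
                "n_spectra": len(grp),
            }
        )
    rows.append(
        {
            "group": "Total",
            "label": "",
            "n_samples": meta["sample_id"].nunique(),
            "n_spectra": len(meta),
        }
    )
    return pd.DataFrame(rows)


def summarize_study_cohort() -> pd.DataFrame:
    """Cohort bookkeeping of the original study table (not simulated data)."""
    study = load_study_cohort()
    out = study.copy()
    n_tumor = study.loc[study["label"] == "Tumor", "n_samples"].sum()
    out["pct_of_glioma"] = np.where(
        out["label"] == "Tumor",
        (out["n_samples"] / n_tumor * 100).round(1),
        np.nan,
    )
    totals = pd.DataFrame(
        [
            {
                "histology": f"{label} total",
                "label": label,
                "n_samples": grp["n_samples"].sum(),
                "n_spectra": grp["n_spectra"].sum(),
            }
            for label, grp in study.groupby("label")
        ]
        + [
            {
                "histology": "Total",
                "label": "",
                "n_samples": study["n_samples"].sum(),
                "n_spectra": study["n_spectra"].sum(),
            }
        ]
    )
    return pd.concat([out, totals], ignore_index=True)


def default_config(seed: int = 0) -> dict:
    return {
        "seed": seed,
        "simulate": {},  # SimConfig overrides; None => load from io paths
        "preprocess": {},  # PreprocessConfig overrides
        "features": {"halfwidth": 3.0, "k": 60, "catalog": None},
        "classify": {"mode": "fixed_params"},
        "stats": {"alpha": 0.05},
        "io": {"out_dir": None, "spectra": None, "meta": None},
    }


def _merge_config(cfg: dict | None, seed: int | None = None) -> dict:
    merged = default_config()
    for key, val in (cfg or {}).items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    if seed is not None:
        merged["seed"] = seed
    return merged


def run_all(cfg: dict | None = None, seed: int | None = None) -> dict:
    """Execute every stage in order and return the run report.

    The report contains the config echo, QC bookkeeping, cohort summary,
    selected shifts, per-model metrics and the band-statistics table; it is
    reproducible bit-for-bit from the echoed config.
    """
    cfg = _merge_config(cfg, seed)
    seed = int(cfg["seed"])
    report: dict = {"config": cfg, "seed": seed}
    t0 = time.time()

    if cfg["simulate"] is not None:
        sim_cfg = sd.SimConfig(seed=derive_seed(seed, "simulate"),
                               **cfg["simulate"])
        sset, _truth = sd.generate_cohort(sim_cfg)
        log.info("simulate: %d spectra in %.1fs", sset.n_spectra, time.time() - t0)
    else:
        sset = sio.read_spectra(cfg["io"]["spectra"], cfg["io"]["meta"])
        log.info("load: %d spectra", sset.n_spectra)
    report["cohort_summary"] = summarize_cohort(sset.meta).to_dict("records")

    t0 = time.time()
    pre_cfg = pp.PreprocessConfig(**cfg["preprocess"])
    processed, qc = pp.run_preprocessing(sset, pre_cfg)
    report["qc"] = qc.to_dict()
    log.info("preprocess: %d -> %d spectra in %.1fs",
             sset.n_spectra, processed.n_spectra, time.time() - t0)

    feat_cfg = cfg["features"]
    catalog = pf.load_catalog(feat_cfg.get("catalog"))
    table = pf.build_feature_table(
        processed, catalog.shifts, halfwidth=feat_cfg.get("halfwidth", 3.0)
    )
    scores = pf.anova_f_scores(table)
    selected = pf.select_top_k(scores, k=min(feat_cfg.get("k", 60), len(scores)))
    table = table.select(selected)
    report["selected_shifts"] = selected

    report["metrics"] = {}
    for family, spec_fn, stage in (
        ("random_forest", cl.default_rf_spec, "classify_rf"),
        ("gradient_boosting", cl.default_gb_spec, "classify_gb"),
    ):
        t0 = time.time()
        spec = spec_fn(seed=derive_seed(seed, stage))
        result = cl.run_lopo(table, spec, mode=cfg["classify"].get(
            "mode", "fixed_params"))
        report["metrics"][family] = {
            "model": family,
            "mode": cfg["classify"].get("mode", "fixed_params"),
            **result.metrics.to_dict(),
            "n_folds": len(result.folds),
            "seed": spec.seed,
        }
        log.info("%s LOPO: accuracy=%.3f auc=%.3f in %.1fs", family,
                 result.metrics.accuracy, result.metrics.auc, time.time() - t0)

    bands = bs.compare_bands(table, catalog)
    report["band_stats"] = bands.to_dict("records")
    means = bs.group_mean_spectra(processed)
    report["band_ratio_720_701"] = {
        label: bs.band_ratio(mean) for label, (mean, _sd) in means.items()
    }

    out_dir = cfg["io"].get("out_dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_jsonable)
        bands.to_csv(out / "band_stats.csv", index=False)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
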