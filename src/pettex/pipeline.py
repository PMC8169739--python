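"""End-to-end orchestration: simulate -> segment -> extract -> stats -> report.

``run_pipeline`` consumes a structured key-value config (YAML file or dict),
produces a per-lesion feature CSV, a group-comparison CSV, a diagnostic ROC
CSV and a run log, and is byte-reproducible at a fixed seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .phantoms import LesionRecord, iter_cohort
from .segmentation import threshold_voi
from .texture import ALL_FEATURE_NAMES, ExtractionConfig, extract_all
from .volume_io import read_mask, read_volume

__all__ = [
    "extract_lesion",
    "extract_cohort_features",
    "load_cohort_dir",
    "run_pipeline",
    "DEFAULT_CONFIG",
]

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "cohort": {"n_tumor": 32, "n_rp": 31, "seed": 0},
    "threshold_fraction": 0.40,
    "bins": 64,
    "pct_low": 1.0,
    "pct_high": 99.0,
    "positive_label": "tumor",
    "output_dir": "pettex_run",
}


def extract_lesion(volume, search_mask, threshold_fraction: float = 0.40,
                   config: ExtractionConfig = ExtractionConfig()) -> dict[str, float]:
    """Segment the VOI at ``threshold_fraction`` x SUVmax inside the search
    region and compute the 61-parameter feature vector."""
    voi = threshold_voi(volume, search_mask, fraction=threshold_fraction)
    return extract_all(volume, voi, config=config)


def extract_cohort_features(
    records: Iterable[LesionRecord],
    threshold_fraction: float = 0.40,
    config: ExtractionConfig = ExtractionConfig(),
) -> pd.DataFrame:
    """Per-lesion feature table (lesion_id, label, 5 + 56 parameters)."""
    rows = []
    for rec in records:
        try:
            feats = extract_lesion(
                rec.volume, rec.mask, threshold_fraction, config
            )
        except Exception as exc:  # surface the failing lesion
            raise RuntimeError(
                f"feature extraction failed for lesion {rec.lesion_id!r}: {exc}"
            ) from exc
        rows.append({"lesion_id": rec.lesion_id, "label": rec.label, **feats})
    df = pd.DataFrame(rows)
    assert list(df.columns[2:]) == list(ALL_FEATURE_NAMES)
    return df


def load_cohort_dir(cohort_dir: str | Path) -> Iterable[LesionRecord]:
    """Iterate lesions from a directory laid out by ``write_cohort``."""
    cohort_dir = Path(cohort_dir)
    truth_path = cohort_dir / "truth.csv"
    if not truth_path.exists():
        raise FileNotFoundError(f"missing truth table: {truth_path}")
    truth = pd.read_csv(truth_path)
    for _, row in truth.iterrows():
        lesion_id = str(row["lesion_id"])
        vol_path = cohort_dir / "volumes" / f"{lesion_id}.nii.gz"
        mask_path = cohort_dir / "masks" / f"{lesion_id}.nii.gz"
        if not vol_path.exists():
            raise FileNotFoundError(f"missing volume for {lesion_id}: {vol_path}")
        if not mask_path.exists():
            raise FileNotFoundError(f"missing mask for {lesion_id}: {mask_path}")
        yield LesionRecord(
            lesion_id=lesion_id,
            label=str(row["label"]),
            spec=None,
            volume=read_volume(vol_path),
            mask=read_mask(mask_path),
        )


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            loaded = yaml.safe_load(fh) or {}
    elif isinstance(config, dict):
        loaded = dict(config)
    else:
        raise TypeError("config must be a mapping or a path to a YAML file")
    merged = {**DEFAULT_CONFIG, **loaded}
    return merged


def run_pipeline(config, out_dir: str | Path | None = None) -> dict[str, Path]:
    """Run the full workflow and return the paths of the written artifacts.

    The config names either a synthetic-cohort spec (``cohort:`` with
    n_tumor / n_rp / seed) or an input directory of volumes + masks + labels
    (``cohort_dir:``).  Identical config and seed give identical outputs.
    If either group has fewer than 2 lesions the statistics stage is skipped
    with a warning and the feature CSV is still written.
    """
    from .stats import group_comparison_report, roc_report  # local: keep import light

    cfg = _load_config(config)
    out = Path(out_dir) if out_dir is not None else Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)

    if "cohort_dir" in cfg and cfg["cohort_dir"]:
        records = load_cohort_dir(cfg["cohort_dir"])
    else:
        c = cfg["cohort"]
        records = iter_cohort(
            n_tumor=int(c.get("n_tumor", 32)),
            n_rp=int(c.get("n_rp", 31)),
            master_seed=int(c.get("seed", 0)),
        )

    extraction = ExtractionConfig(
        n_levels=int(cfg["bins"]), p_lo=float(cfg["pct_low"]),
        p_hi=float(cfg["pct_high"]),
    )
    features = extract_cohort_features(
        records, threshold_fraction=float(cfg["threshold_fraction"]),
        config=extraction,
    )
    paths: dict[str, Path] = {}
    paths["features"] = out / "features.csv"
    features.to_csv(paths["features"], index=False)

    counts = features["label"].value_counts()
    positive = cfg["positive_label"]
    if len(counts) < 2 or counts.min() < 2:
        warnings.warn("group too small: statistics stage skipped")
    else:
        table = features.drop(columns=["lesion_id"])
        comparison = group_comparison_report(
            table, label_col="label", positive_label=positive
        )
        paths["comparison"] = out / "comparison.csv"
        comparison.to_csv(paths["comparison"])

        roc = roc_report(table, label_col="label", positive_label=positive)
        pct_cols = [c for c in roc.columns if c.endswith("_pct")]
        roc[pct_cols] = roc[pct_cols].round(2)
        roc["auc"] = roc["auc"].round(2)
        paths["roc"] = out / "roc.csv"
        roc.to_csv(paths["roc"])

    paths["log"] = out / "run_log.txt"
    with open(paths["log"], "w") as fh:
        fh.write(f"pettex {__version__}\n")
        for key, value in sorted(cfg.items()):
            fh.write(f"{key} = {value}\n")
        fh.write(f"n_lesions = {len(features)}\n")
    return paths
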