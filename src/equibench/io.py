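"""Dataset and config I/O plus run manifests.

The on-disk cohort dialect is two tab-delimited files: ``features.tsv``
(header row of feature ids, first column the sample id) and ``labels.tsv``
(sample id, label in {-1,+1}, group in {1,2}), with an optional
``truth.json`` carrying generator ground truth. Configs are flat YAML/JSON
key-value files mirroring SyntheticConfig field names. Every
artifact-producing command writes a ``manifest.json`` capturing the resolved
config, master seed, package version, input digests and timestamp, so
deterministic outputs can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synth_cohort import BetaPair, Cohort, SyntheticConfig


def save_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write features.tsv, labels.tsv and (when present) truth.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    feat = pd.DataFrame(cohort.X, index=cohort.sample_ids, columns=cohort.feature_ids)
    feat.index.name = "sample_id"
    feat.to_csv(out_dir / "features.tsv", sep="\t")
    labels = pd.DataFrame(
        {"sample_id": cohort.sample_ids, "label": cohort.y, "group": cohort.group}
    )
    labels.to_csv(out_dir / "labels.tsv", sep="\t", index=False)
    if cohort.truth is not None:
        t = cohort.truth
        payload = {
            "de_indices": np.asarray(t["de_indices"]).tolist(),
            "beta1": np.asarray(t["betas"].beta1).tolist(),
            "beta2": np.asarray(t["betas"].beta2).tolist(),
            "thresholds": list(t["thresholds"]),
            "config": dataclasses.asdict(t["config"]),
        }
        (out_dir / "truth.json").write_text(json.dumps(payload, indent=1))
    return out_dir


def load_cohort(path: str | Path) -> Cohort:
    """Load and validate a cohort directory written by :func:`save_cohort`."""
    path = Path(path)
    feat_path, label_path = path / "features.tsv", path / "labels.tsv"
    for p in (feat_path, label_path):
        if not p.exists():
            raise FileNotFoundError(f"missing cohort file: {p}")
    feat = pd.read_csv(feat_path, sep="\t", index_col=0)
    if feat.index.duplicated().any():
        dup = feat.index[feat.index.duplicated()][0]
        raise ValueError(f"duplicated sample id in features.tsv: {dup!r}")
    non_numeric = feat.columns[
        ~feat.apply(lambda c: pd.api.types.is_numeric_dtype(c))
    ]
    if len(non_numeric):
        raise ValueError(f"non-numeric feature column(s): {list(non_numeric[:3])}")
    labels = pd.read_csv(label_path, sep="\t")
    labels = labels.set_index("sample_id")
    missing = [s for s in feat.index if s not in labels.index]
    if missing:
        raise ValueError(f"sample id(s) in features.tsv absent from labels.tsv: {missing[:3]}")
    labels = labels.loc[feat.index]
    bad_label = set(labels["label"].unique()) - {-1, 1}
    if bad_label:
        raise ValueError(f"unknown label value(s): {sorted(bad_label)}")
    bad_group = set(labels["group"].unique()) - {1, 2}
    if bad_group:
        raise ValueError(f"unknown group token(s): {sorted(bad_group)}")

    truth = None
    truth_path = path / "truth.json"
    if truth_path.exists():
        raw = json.loads(truth_path.read_text())
        cfg_raw = raw["config"]
        cfg_raw["beta_counts"] = tuple(cfg_raw["beta_counts"])
        truth = {
            "de_indices": np.asarray(raw["de_indices"], dtype=int),
            "betas": BetaPair(
                beta1=np.asarray(raw["beta1"], dtype=int),
                beta2=np.asarray(raw["beta2"], dtype=int),
            ),
            "thresholds": tuple(raw["thresholds"]),
            "config": SyntheticConfig(**cfg_raw),
        }
    return Cohort(
        X=feat.to_numpy(dtype=float),
        y=labels["label"].to_numpy(),
        group=labels["group"].to_numpy(),
        feature_ids=list(feat.columns),
        sample_ids=list(feat.index),
        truth=truth,
    )


def load_config(path: str | Path, seed_override: int | None = None) -> SyntheticConfig:
    """Flat YAML/JSON key-value file mirroring SyntheticConfig fields."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must hold a key-value mapping")
    if "beta_counts" in raw:
        raw["beta_counts"] = tuple(raw["beta_counts"])
    if seed_override is not None:
        raw["seed"] = seed_override
    return SyntheticConfig(**raw)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_manifest(out_dir: str | Path, command: str, config: dict, seed: int | None,
                   inputs: list[str | Path] = ()) -> Path:
    """Record everything needed to reproduce a command's outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": config,
        "master_seed": seed,
        "package_version": __version__,
        "input_digests": {str(p): _digest(Path(p)) for p in inputs if Path(p).is_file()},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path
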