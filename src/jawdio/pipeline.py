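"""End-to-end experiment orchestration.

A run executes the four-step workflow — beep bandstop filtering, removal of
uninformative low-power blocks, Mel featurization, classification — over a
manifest of WAV segments (real recordings or the bundled synthetic
generator), with the dataset-organization protocol: optional forage
filtering, optional count-balancing of the three behaviors, a seeded
0.7:0.1:0.2 train/validation/test split, fixed-epoch training, and a
held-out evaluation report.

Everything a run produces is determined by its resolved configuration and
seeds.  ``report.json`` contains only deterministic fields so identical
configurations yield byte-identical reports; wall-clock measurements
(normalized processing speed) are written separately to ``timing.json``.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import models
from .audio_io import read_manifest, read_wav
from .cleaning import (
    DEFAULT_BLOCK_SIZE,
    DEFAULT_THRESHOLD,
    BandstopSpec,
    bandstop_filter,
    remove_uninformative,
)
from .dataset import SplitSpec, balance_by_count, filter_by_forage, split
from .evaluation import confusion_matrix, precision_recall_f1, processing_speed
from .features import DEFAULT_T_FIXED, MelConfig, StftConfig, log_mel_spectrogram, to_fixed_input
from .models import ClassifierSpec, TrainConfig
from .synthetic import BeepSpec, default_specs, generate_dataset

logger = logging.getLogger("jawdio.pipeline")


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one experiment run."""

    arch: str = "lstm"
    filtering: str = "filtered"  # original | filtered
    balancing: str = "imbalanced"  # imbalanced | balanced
    forage_species: str | None = None
    forage_height: str | None = None
    # synthesis (used when no data_dir is supplied)
    counts_per_condition: int = 50
    with_beeps: bool = True
    synth_seed: int = 11
    # stage configs
    bandstop: BandstopSpec = field(default_factory=BandstopSpec)
    block_size: int = DEFAULT_BLOCK_SIZE
    threshold: float = DEFAULT_THRESHOLD
    stft: StftConfig = field(default_factory=StftConfig)
    mel: MelConfig = field(default_factory=MelConfig)
    t_fixed: int = DEFAULT_T_FIXED
    # protocol seeds and hyperparameters
    split_seed: int = 7
    balance_seed: int = 13
    train_seed: int = 3
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    dropout: float = 0.1

    def __post_init__(self) -> None:
        if self.filtering not in ("original", "filtered"):
            raise ValueError("filtering must be 'original' or 'filtered'")
        if self.balancing not in ("imbalanced", "balanced"):
            raise ValueError("balancing must be 'imbalanced' or 'balanced'")
        if self.arch not in models.ARCHS:
            raise ValueError(f"arch must be one of {models.ARCHS}")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


class StageError(RuntimeError):
    """Failure in one named pipeline stage."""


def synthesize_default_dataset(
    out_dir: str | Path,
    seed: int = 11,
    counts_per_condition: int = 50,
    with_beeps: bool = True,
) -> pd.DataFrame:
    """Generate the default synthetic study dataset (12 conditions)."""
    specs = default_specs()
    counts = [counts_per_condition] * len(specs)
    beep = BeepSpec() if with_beeps else None
    return generate_dataset(specs, counts, beep, out_dir, seed)


def _featurize(
    manifest: pd.DataFrame, data_dir: Path, cfg: RunConfig
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Clean (per config) and featurize every manifest row.

    Returns (features, labels, manifest of retained rows); rows whose audio
    is entirely uninformative after cleaning are dropped with a log entry.
    """
    feats, keep_rows = [], []
    for i, row in manifest.iterrows():
        segment = read_wav(data_dir / row["file"])
        if cfg.filtering == "filtered":
            try:
                segment = bandstop_filter(segment, cfg.bandstop)
            except ValueError as exc:
                raise StageError(f"bandstop stage failed on {row['file']}: {exc}")
            segment = remove_uninformative(segment, cfg.block_size, cfg.threshold)
            if len(segment.samples) == 0:
                logger.info("dropping %s: fully uninformative", row["file"])
                continue
        mel = log_mel_spectrogram(segment, cfg.stft, cfg.mel)
        feats.append(to_fixed_input(mel, cfg.t_fixed))
        keep_rows.append(i)
    if not feats:
        raise StageError("featurize stage: no informative segments remain")
    kept = manifest.loc[keep_rows].reset_index(drop=True)
    x = np.stack(feats)
    y = models.encode_labels(kept["behavior"])
    return x, y, kept


def run_experiment(
    cfg: RunConfig,
    out_dir: str | Path,
    data_dir: str | Path | None = None,
) -> dict:
    """Execute the full chain; write report, model, logs; return the report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()

    if data_dir is None:
        data_dir = out_dir / "synthetic_data"
        manifest = synthesize_default_dataset(
            data_dir, cfg.synth_seed, cfg.counts_per_condition, cfg.with_beeps
        )
    else:
        data_dir = Path(data_dir)
        manifest = read_manifest(data_dir / "manifest.csv")

    manifest = filter_by_forage(manifest, cfg.forage_species, cfg.forage_height)
    if len(manifest) == 0:
        raise StageError("forage filter stage: no rows match the criteria")

    if cfg.balancing == "balanced":
        manifest = balance_by_count(manifest, cfg.balance_seed)

    x, y, manifest = _featurize(manifest, data_dir, cfg)

    train_m, val_m, test_m = split(
        manifest, SplitSpec(seed=cfg.split_seed, stratify_by="behavior")
    )
    index_of = {f: i for i, f in enumerate(manifest["file"])}
    tr = np.array([index_of[f] for f in train_m["file"]], dtype=int)
    va = np.array([index_of[f] for f in val_m["file"]], dtype=int)
    te = np.array([index_of[f] for f in test_m["file"]], dtype=int)

    spec = ClassifierSpec(
        arch=cfg.arch, input_shape=(cfg.t_fixed, cfg.mel.n_mels),
        dropout=cfg.dropout, seed=cfg.train_seed,
    )
    classifier = models.build(spec)
    trained = models.train(
        classifier, x[tr], y[tr], x[va], y[va],
        TrainConfig(
            epochs=cfg.epochs, batch_size=cfg.batch_size,
            learning_rate=cfg.learning_rate, seed=cfg.train_seed,
        ),
    )
    probs, labels = models.predict(trained, x[te])
    true_labels = [manifest["behavior"].iloc[i] for i in te]
    cm = confusion_matrix(true_labels, labels)
    weighted = precision_recall_f1(cm, averaging="weighted")
    macro = precision_recall_f1(cm, averaging="macro")

    elapsed = time.perf_counter() - t_start
    total_audio_s = float(manifest["duration_s"].sum())

    report = {
        "config": cfg.to_dict(),
        "dataset": {
            "n_segments": int(len(manifest)),
            "n_train": int(len(tr)),
            "n_val": int(len(va)),
            "n_test": int(len(te)),
            "per_behavior": manifest["behavior"].value_counts().to_dict(),
        },
        "model": {
            "arch": cfg.arch,
            "parameter_count": trained.parameter_count,
            "epochs": len(trained.history),
        },
        "history": trained.history,
        "confusion_matrix": {
            "labels": list(cm.labels),
            "counts": cm.counts.tolist(),
            "row_normalized": np.round(cm.row_normalized(), 6).tolist(),
        },
        "metrics": {
            "per_class": weighted.per_class,
            "overall_weighted": weighted.overall,
            "overall_macro": macro.overall,
        },
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out_dir / "timing.json").write_text(
        json.dumps(
            {
                "total_processing_time_s": elapsed,
                "total_audio_duration_s": total_audio_s,
                "normalized_speed_ms_per_s": processing_speed(elapsed, total_audio_s),
            },
            indent=2,
        )
    )
    pd.DataFrame(trained.history).to_csv(out_dir / "history.csv", index=False)
    pd.DataFrame(
        cm.counts, index=list(cm.labels), columns=list(cm.labels)
    ).to_csv(out_dir / "confusion_matrix.csv")
    (out_dir / "resolved_config.yaml").write_text(
        yaml.safe_dump(_yaml_safe(cfg.to_dict()), sort_keys=True)
    )
    models.save(trained, out_dir / "model")
    return report


def _yaml_safe(obj):
    if isinstance(obj, dict):
        return {k: _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_model_grid(
    base: RunConfig, out_dir: str | Path, data_dir: str | Path | None = None
) -> dict[str, dict]:
    """The 12-cell comparison: 3 architectures x 2 filtering x 2 balancing."""
    out_dir = Path(out_dir)
    if data_dir is None:
        data_dir = out_dir / "synthetic_data"
        synthesize_default_dataset(
            data_dir, base.synth_seed, base.counts_per_condition, base.with_beeps
        )
    reports = {}
    for arch in models.ARCHS:
        for filtering in ("original", "filtered"):
            for balancing in ("imbalanced", "balanced"):
                name = f"{arch}_{filtering}_{balancing}"
                cfg = replace(
                    base, arch=arch, filtering=filtering, balancing=balancing
                )
                reports[name] = run_experiment(cfg, out_dir / name, data_dir)
    return reports


def run_forage_grid(
    base: RunConfig, out_dir: str | Path, data_dir: str | Path | None = None
) -> dict[str, dict]:
    """Four forage-stratified runs: each species and each sward height."""
    out_dir = Path(out_dir)
    if data_dir is None:
        data_dir = out_dir / "synthetic_data"
        synthesize_default_dataset(
            data_dir, base.synth_seed, base.counts_per_condition, base.with_beeps
        )
    cells = {
        "alfalfa": {"forage_species": "alfalfa", "forage_height": None},
        "tall_fescue": {"forage_species": "tall_fescue", "forage_height": None},
        "short": {"forage_species": None, "forage_height": "short"},
        "tall": {"forage_species": None, "forage_height": "tall"},
    }
    reports = {}
    for name, kw in cells.items():
        cfg = replace(base, **kw)
        reports[name] = run_experiment(cfg, out_dir / name, data_dir)
    return reports
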