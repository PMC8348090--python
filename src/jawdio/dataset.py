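"""Dataset accounting, class balancing, splitting, and forage stratification.

Manifests are pandas DataFrames with columns
``file, behavior, forage_species, forage_height, duration_s``.  The
reference inventory of the forehead-microphone dairy-cow jaw-movement
dataset (segment counts and total durations per behavior x forage
condition) is embedded so inventory arithmetic and the balancing protocol
can be exercised without the recordings themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .audio_io import BEHAVIORS, HEIGHTS, SPECIES, validate_manifest

#: Published per-condition (file count, total duration s) of the jaw-movement
#: dataset, keyed by (species, height, behavior).
REFERENCE_INVENTORY: dict[tuple[str, str, str], tuple[int, float]] = {
    ("alfalfa", "short", "bite"): (179, 72.78),
    ("alfalfa", "short", "chew"): (260, 74.24),
    ("alfalfa", "short", "chew_bite"): (123, 71.99),
    ("alfalfa", "tall", "bite"): (148, 175.20),
    ("alfalfa", "tall", "chew"): (416, 184.56),
    ("alfalfa", "tall", "chew_bite"): (322, 182.90),
    ("tall_fescue", "short", "bite"): (94, 143.87),
    ("tall_fescue", "short", "chew"): (454, 144.79),
    ("tall_fescue", "short", "chew_bite"): (217, 141.59),
    ("tall_fescue", "tall", "bite"): (100, 155.19),
    ("tall_fescue", "tall", "chew"): (487, 149.78),
    ("tall_fescue", "tall", "chew_bite"): (238, 150.48),
}


@dataclass(frozen=True)
class SplitSpec:
    ratios: tuple[float, float, float] = (0.7, 0.1, 0.2)
    seed: int = 0
    stratify_by: str = "behavior"

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ratios):
            raise ValueError("split ratios must all be positive")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        if self.stratify_by not in ("behavior", "none"):
            raise ValueError("stratify_by must be 'behavior' or 'none'")


def reference_manifest() -> pd.DataFrame:
    """Synthetic manifest matching the reference inventory cell-by-cell.

    Per cell, each of the n files is assigned the cell's mean duration so
    cell totals (and hence behavior and grand totals) are reproduced.
    """
    rows = []
    for (species, height, behavior), (count, total_s) in REFERENCE_INVENTORY.items():
        per_file = total_s / count
        for j in range(count):
            rows.append(
                {
                    "file": f"{species}_{height}_{behavior}_{j:04d}.wav",
                    "behavior": behavior,
                    "forage_species": species,
                    "forage_height": height,
                    "duration_s": per_file,
                }
            )
    return pd.DataFrame(rows)


def inventory(manifest: pd.DataFrame) -> pd.DataFrame:
    """Per (species, height, behavior) file counts and duration sums.

    Returns a DataFrame indexed by the three condition columns with
    ``file_count`` and ``total_duration_s`` columns; includes per-behavior
    and grand totals accessible via :func:`behavior_totals` /
    :func:`grand_totals`.
    """
    if len(manifest) == 0:
        idx = pd.MultiIndex.from_tuples(
            [], names=["forage_species", "forage_height", "behavior"]
        )
        return pd.DataFrame(
            {"file_count": pd.Series(dtype=int),
             "total_duration_s": pd.Series(dtype=float)},
            index=idx,
        )
    manifest = validate_manifest(manifest)
    grouped = manifest.groupby(
        ["forage_species", "forage_height", "behavior"], sort=True
    ).agg(file_count=("file", "count"), total_duration_s=("duration_s", "sum"))
    return grouped


def behavior_totals(manifest: pd.DataFrame) -> pd.DataFrame:
    if len(manifest) == 0:
        return pd.DataFrame(
            {"file_count": pd.Series(dtype=int),
             "total_duration_s": pd.Series(dtype=float)}
        )
    manifest = validate_manifest(manifest)
    return manifest.groupby("behavior", sort=True).agg(
        file_count=("file", "count"), total_duration_s=("duration_s", "sum")
    )


def grand_totals(manifest: pd.DataFrame) -> tuple[int, float]:
    if len(manifest) == 0:
        return 0, 0.0
    manifest = validate_manifest(manifest)
    return int(len(manifest)), float(manifest["duration_s"].sum())


def balance_by_count(manifest: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Subsample every behavior to the minority class count.

    Selection within each over-represented behavior is uniform without
    replacement; the minority class is retained in full.  Original row
    order is preserved among kept rows.
    """
    manifest = validate_manifest(manifest)
    counts = manifest["behavior"].value_counts()
    for b in BEHAVIORS:
        if counts.get(b, 0) == 0:
            raise ValueError(f"cannot balance: behavior {b!r} has no files")
    target = int(counts.min())
    rng = np.random.default_rng(seed)
    keep_idx: list[np.ndarray] = []
    for b in BEHAVIORS:
        idx = manifest.index[manifest["behavior"] == b].to_numpy()
        if len(idx) > target:
            idx = rng.choice(idx, size=target, replace=False)
        keep_idx.append(idx)
    kept = np.sort(np.concatenate(keep_idx))
    return manifest.loc[kept].reset_index(drop=True)


def _split_sizes(n: int, ratios: tuple[float, float, float]) -> tuple[int, int, int]:
    n_train = int(np.floor(ratios[0] * n))
    n_val = int(np.floor(ratios[1] * n))
    return n_train, n_val, n - n_train - n_val


def split(
    manifest: pd.DataFrame, spec: SplitSpec | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/validation/test partition.

    Sizes are floor(r_train*n), floor(r_val*n), remainder; when stratifying
    by behavior the policy applies within each behavior stratum.  The
    shuffle is seeded, so the partition is reproducible given (manifest row
    order, seed).
    """
    spec = spec or SplitSpec()
    manifest = validate_manifest(manifest).reset_index(drop=True)
    rng = np.random.default_rng(spec.seed)

    def partition(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        perm = rng.permutation(idx)
        n_train, n_val, _ = _split_sizes(len(idx), spec.ratios)
        return (
            perm[:n_train],
            perm[n_train : n_train + n_val],
            perm[n_train + n_val :],
        )

    if spec.stratify_by == "behavior":
        parts: list[list[np.ndarray]] = [[], [], []]
        for b in BEHAVIORS:
            idx = manifest.index[manifest["behavior"] == b].to_numpy()
            if 0 < len(idx) < 3:
                raise ValueError(
                    f"behavior stratum {b!r} has only {len(idx)} rows; "
                    "at least 3 are required for a stratified 3-way split"
                )
            if len(idx) == 0:
                continue
            for part, chunk in zip(parts, partition(idx)):
                part.append(chunk)
        train_i, val_i, test_i = (
            np.sort(np.concatenate(p)) if p else np.array([], dtype=int)
            for p in parts
        )
    else:
        train_i, val_i, test_i = (
            np.sort(p) for p in partition(manifest.index.to_numpy())
        )
    return (
        manifest.loc[train_i].reset_index(drop=True),
        manifest.loc[val_i].reset_index(drop=True),
        manifest.loc[test_i].reset_index(drop=True),
    )


def filter_by_forage(
    manifest: pd.DataFrame,
    species: str | None = None,
    height: str | None = None,
) -> pd.DataFrame:
    """Rows matching the forage criteria; ``None`` imposes no constraint."""
    manifest = validate_manifest(manifest)
    if species is not None and species not in SPECIES:
        raise ValueError(f"unknown forage species {species!r}")
    if height is not None and height not in HEIGHTS:
        raise ValueError(f"unknown forage height {height!r}")
    sel = pd.Series(True, index=manifest.index)
    if species is not None:
        sel &= manifest["forage_species"] == species
    if height is not None:
        sel &= manifest["forage_height"] == height
    return manifest[sel].reset_index(drop=True)
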