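"""Monte Carlo augmentation of milk residue data.

The FDA residue-depletion calculation requires at least 10 animals and
triplicate measurements per sample.  Field studies frequently have fewer
animals and single measurements, so this module expands a measured milk
dataset the way the study's Monte Carlo procedure does: each measured value
is replicated by drawing from a normal distribution centred on the measured
value with SD = intra-assay CV x value, and additional virtual animals are
drawn per time point from the real animals' mean and SD at that time.
Real measurements always pass through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AugmentationSpec",
    "AugmentedDataset",
    "TimeGridError",
    "generate_replicates",
    "generate_virtual_animals",
    "augment_dataset",
]

#: Sampling times closer than this (h) are treated as the same nominal time.
TIME_MATCH_TOL_H = 0.01

RECORD_COLUMNS = ["animal_id", "virtual", "time_h", "replicate", "conc_ng_ml"]


class TimeGridError(ValueError):
    """Animals do not share a common sampling-time grid."""


@dataclass(frozen=True)
class AugmentationSpec:
    """How to expand a measured dataset to the FDA data contract.

    ``n_replicates_per_sample`` counts *additional* replicates per measured
    value (2 additional gives triplicates).  ``truncate_at_zero`` and
    ``include_subloq`` surface choices the procedure leaves open: negative
    draws are truncated to zero by default, and sub-LOQ times are excluded
    upstream by default.
    """

    n_replicates_per_sample: int = 2
    intra_assay_cv: float = 0.032
    n_target_animals: int = 10
    seed: int = 0
    truncate_at_zero: bool = True
    include_subloq: bool = False
    require_common_grid: bool = False

    def __post_init__(self) -> None:
        if self.n_replicates_per_sample < 1:
            raise ValueError("n_replicates_per_sample must be >= 1")
        if not 0 <= self.intra_assay_cv < 1:
            raise ValueError("intra_assay_cv must be in [0, 1)")


@dataclass
class AugmentedDataset:
    """Long-format augmented records plus provenance counts.

    ``records`` columns: animal_id, virtual (bool), time_h, replicate
    (0 = the original measurement), conc_ng_ml.
    """

    records: pd.DataFrame
    n_real_animals: int
    n_virtual_animals: int
    n_replicates_per_sample: int

    def __post_init__(self) -> None:
        missing = set(RECORD_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"records missing columns: {sorted(missing)}")


def generate_replicates(value: float, cv: float, k: int,
                        seed: int | np.random.Generator,
                        truncate_at_zero: bool = True) -> np.ndarray:
    """k draws from normal(mean=value, sd=cv*value), truncated at 0.

    Emulates generating assay replicates of a single measured concentration;
    cv = 0 (or value = 0) returns exact copies.
    """
    if value < 0:
        raise ValueError("value must be >= 0")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = cv * value
    if sd == 0:
        return np.full(k, float(value))
    draws = rng.normal(value, sd, size=k)
    if truncate_at_zero:
        draws = np.maximum(draws, 0.0)
    return draws


def _align_time_grid(df: pd.DataFrame, tol: float,
                     require_common_grid: bool) -> tuple[np.ndarray, pd.DataFrame]:
    """Snap sampling times onto a common grid within ``tol`` hours.

    Times are clustered by gap <= ``tol``; each cluster's first time is its
    nominal grid value.  With ``require_common_grid`` every animal must
    carry every grid time, otherwise an error lists the missing times.
    """
    uniq = np.sort(df["time_h"].unique())
    reps: list[float] = []
    for t in uniq:
        if not reps or t - reps[-1] > tol:
            reps.append(float(t))
    grid = np.asarray(reps)

    out = df.copy()
    snapped = np.empty(len(out))
    for idx, t in enumerate(out["time_h"].to_numpy()):
        j = int(np.searchsorted(grid, t, side="right")) - 1
        snapped[idx] = grid[j]
    out["time_h"] = snapped

    if require_common_grid:
        missing = {
            a: sorted(set(grid) - set(out.loc[out.animal_id == a, "time_h"]))
            for a in out["animal_id"].unique()
        }
        missing = {a: m for a, m in missing.items() if m}
        if missing:
            raise TimeGridError(
                f"animals do not share a common time grid within {tol} h; "
                f"missing times: {missing}")
    return grid, out


def generate_virtual_animals(dataset: pd.DataFrame,
                             n_target: int,
                             seed: int | np.random.Generator,
                             time_tol: float = TIME_MATCH_TOL_H,
                             truncate_at_zero: bool = True,
                             require_common_grid: bool = True) -> AugmentedDataset:
    """Expand to ``n_target`` animals by per-time-point normal draws.

    ``dataset`` needs columns animal_id, time_h, conc_ng_ml with at least
    two real animals sharing a time grid (matched within ``time_tol``).
    Virtual animals receive one value per grid time drawn from the real
    animals' mean and SD at that time (independent across times), truncated
    at 0; real animals pass through byte-identical.  With
    ``require_common_grid`` (the default) every animal must carry every
    grid time; without it, grid times observed in fewer than two animals
    are simply not generated for virtual animals (this accommodates
    censoring-driven dropout at late times).
    """
    df = dataset[["animal_id", "time_h", "conc_ng_ml"]].copy()
    real_ids = list(df["animal_id"].unique())
    if len(real_ids) < 2:
        raise ValueError("need >= 2 real animals to estimate per-time SD")
    if n_target < len(real_ids):
        raise ValueError(
            f"n_target ({n_target}) < number of real animals ({len(real_ids)})")
    grid, aligned = _align_time_grid(df, time_tol, require_common_grid)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    stats_t = aligned.groupby("time_h")["conc_ng_ml"].agg(["mean", "std", "count"])
    stats_t = stats_t[stats_t["count"] >= 2]

    real = dataset.copy()
    real["virtual"] = False
    real["replicate"] = 0
    rows = [real[RECORD_COLUMNS]]
    n_virtual = n_target - len(real_ids)
    for v in range(n_virtual):
        vals = rng.normal(stats_t["mean"].to_numpy(), stats_t["std"].to_numpy())
        if truncate_at_zero:
            vals = np.maximum(vals, 0.0)
        # a time where every real value is zero has mean = sd = 0 -> virtual 0
        rows.append(pd.DataFrame({
            "animal_id": f"virtual-{v + 1:02d}",
            "virtual": True,
            "time_h": stats_t.index.to_numpy(),
            "replicate": 0,
            "conc_ng_ml": vals,
        }))
    records = pd.concat(rows, ignore_index=True)
    return AugmentedDataset(records, n_real_animals=len(real_ids),
                            n_virtual_animals=n_virtual,
                            n_replicates_per_sample=0)


def augment_dataset(dataset: pd.DataFrame,
                    spec: AugmentationSpec) -> AugmentedDataset:
    """Full augmentation: virtual animals first, then per-sample replicates.

    Every sample (real or virtual, replicate 0) gains
    ``spec.n_replicates_per_sample`` additional replicate records drawn with
    the intra-assay CV, so each sample contributes n+1 records in total.
    Deterministic under ``spec.seed``.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_virtual, rng_reps = (np.random.default_rng(s) for s in ss.spawn(2))
    base = generate_virtual_animals(dataset, spec.n_target_animals, rng_virtual,
                                    truncate_at_zero=spec.truncate_at_zero,
                                    require_common_grid=spec.require_common_grid)
    originals = base.records
    extra_rows = []
    for row in originals.itertuples(index=False):
        reps = generate_replicates(row.conc_ng_ml, spec.intra_assay_cv,
                                   spec.n_replicates_per_sample, rng_reps,
                                   truncate_at_zero=spec.truncate_at_zero)
        for r, val in enumerate(reps, start=1):
            extra_rows.append((row.animal_id, row.virtual, row.time_h, r, val))
    extra = pd.DataFrame(extra_rows, columns=RECORD_COLUMNS)
    records = pd.concat([originals, extra], ignore_index=True)
    records = records.sort_values(
        ["virtual", "animal_id", "time_h", "replicate"], kind="stable",
    ).reset_index(drop=True)
    return AugmentedDataset(records, base.n_real_animals,
                            base.n_virtual_animals,
                            spec.n_replicates_per_sample)
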