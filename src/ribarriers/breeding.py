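"""Fruit-set estimation with cluster-level uncertainty, and cross asymmetry.

Hand-pollination experiments nest flowers within plants, so flowers of one
plant are not independent. Both procedures here therefore treat the plant
(more precisely, each distinct plant-by-treatment record group) as the
resampling/permutation unit: bootstrap intervals resample plants with
replacement, and the treatment permutation test reassigns labels to whole
plants, never to individual flowers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import CrossingTable, ValidationError


@dataclass(frozen=True)
class FruitSetEstimate:
    """Pooled fruit-set proportion for one group with a percentile bootstrap CI."""

    group: tuple
    proportion: float
    ci_low: float
    ci_high: float
    n_flowers: int
    n_fruits: int
    n_plants: int
    degenerate: bool = False  # single-plant group: CI carries no information


@dataclass(frozen=True)
class AsymmetryResult:
    """Fold difference between the two directions of a reciprocal cross."""

    ratio: float
    direction: str
    undefined: bool = False


def _plant_sums(df: pd.DataFrame) -> pd.DataFrame:
    return (
        df.groupby(["population", "plant_id"], sort=True)[["fruits", "flowers"]]
        .sum()
        .reset_index()
    )


def estimate_fruit_set_ci(
    table: CrossingTable,
    group_by: Sequence[str] | None = None,
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> list[FruitSetEstimate]:
    """Pooled fruit set per group with a plant-resampling percentile CI.

    The point estimate is the ratio of sums (total fruits over total
    flowers). The interval resamples plants — the experimental clusters —
    with replacement within each group, recomputing the pooled ratio
    ``n_boot`` times and taking the percentile interval. Groups holding a
    single plant get a degenerate interval and are flagged.
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    group_by = list(group_by or [])
    df = table.df
    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci_level) / 2.0

    grouped = [((), df)] if not group_by else [
        (key if isinstance(key, tuple) else (key,), sub)
        for key, sub in df.groupby(group_by, sort=True)
    ]

    out: list[FruitSetEstimate] = []
    for key, sub in grouped:
        plants = _plant_sums(sub)
        fruits = plants["fruits"].to_numpy(dtype=float)
        flowers = plants["flowers"].to_numpy(dtype=float)
        k = len(plants)
        point = float(fruits.sum() / flowers.sum())
        if k == 1:
            lo = hi = point
            degenerate = True
        else:
            idx = rng.integers(0, k, size=(n_boot, k))
            boot = fruits[idx].sum(axis=1) / flowers[idx].sum(axis=1)
            lo, hi = (float(q) for q in np.quantile(boot, [alpha, 1.0 - alpha]))
            degenerate = False
        out.append(
            FruitSetEstimate(
                group=key,
                proportion=point,
                ci_low=lo,
                ci_high=hi,
                n_flowers=int(flowers.sum()),
                n_fruits=int(fruits.sum()),
                n_plants=k,
                degenerate=degenerate,
            )
        )
    return out


def write_fruit_set_estimates(estimates: Sequence[FruitSetEstimate], path) -> None:
    rows = [
        {
            "group": "|".join(str(g) for g in e.group) or "all",
            "proportion": e.proportion,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "n_flowers": e.n_flowers,
            "n_fruits": e.n_fruits,
            "n_plants": e.n_plants,
        }
        for e in estimates
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def permutation_treatment_test(
    table: CrossingTable,
    factor: str = "treatment",
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Plant-level permutation test of a factor's effect on fruit set.

    The statistic is the range (max minus min) of pooled fruit-set
    proportions across factor levels. Labels are permuted over whole
    plant-level record groups — all flowers sharing (population, plant_id,
    level) move together — so within-plant correlation cannot inflate the
    test. The p-value uses the add-one estimator
    ``(1 + #{permuted >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    df = table.df
    if factor not in df.columns:
        raise ValidationError(f"unknown factor column {factor!r}")
    clusters = (
        df.groupby(["population", "plant_id", factor], sort=True)[["fruits", "flowers"]]
        .sum()
        .reset_index()
    )
    levels, codes = np.unique(clusters[factor].to_numpy(), return_inverse=True)
    if len(levels) < 2:
        raise ValidationError("permutation test requires at least two factor levels")
    fruits = clusters["fruits"].to_numpy(dtype=float)
    flowers = clusters["flowers"].to_numpy(dtype=float)
    n_levels = len(levels)

    def stat(c: np.ndarray) -> float:
        fr = np.bincount(c, weights=fruits, minlength=n_levels)
        fl = np.bincount(c, weights=flowers, minlength=n_levels)
        props = fr / fl
        return float(props.max() - props.min())

    observed = stat(codes)
    rng = np.random.default_rng(seed)
    hits = 0
    perm = codes.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if stat(perm) >= observed - 1e-12:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def interspecific_asymmetry(
    fs_ab: float,
    fs_ba: float,
    label_ab: str = "CO→AO",
    label_ba: str = "AO→CO",
) -> AsymmetryResult:
    """Fold asymmetry between the two directions of a reciprocal cross.

    Returns max/min with the direction of the larger value. When the smaller
    proportion is zero the ratio is undefined (flagged, not an exception);
    when both are zero the whole comparison is undefined.
    """
    for v in (fs_ab, fs_ba):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"fruit-set proportions must be in [0, 1], got {v}")
    if fs_ab == fs_ba == 0.0:
        return AsymmetryResult(ratio=math.nan, direction="undefined", undefined=True)
    if fs_ab == fs_ba:
        return AsymmetryResult(ratio=1.0, direction="symmetric")
    hi_label = label_ab if fs_ab > fs_ba else label_ba
    lo = min(fs_ab, fs_ba)
    if lo == 0.0:
        return AsymmetryResult(ratio=math.inf, direction=f"{hi_label} higher", undefined=True)
    return AsymmetryResult(ratio=max(fs_ab, fs_ba) / lo, direction=f"{hi_label} higher")
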