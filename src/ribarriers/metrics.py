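"""Per-barrier reproductive-isolation strength metrics.

Three metrics are implemented, all expressing a barrier as a deviation from
random mating or random co-occurrence:

* **symmetric** (mating-based): ``RI = 1 - 2 * H / (H + C)``, ranging from
  -1 (complete heterospecific advantage) through 0 (random mating) to 1
  (complete isolation).
* **co-occurrence** (sharing-based): ``RI = 1 - S / (S + U)``, in [0, 1]
  for non-negative shared/unshared fractions.
* **proportional** (gene-flow reduction): ``RI = 1 - H / C``, the fraction
  of conspecific-level gene flow removed by the barrier; this is the form
  whose sequential products reproduce cumulative-contribution tables.

Values are deliberately not clipped: a negative RI indicates heterospecific
advantage and is reported as-is (callers can warn on it), because silently
clipping would hide real signal or data problems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from .datamodel import (
    BarrierEstimate,
    CrossingTable,
    MatingOutcome,
    SharingSummary,
    SpeciesAssemblage,
    UndefinedInputError,
    ValidationError,
)

STRENGTH_METRICS = ("proportional", "symmetric")


@dataclass(frozen=True)
class IsolationValue:
    """A single RI metric value together with the metric that produced it."""

    value: float
    metric: str  # "symmetric" | "cooccurrence" | "proportional"

    def __float__(self) -> float:
        return self.value


def ri_symmetric(outcome: MatingOutcome) -> IsolationValue:
    """Symmetric mating-based RI: ``1 - 2 * H / (H + C)``.

    Zero under random mating (H = C), 1 when no heterospecific matings occur,
    and negative when heterospecific matings exceed conspecific ones.
    Undefined when H + C = 0.
    """
    h, c = outcome.heterospecific_success, outcome.conspecific_success
    if h + c <= 0:
        raise UndefinedInputError("symmetric RI undefined: H + C must be positive")
    return IsolationValue(1.0 - 2.0 * h / (h + c), "symmetric")


def ri_cooccurrence(sharing: SharingSummary) -> IsolationValue:
    """Co-occurrence RI from shared/unshared extent: ``1 - S / (S + U)``.

    1 when nothing is shared (complete ecological separation), 0 when
    everything is. Undefined when S + U = 0.
    """
    s, u = sharing.shared_fraction, sharing.unshared_fraction
    if s + u <= 0:
        raise UndefinedInputError("co-occurrence RI undefined: S + U must be positive")
    return IsolationValue(1.0 - s / (s + u), "cooccurrence")


def ri_proportional(outcome: MatingOutcome) -> IsolationValue:
    """Proportional gene-flow reduction: ``1 - H / C``.

    The fraction of conspecific-level mating success lost to the barrier;
    this is the per-stage strength whose sequential cascade reproduces
    cumulative-contribution tables. Undefined when C = 0; negative when
    heterospecific crosses outperform conspecific ones.
    """
    h, c = outcome.heterospecific_success, outcome.conspecific_success
    if c <= 0:
        raise UndefinedInputError("proportional RI undefined: C must be positive")
    return IsolationValue(1.0 - h / c, "proportional")


def assemblage_sharing(
    a: SpeciesAssemblage, b: SpeciesAssemblage, method: str = "count_jaccard"
) -> SharingSummary:
    """Shared/unshared summary of two same-guild assemblages.

    ``count_jaccard``: S = |a ∩ b| / |a ∪ b| on the species lists (counts
    ignored). ``abundance_weighted``: S = fraction of all recorded
    visits/records, pooled over both populations, made by shared species;
    requires counts in both assemblages.
    """
    if a.guild != b.guild:
        raise ValidationError(f"guild mismatch: {a.guild!r} vs {b.guild!r}")
    union = a.species | b.species
    if not union:
        raise UndefinedInputError("sharing undefined for two empty assemblages")
    shared = a.species & b.species
    if method == "count_jaccard":
        s = len(shared) / len(union)
    elif method == "abundance_weighted":
        if a.counts is None or b.counts is None:
            raise ValidationError("abundance_weighted sharing requires counts in both assemblages")
        total = a.total_count + b.total_count
        if total == 0:
            raise UndefinedInputError("abundance_weighted sharing undefined: no recorded visits")
        shared_visits = sum(a.counts.get(sp, 0) + b.counts.get(sp, 0) for sp in shared)
        s = shared_visits / total
    else:
        raise ValidationError(f"unknown sharing method {method!r}")
    return SharingSummary(shared_fraction=s, unshared_fraction=1.0 - s, method=method, guild=a.guild)


def fruit_set(table: CrossingTable, group_by: list[str] | None = None) -> dict:
    """Pooled fruit set per group: sum of fruits over sum of flowers.

    ``group_by`` names columns of the crossing table; an empty list pools the
    whole table under the key ``()``. The pooled (ratio-of-sums) estimator
    matches the definition of fruit set as fruits produced over flowers
    pollinated, weighting every flower equally.
    """
    group_by = list(group_by or [])
    df = table.df
    if not group_by:
        return {(): table.total_fruits / table.total_flowers}
    sums = df.groupby(group_by, sort=True)[["fruits", "flowers"]].sum()
    out: dict = {}
    for key, row in sums.iterrows():
        key_t = key if isinstance(key, tuple) else (key,)
        out[key_t] = float(row["fruits"] / row["flowers"])
    return out


def barrier_from_crosses(
    outcome: MatingOutcome, name: str, strength_metric: str = "proportional"
) -> BarrierEstimate:
    """Build a post-pollination barrier from a heterospecific/conspecific outcome.

    The symmetric RI is always computed for display; ``strength_metric``
    selects which metric drives the cascade (default ``proportional``).
    """
    if strength_metric not in STRENGTH_METRICS:
        raise ValidationError(
            f"strength_metric must be one of {STRENGTH_METRICS}, got {strength_metric!r}"
        )
    symmetric = ri_symmetric(outcome).value
    strength = symmetric if strength_metric == "symmetric" else ri_proportional(outcome).value
    if strength < 0:
        warnings.warn(
            f"barrier {name!r} has negative strength {strength:.3f} "
            "(heterospecific advantage); propagating unclipped",
            stacklevel=2,
        )
    return BarrierEstimate(
        name=name, stage="post", strength=strength, raw=outcome, ri_symmetric=symmetric
    )


def barrier_from_sharing(sharing: SharingSummary, name: str) -> BarrierEstimate:
    """Build a pre-pollination barrier from an existing shared/unshared summary."""
    value = ri_cooccurrence(sharing).value
    return BarrierEstimate(
        name=name, stage="pre", strength=value, raw=sharing, ri_cooccurrence=value
    )


def barrier_from_assemblages(
    a: SpeciesAssemblage, b: SpeciesAssemblage, name: str, method: str = "count_jaccard"
) -> BarrierEstimate:
    """Build a pre-pollination barrier from two same-guild assemblages."""
    return barrier_from_sharing(assemblage_sharing(a, b, method=method), name)
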