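"""Domain types, delimited-file I/O, configuration, and the packaged study fixture.

The types here model the two inputs a reproductive-isolation (RI) barrier
analysis needs:

* mating outcomes — heterospecific (H) vs conspecific (C) cross success,
  typically fruit set from reciprocal hand-pollination experiments; and
* assemblage sharing — the shared (S) vs unshared (U) extent of an
  ecological resource (pollinators, host trees, seed dispersers) between
  two populations.

All proportions are stored as decimals in [0, 1]; callers holding
percentages must divide by 100 before constructing these types.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

#: Closed vocabulary of hand-pollination treatments. Unknown values are errors.
TREATMENTS = ("autogamy", "geitonogamy", "xenogamy", "open", "interspecific")

#: Ecological guilds whose assemblages can act as pre-pollination barriers.
GUILDS = ("pollinator", "disperser", "host")

#: How a shared/unshared summary was obtained.
SHARING_METHODS = ("count_jaccard", "abundance_weighted", "direct")

#: Barrier stages relative to pollen transfer.
STAGES = ("pre", "post")

CROSSING_COLUMNS = ("population", "plant_id", "treatment", "pollen_source", "flowers", "fruits")
ASSEMBLAGE_COLUMNS = ("population", "guild", "species", "count")
BARRIER_COLUMNS = ("name", "stage", "guild", "raw_a", "raw_b")


class ValidationError(ValueError):
    """An input violates a domain invariant (e.g. fruits > flowers)."""


class SchemaError(ValidationError):
    """A delimited file does not match its documented column schema."""


class UndefinedInputError(ValueError):
    """A metric is undefined for the given input (e.g. H + C = 0)."""


def normalize_species(name: str) -> str:
    """Normalize a species name: trim, collapse internal whitespace, case-fold."""
    return re.sub(r"\s+", " ", name.strip()).casefold()


# ---------------------------------------------------------------------------
# Core domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatingOutcome:
    """Heterospecific (H) and conspecific (C) mating success for one cross direction.

    Both are proportions in [0, 1]; H + C must be positive before any RI
    metric can be computed from them.
    """

    heterospecific_success: float
    conspecific_success: float
    label: str = ""

    def __post_init__(self) -> None:
        for field_name, v in (
            ("heterospecific_success", self.heterospecific_success),
            ("conspecific_success", self.conspecific_success),
        ):
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{field_name} must be in [0, 1], got {v!r}")

    @property
    def total(self) -> float:
        return self.heterospecific_success + self.conspecific_success


@dataclass(frozen=True)
class SharingSummary:
    """Shared (S) and unshared (U) extent of a resource between two populations.

    For ``count_jaccard`` and ``abundance_weighted`` the two fractions are
    complementary (S + U = 1); ``direct`` carries externally supplied values
    and only requires non-negativity.
    """

    shared_fraction: float
    unshared_fraction: float
    method: str = "direct"
    guild: Optional[str] = None

    def __post_init__(self) -> None:
        if self.method not in SHARING_METHODS:
            raise ValidationError(
                f"unknown sharing method {self.method!r}; expected one of {SHARING_METHODS}"
            )
        if self.guild is not None and self.guild not in GUILDS:
            raise ValidationError(f"unknown guild {self.guild!r}; expected one of {GUILDS}")
        if self.shared_fraction < 0 or self.unshared_fraction < 0:
            raise ValidationError("shared/unshared fractions must be non-negative")
        if self.method != "direct":
            if abs(self.shared_fraction + self.unshared_fraction - 1.0) > 1e-9:
                raise ValidationError(
                    "shared + unshared must equal 1 for method "
                    f"{self.method!r}: got {self.shared_fraction} + {self.unshared_fraction}"
                )

    @property
    def total(self) -> float:
        return self.shared_fraction + self.unshared_fraction


@dataclass(frozen=True)
class SpeciesAssemblage:
    """The species of one guild recorded in one population, optionally with counts.

    Species names are normalized (trimmed, internal whitespace collapsed,
    case-folded) so that formatting differences between data sources do not
    create spurious distinct taxa.
    """

    population: str
    guild: str
    species: frozenset[str]
    counts: Optional[Mapping[str, int]] = None

    def __post_init__(self) -> None:
        if self.guild not in GUILDS:
            raise ValidationError(f"unknown guild {self.guild!r}; expected one of {GUILDS}")
        normalized = frozenset(normalize_species(s) for s in self.species)
        if len(normalized) != len(self.species):
            raise ValidationError(
                f"species names collide after normalization in {self.population}/{self.guild}"
            )
        object.__setattr__(self, "species", normalized)
        if self.counts is not None:
            counts = {normalize_species(k): int(v) for k, v in self.counts.items()}
            if any(v < 0 for v in counts.values()):
                raise ValidationError("species counts must be non-negative")
            unknown = set(counts) - self.species
            if unknown:
                raise ValidationError(f"counts given for species not in assemblage: {sorted(unknown)}")
            object.__setattr__(self, "counts", counts)

    @property
    def total_count(self) -> int:
        return 0 if self.counts is None else sum(self.counts.values())


@dataclass(frozen=True)
class BarrierEstimate:
    """One named isolating barrier with its stage and strength.

    ``strength`` is the value fed to the sequential cascade. Pre-pollination
    barriers carry a :class:`SharingSummary` payload and use the co-occurrence
    metric; post-pollination barriers carry a :class:`MatingOutcome` and may
    use either the symmetric or the proportional metric (both are retained so
    reports can display one while the cascade consumes the other).
    """

    name: str
    stage: str
    strength: float
    raw: Union[MatingOutcome, SharingSummary]
    ri_symmetric: Optional[float] = None
    ri_cooccurrence: Optional[float] = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.stage == "pre" and not isinstance(self.raw, SharingSummary):
            raise ValidationError("pre-pollination barriers require a SharingSummary payload")
        if self.stage == "post" and not isinstance(self.raw, MatingOutcome):
            raise ValidationError("post-pollination barriers require a MatingOutcome payload")


@dataclass(frozen=True)
class CascadeResult:
    """Ordered cumulative contributions of sequential barriers.

    ``absolute[n]`` is the share of total gene flow removed by barrier n given
    everything upstream already acted; ``relative[n]`` is that share divided by
    the (unrounded) total. ``relative`` is ``None`` when the total is zero.
    """

    order: tuple[str, ...]
    strengths: tuple[float, ...]
    absolute: tuple[float, ...]
    relative: Optional[tuple[float, ...]]
    total: float

    def __post_init__(self) -> None:
        n = len(self.order)
        if not (len(self.strengths) == len(self.absolute) == n):
            raise ValidationError("order, strengths and absolute must have equal length")
        if self.relative is not None and len(self.relative) != n:
            raise ValidationError("relative must match the number of barriers")
        if abs(self.total - sum(self.absolute)) > 1e-12:
            raise ValidationError("total must equal the sum of absolute contributions")
        if self.relative is not None and abs(sum(self.relative) - 1.0) > 1e-9:
            raise ValidationError("relative contributions must sum to 1")


# ---------------------------------------------------------------------------
# Crossing tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrossingRecord:
    population: str
    plant_id: str
    treatment: str
    pollen_source: str
    flowers: int
    fruits: int


class CrossingTable:
    """Per-plant hand-pollination records: flowers treated and fruits set.

    Thin validated wrapper around a :class:`pandas.DataFrame` with columns
    ``population, plant_id, treatment, pollen_source, flowers, fruits``.
    """

    def __init__(self, df: pd.DataFrame):
        self._df = self._validate(df)

    @staticmethod
    def _validate(df: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in CROSSING_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"crossing table missing column(s): {', '.join(missing)}")
        extra = [c for c in df.columns if c not in CROSSING_COLUMNS]
        if extra:
            raise SchemaError(f"crossing table has unknown column(s): {', '.join(extra)}")
        df = df[list(CROSSING_COLUMNS)].copy()
        df["flowers"] = df["flowers"].astype(int)
        df["fruits"] = df["fruits"].astype(int)
        for col in ("population", "plant_id", "treatment", "pollen_source"):
            df[col] = df[col].astype(str)
        for i, row in enumerate(df.itertuples(index=False), start=1):
            if row.treatment not in TREATMENTS:
                raise ValidationError(
                    f"row {i}: unknown treatment {row.treatment!r}; expected one of {TREATMENTS}"
                )
            if row.flowers < 1:
                raise ValidationError(f"row {i}: flowers must be >= 1, got {row.flowers}")
            if row.fruits < 0:
                raise ValidationError(f"row {i}: fruits must be >= 0, got {row.fruits}")
            if row.fruits > row.flowers:
                raise ValidationError(
                    f"row {i}: fruits ({row.fruits}) exceed flowers ({row.flowers})"
                )
            if row.treatment == "interspecific" and row.pollen_source == row.population:
                raise ValidationError(
                    f"row {i}: interspecific cross requires pollen_source != population"
                )
        return df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[CrossingRecord | Mapping]) -> "CrossingTable":
        rows = []
        for r in records:
            if isinstance(r, CrossingRecord):
                rows.append(r.__dict__)
            else:
                rows.append(dict(r))
        return cls(pd.DataFrame(rows, columns=list(CROSSING_COLUMNS)))

    @property
    def df(self) -> pd.DataFrame:
        return self._df.copy()

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CrossingTable):
            return NotImplemented
        return self._df.equals(other._df)

    def records(self) -> list[CrossingRecord]:
        return [CrossingRecord(**row) for row in self._df.to_dict("records")]

    @property
    def total_fruits(self) -> int:
        return int(self._df["fruits"].sum())

    @property
    def total_flowers(self) -> int:
        return int(self._df["flowers"].sum())


def read_crossing_table(path: Union[str, Path]) -> CrossingTable:
    """Read a crossing-experiment CSV and validate every record.

    Schema: ``population,plant_id,treatment,pollen_source,flowers,fruits``.
    Raises :class:`SchemaError` for missing/unknown columns and
    :class:`ValidationError` (with the offending row number) for records
    violating ``fruits <= flowers`` or the treatment vocabulary.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return CrossingTable(df)


def write_crossing_table(table: CrossingTable, path: Union[str, Path]) -> None:
    table.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Assemblage tables
# ---------------------------------------------------------------------------


def read_assemblage_table(path: Union[str, Path]) -> list[SpeciesAssemblage]:
    """Read an assemblage CSV into one :class:`SpeciesAssemblage` per (population, guild).

    Schema: ``population,guild,species[,count]`` — the count column is
    optional and individual counts may be blank. Species names are
    normalized; rows that normalize to the same species have their counts
    summed, but an exact duplicate row is rejected as a data error.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        required = ["population", "guild", "species"]
        missing = [c for c in required if c not in header]
        if missing:
            raise SchemaError(f"assemblage table missing column(s): {', '.join(missing)}")
        extra = [c for c in header if c not in ASSEMBLAGE_COLUMNS]
        if extra:
            raise SchemaError(f"assemblage table has unknown column(s): {', '.join(extra)}")
        has_count = "count" in header

        seen_raw: set[tuple[str, str, str]] = set()
        acc: dict[tuple[str, str], dict[str, Optional[int]]] = {}
        for i, row in enumerate(reader, start=2):
            pop, guild, raw_species = row["population"], row["guild"], row["species"]
            key_raw = (pop, guild, raw_species)
            if key_raw in seen_raw:
                raise ValidationError(f"line {i}: duplicate row for {key_raw}")
            seen_raw.add(key_raw)
            sp = normalize_species(raw_species)
            count: Optional[int] = None
            if has_count and row.get("count", "") != "":
                count = int(row["count"])
                if count < 0:
                    raise ValidationError(f"line {i}: negative count {count}")
            bucket = acc.setdefault((pop, guild), {})
            if sp in bucket:
                prev = bucket[sp]
                bucket[sp] = (prev or 0) + (count or 0) if (prev is not None or count is not None) else None
            else:
                bucket[sp] = count

    out = []
    for (pop, guild), species_counts in acc.items():
        counts = {k: v for k, v in species_counts.items() if v is not None}
        out.append(
            SpeciesAssemblage(
                population=pop,
                guild=guild,
                species=frozenset(species_counts),
                counts=counts or None,
            )
        )
    return out


def write_assemblage_table(assemblages: Sequence[SpeciesAssemblage], path: Union[str, Path]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ASSEMBLAGE_COLUMNS)
        for a in assemblages:
            for sp in sorted(a.species):
                count = "" if a.counts is None or sp not in a.counts else a.counts[sp]
                writer.writerow([a.population, a.guild, sp, count])


# ---------------------------------------------------------------------------
# Barrier tables (raw inputs for the cascade)
# ---------------------------------------------------------------------------


def read_barrier_table(path) -> list[tuple[str, str, Union[MatingOutcome, SharingSummary]]]:
    """Read raw barrier inputs: ``name,stage,guild,raw_a,raw_b``.

    For ``pre`` rows ``raw_a``/``raw_b`` are the shared/unshared fractions;
    for ``post`` rows they are the heterospecific/conspecific successes.
    Returns (name, stage, payload) triples in file order.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        if list(header) != list(BARRIER_COLUMNS):
            raise SchemaError(
                f"barrier table header must be {','.join(BARRIER_COLUMNS)}, got {','.join(header)}"
            )
        out: list[tuple[str, str, Union[MatingOutcome, SharingSummary]]] = []
        for i, row in enumerate(reader, start=2):
            stage = row["stage"]
            a, b = float(row["raw_a"]), float(row["raw_b"])
            if stage == "pre":
                guild = row["guild"] or None
                payload: Union[MatingOutcome, SharingSummary] = SharingSummary(
                    shared_fraction=a, unshared_fraction=b, method="direct", guild=guild
                )
            elif stage == "post":
                payload = MatingOutcome(
                    heterospecific_success=a, conspecific_success=b, label=row["name"]
                )
            else:
                raise ValidationError(f"line {i}: stage must be 'pre' or 'post', got {stage!r}")
            out.append((row["name"], stage, payload))
        return out


def write_barrier_table(
    rows: Sequence[tuple[str, str, Union[MatingOutcome, SharingSummary]]],
    path: Union[str, Path],
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(BARRIER_COLUMNS)
        for name, stage, payload in rows:
            if isinstance(payload, SharingSummary):
                writer.writerow([name, stage, payload.guild or "", payload.shared_fraction, payload.unshared_fraction])
            else:
                writer.writerow([name, stage, "", payload.heterospecific_success, payload.conspecific_success])


# ---------------------------------------------------------------------------
# Synthetic-experiment configuration
# ---------------------------------------------------------------------------


@dataclass
class SyntheticConfig:
    """Parameters for the synthetic crossing/assemblage/visitation generators.

    ``success_probs`` maps population -> treatment -> per-flower fruit-set
    probability; the ``interspecific`` entry of a population is the success of
    pollen arriving *from the other population* onto that population's
    flowers. ``plant_sd`` is the between-plant spread on the logit scale
    (0 recovers iid Bernoulli flowers). ``species_pool`` holds the two
    assemblage sizes per guild and ``overlap_target`` the desired Jaccard
    sharing. ``visit_proportions``/``visit_totals`` drive the multinomial
    visitation generator.
    """

    seed: int = 0
    n_plants: int = 10
    flowers_per_plant: int = 3
    plant_sd: float = 0.0
    success_probs: dict[str, dict[str, float]] = field(default_factory=dict)
    species_pool: dict[str, tuple[int, int]] = field(default_factory=dict)
    overlap_target: dict[str, float] = field(default_factory=dict)
    visit_totals: dict[str, int] = field(default_factory=dict)
    visit_proportions: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_plants < 0 or self.flowers_per_plant < 0:
            raise ValidationError("counts must be non-negative")
        if self.plant_sd < 0:
            raise ValidationError("plant_sd must be non-negative")
        for pop, probs in self.success_probs.items():
            for treatment, p in probs.items():
                if treatment not in TREATMENTS:
                    raise ValidationError(
                        f"unknown treatment {treatment!r} in success_probs[{pop!r}]"
                    )
                if not (0.0 <= p <= 1.0):
                    raise ValidationError(
                        f"success_probs[{pop!r}][{treatment!r}] must be in [0, 1], got {p}"
                    )
        self.species_pool = {g: tuple(v) for g, v in self.species_pool.items()}
        for g, sizes in self.species_pool.items():
            if g not in GUILDS:
                raise ValidationError(f"unknown guild {g!r} in species_pool")
            if len(sizes) != 2 or any(s < 0 for s in sizes):
                raise ValidationError(f"species_pool[{g!r}] must be two non-negative sizes")
        for g, t in self.overlap_target.items():
            if not (0.0 <= t <= 1.0):
                raise ValidationError(f"overlap_target[{g!r}] must be in [0, 1], got {t}")
        for pop, total in self.visit_totals.items():
            if total < 0:
                raise ValidationError(f"visit_totals[{pop!r}] must be >= 0")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_plants": self.n_plants,
            "flowers_per_plant": self.flowers_per_plant,
            "plant_sd": self.plant_sd,
            "success_probs": {p: dict(t) for p, t in self.success_probs.items()},
            "species_pool": {g: list(v) for g, v in self.species_pool.items()},
            "overlap_target": dict(self.overlap_target),
            "visit_totals": dict(self.visit_totals),
            "visit_proportions": {p: dict(t) for p, t in self.visit_proportions.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        if "species_pool" in d:
            d["species_pool"] = {g: tuple(v) for g, v in d["species_pool"].items()}
        return cls(**d)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# Packaged study fixture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyFixture:
    """The published worked example: five raw barrier inputs in study order,
    plus the two sympatric hummingbird-pollinator assemblages."""

    barriers: tuple[tuple[str, str, Union[MatingOutcome, SharingSummary]], ...]
    assemblages: tuple[SpeciesAssemblage, ...]

    def barrier_raw(self, name: str) -> Union[MatingOutcome, SharingSummary]:
        for n, _stage, payload in self.barriers:
            if n == name:
                return payload
        raise KeyError(name)

    def assemblage(self, population: str, guild: str = "pollinator") -> SpeciesAssemblage:
        for a in self.assemblages:
            if a.population == population and a.guild == guild:
                return a
        raise KeyError((population, guild))


def _data_path(name: str):
    return resources.files("ribarriers.data").joinpath(name)


def load_study_fixture() -> StudyFixture:
    """Load the packaged mistletoe study inputs.

    Returns the five barriers in the study's cascade order — host trees,
    seed dispersers, hummingbird pollinators, then the two reciprocal
    interspecific cross directions — with their raw shared/unshared or
    heterospecific/conspecific values, and the two sympatric pollinator
    assemblages with observed visit counts.
    """
    with resources.as_file(_data_path("study_barriers.csv")) as p:
        barriers = tuple(read_barrier_table(p))
    with resources.as_file(_data_path("study_assemblages.csv")) as p:
        assemblages = tuple(read_assemblage_table(p))
    return StudyFixture(barriers=barriers, assemblages=assemblages)


#: Cascade order used in the published analysis.
STUDY_BARRIER_ORDER = (
    "Host species isolation",
    "Seed dispersers isolation",
    "Pollinator isolation",
    "CO Fruit set",
    "AO Fruit set",
)
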