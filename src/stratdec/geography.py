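"""Areas, range states, epoch-stratified dispersal multipliers, and tip coding.

A geographic *range* is a subset of K discrete areas, encoded as a bitmask
(bit i set = area with index i occupied).  The ordered list of all non-empty
subsets — plus a distinguished empty ("null") state used only as an internal
absorbing state — is the state space of the DEC Markov chain.

Dispersal opportunity changes through geological time (continents drift), so
the dispersal multiplier matrix is stratified into epochs: contiguous,
non-overlapping time slices given in Ma before present, oldest first.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Area",
    "RangeState",
    "DispersalMultiplierMatrix",
    "EpochModel",
    "CodingTable",
    "ConfigError",
    "CodingError",
    "CODING_STRATEGIES",
    "enumerate_ranges",
    "load_coding",
    "write_coding",
    "validate_epochs",
    "load_area_config",
]

#: The three terminal-coding strategies for widespread higher taxa:
#: "anything-goes" codes them as present everywhere, "exemplar" uses only the
#: sampled genus's own range, "ancestral-inference" uses the best available
#: reconstruction for the clade the terminal represents.
CODING_STRATEGIES = ("anything-goes", "exemplar", "ancestral-inference")


class ConfigError(ValueError):
    """Invalid area/epoch configuration."""


class CodingError(ValueError):
    """Invalid terminal-to-area coding."""


@dataclass(frozen=True)
class Area:
    name: str
    index: int


@dataclass(frozen=True, order=True)
class RangeState:
    """A subset of areas as a bitmask over K areas."""

    bits: int
    n_areas: int

    def __post_init__(self) -> None:
        if self.bits < 0 or self.bits >= (1 << self.n_areas):
            raise ConfigError(
                f"bitmask {self.bits} out of range for {self.n_areas} areas"
            )

    @property
    def size(self) -> int:
        return self.bits.bit_count()

    @property
    def is_null(self) -> bool:
        return self.bits == 0

    def areas(self) -> tuple[int, ...]:
        return tuple(i for i in range(self.n_areas) if self.bits >> i & 1)

    def label(self, names: Sequence[str] | None = None) -> str:
        if self.is_null:
            return "null"
        if names is None:
            names = [chr(ord("A") + i) for i in range(self.n_areas)]
        return "+".join(names[i] for i in self.areas())

    @classmethod
    def from_areas(cls, areas: Iterable[int], n_areas: int) -> "RangeState":
        bits = 0
        for a in areas:
            bits |= 1 << a
        return cls(bits, n_areas)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label()


@dataclass(frozen=True)
class DispersalMultiplierMatrix:
    """K x K multipliers m[i][j] in [0, 1] scaling dispersal from area i to j.

    The diagonal is ignored (there is no self-dispersal).  Symmetric matrices
    are the common case but asymmetric input is accepted.
    """

    m: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.m, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ConfigError(f"multiplier matrix must be square, got {arr.shape}")
        off = arr[~np.eye(arr.shape[0], dtype=bool)]
        if off.size and (off.min() < 0.0 or off.max() > 1.0):
            raise ConfigError("dispersal multipliers must lie in [0, 1]")
        object.__setattr__(self, "m", arr)

    @property
    def n_areas(self) -> int:
        return self.m.shape[0]

    @classmethod
    def ones(cls, n_areas: int) -> "DispersalMultiplierMatrix":
        return cls(np.ones((n_areas, n_areas)))


@dataclass(frozen=True)
class EpochSlice:
    older_bound: float  # Ma, exclusive start of the slice going forward in time
    younger_bound: float  # Ma
    multipliers: DispersalMultiplierMatrix

    def __post_init__(self) -> None:
        if self.older_bound <= self.younger_bound:
            raise ConfigError(
                f"epoch slice bounds must decrease toward the present: "
                f"{self.older_bound}-{self.younger_bound} Ma"
            )


@dataclass(frozen=True)
class EpochModel:
    """Ordered geological time slices, oldest first, youngest ending at 0 Ma.

    A time t (Ma) belongs to the slice with older_bound >= t > younger_bound,
    i.e. slices are half-open [older, younger) running toward the present; the
    youngest slice also contains t = 0.
    """

    slices: tuple[EpochSlice, ...]

    def __post_init__(self) -> None:
        if not self.slices:
            raise ConfigError("epoch model needs at least one slice")
        object.__setattr__(self, "slices", tuple(self.slices))
        k = self.slices[0].multipliers.n_areas
        for s in self.slices:
            if s.multipliers.n_areas != k:
                raise ConfigError("all epoch multiplier matrices must share K")
        for older, younger in itertools.pairwise(self.slices):
            if abs(older.younger_bound - younger.older_bound) > 1e-9:
                raise ConfigError(
                    f"epoch slices must be contiguous: gap/overlap between "
                    f"{older.older_bound}-{older.younger_bound} and "
                    f"{younger.older_bound}-{younger.younger_bound} Ma"
                )
        if abs(self.slices[-1].younger_bound) > 1e-9:
            raise ConfigError("youngest epoch slice must end at 0 Ma")

    @property
    def n_areas(self) -> int:
        return self.slices[0].multipliers.n_areas

    @property
    def oldest_bound(self) -> float:
        return self.slices[0].older_bound

    def slice_index_at(self, age: float) -> int:
        """Index of the slice containing time ``age`` Ma."""
        if age > self.oldest_bound + 1e-9 or age < 0:
            raise ConfigError(f"age {age} Ma outside epoch span")
        for i, s in enumerate(self.slices):
            if age > s.younger_bound + 1e-12:
                return i
        return len(self.slices) - 1

    @classmethod
    def single(cls, mult: DispersalMultiplierMatrix, older_bound: float) -> "EpochModel":
        return cls((EpochSlice(older_bound, 0.0, mult),))

    @classmethod
    def uniform(cls, bounds: Sequence[float], n_areas: int) -> "EpochModel":
        """Epoch model with all multipliers 1.0 and the given boundary ages.

        ``bounds`` are the slice boundaries oldest-first, ending at 0, e.g.
        ``[105, 80, 50, 30, 0]``.
        """
        ones = DispersalMultiplierMatrix.ones(n_areas)
        return cls(
            tuple(
                EpochSlice(a, b, ones) for a, b in itertools.pairwise(bounds)
            )
        )


def default_epoch_bounds() -> list[float]:
    """The four-interval Gondwanan break-up frame: 105-80, 80-50, 50-30, 30-0 Ma."""
    return [105.0, 80.0, 50.0, 30.0, 0.0]


def enumerate_ranges(n_areas: int, max_size: int | None = None) -> list[RangeState]:
    """All non-empty ranges over ``n_areas`` areas, plus the null state last.

    Order is deterministic: by range size, then by bitmask value.  The null
    range is appended as a distinguished final state; it is used internally as
    the absorbing "extinct everywhere" state and is never a valid tip or
    ancestral range.
    """
    if n_areas < 1:
        raise ConfigError("need at least one area")
    if max_size is not None and (max_size < 1 or max_size > n_areas):
        raise ConfigError(f"max_size {max_size} not in [1, {n_areas}]")
    cap = n_areas if max_size is None else max_size
    states = [
        RangeState(bits, n_areas)
        for bits in range(1, 1 << n_areas)
        if bits.bit_count() <= cap
    ]
    states.sort(key=lambda r: (r.size, r.bits))
    states.append(RangeState(0, n_areas))
    return states


@dataclass
class CodingTable:
    """Terminal label -> observed RangeState under one coding strategy."""

    strategy: str
    assignments: dict[str, RangeState]
    area_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for label, rng in self.assignments.items():
            if rng.is_null:
                raise CodingError(f"terminal {label!r} coded with an empty range")

    @property
    def n_areas(self) -> int:
        return next(iter(self.assignments.values())).n_areas

    def require(self, labels: Iterable[str]) -> None:
        missing = sorted(set(labels) - set(self.assignments))
        if missing:
            raise CodingError(f"terminals without a range coding: {missing}")


def load_coding(
    path: str | Path,
    strategy: str,
    area_names: Sequence[str] | None = None,
) -> CodingTable:
    """Read a coding table (CSV/TSV) for one strategy.

    Expected columns: ``terminal`` plus one 0/1 column per area named
    ``<strategy>.<area>``.  Rows coding a terminal to no area at all are
    rejected — the null range is not observable at a tip.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    return coding_from_frame(df, strategy, area_names)


def coding_from_frame(
    df: pd.DataFrame,
    strategy: str,
    area_names: Sequence[str] | None = None,
) -> CodingTable:
    if "terminal" not in df.columns:
        raise CodingError("coding table must have a 'terminal' column")
    prefix = f"{strategy}."
    cols = [c for c in df.columns if c.startswith(prefix)]
    if not cols:
        known = sorted({c.split(".", 1)[0] for c in df.columns if "." in c})
        raise CodingError(
            f"unknown coding strategy {strategy!r}; table provides {known}"
        )
    names = tuple(c[len(prefix):] for c in cols)
    if area_names is not None:
        if set(names) != set(area_names):
            raise CodingError(
                f"coding areas {sorted(names)} do not match configured areas "
                f"{sorted(area_names)}"
            )
        cols = [prefix + a for a in area_names]
        names = tuple(area_names)
    k = len(names)
    assignments: dict[str, RangeState] = {}
    for _, row in df.iterrows():
        label = str(row["terminal"])
        vals = row[cols].to_numpy()
        if not np.isin(vals, [0, 1]).all():
            raise CodingError(f"terminal {label!r}: coding values must be 0/1")
        bits = int(sum(1 << i for i, v in enumerate(vals) if v == 1))
        if bits == 0:
            raise CodingError(
                f"terminal {label!r} is coded absent from every area"
            )
        if label in assignments:
            raise CodingError(f"duplicate terminal {label!r} in coding table")
        assignments[label] = RangeState(bits, k)
    if not assignments:
        raise CodingError("coding table is empty")
    return CodingTable(strategy=strategy, assignments=assignments, area_names=names)


def write_coding(
    tables: Mapping[str, CodingTable], path: str | Path
) -> Path:
    """Write one or more strategies' codings to a single CSV/TSV."""
    path = Path(path)
    strategies = list(tables)
    first = tables[strategies[0]]
    names = first.area_names or tuple(
        chr(ord("A") + i) for i in range(first.n_areas)
    )
    terminals = sorted(first.assignments)
    data: dict[str, list] = {"terminal": terminals}
    for strat in strategies:
        tab = tables[strat]
        for i, a in enumerate(names):
            data[f"{strat}.{a}"] = [
                tab.assignments[t].bits >> i & 1 for t in terminals
            ]
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    pd.DataFrame(data).to_csv(path, sep=sep, index=False)
    return path


def validate_epochs(model: EpochModel, root_age: float) -> EpochModel:
    """Check an epoch model against a tree's root age.

    If the root predates the oldest slice boundary the oldest slice is
    extended to cover it (the change is reported via the returned model; the
    stratification within the covered span is untouched).
    """
    if root_age <= 0:
        raise ConfigError(f"root age must be positive, got {root_age}")
    if root_age <= model.oldest_bound + 1e-9:
        return model
    old = model.slices[0]
    extended = EpochSlice(float(root_age), old.younger_bound, old.multipliers)
    return EpochModel((extended,) + model.slices[1:])


def load_area_config(path: str | Path) -> tuple[list[Area], EpochModel]:
    """Load areas + epoch model from YAML or JSON.

    Schema::

        areas: [HOL, SEA, SA, SAfr, MAD, AGC]
        epochs:
          - {from: 105, to: 80, multipliers: [[...], ...]}
          - ...

    ``multipliers`` may be omitted for an all-1.0 matrix.  Area order in the
    file fixes the bitmask/area indexing everywhere downstream.
    """
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    names = [str(a) for a in cfg.get("areas", [])]
    if not names:
        raise ConfigError("config must list at least one area")
    if len(set(names)) != len(names):
        raise ConfigError("area names must be unique")
    areas = [Area(n, i) for i, n in enumerate(names)]
    k = len(names)
    slices = []
    for ep in cfg.get("epochs", []):
        mult = ep.get("multipliers")
        mat = (
            DispersalMultiplierMatrix.ones(k)
            if mult is None
            else DispersalMultiplierMatrix(np.asarray(mult, dtype=float))
        )
        if mat.n_areas != k:
            raise ConfigError("multiplier matrix size does not match area count")
        slices.append(EpochSlice(float(ep["from"]), float(ep["to"]), mat))
    if not slices:
        raise ConfigError("config must define at least one epoch")
    return areas, EpochModel(tuple(slices))
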