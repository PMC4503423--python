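"""Taxon range records: reading, validation, and resolution to stage indices.

A range is the closed interval of stages from a family's first to last
occurrence; records may be resolved only to epoch or period.  Coarse records
are mapped to stages under one of three assumptions:

``literal``
    endpoints must already be stage-rank (error otherwise);
``maximum``
    the taxon originates in the oldest stage of its first interval and goes
    extinct in the youngest stage of its last interval (widest reading);
``minimum``
    origination in the youngest stage of the first interval, extinction in
    the oldest stage of the last interval (narrowest reading).  A coarse
    record confined to a single epoch/period has no defensible span under
    this reading and is removed.

Extant taxa always terminate at the timescale's terminal Recent pseudo-stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterator, Literal, Union

import pandas as pd

from .errors import ResolutionError, UnknownIntervalError, ValidationError
from .timescale import Timescale, _norm

logger = logging.getLogger(__name__)

Assumption = Literal["literal", "maximum", "minimum"]
ASSUMPTIONS = ("literal", "maximum", "minimum")

_TRUE = {"1", "true", "yes", "y", "t"}
_FALSE = {"0", "false", "no", "n", "f", ""}


def _parse_extant(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().casefold()
    if s in _TRUE:
        return True
    if s in _FALSE or s == "nan":
        return False
    raise ValidationError(f"unparseable extant flag {value!r}")


@dataclass(frozen=True)
class TaxonRange:
    """One family's first/last occurrence, possibly at coarse resolution."""

    taxon: str
    first_interval: str
    last_interval: str
    extant: bool = False
    group: str | None = None
    class_tag: str | None = None

    @property
    def key(self) -> str:
        """Normalized taxon name used for joins and duplicate detection."""
        return _norm(self.taxon)


@dataclass(frozen=True)
class ResolvedRange:
    """A range mapped to the ordinal stage axis; closed span [first, last]."""

    taxon: str
    first_stage: int
    last_stage: int
    extant: bool = False
    group: str | None = None

    def __post_init__(self) -> None:
        if self.first_stage > self.last_stage:
            raise ValidationError(
                f"{self.taxon!r}: first_stage {self.first_stage} > last_stage {self.last_stage}"
            )

    def __contains__(self, stage: int) -> bool:
        return self.first_stage <= stage <= self.last_stage

    @property
    def n_stages(self) -> int:
        return self.last_stage - self.first_stage + 1


@dataclass
class Dataset:
    """Named collection of taxon ranges with simple provenance metadata."""

    records: list[TaxonRange]
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TaxonRange]:
        return iter(self.records)

    def taxa(self) -> set[str]:
        return {r.key for r in self.records}

    def by_key(self) -> dict[str, TaxonRange]:
        return {r.key: r for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon": [r.taxon for r in self.records],
                "group": [r.group for r in self.records],
                "first": [r.first_interval for r in self.records],
                "last": [r.last_interval for r in self.records],
                "extant": [int(r.extant) for r in self.records],
            }
        )

    def write_csv(self, path: Union[str, PathLike]) -> None:
        self.to_frame().to_csv(path, index=False)


def read_ranges(
    source: Union[str, PathLike, pd.DataFrame],
    timescale: Timescale,
    *,
    label: str = "",
    on_duplicate: Literal["error", "warn"] = "error",
) -> Dataset:
    """Read and validate a canonical range CSV (taxon,group,first,last,extant).

    Every interval name is checked against ``timescale``; unknown names are
    reported with their row numbers.  Duplicate taxon names (after
    normalization) are an error by default.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    required = {"taxon", "first", "last"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"range table lacks columns {sorted(missing)}")
    if df.empty:
        warnings.warn(f"range table {label or source!r} is empty", stacklevel=2)
        return Dataset([], label=label)

    bad_rows = []
    records: list[TaxonRange] = []
    seen: dict[str, int] = {}
    for pos, (_, row) in enumerate(df.iterrows()):
        first, last = str(row["first"]).strip(), str(row["last"]).strip()
        for name in (first, last):
            if name not in timescale:
                bad_rows.append((pos, str(row["taxon"]), name))
        if bad_rows and bad_rows[-1][0] == pos:
            continue
        rec = TaxonRange(
            taxon=" ".join(str(row["taxon"]).split()),
            first_interval=timescale[first].name,
            last_interval=timescale[last].name,
            extant=_parse_extant(row["extant"]) if "extant" in df.columns else False,
            group=(str(row["group"]).strip() or None)
            if "group" in df.columns and pd.notna(row["group"])
            else None,
        )
        if rec.key in seen:
            msg = f"duplicate taxon {rec.taxon!r} (rows {seen[rec.key]} and {pos})"
            if on_duplicate == "error":
                raise ValidationError(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        seen[rec.key] = pos
        _check_order(rec, timescale)
        records.append(rec)

    if bad_rows:
        listing = "; ".join(f"row {i} ({t!r}): {n!r}" for i, t, n in bad_rows[:20])
        raise UnknownIntervalError(
            f"{len(bad_rows)} row(s) name intervals absent from the timescale: {listing}"
        )
    return Dataset(records, label=label)


def _check_order(r: TaxonRange, timescale: Timescale) -> None:
    """Reject ranges whose first interval is younger than the last (via oldest stages)."""
    f0 = timescale.stages_of(r.first_interval)[0].index
    l0 = timescale.stages_of(r.last_interval)[0].index
    if f0 > l0:
        raise ValidationError(
            f"{r.taxon!r}: first interval {r.first_interval!r} is younger than "
            f"last interval {r.last_interval!r}"
        )


def resolve_range(
    r: TaxonRange,
    timescale: Timescale,
    assumption: Assumption = "literal",
) -> ResolvedRange | None:
    """Map a range to stage indices under the given resolution assumption.

    Returns ``None`` when the record is removed under the ``minimum``
    assumption (coarse and confined to one interval).  Stage-resolved records
    are unchanged under every assumption.
    """
    if assumption not in ASSUMPTIONS:
        raise ValueError(f"unknown assumption {assumption!r}")
    first_stages = timescale.stages_of(r.first_interval)
    last_stages = timescale.stages_of(r.last_interval)
    coarse = len(first_stages) > 1 or len(last_stages) > 1

    if assumption == "literal":
        if coarse:
            raise ResolutionError(
                f"{r.taxon!r}: endpoint(s) at {timescale[r.first_interval].rank}/"
                f"{timescale[r.last_interval].rank} rank cannot be resolved literally"
            )
        first, last = first_stages[0].index, last_stages[0].index
    elif assumption == "maximum":
        first, last = first_stages[0].index, last_stages[-1].index
    else:  # minimum
        same_interval = _norm(r.first_interval) == _norm(r.last_interval)
        if coarse and same_interval:
            return None
        first, last = first_stages[-1].index, last_stages[0].index

    if r.extant and timescale.has_recent:
        last = timescale.recent.index
    assert first is not None and last is not None
    return ResolvedRange(
        taxon=r.taxon, first_stage=first, last_stage=last, extant=r.extant, group=r.group
    )


def resolve_dataset(
    d: Dataset,
    timescale: Timescale,
    assumption: Assumption = "literal",
) -> tuple[list[ResolvedRange], int]:
    """Resolve every record; returns (resolved ranges, count removed)."""
    resolved: list[ResolvedRange] = []
    dropped = 0
    for r in d:
        rr = resolve_range(r, timescale, assumption)
        if rr is None:
            dropped += 1
        else:
            resolved.append(rr)
    if dropped:
        logger.info(
            "%d record(s) removed under the %s assumption (coarse single-interval)",
            dropped,
            assumption,
        )
    return resolved, dropped


def restrict_to_group(d: Dataset, tag: str) -> Dataset:
    """Subset of ``d`` whose group tag matches ``tag`` (case-insensitive)."""
    key = _norm(tag)
    records = [r for r in d if r.group is not None and _norm(r.group) == key]
    if not records:
        warnings.warn(f"no records carry group tag {tag!r}", stacklevel=2)
    return Dataset(records, label=f"{d.label}[{tag}]" if d.label else tag)
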