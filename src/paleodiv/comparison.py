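"""Family-by-family diff between two versions of a range compendium.

Every family in the union of the two datasets receives exactly one category:

* ``no_change``   — identical resolved stage sets;
* ``new_in_list`` — present only in the new dataset;
* ``contraction`` — the new range covers fewer stages than the old;
* ``extension``   — the new range covers more stages (non-overlap allowed:
  a range can move wholesale and still count as an extension if it grew);
* ``shift``       — a different set of stages but the same total number;
* ``range_change``— a changed range that is not sub-typed (used when the old
  record is coarse, so stage-level sub-typing is not meaningful);
* ``removed``     — present only in the old dataset (synonymized, subsumed,
  or no longer considered to have a fossil record).

Two old-record policies are supported.  ``stage`` requires the old dataset at
stage resolution and sub-types every range change.  ``confirm`` accepts
coarse old records: the comparison declares ``no_change`` when the new
stage range confirms presence throughout exactly the old record's (maximally
read) span, and otherwise emits an unsubtyped ``range_change``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import pandas as pd

from .errors import ConfigError
from .ranges import Dataset, TaxonRange, resolve_range
from .timescale import Timescale, _norm

CATEGORIES = (
    "no_change",
    "new_in_list",
    "contraction",
    "extension",
    "shift",
    "range_change",
    "removed",
)
NEW_SIDE_CATEGORIES = tuple(c for c in CATEGORIES if c != "removed")

OldResolutionPolicy = Literal["stage", "confirm"]


@dataclass(frozen=True)
class ChangeRecord:
    taxon: str
    category: str
    old_first: str | None = None
    old_last: str | None = None
    new_first: str | None = None
    new_last: str | None = None
    old_n_stages: int | None = None
    new_n_stages: int | None = None


@dataclass
class ComparisonSummary:
    """Counts and proportions per category.

    Proportions are over taxa present in the new dataset (``removed`` is
    tallied but excluded from the denominator, mirroring how revision
    proportions are quoted against the current list).
    """

    counts: dict[str, int]
    proportions: dict[str, float]
    denominator: int
    removed: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"category": c, "count": self.counts.get(c, 0), "proportion": self.proportions.get(c, float("nan"))}
            for c in CATEGORIES
        ]
        return pd.DataFrame(rows)


def _stage_set(r: TaxonRange, ts: Timescale, assumption: str) -> frozenset[int]:
    rr = resolve_range(r, ts, assumption)
    assert rr is not None  # literal/maximum never drop records
    return frozenset(range(rr.first_stage, rr.last_stage + 1))


def _is_coarse(r: TaxonRange, ts: Timescale) -> bool:
    return (
        ts[r.first_interval].rank != "stage" or ts[r.last_interval].rank != "stage"
    )


def compare_datasets(
    new: Dataset,
    old: Dataset,
    timescale: Timescale,
    old_resolution_policy: OldResolutionPolicy = "stage",
    *,
    synonymy: Mapping[str, str] | None = None,
) -> list[ChangeRecord]:
    """Categorize every family in the union of ``new`` and ``old``.

    ``synonymy`` optionally maps old taxon names onto their new-list names
    before the join (an old family subsumed elsewhere then counts against its
    new home rather than as removed).
    """
    new_by = new.by_key()
    old_by: dict[str, TaxonRange] = {}
    syn = { _norm(k): v for k, v in (synonymy or {}).items() }
    for r in old:
        key = _norm(syn.get(r.key, r.taxon))
        if key in old_by:
            raise ConfigError(f"old dataset has duplicate taxon {r.taxon!r} after synonymy")
        old_by[key] = r

    records: list[ChangeRecord] = []
    for key, nr in new_by.items():
        new_set = _stage_set(nr, timescale, "literal" if not _is_coarse(nr, timescale) else "maximum")
        if key not in old_by:
            records.append(
                ChangeRecord(
                    taxon=nr.taxon,
                    category="new_in_list",
                    new_first=nr.first_interval,
                    new_last=nr.last_interval,
                    new_n_stages=len(new_set),
                )
            )
            continue
        orr = old_by[key]
        coarse_old = _is_coarse(orr, timescale)
        if old_resolution_policy == "stage" and coarse_old:
            raise ConfigError(
                f"old record {orr.taxon!r} is not stage-resolved; use the 'confirm' policy"
            )
        old_set = _stage_set(orr, timescale, "maximum" if coarse_old else "literal")

        if new_set == old_set:
            category = "no_change"
        elif coarse_old:
            category = "range_change"
        elif len(new_set) < len(old_set):
            category = "contraction"
        elif len(new_set) > len(old_set):
            category = "extension"
        else:
            category = "shift"
        records.append(
            ChangeRecord(
                taxon=nr.taxon,
                category=category,
                old_first=orr.first_interval,
                old_last=orr.last_interval,
                new_first=nr.first_interval,
                new_last=nr.last_interval,
                old_n_stages=len(old_set),
                new_n_stages=len(new_set),
            )
        )

    for key, orr in old_by.items():
        if key not in new_by:
            records.append(
                ChangeRecord(
                    taxon=orr.taxon,
                    category="removed",
                    old_first=orr.first_interval,
                    old_last=orr.last_interval,
                )
            )
    return records


def summarize(records: Iterable[ChangeRecord]) -> ComparisonSummary:
    """Category counts and proportions over the new-dataset taxa."""
    counts: dict[str, int] = {c: 0 for c in CATEGORIES}
    for rec in records:
        if rec.category not in counts:
            raise ValueError(f"unknown category {rec.category!r}")
        counts[rec.category] += 1
    removed = counts["removed"]
    denom = sum(counts[c] for c in NEW_SIDE_CATEGORIES)
    proportions = {
        c: (counts[c] / denom if denom else float("nan")) for c in NEW_SIDE_CATEGORIES
    }
    return ComparisonSummary(
        counts=counts, proportions=proportions, denominator=denom, removed=removed
    )


def records_to_frame(records: Iterable[ChangeRecord]) -> pd.DataFrame:
    """Tabulate change records (taxon,category,old_first,old_last,new_first,new_last)."""
    return pd.DataFrame(
        [
            {
                "taxon": r.taxon,
                "category": r.category,
                "old_first": r.old_first,
                "old_last": r.old_last,
                "new_first": r.new_first,
                "new_last": r.new_last,
            }
            for r in records
        ]
    )
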