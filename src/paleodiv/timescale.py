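"""Ordered geological timescale: stages, their parents, durations and midpoints.

The canonical time axis is the ordinal index of the stage-rank intervals,
increasing toward the present; ages in Ma are carried as metadata.  A terminal
``Recent`` pseudo-stage with ``top_age == 0`` makes extant taxa ordinary
boundary-crossers.  The packaged default table is a transcription of the
2008 ICS-based chart, stages from the Lochkovian to the Recent; any CSV with
the same schema can be substituted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from os import PathLike
from typing import Iterable, Union

import pandas as pd

from .errors import TimescaleStructureError, UnknownIntervalError

RANKS = ("stage", "epoch", "period", "era", "special")

#: Relative tolerance used when checking that consecutive stage boundaries meet.
_AGE_RTOL = 1e-9
_AGE_ATOL = 1e-6


def _norm(name: str) -> str:
    """Normalize an interval name for lookup: trim, collapse whitespace, casefold."""
    return " ".join(str(name).split()).casefold()


@dataclass(frozen=True)
class Interval:
    """A named geological time bin.

    ``base_age`` is the older bound and ``top_age`` the younger, both in Ma;
    ``index`` is the ordinal position among stage-rank intervals (increasing
    toward the present) and is ``None`` for coarser ranks.
    """

    name: str
    rank: str
    base_age: float
    top_age: float
    parent: str | None = None
    index: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise TimescaleStructureError(
                f"{self.name!r}: unknown rank {self.rank!r} (expected one of {RANKS})"
            )
        if not (self.base_age > self.top_age >= 0):
            raise TimescaleStructureError(
                f"{self.name!r}: require base_age > top_age >= 0, "
                f"got base={self.base_age}, top={self.top_age}"
            )

    @property
    def midpoint(self) -> float:
        return (self.base_age + self.top_age) / 2.0

    @property
    def duration(self) -> float:
        """Interval length in Myr."""
        return self.base_age - self.top_age


class Timescale:
    """Validated, ordered collection of intervals.

    Stages must tile time without gaps or overlaps; every epoch/period/era
    must cover a non-empty contiguous run of stages; names must be unique
    after whitespace/case normalization.
    """

    def __init__(self, intervals: Iterable[Interval]):
        intervals = list(intervals)
        by_name: dict[str, Interval] = {}
        for iv in intervals:
            key = _norm(iv.name)
            if key in by_name:
                raise TimescaleStructureError(f"duplicate interval name {iv.name!r}")
            by_name[key] = iv

        stages = sorted(
            (iv for iv in intervals if iv.rank == "stage"),
            key=lambda iv: -iv.base_age,
        )
        if not stages:
            raise TimescaleStructureError("timescale contains no stage-rank intervals")
        for older, younger in zip(stages, stages[1:]):
            if not math.isclose(
                younger.base_age, older.top_age, rel_tol=_AGE_RTOL, abs_tol=_AGE_ATOL
            ):
                raise TimescaleStructureError(
                    f"stages {older.name!r} and {younger.name!r} do not meet: "
                    f"top({older.name})={older.top_age} vs base({younger.name})={younger.base_age}"
                )

        # Re-create stages with their ordinal index attached (oldest = 0).
        stages = [
            Interval(s.name, s.rank, s.base_age, s.top_age, s.parent, index=i)
            for i, s in enumerate(stages)
        ]
        for s in stages:
            by_name[_norm(s.name)] = s

        for iv in intervals:
            if iv.parent and _norm(iv.parent) not in by_name:
                raise UnknownIntervalError(
                    f"{iv.name!r} names unknown parent {iv.parent!r}"
                )

        self._by_name = by_name
        self._stages = stages
        self._intervals = [by_name[_norm(iv.name)] for iv in intervals]

        # Child-stage map for coarser ranks, via the parent chain.
        children: dict[str, list[Interval]] = {}
        for s in stages:
            anc = s.parent
            seen = set()
            while anc is not None:
                key = _norm(anc)
                if key in seen:
                    raise TimescaleStructureError(f"parent cycle at {anc!r}")
                seen.add(key)
                children.setdefault(key, []).append(s)
                anc = by_name[key].parent
        for key, kids in children.items():
            idx = [k.index for k in kids]
            if idx != list(range(idx[0], idx[0] + len(idx))):
                raise TimescaleStructureError(
                    f"{by_name[key].name!r} does not cover a contiguous run of stages"
                )
        for iv in intervals:
            if iv.rank != "stage" and _norm(iv.name) not in children:
                raise TimescaleStructureError(
                    f"{iv.name!r} ({iv.rank}) contains no stages"
                )
        self._children = children

    # -- lookup ---------------------------------------------------------------

    def __getitem__(self, name: str) -> Interval:
        try:
            return self._by_name[_norm(name)]
        except KeyError:
            raise UnknownIntervalError(f"unknown interval {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return _norm(name) in self._by_name

    def __len__(self) -> int:
        return len(self._intervals)

    @property
    def stages(self) -> list[Interval]:
        """All stage-rank intervals, oldest first."""
        return list(self._stages)

    @property
    def n_stages(self) -> int:
        return len(self._stages)

    @property
    def recent(self) -> Interval:
        """The terminal pseudo-stage (youngest stage; its top age must be 0)."""
        return self._stages[-1]

    @property
    def has_recent(self) -> bool:
        """True when the scale ends in a designated ``Recent`` pseudo-stage.

        The pseudo-stage is recognized by name so that closed-history scales
        that simply end at 0 Ma are not mistaken for ones carrying the
        living fauna.
        """
        last = self._stages[-1]
        return last.top_age == 0.0 and _norm(last.name) == "recent"

    def stage_at(self, index: int) -> Interval:
        return self._stages[index]

    def stage_index(self, name: str) -> int:
        iv = self[name]
        if iv.rank != "stage":
            raise UnknownIntervalError(f"{name!r} is a {iv.rank}, not a stage")
        assert iv.index is not None
        return iv.index

    # -- derived series -------------------------------------------------------

    def durations(self) -> pd.Series:
        """Stage durations in Myr, indexed by stage name, oldest first."""
        return pd.Series(
            [s.duration for s in self._stages],
            index=[s.name for s in self._stages],
            name="delta_t",
        )

    def midpoints(self) -> pd.Series:
        """Stage midpoints in Ma, indexed by stage name, oldest first."""
        return pd.Series(
            [s.midpoint for s in self._stages],
            index=[s.name for s in self._stages],
            name="midpoint",
        )

    # -- structure ------------------------------------------------------------

    def stages_of(self, name: str) -> list[Interval]:
        """Stages contained in ``name``: the singleton for a stage, else the
        contiguous run whose parent chain includes ``name``, oldest first."""
        iv = self[name]
        if iv.rank == "stage":
            return [iv]
        return list(self._children[_norm(iv.name)])

    def window(self, from_stage: str, to_stage: str) -> list[Interval]:
        """Inclusive run of stages from ``from_stage`` (older) to ``to_stage``."""
        i, j = self.stage_index(from_stage), self.stage_index(to_stage)
        if i > j:
            raise ValueError(
                f"window endpoints reversed: {from_stage!r} is younger than {to_stage!r}"
            )
        return self._stages[i : j + 1]

    def __repr__(self) -> str:
        s = self._stages
        return (
            f"<Timescale: {self.n_stages} stages, "
            f"{s[0].name} ({s[0].base_age} Ma) – {s[-1].name} ({s[-1].top_age} Ma)>"
        )


def load_timescale(source: Union[str, PathLike, pd.DataFrame]) -> Timescale:
    """Read a timescale from a CSV with columns name,rank,base_age,top_age,parent."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    required = {"name", "rank", "base_age", "top_age"}
    missing = required - set(df.columns)
    if missing:
        raise TimescaleStructureError(f"timescale table lacks columns {sorted(missing)}")
    if "parent" not in df.columns:
        df = df.assign(parent=None)
    intervals = [
        Interval(
            name=str(row["name"]).strip(),
            rank=str(row["rank"]).strip().lower(),
            base_age=float(row["base_age"]),
            top_age=float(row["top_age"]),
            parent=None if pd.isna(row["parent"]) or str(row["parent"]).strip() == "" else str(row["parent"]).strip(),
        )
        for _, row in df.iterrows()
    ]
    return Timescale(intervals)


@lru_cache(maxsize=1)
def default_timescale() -> Timescale:
    """The packaged 2008-chart stage table (Lochkovian → Recent)."""
    with resources.files("paleodiv.data").joinpath("gts2008_stages.csv").open("rb") as fh:
        return load_timescale(pd.read_csv(fh))


def uniform_timescale(
    n_stages: int,
    duration: float = 5.0,
    *,
    epoch_size: int | None = None,
    include_recent: bool = True,
) -> Timescale:
    """Synthetic timescale of ``n_stages`` equal-length stages ending at 0 Ma.

    Stages are named S01, S02, ... oldest first.  With ``include_recent`` a
    zero-duration-adjacent ``Recent`` pseudo-stage (duration = ``duration``/1000)
    is appended so extant marking behaves as on the real scale.  With
    ``epoch_size`` the stages are grouped into epochs E1, E2, ... of that many
    stages (the trailing epoch may be shorter), for coarse-resolution tests.
    """
    if n_stages < 1 or duration <= 0:
        raise ValueError("need n_stages >= 1 and duration > 0")
    recent_len = duration / 1000.0 if include_recent else 0.0
    base0 = n_stages * duration + recent_len
    intervals: list[Interval] = []
    epoch_of: dict[int, str] = {}
    if epoch_size:
        for e, start in enumerate(range(0, n_stages, epoch_size)):
            stop = min(start + epoch_size, n_stages)
            intervals.append(
                Interval(
                    name=f"E{e + 1}",
                    rank="epoch",
                    base_age=base0 - start * duration,
                    top_age=base0 - stop * duration,
                    parent=None,
                )
            )
            for k in range(start, stop):
                epoch_of[k] = f"E{e + 1}"
    for k in range(n_stages):
        intervals.append(
            Interval(
                name=f"S{k + 1:02d}",
                rank="stage",
                base_age=base0 - k * duration,
                top_age=base0 - (k + 1) * duration,
                parent=epoch_of.get(k),
            )
        )
    if include_recent:
        intervals.append(
            Interval(name="Recent", rank="stage", base_age=recent_len, top_age=0.0)
        )
    return Timescale(intervals)
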