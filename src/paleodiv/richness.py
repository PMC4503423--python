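"""Per-stage taxon classification and richness time series.

Within any time bin a taxon with a known first and last occurrence falls in
exactly one of four classes:

* ``FL`` — first and last occurrence both in the bin (single-interval taxon);
* ``bL`` — ranges in across the bottom boundary, last occurrence in the bin;
* ``Ft`` — first occurrence in the bin, ranges out across the top boundary;
* ``bt`` — ranges through, crossing both boundaries.

From the per-stage tallies three richness series follow:

* range-through  RT  = bt + Ft + bL + FL (taxa observed or inferred present);
* boundary-crossers  BC = bt + bL at the bottom boundary (a faunal cohort at
  an instant, immune to bin-length variation, excluding FL taxa); per-stage
  values use the geometric mean of the bottom and top boundary counts;
* minimum assumption  MIN = Ft + FL + bL (only documented events, no
  range interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .ranges import Assumption, Dataset, ResolvedRange, resolve_dataset
from .timescale import Timescale

CLASS_COLUMNS = ("FL", "bL", "Ft", "bt")


class TaxonClass(str, Enum):
    FL = "FL"
    bL = "bL"
    Ft = "Ft"
    bt = "bt"
    absent = "absent"


def classify(r: ResolvedRange, stage: int) -> TaxonClass:
    """Class of taxon ``r`` in stage ``stage`` (or ``absent``)."""
    if stage < r.first_stage or stage > r.last_stage:
        return TaxonClass.absent
    first_here = r.first_stage == stage
    last_here = r.last_stage == stage
    if first_here and last_here:
        return TaxonClass.FL
    if first_here:
        return TaxonClass.Ft
    if last_here:
        return TaxonClass.bL
    return TaxonClass.bt


@dataclass
class ClassCounts:
    """Per-stage tallies of the four classes, index = stage names (oldest first)."""

    frame: pd.DataFrame  # columns FL, bL, Ft, bt
    assumption: str = "literal"
    dropped: int = 0  # records removed under the minimum assumption

    def __post_init__(self) -> None:
        missing = set(CLASS_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"class-count frame lacks columns {sorted(missing)}")
        self.frame = self.frame[list(CLASS_COLUMNS)].astype(int)

    @property
    def stages(self) -> pd.Index:
        return self.frame.index


def count_classes(
    d: Dataset | Sequence[ResolvedRange],
    timescale: Timescale,
    assumption: Assumption = "literal",
) -> ClassCounts:
    """Tally FL/bL/Ft/bt per stage over the whole timescale.

    Accepts either a raw :class:`Dataset` (resolved here under ``assumption``)
    or already-resolved ranges.  The tally is vectorized: each taxon
    contributes one Ft (or FL) at its first stage, one bL at its last, and bt
    everywhere strictly between.
    """
    if isinstance(d, Dataset):
        resolved, dropped = resolve_dataset(d, timescale, assumption)
    else:
        resolved, dropped = list(d), 0

    n = timescale.n_stages
    fl = np.zeros(n, dtype=int)
    bl = np.zeros(n, dtype=int)
    ft = np.zeros(n, dtype=int)
    bt = np.zeros(n, dtype=int)
    if resolved:
        first = np.array([r.first_stage for r in resolved])
        last = np.array([r.last_stage for r in resolved])
        single = first == last
        np.add.at(fl, first[single], 1)
        np.add.at(ft, first[~single], 1)
        np.add.at(bl, last[~single], 1)
        # bt via difference array: +1 on (first, last) exclusive
        diff = np.zeros(n + 1, dtype=int)
        multi = ~single & (last - first >= 2)
        np.add.at(diff, first[multi] + 1, 1)
        np.add.at(diff, last[multi], -1)
        bt = np.cumsum(diff[:-1])

    frame = pd.DataFrame(
        {"FL": fl, "bL": bl, "Ft": ft, "bt": bt},
        index=pd.Index([s.name for s in timescale.stages], name="stage"),
    )
    return ClassCounts(frame, assumption=assumption, dropped=dropped)


def range_through(cc: ClassCounts) -> pd.Series:
    """RT = bt + Ft + bL + FL per stage."""
    f = cc.frame
    return (f["bt"] + f["Ft"] + f["bL"] + f["FL"]).rename("RT")


def min_series(cc: ClassCounts) -> pd.Series:
    """MIN = Ft + FL + bL per stage (documented events only)."""
    f = cc.frame
    return (f["Ft"] + f["FL"] + f["bL"]).rename("MIN")


def boundary_crossers(cc: ClassCounts) -> pd.DataFrame:
    """Boundary-crosser counts per stage.

    ``BC_bottom(i) = bt + bL`` (taxa ranging in across the bottom boundary),
    ``BC_top(i) = bt + Ft`` (taxa ranging out across the top), and
    ``BC_interval = sqrt(BC_bottom * BC_top)``, the geometric mean used to
    place a boundary quantity at the stage midpoint; it is 0 whenever either
    boundary count is 0.  ``BC_top`` of stage *i* equals ``BC_bottom`` of
    stage *i + 1* by construction.
    """
    f = cc.frame
    bottom = f["bt"] + f["bL"]
    top = f["bt"] + f["Ft"]
    interval = np.sqrt(bottom.astype(float) * top.astype(float))
    return pd.DataFrame(
        {"BC_bottom": bottom, "BC_top": top, "BC_interval": interval}
    )


def richness_table(cc: ClassCounts) -> pd.DataFrame:
    """RT, MIN, and BC series side by side (one row per stage)."""
    bc = boundary_crossers(cc)
    return pd.DataFrame(
        {
            "RT": range_through(cc),
            "MIN": min_series(cc),
            "BC_bottom": bc["BC_bottom"],
            "BC_top": bc["BC_top"],
            "BC_interval": bc["BC_interval"],
        }
    )


def richness_long(cc: ClassCounts) -> pd.DataFrame:
    """Long-format table stage,method,assumption,value for CSV export."""
    wide = richness_table(cc)
    long = (
        wide.reset_index()
        .melt(id_vars="stage", var_name="method", value_name="value")
        .assign(assumption=cc.assumption)
    )
    return long[["stage", "method", "assumption", "value"]]
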