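"""Origination/extinction event counts and Foote per-capita rates.

The per-capita rate estimators use only boundary-crossing taxa:

    p_hat = -ln(N_bt / N_t) / dt        (origination, per Myr)
    q_hat = -ln(N_bt / N_b) / dt        (extinction, per Myr)

where ``N_b = bt + bL`` crosses the bottom boundary into the stage,
``N_t = bt + Ft`` crosses the top boundary out, and ``N_bt = bt`` crosses
both.  They are robust to interval-length variation and ignore
single-interval (FL) taxa entirely.  Stages where ``N_bt`` or the relevant
denominator is 0 have no defined rate and are reported as missing with a
reason code, never as 0 or infinity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError
from .richness import ClassCounts
from .timescale import Timescale

#: reason codes attached to missing rates / edge stages
REASON_NO_BT = "no two-boundary crossers"
REASON_NO_DENOM = "empty boundary count"
FLAG_EDGE = "edge"
FLAG_TERMINAL = "terminal pseudo-stage"


def event_counts(cc: ClassCounts) -> pd.DataFrame:
    """Per-stage origination/extinction event counts.

    ``orig_incl = Ft + FL`` and ``ext_incl = bL + FL`` count all events;
    the ``_excl`` variants leave out single-interval taxa.
    """
    f = cc.frame
    return pd.DataFrame(
        {
            "orig_incl": f["Ft"] + f["FL"],
            "orig_excl": f["Ft"],
            "ext_incl": f["bL"] + f["FL"],
            "ext_excl": f["bL"],
        }
    )


def per_capita_rates(
    cc: ClassCounts,
    timescale: Timescale,
    *,
    unit_durations: bool = False,
    exclude_recent: bool = True,
) -> pd.DataFrame:
    """Foote per-capita origination and extinction rates per stage.

    Returns a frame with columns N_b, N_t, N_bt, delta_t, p_hat, q_hat,
    flag, p_reason, q_reason.  With ``unit_durations`` every stage counts as
    one time unit (rates per stage rather than per Myr).  The terminal
    Recent pseudo-stage is excluded by default: its duration is geologically
    negligible and every extant taxon terminates there by construction.
    The first and last real stages are flagged ``edge``: their boundary
    counts touch the limits of the data's extent.
    """
    f = cc.frame
    durations = timescale.durations()
    if not unit_durations and (durations <= 0).any():
        raise ConfigError("non-positive stage duration in timescale")
    if list(f.index) != list(durations.index):
        raise ConfigError("class counts and timescale index different stages")

    n_b = (f["bt"] + f["bL"]).astype(float)
    n_t = (f["bt"] + f["Ft"]).astype(float)
    n_bt = f["bt"].astype(float)
    dt = pd.Series(1.0, index=f.index) if unit_durations else durations

    with np.errstate(divide="ignore", invalid="ignore"):
        p = -np.log(n_bt / n_t) / dt
        q = -np.log(n_bt / n_b) / dt

    p_reason = pd.Series("", index=f.index, dtype=object)
    q_reason = pd.Series("", index=f.index, dtype=object)
    no_bt = n_bt == 0
    p_reason[no_bt] = REASON_NO_BT
    q_reason[no_bt] = REASON_NO_BT
    p_reason[(~no_bt) & (n_t == 0)] = REASON_NO_DENOM
    q_reason[(~no_bt) & (n_b == 0)] = REASON_NO_DENOM
    p[p_reason != ""] = np.nan
    q[q_reason != ""] = np.nan

    out = pd.DataFrame(
        {
            "N_b": n_b.astype(int),
            "N_t": n_t.astype(int),
            "N_bt": n_bt.astype(int),
            "delta_t": dt,
            "p_hat": p,
            "q_hat": q,
            "flag": "",
            "p_reason": p_reason,
            "q_reason": q_reason,
        }
    )
    out.index = f.index.copy()  # joining with dt can drop the index name
    if exclude_recent and timescale.has_recent:
        out = out.drop(index=timescale.recent.name)
    if len(out) > 0:
        out.iloc[0, out.columns.get_loc("flag")] = FLAG_EDGE
        out.iloc[-1, out.columns.get_loc("flag")] = FLAG_EDGE
    return out


def interior_rates(rates: pd.DataFrame) -> pd.DataFrame:
    """Rows of a rate table not flagged as edge stages."""
    return rates[rates["flag"] != FLAG_EDGE]
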