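"""Shared configuration for the synthetic-record study scripts.

One fixed study configuration is used by every numbered driver so that the
scripts can be run in any order and always describe the same record.  The
settings emulate a family-level continental arthropod record: a handful of
founding lineages in the Early Devonian, origination modestly exceeding
extinction so standing richness grows toward several hundred families at
the present, imperfect per-stage sampling, and a minority of records
resolved only to epoch level.
"""

from __future__ import annotations

from pathlib import Path

from paleodiv import (
    SimulationConfig,
    apply_preservation,
    coarsen,
    default_timescale,
    simulate_ranges,
)

SEED = 11
N0 = 5                   # founding family-level lineages
P_TRUE = 0.030           # per-capita origination, per Myr
Q_TRUE = 0.017           # per-capita extinction, per Myr
PRESERVATION = 0.70      # per-stage sampling probability
COARSE_FRACTION = 0.15   # share of records degraded to epoch resolution
GROUPS = {
    "Apterygota": 0.04,
    "Palaeoptera": 0.14,
    "Polyneoptera": 0.22,
    "Paraneoptera": 0.24,
    "Holometabola": 0.36,
}

RESULTS = Path(__file__).resolve().parent.parent / "results"


def build_record():
    """(true dataset, observed stage-level dataset, mixed-resolution dataset, ledger)."""
    ts = default_timescale()
    cfg = SimulationConfig(
        timescale=ts, n0=N0, p=P_TRUE, q=Q_TRUE, groups=GROUPS, seed=SEED
    )
    true_d, ledger = simulate_ranges(cfg)
    observed = apply_preservation(true_d, ledger, PRESERVATION, seed=SEED + 1)
    mixed = coarsen(observed, COARSE_FRACTION, ts, seed=SEED + 2)
    return true_d, observed, mixed, ledger


def timescale():
    return default_timescale()
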