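"""Synthetic taxon-range data with the statistical structure the analyses assume.

``simulate_ranges`` runs a stage-wise branching process on a timescale: a
lineage alive at a stage's bottom boundary survives to the top boundary with
probability ``exp(-q * dt)``, and new lineages arise in the stage following a
Poisson law whose mean makes the expected top-boundary count equal
``N_b * exp((p - q) * dt)`` — i.e. the per-capita origination/extinction
rates ``p`` and ``q`` (per Myr) are the truth the rate estimators should
recover.  Originations are placed at stage granularity only, since all
downstream counting is bin-wise.  Lineages alive at the final real stage's
top boundary are marked extant (ranging to the Recent pseudo-stage), or can
be killed there for closed-history tests.

``apply_preservation`` thins each lineage's presence to the stages in which
it happens to be sampled (per-stage probability ``r``), truncating observed
ranges inward the way incomplete sampling drags last occurrences backward in
time (and first occurrences forward).  ``coarsen`` degrades a fraction of
records to epoch-level endpoints, emulating compendia with mixed
stratigraphic resolution.  ``perturb_dataset`` manufactures a "revised"
dataset realizing exact target counts of revision categories, with a ledger
for round-trip testing of the comparison module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .ranges import Dataset, TaxonRange, resolve_dataset
from .timescale import Timescale

NEW_SIDE = ("no_change", "new_in_list", "contraction", "extension", "shift")


def _per_stage(value, n: int, name: str) -> np.ndarray:
    arr = np.full(n, float(value)) if np.isscalar(value) else np.asarray(value, dtype=float)
    if arr.shape != (n,):
        raise ConfigError(f"{name} must be a scalar or a length-{n} sequence")
    if (arr < 0).any():
        raise ConfigError(f"{name} must be non-negative")
    return arr


@dataclass
class SimulationConfig:
    """Parameters of the branching-process range simulator.

    ``p`` and ``q`` are true per-capita origination/extinction rates per Myr
    (scalar or one value per real stage); ``preservation`` is the per-stage
    probability that a living lineage is sampled; ``coarse_fraction`` of the
    surviving records are degraded to epoch resolution; ``extant_marking``
    is ``"extant"`` (lineages alive at the end range to the Recent) or
    ``"kill"`` (closed history).
    """

    timescale: Timescale
    n0: int = 200
    p: float | Sequence[float] = 0.05
    q: float | Sequence[float] = 0.05
    preservation: float | Sequence[float] = 1.0
    coarse_fraction: float = 0.0
    extant_marking: str = "extant"
    groups: Mapping[str, float] | None = None
    seed: int | None = None
    diversity_cap: int = 1_000_000

    def __post_init__(self) -> None:
        if self.n0 < 0:
            raise ConfigError("n0 must be >= 0")
        if self.extant_marking not in ("extant", "kill"):
            raise ConfigError("extant_marking must be 'extant' or 'kill'")
        if not 0.0 <= self.coarse_fraction <= 1.0:
            raise ConfigError("coarse_fraction must be in [0, 1]")


@dataclass
class SimulationLedger:
    """Ground truth retained alongside a simulated dataset."""

    true_ranges: pd.DataFrame  # taxon, first_stage, last_stage, extant
    boundary_counts: pd.DataFrame  # per real stage: N_b, N_t, N_bt
    group_counts: dict[str, int] = field(default_factory=dict)
    dropped_unsampled: int = 0
    observed_ranges: pd.DataFrame | None = None
    categories: pd.DataFrame | None = None  # perturbation ledger


def _real_stages(ts: Timescale):
    stages = ts.stages
    return stages[:-1] if ts.has_recent else stages


def simulate_ranges(cfg: SimulationConfig) -> tuple[Dataset, SimulationLedger]:
    """Run the branching process; returns (dataset, ground-truth ledger).

    The dataset records perfect (untruncated) ranges; chain
    :func:`apply_preservation` and :func:`coarsen` for degraded variants.
    """
    ts = cfg.timescale
    stages = _real_stages(ts)
    n_real = len(stages)
    p = _per_stage(cfg.p, n_real, "p")
    q = _per_stage(cfg.q, n_real, "q")
    dt = np.array([s.duration for s in stages])
    rng = np.random.default_rng(cfg.seed)

    first: list[int] = [0] * cfg.n0  # initial cohort enters at the bottom of stage 0
    last: list[int] = [-1] * cfg.n0
    alive = list(range(cfg.n0))
    n_b = np.zeros(n_real, dtype=int)
    n_t = np.zeros(n_real, dtype=int)
    n_bt = np.zeros(n_real, dtype=int)

    for i in range(n_real):
        # the founding cohort first-occurs in stage 0, so it does not cross
        # that stage's bottom boundary in the observable record
        n_b[i] = len(alive) if i > 0 else 0
        surv_prob = float(np.exp(-q[i] * dt[i]))
        survived = rng.random(len(alive)) < surv_prob
        survivors = []
        for taxon, ok in zip(alive, survived):
            if ok:
                survivors.append(taxon)
            else:
                last[taxon] = i
        n_bt[i] = len(survivors) if i > 0 else 0
        growth = float(np.exp((p[i] - q[i]) * dt[i]))
        mean_new = max(len(alive) * (growth - surv_prob), 0.0)
        n_new = int(rng.poisson(mean_new))
        for _ in range(n_new):
            first.append(i)
            last.append(-1)
            survivors.append(len(first) - 1)
        alive = survivors
        n_t[i] = len(alive)
        if len(first) > cfg.diversity_cap:
            raise ConfigError(
                f"diversity cap exceeded at stage {stages[i].name!r}: "
                f"{len(first)} lineages generated (cap {cfg.diversity_cap}); "
                "the configured rates are explosive for this timescale"
            )

    extant_idx = ts.recent.index if (ts.has_recent and cfg.extant_marking == "extant") else n_real - 1
    extant_flags = [False] * len(first)
    for taxon in alive:
        extant_flags[taxon] = cfg.extant_marking == "extant"
        last[taxon] = extant_idx if extant_flags[taxon] else n_real - 1

    group_names: list[str | None] = [None] * len(first)
    group_counts: dict[str, int] = {}
    if cfg.groups:
        tags = list(cfg.groups)
        probs = np.array([cfg.groups[t] for t in tags], dtype=float)
        probs = probs / probs.sum()
        draws = rng.choice(len(tags), size=len(first), p=probs)
        group_names = [tags[k] for k in draws]
        for g in group_names:
            group_counts[g] = group_counts.get(g, 0) + 1

    records = [
        TaxonRange(
            taxon=f"Fam{k + 1:04d}",
            first_interval=ts.stage_at(first[k]).name,
            last_interval=ts.stage_at(last[k]).name,
            extant=extant_flags[k],
            group=group_names[k],
        )
        for k in range(len(first))
    ]
    ledger = SimulationLedger(
        true_ranges=pd.DataFrame(
            {
                "taxon": [r.taxon for r in records],
                "first_stage": first,
                "last_stage": last,
                "extant": extant_flags,
            }
        ),
        boundary_counts=pd.DataFrame(
            {"N_b": n_b, "N_t": n_t, "N_bt": n_bt},
            index=pd.Index([s.name for s in stages], name="stage"),
        ),
        group_counts=group_counts,
    )
    dataset = Dataset(records, label="simulated", metadata={"seed": cfg.seed})
    return dataset, ledger


def apply_preservation(
    d: Dataset,
    ledger: SimulationLedger,
    r: float | Sequence[float],
    seed: int | None = None,
) -> Dataset:
    """Thin ranges by per-stage sampling probability ``r``.

    A lineage's observed range runs from its first to its last sampled
    stage; lineages never sampled are dropped (counted in the ledger).
    Extant lineages keep their terminal Recent endpoint — they are known
    from the living fauna — but still need at least one sampled stage to
    possess a fossil record at all.
    """
    ts_n = len(ledger.boundary_counts)
    rr = _per_stage(r, ts_n, "preservation")
    if (rr > 1).any():
        raise ConfigError("preservation probabilities must be <= 1")
    rng = np.random.default_rng(seed)
    true = ledger.true_ranges.set_index("taxon")
    by_key = {rec.taxon: rec for rec in d}

    kept: list[TaxonRange] = []
    observed_rows = []
    dropped = 0
    for taxon, row in true.iterrows():
        rec = by_key.get(taxon)
        if rec is None:
            continue
        lo = int(row["first_stage"])
        hi = min(int(row["last_stage"]), ts_n - 1)  # clip the Recent endpoint
        stages_alive = np.arange(lo, hi + 1)
        sampled = stages_alive[rng.random(stages_alive.size) < rr[stages_alive]]
        if sampled.size == 0:
            dropped += 1
            continue
        obs_first = int(sampled[0])
        obs_last = int(row["last_stage"]) if row["extant"] else int(sampled[-1])
        kept.append(
            TaxonRange(
                taxon=rec.taxon,
                first_interval=_stage_name(d, ledger, obs_first),
                last_interval=_stage_name(d, ledger, obs_last),
                extant=bool(row["extant"]),
                group=rec.group,
            )
        )
        observed_rows.append(
            {"taxon": rec.taxon, "first_stage": obs_first, "last_stage": obs_last}
        )
    ledger.dropped_unsampled = dropped
    ledger.observed_ranges = pd.DataFrame(observed_rows)
    return Dataset(kept, label=f"{d.label}+preservation", metadata=dict(d.metadata))


def _stage_name(d: Dataset, ledger: SimulationLedger, idx: int) -> str:
    # ledger.boundary_counts indexes the real stages; the Recent pseudo-stage
    # sits one past its end.
    names = list(ledger.boundary_counts.index)
    if idx < len(names):
        return names[idx]
    return "Recent"


def coarsen(
    d: Dataset,
    fraction: float,
    timescale: Timescale,
    seed: int | None = None,
) -> Dataset:
    """Degrade an exact fraction of records to epoch-level endpoints.

    Both endpoints of each selected record are replaced by their parent
    epoch names (the Recent endpoint of an extant record is left alone).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ConfigError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(d)
    k = int(round(fraction * n))
    chosen = set(rng.choice(n, size=k, replace=False)) if k else set()

    out: list[TaxonRange] = []
    for i, rec in enumerate(d):
        if i not in chosen:
            out.append(rec)
            continue
        out.append(
            TaxonRange(
                taxon=rec.taxon,
                first_interval=_parent_epoch(timescale, rec.first_interval),
                last_interval=rec.last_interval
                if rec.extant
                else _parent_epoch(timescale, rec.last_interval),
                extant=rec.extant,
                group=rec.group,
            )
        )
    return Dataset(out, label=f"{d.label}+coarse", metadata=dict(d.metadata))


def _parent_epoch(ts: Timescale, stage_name: str) -> str:
    iv = ts[stage_name]
    if iv.rank != "stage":
        return iv.name  # already coarse
    if iv.parent is None:
        raise ConfigError(f"stage {iv.name!r} has no parent epoch to coarsen to")
    return ts[iv.parent].name


# --------------------------------------------------------------------------
# perturbation pairs for the comparison module
# --------------------------------------------------------------------------

def _largest_remainder(props: Mapping[str, float], total: int) -> dict[str, int]:
    names = list(props)
    raw = np.array([props[n] for n in names], dtype=float)
    if (raw < 0).any() or not np.isclose(raw.sum(), 1.0):
        raise ConfigError("category proportions must be non-negative and sum to 1")
    floors = np.floor(raw * total).astype(int)
    remainder = total - floors.sum()
    order = np.argsort(-(raw * total - floors), kind="stable")
    for j in order[:remainder]:
        floors[j] += 1
    return dict(zip(names, floors.tolist()))


def perturb_dataset(
    d: Dataset,
    target_proportions: Mapping[str, float],
    timescale: Timescale,
    seed: int | None = None,
    *,
    n_new: int | None = None,
    max_redraws: int = 50,
) -> tuple[Dataset, pd.DataFrame]:
    """Build a revised dataset realizing exact revision-category counts.

    ``target_proportions`` gives proportions over the new-dataset categories
    {no_change, new_in_list, contraction, extension, shift}; counts are
    fixed by largest-remainder apportionment of ``n_new`` (defaults to
    ``len(d)``).  Old taxa not carried into the revision are the implied
    ``removed`` set.  Category feasibility is respected (a contraction needs
    a span of at least two stages; shifts and contractions need non-extant,
    stage-resolved records); infeasible draws are re-shuffled up to
    ``max_redraws`` times before raising.

    Returns the revised dataset and a ledger frame (taxon, category).
    """
    unknown = set(target_proportions) - set(NEW_SIDE)
    if unknown:
        raise ConfigError(f"unknown categories in target: {sorted(unknown)}")
    props = {c: float(target_proportions.get(c, 0.0)) for c in NEW_SIDE}
    total = n_new if n_new is not None else len(d)
    counts = _largest_remainder(props, total)
    shared_needed = total - counts["new_in_list"]
    if shared_needed > len(d):
        raise ConfigError(
            f"target needs {shared_needed} carried-over taxa but the source has {len(d)}"
        )

    resolved, _ = resolve_dataset(d, timescale, "literal")
    by_taxon = {rr.taxon: rr for rr in resolved}
    last_real = (timescale.n_stages - 2) if timescale.has_recent else (timescale.n_stages - 1)
    rng = np.random.default_rng(seed)

    def eligible(rr, category: str) -> bool:
        span = rr.last_stage - rr.first_stage + 1
        if category == "no_change":
            return True
        if rr.extant:
            # only an older first occurrence can change an extant range cleanly
            return category == "extension" and rr.first_stage > 0
        if category == "contraction":
            return span >= 2
        if category == "extension":
            return rr.first_stage > 0 or rr.last_stage < last_real
        if category == "shift":
            return span <= last_real and not (rr.first_stage == 0 and rr.last_stage == last_real)
        raise AssertionError(category)

    taxa = [rec.taxon for rec in d]
    assignment: dict[str, str] | None = None
    for _ in range(max_redraws):
        order = list(taxa)
        rng.shuffle(order)
        trial: dict[str, str] = {}
        pool = list(order)
        ok = True
        # fill the constrained categories first
        for category in ("shift", "contraction", "extension", "no_change"):
            need = counts[category]
            chosen = []
            rest = []
            for t in pool:
                if len(chosen) < need and eligible(by_taxon[t], category):
                    chosen.append(t)
                else:
                    rest.append(t)
            if len(chosen) < need:
                ok = False
                break
            for t in chosen:
                trial[t] = category
            pool = rest
        if ok:
            assignment = trial
            removed_taxa = pool
            break
    if assignment is None:
        raise ValidationError(
            "could not realize the requested category counts on this dataset "
            f"(counts {counts}); too few eligible records"
        )

    name_of = {s.index: s.name for s in timescale.stages}
    old_by = d.by_key()
    out: list[TaxonRange] = []
    ledger_rows = []

    def emit(taxon: str, first: int, last: int, extant: bool, group, category: str):
        out.append(
            TaxonRange(
                taxon=taxon,
                first_interval=name_of[first],
                last_interval=name_of[last],
                extant=extant,
                group=group,
            )
        )
        ledger_rows.append({"taxon": taxon, "category": category})

    for rec in d:
        category = assignment.get(rec.taxon)
        if category is None:
            ledger_rows.append({"taxon": rec.taxon, "category": "removed"})
            continue
        rr = by_taxon[rec.taxon]
        first, last, span = rr.first_stage, rr.last_stage, rr.n_stages
        if category == "no_change":
            out.append(rec)
            ledger_rows.append({"taxon": rec.taxon, "category": category})
        elif category == "contraction":
            new_span = int(rng.integers(1, span))
            a = int(rng.integers(0, span - new_span + 1))
            emit(rec.taxon, first + a, first + a + new_span - 1, False, rec.group, category)
        elif category == "extension":
            if rr.extant:
                a = int(rng.integers(1, first + 1))
                emit(rec.taxon, first - a, last, True, rec.group, category)
            else:
                max_left, max_right = first, last_real - last
                while True:
                    a = int(rng.integers(0, max_left + 1))
                    b = int(rng.integers(0, max_right + 1))
                    if a + b > 0:
                        break
                emit(rec.taxon, first - a, last + b, False, rec.group, category)
        elif category == "shift":
            positions = [s for s in range(0, last_real - span + 2) if s != first]
            new_first = int(rng.choice(positions))
            emit(rec.taxon, new_first, new_first + span - 1, False, rec.group, category)

    for j in range(counts["new_in_list"]):
        lo = int(rng.integers(0, last_real + 1))
        hi = int(rng.integers(lo, last_real + 1))
        emit(f"Newfam{j + 1:04d}", lo, hi, False, None, "new_in_list")

    ledger = pd.DataFrame(ledger_rows)
    revised = Dataset(out, label=f"{d.label}+revision", metadata={"seed": seed})
    # bookkeeping sanity: the realized new-side counts match the target exactly
    realized = ledger[ledger["category"] != "removed"]["category"].value_counts()
    for category, want in counts.items():
        if int(realized.get(category, 0)) != want:
            raise AssertionError(f"internal: realized {category} != target")
    return revised, ledger
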