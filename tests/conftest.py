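import numpy as np
import pytest

from paleodiv import (
    Dataset,
    SimulationConfig,
    TaxonRange,
    default_timescale,
    simulate_ranges,
    uniform_timescale,
)


@pytest.fixture(scope="session")
def gts():
    """The packaged geological timescale (Lochkovian → Recent)."""
    return default_timescale()


@pytest.fixture(scope="session")
def ts20():
    """Uniform 20-stage, 5-Myr synthetic timescale with epochs of 4 stages."""
    return uniform_timescale(20, 5.0, epoch_size=4)


@pytest.fixture()
def sim_dataset(ts20):
    """A moderately sized simulated dataset plus its ground-truth ledger."""
    cfg = SimulationConfig(timescale=ts20, n0=150, p=0.05, q=0.05, seed=424242)
    return simulate_ranges(cfg)


def random_resolved_dataset(rng: np.random.Generator, ts, n_taxa: int) -> Dataset:
    """Arbitrary stage-resolved dataset for oracle comparisons."""
    last_real = ts.n_stages - 2 if ts.has_recent else ts.n_stages - 1
    records = []
    for k in range(n_taxa):
        first = int(rng.integers(0, last_real + 1))
        last = int(rng.integers(first, last_real + 1))
        extant = bool(rng.random() < 0.1)
        records.append(
            TaxonRange(
                taxon=f"T{k:03d}",
                first_interval=ts.stage_at(first).name,
                last_interval=ts.stage_at(ts.recent.index if extant else last).name,
                extant=extant,
            )
        )
    return Dataset(records, label="random")
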