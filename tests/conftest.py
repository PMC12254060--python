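import numpy as np
import pytest

from polliturn.records import InteractionNetwork, InteractionRecord
from polliturn.simulate import reference_dataset

ALL_PLOTS = frozenset(f"P{i}" for i in range(1, 7))


def make_network(links, year=2015, week=1, day=160, plots=("A",)):
    """Network from an iterable of (plant, pollinator[, count]) tuples."""
    link_map = {}
    for link in links:
        plant, poll, *rest = link
        link_map[(plant, poll)] = rest[0] if rest else 1
    return InteractionNetwork(
        year=year,
        week_index=week,
        ordinal_day=day,
        plots_included=frozenset(plots),
        links=link_map,
    )


def random_network(rng, max_plants=8, max_pollinators=8, week=1, day=160):
    """Random small binary network; guaranteed at least one link."""
    n_pl = rng.integers(1, max_plants + 1)
    n_po = rng.integers(1, max_pollinators + 1)
    density = rng.uniform(0.15, 0.8)
    mask = rng.random((n_pl, n_po)) < density
    if not mask.any():
        mask[rng.integers(0, n_pl), rng.integers(0, n_po)] = True
    links = {
        (f"p{i}", f"i{j}"): int(rng.integers(1, 5))
        for i, j in zip(*np.nonzero(mask))
    }
    return make_network([(p, q, c) for (p, q), c in links.items()], week=week, day=day)


def make_record(**kw):
    defaults = dict(
        year=2015, ordinal_day=160, week_index=1, plot="A",
        plant="p1", pollinator="i1", count=1,
    )
    defaults.update(kw)
    return InteractionRecord(**defaults)


@pytest.fixture(scope="session")
def reference_records():
    """The canonical simulated survey (6 plots, 8 years, documented seed)."""
    return reference_dataset()
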