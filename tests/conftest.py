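import datetime as dt

import pytest

from photoid import (FlankCatalogue, SightingRecord, SiteSpec, WorldConfig,
                     simulate_world)


def rec(iid, site, date, sex="male", flanks=("left",)):
    return SightingRecord(iid, site, dt.date.fromisoformat(date), sex,
                          frozenset(flanks))


@pytest.fixture
def toy_view():
    """Hand-enumerable LB view: A seen 2005 and 2006, B seen 2006 only."""
    return FlankCatalogue("LB", [
        rec("A", "north", "2005-04-01"),
        rec("A", "north", "2006-05-02"),
        rec("B", "north", "2006-06-03"),
    ])


@pytest.fixture
def two_site_world():
    """Two closed sites, no migration, moderate sighting probability."""
    config = WorldConfig(
        sites=[
            SiteSpec("alpha", 120, 0.4, flank_probs=(0.6, 0.25, 0.15)),
            SiteSpec("beta", 80, 0.3, flank_probs=(0.5, 0.3, 0.2)),
        ],
        years=(2005, 2010),
        seed=42,
    )
    return simulate_world(config)
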