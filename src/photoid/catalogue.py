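"""Sighting-catalogue data model and I/O.

A photo-identification catalogue is a flat table of encounters: one row per
photo-identified sighting of an individual at an aggregation site on a date,
with the sex recorded (male / female / indeterminate) and the flank(s)
photographed. Because the natural marking patterns on the left and right
flanks of an animal differ, an individual photographed only on one side can
never be matched against photographs of the other side. All downstream
analyses therefore run on two overlapping views of the catalogue:

* **LB** — records whose photographs include the left flank (left-only or
  both flanks),
* **RB** — records whose photographs include the right flank.

Running every analysis on both views, and reporting the left-based one by
default (it is conventionally the larger sample), guards against double
counting of individuals whose two sides were photographed on disjoint
occasions.

Population sizes at each site enter the power analysis as point estimates
with 95% confidence intervals taken from published mark-recapture studies;
:class:`PopulationEstimate` converts the interval into a standard error
under a symmetric-normal assumption.
"""

from __future__ import annotations

import csv
import datetime as _dt
import logging
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

#: two-sided 97.5% standard-normal quantile used to convert 95% CIs to SEs
Z_95 = 1.959963984540054

SEXES = ("male", "female", "indeterminate")

CSV_HEADER = ["individual_id", "site", "date", "sex", "flanks"]

_FLANK_CODES = {
    "L": frozenset({"left"}),
    "R": frozenset({"right"}),
    "LR": frozenset({"left", "right"}),
    "RL": frozenset({"left", "right"}),
}


class CatalogueFormatError(ValueError):
    """Raised when a catalogue file is structurally unusable (bad header)."""


def encode_flanks(flanks: frozenset[str]) -> str:
    """Serialize a flank set to its CSV code ("L", "R" or "LR")."""
    if flanks == frozenset({"left"}):
        return "L"
    if flanks == frozenset({"right"}):
        return "R"
    if flanks == frozenset({"left", "right"}):
        return "LR"
    raise ValueError(f"invalid flank set: {flanks!r}")


@dataclass(frozen=True, order=True)
class SightingRecord:
    """One photo-identified encounter of an individual."""

    individual_id: str
    site: str
    date: _dt.date
    sex: str
    flanks: frozenset[str]

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not self.flanks or not self.flanks <= {"left", "right"}:
            raise ValueError(f"flanks must be a nonempty subset of left/right, got {self.flanks!r}")

    @property
    def year(self) -> int:
        return self.date.year


def _parse_row(row: dict, site_set: set[str] | None,
               study_window: tuple[int, int] | None) -> SightingRecord:
    iid = (row.get("individual_id") or "").strip()
    if not iid:
        raise ValueError("empty individual_id")
    site = (row.get("site") or "").strip()
    if site_set is not None and site not in site_set:
        raise ValueError(f"site {site!r} not in declared site set")
    if not site:
        raise ValueError("empty site")
    date = _dt.date.fromisoformat((row.get("date") or "").strip())
    if study_window is not None and not (study_window[0] <= date.year <= study_window[1]):
        raise ValueError(f"date {date} outside study window {study_window}")
    sex = (row.get("sex") or "").strip().lower()
    code = (row.get("flanks") or "").strip().upper()
    if code not in _FLANK_CODES:
        raise ValueError(f"flank code {code!r} not one of L/R/LR")
    return SightingRecord(iid, site, date, sex, _FLANK_CODES[code])


def read_catalogue(path, site_set: set[str] | None = None,
                   study_window: tuple[int, int] | None = None) -> list[SightingRecord]:
    """Read a sighting catalogue CSV.

    The file must carry the fixed header ``individual_id,site,date,sex,flanks``
    with ISO dates and flanks encoded as ``L``, ``R`` or ``LR``. Rows that fail
    validation (unknown site, bad date, bad flank code, date outside
    ``study_window``) are skipped with a logged warning; a missing column is
    fatal.

    Returns the parsed records; the number skipped is logged.
    """
    records: list[SightingRecord] = []
    n_skipped = 0
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(CSV_HEADER) - set(reader.fieldnames or ())
        if missing:
            raise CatalogueFormatError(
                f"{path}: missing required column(s): {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(_parse_row(row, site_set, study_window))
            except (ValueError, KeyError) as exc:
                n_skipped += 1
                log.warning("%s line %d skipped: %s", path, lineno, exc)
    if n_skipped:
        log.warning("%s: %d row(s) skipped", path, n_skipped)
    return records


def write_catalogue(records, path) -> None:
    """Write records back to the canonical CSV format (UTF-8, fixed header)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for r in records:
            writer.writerow([r.individual_id, r.site, r.date.isoformat(),
                             r.sex, encode_flanks(r.flanks)])


@dataclass
class FlankCatalogue:
    """One flank view (LB or RB) of a catalogue — the unit of all analyses."""

    side: str  # "LB" or "RB"
    records: list[SightingRecord] = field(default_factory=list)

    def __post_init__(self):
        if self.side not in ("LB", "RB"):
            raise ValueError("side must be 'LB' or 'RB'")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def individuals(self) -> set[str]:
        return {r.individual_id for r in self.records}

    @property
    def sites(self) -> set[str]:
        return {r.site for r in self.records}

    def site_years(self) -> dict[str, set[int]]:
        """Per-site set of sampled years."""
        out: dict[str, set[int]] = {}
        for r in self.records:
            out.setdefault(r.site, set()).add(r.year)
        return out

    def to_frame(self):
        """Tidy DataFrame of the view (one row per record)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "individual_id": [r.individual_id for r in self.records],
                "site": [r.site for r in self.records],
                "date": [r.date for r in self.records],
                "year": [r.year for r in self.records],
                "sex": [r.sex for r in self.records],
            }
        )


def build_flank_views(records) -> tuple[FlankCatalogue, FlankCatalogue]:
    """Split records into the LB and RB flank views.

    A record photographed on both flanks appears in both views, so
    ``len(LB) + len(RB) - n_both == len(records)``. Empty views are allowed
    (with a warning) so single-sided catalogues still process.
    """
    lb = FlankCatalogue("LB", [r for r in records if "left" in r.flanks])
    rb = FlankCatalogue("RB", [r for r in records if "right" in r.flanks])
    for view in (lb, rb):
        if not view.records:
            log.warning("%s view is empty", view.side)
    counts = {}
    for r in records:
        counts.setdefault(r.site, [0, 0])
        if "left" in r.flanks:
            counts[r.site][0] += 1
        if "right" in r.flanks:
            counts[r.site][1] += 1
    for site, (nl, nr) in sorted(counts.items()):
        log.info("site %s: %d LB records, %d RB records", site, nl, nr)
    return lb, rb


def population_point_estimate(est_a: float, est_b: float) -> float:
    """Average two independent point estimates of the same population.

    Used when a site has two published estimates (e.g. one from researcher
    photographs and one from public submissions). Rounding to a whole number
    of individuals is left to the reporting layer.
    """
    if est_a <= 0 or est_b <= 0:
        raise ValueError("population estimates must be positive")
    return (est_a + est_b) / 2.0


def derive_se_from_ci(ci_low: float, ci_high: float) -> float:
    """Standard error implied by a symmetric-normal 95% confidence interval."""
    if ci_high <= ci_low:
        raise ValueError("degenerate CI: ci_high must exceed ci_low")
    return (ci_high - ci_low) / (2.0 * Z_95)


@dataclass
class PopulationEstimate:
    """A site's population size with 95% CI and derived standard error.

    ``se`` may be supplied explicitly (e.g. when the printed interval is a
    pair of alternative point estimates rather than a true CI); otherwise it
    is derived from the CI under a symmetric-normal assumption. An explicit
    ``se`` of zero marks the estimate as exact — the degenerate limit in
    which Monte Carlo draws collapse to the point value.
    """

    site: str
    mean: float
    ci_low: float
    ci_high: float
    se: float | None = None

    def __post_init__(self):
        if not (self.ci_low <= self.mean <= self.ci_high):
            raise ValueError(
                f"{self.site}: require ci_low <= mean <= ci_high, "
                f"got {self.ci_low}, {self.mean}, {self.ci_high}")
        if self.se is None:
            self.se = derive_se_from_ci(self.ci_low, self.ci_high)
        if self.se < 0:
            raise ValueError("se must be nonnegative")


# Published per-site inputs for the Indian Ocean whale-shark power analysis:
# Jolly-Seber population estimates (point, 95% CI) and the average number of
# unique individuals photo-identified per year. Maldives carries two published
# point estimates (77 and 98.5) whose average, 87.75, is the working size;
# Mozambique has no published population estimate and must be supplied by the
# user before any power run that involves it.
REFERENCE_SITES: dict[str, dict] = {
    "ningaloo": {
        "population": PopulationEstimate("ningaloo", 380.0, 320.0, 440.0),
        "yearly_ids": 104.0,
    },
    "maldives": {
        "population": PopulationEstimate(
            "maldives", population_point_estimate(77.0, 98.5), 77.0, 98.5),
        "yearly_ids": 28.0,
    },
    "seychelles": {
        "population": PopulationEstimate("seychelles", 513.0, 469.0, 557.0),
        "yearly_ids": 59.0,
    },
    "mozambique": {
        "population": None,  # not published; user must supply an estimate
        "yearly_ids": 77.0,
    },
}
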