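"""Descriptive resight statistics for a flank view of a catalogue.

All metrics operate on a single :class:`~photoid.catalogue.FlankCatalogue`
(LB or RB) and count an individual at most once per site-year. A *resight*
is an individual recorded at the same site in a previous sampled year —
repeat encounters within one year do not count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalogue import FlankCatalogue

log = logging.getLogger(__name__)

YEARS_OBSERVED_WINDOW = 6  # consecutive sampled years entering the return-years table


def site_year_summaries(view: FlankCatalogue,
                        year_range: tuple[int, int] | None = None) -> pd.DataFrame:
    """Per site-year counts of unique, first-ever and resighted individuals.

    Returns a DataFrame with columns ``site, year, n_unique, n_new,
    n_resight`` where ``n_unique = n_new + n_resight`` and the first sampled
    year of a site has ``n_resight = 0``. ``year_range`` restricts the
    records considered (inclusive) before first-sighting years are assigned,
    so it defines the analysis window, not a post-hoc filter.
    """
    if not view.records:
        raise ValueError("view is empty")
    df = view.to_frame()
    if year_range is not None:
        lo, hi = year_range
        if lo > hi:
            raise ValueError("empty year range")
        df = df[(df["year"] >= lo) & (df["year"] <= hi)]
        if df.empty:
            raise ValueError(f"no records in year range {year_range}")
    pres = df[["individual_id", "site", "year"]].drop_duplicates()
    first_year = pres.groupby(["site", "individual_id"])["year"].min().rename("first_year")
    pres = pres.join(first_year, on=["site", "individual_id"])
    pres["is_new"] = pres["year"] == pres["first_year"]
    out = (pres.groupby(["site", "year"])
           .agg(n_unique=("individual_id", "size"), n_new=("is_new", "sum"))
           .reset_index())
    out["n_new"] = out["n_new"].astype(int)
    out["n_resight"] = out["n_unique"] - out["n_new"]
    return out.sort_values(["site", "year"], ignore_index=True)


def proportion_resighted_per_year(summaries: pd.DataFrame) -> pd.DataFrame:
    """Yearly resight proportion per site, excluding each site's first year.

    The first sampled year offers no possibility of a resight and is dropped;
    a site sampled in a single year is excluded entirely (with a warning).
    Returns columns ``site, year, prop_resight``.
    """
    rows = []
    for site, grp in summaries.groupby("site"):
        grp = grp.sort_values("year")
        if len(grp) < 2:
            log.warning("site %s sampled in a single year; excluded from "
                        "resight proportions", site)
            continue
        for _, r in grp.iloc[1:].iterrows():
            rows.append({"site": site, "year": int(r["year"]),
                         "prop_resight": r["n_resight"] / r["n_unique"]})
    return pd.DataFrame(rows, columns=["site", "year", "prop_resight"])


def years_observed_distribution(view: FlankCatalogue,
                                windows: dict[str, tuple[int, int]],
                                pool_top: bool = True) -> pd.DataFrame:
    """Distribution of the number of distinct years individuals were observed.

    ``windows`` maps each site to an inclusive run of
    :data:`YEARS_OBSERVED_WINDOW` consecutive years that must lie within the
    site's sampled years. Counts are over unique individuals seen at least
    once inside the window. With ``pool_top`` the two highest categories are
    merged (``5-6``) — the pooling used to keep expected contingency-table
    cell counts adequate.

    Returns a DataFrame indexed by site with one column per category.
    """
    site_years = view.site_years()
    w = YEARS_OBSERVED_WINDOW
    frames = {}
    df = view.to_frame()
    for site, (lo, hi) in windows.items():
        if hi - lo + 1 != w:
            raise ValueError(f"{site}: window must span exactly {w} years")
        if site not in site_years:
            raise ValueError(f"{site}: no records in view")
        sampled = site_years[site]
        missing = set(range(lo, hi + 1)) - sampled
        if missing:
            raise ValueError(
                f"{site}: window {lo}-{hi} includes unsampled year(s) {sorted(missing)}")
        sub = df[(df["site"] == site) & (df["year"] >= lo) & (df["year"] <= hi)]
        n_years = sub.groupby("individual_id")["year"].nunique()
        counts = n_years.value_counts().reindex(range(1, w + 1), fill_value=0)
        if pool_top:
            pooled = counts.iloc[: w - 2].copy()
            pooled[f"{w - 1}-{w}"] = counts.iloc[w - 2:].sum()
            pooled.index = [str(i) for i in range(1, w - 1)] + [f"{w - 1}-{w}"]
            frames[site] = pooled
        else:
            counts.index = [str(i) for i in counts.index]
            frames[site] = counts
    table = pd.DataFrame(frames).T.astype(int)
    table.index.name = "site"
    return table


def mean_years_observed(view: FlankCatalogue) -> pd.DataFrame:
    """Per-site mean (± SE) number of distinct years individuals were observed.

    Computed over unique individuals across the entire study period; SE is
    the standard error of the mean (0 when every individual has the same
    count or only one individual was seen).
    """
    df = view.to_frame()
    if df.empty:
        raise ValueError("view is empty")
    per_ind = (df.drop_duplicates(["site", "individual_id", "year"])
               .groupby(["site", "individual_id"])["year"].nunique())
    rows = []
    for site, vals in per_ind.groupby(level="site"):
        arr = vals.to_numpy(dtype=float)
        se = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
        rows.append({"site": site, "n_individuals": len(arr),
                     "mean_years": float(arr.mean()), "se_years": se})
    return pd.DataFrame(rows)


def max_consecutive_years(view: FlankCatalogue) -> dict[str, int]:
    """Longest run of consecutive calendar years each individual was recorded
    at a single site (maximum over sites for individuals seen at several)."""
    runs: dict[str, int] = {}
    per = {}
    for r in view.records:
        per.setdefault((r.individual_id, r.site), set()).add(r.year)
    for (iid, _site), years in per.items():
        best = cur = 1
        ordered = sorted(years)
        for a, b in zip(ordered, ordered[1:]):
            cur = cur + 1 if b == a + 1 else 1
            best = max(best, cur)
        runs[iid] = max(runs.get(iid, 0), best)
    return runs


@dataclass
class CrossSiteMatch:
    """An individual photo-identified at two or more sites.

    The elapsed time for the first site change is measured from the last
    sighting at the original site to the first sighting at the new one —
    the minimum window in which the journey must have occurred.
    """

    individual_id: str
    #: chronologically ordered (site, date) visits
    itinerary: list
    distance_km: float | None = None

    @property
    def first_leg(self) -> tuple[str, str]:
        """(from_site, to_site) of the first site change."""
        first_site = self.itinerary[0][0]
        to_site = next(s for s, _ in self.itinerary if s != first_site)
        return first_site, to_site

    @property
    def elapsed_days(self) -> int:
        first_site, _ = self.first_leg
        arrival = next(d for s, d in self.itinerary if s != first_site)
        departure = max(d for s, d in self.itinerary if s == first_site and d < arrival)
        return (arrival - departure).days

    @property
    def speed_km_per_day(self) -> float | None:
        if self.distance_km is None:
            return None
        return min_travel_speed(self.distance_km, self.elapsed_days)


def cross_site_matches(view: FlankCatalogue,
                       distances_km: dict[tuple[str, str], float] | None = None
                       ) -> list[CrossSiteMatch]:
    """Individuals recorded at two or more distinct sites.

    ``distances_km`` optionally maps site pairs (either order) to
    straight-line distances so an implied minimum swimming speed can be
    reported for the first site change.
    """
    by_ind: dict[str, list] = {}
    for r in view.records:
        by_ind.setdefault(r.individual_id, []).append((r.site, r.date))
    matches = []
    for iid, visits in sorted(by_ind.items()):
        sites = {s for s, _ in visits}
        if len(sites) < 2:
            continue
        itinerary = sorted(visits, key=lambda sd: (sd[1], sd[0]))
        match = CrossSiteMatch(iid, itinerary)
        if distances_km is not None:
            pair = match.first_leg
            match.distance_km = distances_km.get(pair, distances_km.get(pair[::-1]))
        matches.append(match)
    return matches


def min_travel_speed(distance_km: float, days: float) -> float:
    """Minimum average speed (km/day) implied by a straight-line distance
    covered in a known number of days. Rounding to one decimal is left to
    the reporting layer."""
    if distance_km <= 0 or days <= 0:
        raise ValueError("distance and days must be positive")
    return distance_km / days


def sex_composition(view: FlankCatalogue) -> pd.DataFrame:
    """Per-site sex proportions over unique individuals.

    Sex is taken as fixed per individual: the first non-indeterminate value
    in date order wins (conflicting records are logged), falling back to
    indeterminate. Returns columns ``site, male, female, indeterminate,
    n_individuals``.
    """
    resolved: dict[tuple[str, str], str] = {}
    for r in sorted(view.records, key=lambda r: (r.site, r.individual_id, r.date)):
        key = (r.site, r.individual_id)
        cur = resolved.get(key)
        if cur is None or (cur == "indeterminate" and r.sex != "indeterminate"):
            resolved[key] = r.sex
        elif r.sex not in ("indeterminate", cur):
            log.warning("individual %s at %s has conflicting sex records "
                        "(%s vs %s); keeping %s", key[1], key[0], cur, r.sex, cur)
    rows = []
    by_site: dict[str, list[str]] = {}
    for (site, _iid), sex in resolved.items():
        by_site.setdefault(site, []).append(sex)
    for site, sexes in sorted(by_site.items()):
        n = len(sexes)
        rows.append({"site": site,
                     "male": sexes.count("male") / n,
                     "female": sexes.count("female") / n,
                     "indeterminate": sexes.count("indeterminate") / n,
                     "n_individuals": n})
    return pd.DataFrame(rows)
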