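"""Dated faunal-assemblage records and their assignment to time slices.

A *site* is a dated assemblage of taxa: a location, a set of taxa recovered
there, and a calibrated date interval given as earliest and latest possible
years BP (before 1950 CE).  Because a date interval can span more than one
of the labelled year-BP slices used for hindcast rasters, a record is either
assigned to every slice its interval overlaps (``mode="interval"``) or only
to the slice containing the interval midpoint (``mode="midpoint"``).

Presence/absence of a *target* taxon is then derived per (site, slice): a
site is a presence in a slice if any of its assemblages assigned to that
slice contains the taxon, and an absence otherwise — the compilation records
what was found, so absence is inferred from a dated assemblage that lacks
the taxon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, EmptyInputError

logger = logging.getLogger(__name__)

PRESENCE = "presence"
ABSENCE = "absence"


@dataclass(frozen=True)
class PaleoSite:
    """One dated faunal assemblage.

    ``latest_bp <= earliest_bp``: the interval runs from the latest possible
    date (younger) to the earliest possible date (older).
    """

    site_id: str
    longitude: float
    latitude: float
    taxa: frozenset[str]
    earliest_bp: int
    latest_bp: int

    def __post_init__(self):
        if self.latest_bp > self.earliest_bp:
            raise ValueError(
                f"site {self.site_id}: latest_bp ({self.latest_bp}) exceeds "
                f"earliest_bp ({self.earliest_bp})"
            )
        if self.latest_bp < 0:
            raise ValueError(f"site {self.site_id}: negative date")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"site {self.site_id}: longitude out of range")
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"site {self.site_id}: latitude out of range")
        if not self.taxa:
            raise ValueError(f"site {self.site_id}: empty taxa set")
        if not isinstance(self.taxa, frozenset):
            object.__setattr__(self, "taxa", frozenset(self.taxa))


@dataclass(frozen=True)
class TimeSlice:
    """A labelled closed integer interval of years BP."""

    label: str
    start_bp: int  # inclusive lower (younger) bound
    end_bp: int  # inclusive upper (older) bound

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError(f"slice {self.label}: start_bp > end_bp")

    def contains(self, year_bp: int) -> bool:
        return self.start_bp <= year_bp <= self.end_bp

    def overlaps(self, latest_bp: int, earliest_bp: int) -> bool:
        return self.start_bp <= earliest_bp and latest_bp <= self.end_bp


@dataclass(frozen=True)
class TimeSliceScheme:
    """Ordered, pairwise-disjoint slices whose union is one contiguous
    integer range of years BP."""

    slices: tuple[TimeSlice, ...]

    def __post_init__(self):
        if not self.slices:
            raise ValueError("scheme needs at least one slice")
        object.__setattr__(self, "slices", tuple(self.slices))
        ordered = sorted(self.slices, key=lambda s: s.start_bp)
        for younger, older in zip(ordered, ordered[1:]):
            if older.start_bp != younger.end_bp + 1:
                raise ValueError(
                    f"slices {younger.label} and {older.label} are not "
                    "contiguous/disjoint at integer-year resolution"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.slices)

    @property
    def start_bp(self) -> int:
        return min(s.start_bp for s in self.slices)

    @property
    def end_bp(self) -> int:
        return max(s.end_bp for s in self.slices)

    def __getitem__(self, label: str) -> TimeSlice:
        for s in self.slices:
            if s.label == label:
                return s
        raise KeyError(label)

    def slice_of(self, year_bp: int) -> TimeSlice | None:
        """The unique slice containing an integer year, or None."""
        for s in self.slices:
            if s.contains(year_bp):
                return s
        return None


#: Eight Holocene slices used throughout: each label names the rounded
#: mid-century of its interval, jointly covering 200-7850 BP.
DEFAULT_SCHEME = TimeSliceScheme(
    (
        TimeSlice("600", 200, 1000),
        TimeSlice("1500", 1001, 2000),
        TimeSlice("2500", 2001, 3000),
        TimeSlice("3500", 3001, 4000),
        TimeSlice("4500", 4001, 5000),
        TimeSlice("5500", 5001, 6000),
        TimeSlice("6500", 6001, 7000),
        TimeSlice("7500", 7001, 7850),
    )
)


@dataclass(frozen=True)
class SlicedObservation:
    """Presence/absence of one taxon at one site in one time slice."""

    site_id: str
    longitude: float
    latitude: float
    slice_label: str
    taxon: str
    status: str  # PRESENCE or ABSENCE

    def __post_init__(self):
        if self.status not in (PRESENCE, ABSENCE):
            raise ValueError(f"bad status {self.status!r}")


DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "site": "site",
    "lon": "longitude",
    "lat": "latitude",
    "taxon": "taxon",
    "earliest_bp": "earliest_bp",
    "latest_bp": "latest_bp",
}


@dataclass
class IngestReport:
    """Row-level accounting of a record-file ingest."""

    n_rows: int = 0
    n_sites: int = 0
    dropped_missing_coords: int = 0
    dropped_bad_dates: int = 0
    dropped_interval_order: int = 0

    @property
    def n_dropped(self) -> int:
        return (
            self.dropped_missing_coords
            + self.dropped_bad_dates
            + self.dropped_interval_order
        )


def read_paleo_records(
    path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> tuple[list[PaleoSite], IngestReport]:
    """Read a faunal compilation (CSV/TSV, one row per site-assemblage-taxon).

    Parameters
    ----------
    path:
        Delimited text file. ``sep=None`` sniffs the delimiter.
    column_map:
        Maps the logical names ``site, lon, lat, taxon, earliest_bp,
        latest_bp`` to the file's column names.

    Returns one :class:`PaleoSite` per (site, date-interval) group, taxa
    unioned across rows, plus an :class:`IngestReport` counting dropped rows.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    with open(path) as fh:
        if not fh.read(4096).strip():
            raise EmptyInputError(f"no rows in {path}")
    try:
        df = pd.read_csv(path, sep=sep, engine="python")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"no rows in {path}") from None
    if df.empty:
        raise EmptyInputError(f"no rows in {path}")

    for logical, col in cmap.items():
        if col not in df.columns:
            raise ConfigurationError(
                f"mandatory column {col!r} (mapped from {logical!r}) "
                f"not found in {path}"
            )

    report = IngestReport(n_rows=len(df))

    lon = pd.to_numeric(df[cmap["lon"]], errors="coerce")
    lat = pd.to_numeric(df[cmap["lat"]], errors="coerce")
    earliest = pd.to_numeric(df[cmap["earliest_bp"]], errors="coerce")
    latest = pd.to_numeric(df[cmap["latest_bp"]], errors="coerce")

    bad_coords = lon.isna() | lat.isna()
    bad_dates = ~bad_coords & (earliest.isna() | latest.isna() | (earliest < 0) | (latest < 0))
    bad_order = ~bad_coords & ~bad_dates & (latest > earliest)
    report.dropped_missing_coords = int(bad_coords.sum())
    report.dropped_bad_dates = int(bad_dates.sum())
    report.dropped_interval_order = int(bad_order.sum())

    keep = ~(bad_coords | bad_dates | bad_order)
    clean = pd.DataFrame(
        {
            "site": df[cmap["site"]].astype(str),
            "lon": lon,
            "lat": lat,
            "taxon": df[cmap["taxon"]].astype(str),
            "earliest": earliest,
            "latest": latest,
        }
    )[keep]

    sites: list[PaleoSite] = []
    for (site_id, e_bp, l_bp), grp in clean.groupby(
        ["site", "earliest", "latest"], sort=True
    ):
        sites.append(
            PaleoSite(
                site_id=str(site_id),
                longitude=float(grp["lon"].iloc[0]),
                latitude=float(grp["lat"].iloc[0]),
                taxa=frozenset(grp["taxon"]),
                earliest_bp=int(e_bp),
                latest_bp=int(l_bp),
            )
        )
    report.n_sites = len(sites)
    return sites, report


def interval_midpoint(latest_bp: int, earliest_bp: int) -> int:
    """Midpoint of a closed date interval, rounding half up."""
    return (earliest_bp + latest_bp + 1) // 2


def assign_time_slices(
    site: PaleoSite,
    scheme: TimeSliceScheme = DEFAULT_SCHEME,
    mode: str = "interval",
) -> set[str]:
    """Labels of the slices a site's date interval is assigned to.

    ``mode="interval"`` assigns to every slice the interval overlaps fully
    or partially; ``mode="midpoint"`` assigns only to the slice containing
    the rounded interval midpoint.  An interval wholly outside the scheme's
    range yields an empty set (with a logged warning).
    """
    if mode not in ("interval", "midpoint"):
        raise ValueError(f"mode must be 'interval' or 'midpoint', got {mode!r}")

    if mode == "interval":
        labels = {
            s.label
            for s in scheme.slices
            if s.overlaps(site.latest_bp, site.earliest_bp)
        }
    else:
        mid = interval_midpoint(site.latest_bp, site.earliest_bp)
        hit = scheme.slice_of(mid)
        labels = {hit.label} if hit is not None else set()

    if not labels:
        logger.warning(
            "site %s: date interval [%d, %d] BP lies outside the scheme "
            "range %d-%d BP; record dropped from slicing",
            site.site_id,
            site.latest_bp,
            site.earliest_bp,
            scheme.start_bp,
            scheme.end_bp,
        )
    return labels


def presence_absence_table(
    sites: Sequence[PaleoSite],
    taxon: str,
    scheme: TimeSliceScheme = DEFAULT_SCHEME,
    mode: str = "interval",
) -> list[SlicedObservation]:
    """Derive per-(site, slice) presence/absence of one taxon.

    Exactly one observation per (site_id, slice) pair: presence if *any*
    assemblage of that site assigned to the slice contains the taxon
    (presence dominates), else absence.
    """
    if not taxon:
        raise ValueError("taxon name must be non-empty")

    # (site_id, slice) -> [is_presence, lon, lat]
    cells: dict[tuple[str, str], list] = {}
    for site in sites:
        has_taxon = taxon in site.taxa
        for label in assign_time_slices(site, scheme, mode):
            key = (site.site_id, label)
            if key in cells:
                cells[key][0] = cells[key][0] or has_taxon
            else:
                cells[key] = [has_taxon, site.longitude, site.latitude]

    label_order = {lab: i for i, lab in enumerate(scheme.labels)}
    out = [
        SlicedObservation(
            site_id=sid,
            longitude=lon,
            latitude=lat,
            slice_label=lab,
            taxon=taxon,
            status=PRESENCE if present else ABSENCE,
        )
        for (sid, lab), (present, lon, lat) in cells.items()
    ]
    out.sort(key=lambda o: (label_order[o.slice_label], o.site_id))
    return out


def site_richness(sites: Iterable[PaleoSite]) -> dict[str, int]:
    """Species richness per site: cardinality of the union of taxa over all
    assemblages sharing a site_id."""
    taxa: dict[str, set[str]] = {}
    for site in sites:
        taxa.setdefault(site.site_id, set()).update(site.taxa)
    return {sid: len(tx) for sid, tx in taxa.items()}


def observations_to_frame(obs: Sequence[SlicedObservation]) -> pd.DataFrame:
    """Sliced observations as a tidy table (CSV-ready)."""
    return pd.DataFrame(
        {
            "site_id": [o.site_id for o in obs],
            "longitude": [o.longitude for o in obs],
            "latitude": [o.latitude for o in obs],
            "slice": [o.slice_label for o in obs],
            "taxon": [o.taxon for o in obs],
            "status": [o.status for o in obs],
        }
    )
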