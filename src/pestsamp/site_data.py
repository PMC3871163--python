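"""Site dataset containers and I/O.

A *site* is a one-time dense pre-sample of a pest-infested stand: one row
per surveyed tree, with local metre coordinates, the infestation measures
(percent of needles galled, optionally a raw gall count), and the order in
which the field crew visited the trees.  Everything downstream — dispersion
fitting, spatial diagnostics, simulated sampling — operates on this
container.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TreeRecord",
    "SiteSample",
    "GeoReference",
    "convert_latlon",
    "read_site",
    "write_site",
    "round_pct_to_pseudocount",
]

#: Mean Earth radius in metres, used by the local equirectangular projection.
EARTH_RADIUS_M = 6_371_000.0


@dataclass(frozen=True)
class TreeRecord:
    """One surveyed tree.

    Parameters
    ----------
    tree_id : str
        Label, unique within a site.
    east, north : float
        Local coordinates in metres.
    pct_galled : float
        Percent of needles galled, in [0, 100].
    collection_index : int
        1-based position in the field-collection order.
    gall_count : int, optional
        Raw gall count, when recorded.
    """

    tree_id: str
    east: float
    north: float
    pct_galled: float
    collection_index: int
    gall_count: int | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.east) and math.isfinite(self.north)):
            raise ValueError(f"tree {self.tree_id!r}: non-finite coordinates")
        if not 0.0 <= self.pct_galled <= 100.0:
            raise ValueError(
                f"tree {self.tree_id!r}: pct_galled={self.pct_galled} outside [0, 100]"
            )
        if self.gall_count is not None and self.gall_count < 0:
            raise ValueError(f"tree {self.tree_id!r}: negative gall_count")


@dataclass
class SiteSample:
    """An ordered pre-sample of trees for one site.

    ``trees`` are stored in field-collection order; this is the universe that
    every simulated sampling scheme draws from.
    """

    site_id: str
    trees: list[TreeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.trees) < 1:
            raise ValueError("a site needs at least one tree")
        idx = [t.collection_index for t in self.trees]
        if len(set(idx)) != len(idx):
            raise ValueError(f"site {self.site_id!r}: duplicate collection_index")

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def coords(self) -> np.ndarray:
        """(N, 2) array of (east, north) metres."""
        return np.array([[t.east, t.north] for t in self.trees], dtype=float)

    def pct_values(self) -> np.ndarray:
        return np.array([t.pct_galled for t in self.trees], dtype=float)

    def gall_counts(self) -> np.ndarray:
        if any(t.gall_count is None for t in self.trees):
            raise ValueError(f"site {self.site_id!r}: gall_count not recorded")
        return np.array([t.gall_count for t in self.trees], dtype=int)

    def pseudocounts(self) -> np.ndarray:
        """Percent galling rounded to the nearest 1% (integer pseudo-counts)."""
        return np.array(
            [round_pct_to_pseudocount(t.pct_galled) for t in self.trees], dtype=int
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": self.site_id,
                "tree_id": [t.tree_id for t in self.trees],
                "east_m": [t.east for t in self.trees],
                "north_m": [t.north for t in self.trees],
                "pct_galled": [t.pct_galled for t in self.trees],
                "gall_count": [t.gall_count for t in self.trees],
                "collection_index": [t.collection_index for t in self.trees],
            }
        )


@dataclass(frozen=True)
class GeoReference:
    """Reference point for the local equirectangular projection."""

    lat0: float
    lon0: float
    earth_radius: float = EARTH_RADIUS_M

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat0 <= 90.0:
            raise ValueError("lat0 outside [-90, 90]")
        if self.earth_radius <= 0:
            raise ValueError("earth_radius must be positive")


def convert_latlon(
    lat: float, lon: float, ref: GeoReference
) -> tuple[float, float]:
    """Convert degrees latitude/longitude to local (east, north) metres.

    Equirectangular (small-area) approximation about the reference point:
    north is proportional to the latitude offset, east to the longitude
    offset scaled by cos(lat0).  Adequate for stands spanning ~1 km.
    """
    if not (math.isfinite(lat) and math.isfinite(lon)):
        raise ValueError("non-finite coordinate")
    if not -90.0 <= lat <= 90.0:
        raise ValueError(f"latitude {lat} outside [-90, 90]")
    rad = math.pi / 180.0
    north = ref.earth_radius * (lat - ref.lat0) * rad
    east = ref.earth_radius * math.cos(ref.lat0 * rad) * (lon - ref.lon0) * rad
    return east, north


def round_pct_to_pseudocount(pct: float) -> int:
    """Round a percent-galling value to the nearest 1%, halves away from zero.

    The rounded value is a *pseudo-count*: an integer that discrete count
    distributions (here the negative binomial) can be fitted to.
    """
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"pct={pct} outside [0, 100]")
    return int(math.floor(pct + 0.5))


# Column roles understood by read_site; east/north OR lat/lon must be mapped.
_ROLES = (
    "site_id",
    "tree_id",
    "east",
    "north",
    "lat",
    "lon",
    "pct_galled",
    "gall_count",
    "collection_index",
)


def read_site(
    path: str | Path,
    column_map: Mapping[str, str],
    site_id: str | None = None,
    geo_ref: GeoReference | None = None,
) -> SiteSample:
    """Read a delimited site table into a :class:`SiteSample`.

    Parameters
    ----------
    path : path
        CSV file with a header row.
    column_map : mapping
        Maps roles (``tree_id``, ``east``, ``north``, ``lat``, ``lon``,
        ``pct_galled``, ``gall_count``, ``collection_index``) to the file's
        column names.  ``pct_galled`` plus either metre coordinates
        (``east``/``north``) or degree coordinates (``lat``/``lon``) are
        required; the rest are optional.  Explicit mapping is deliberate:
        deposited field tables do not share a column layout.
    site_id : str, optional
        Defaults to the file stem.
    geo_ref : GeoReference, optional
        Required when lat/lon columns are mapped.
    """
    path = Path(path)
    unknown = set(column_map) - set(_ROLES)
    if unknown:
        raise ValueError(f"unknown column roles: {sorted(unknown)}")

    df = pd.read_csv(path)
    for role, col in column_map.items():
        if col not in df.columns:
            raise ValueError(f"column {col!r} (role {role!r}) not found in {path.name}")

    if "pct_galled" not in column_map:
        raise ValueError("column_map must map 'pct_galled'")
    has_metric = "east" in column_map and "north" in column_map
    has_geo = "lat" in column_map and "lon" in column_map
    if not has_metric and not has_geo:
        raise ValueError("column_map must map 'east'+'north' or 'lat'+'lon'")
    if has_geo and not has_metric and geo_ref is None:
        raise ValueError("geo_ref is required when coordinates are lat/lon")

    n = len(df)
    if has_metric:
        east = df[column_map["east"]].astype(float).to_numpy()
        north = df[column_map["north"]].astype(float).to_numpy()
    else:
        lat = df[column_map["lat"]].astype(float).to_numpy()
        lon = df[column_map["lon"]].astype(float).to_numpy()
        en = [convert_latlon(la, lo, geo_ref) for la, lo in zip(lat, lon)]
        east = np.array([e for e, _ in en])
        north = np.array([no for _, no in en])

    pct = df[column_map["pct_galled"]].astype(float).to_numpy()
    for i, p in enumerate(pct):
        if not 0.0 <= p <= 100.0:
            raise ValueError(
                f"{path.name} row {i + 2}: pct_galled={p} outside [0, 100]"
            )

    ids = (
        df[column_map["tree_id"]].astype(str).tolist()
        if "tree_id" in column_map
        else [f"T{i + 1:04d}" for i in range(n)]
    )
    if "gall_count" in column_map:
        gc = df[column_map["gall_count"]]
        galls = [None if pd.isna(v) else int(v) for v in gc]
    else:
        galls = [None] * n
    order = (
        df[column_map["collection_index"]].astype(int).tolist()
        if "collection_index" in column_map
        else list(range(1, n + 1))
    )

    if site_id is None:
        if "site_id" in column_map:
            site_id = str(df[column_map["site_id"]].iloc[0])
        else:
            site_id = path.stem

    rows = sorted(range(n), key=lambda i: order[i])
    trees = [
        TreeRecord(
            tree_id=ids[i],
            east=float(east[i]),
            north=float(north[i]),
            pct_galled=float(pct[i]),
            collection_index=int(order[i]),
            gall_count=galls[i],
        )
        for i in rows
    ]
    return SiteSample(site_id=site_id, trees=trees)


def write_site(site: SiteSample, path: str | Path) -> None:
    """Write a site as CSV in the canonical column order."""
    site.to_dataframe().to_csv(path, index=False)


def read_site_canonical(path: str | Path, site_id: str | None = None) -> SiteSample:
    """Read a CSV previously written by :func:`write_site`."""
    return read_site(
        path,
        {
            "site_id": "site_id",
            "tree_id": "tree_id",
            "east": "east_m",
            "north": "north_m",
            "pct_galled": "pct_galled",
            "gall_count": "gall_count",
            "collection_index": "collection_index",
        },
        site_id=site_id,
    )
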