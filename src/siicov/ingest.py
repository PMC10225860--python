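"""Reading and annualizing the two observation streams.

Two very different data-collection processes feed the indicator:

* *occurrence records* — dated, georeferenced point reports of a species,
  Darwin-Core-style CSV (``scientificName``, ``decimalLatitude``,
  ``decimalLongitude``, ``eventDate``);
* *camera-trap data* — a deployments table (camera placements with an active
  start/end interval) plus a detections table (species detections keyed by
  deployment).

Both are reduced to the same currency, an :class:`AnnualPresence`: the
deduplicated set of (accepted species, grid cell, calendar year) triples.
Repeated images, sequences and same-day duplicates all collapse to a single
triple, because every downstream coverage metric is defined at location-year
resolution.

Every dropped row is counted in a conservation ledger so that
``kept + dropped == input`` at every stage.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridSpec
from .taxonomy import SynonymTable, normalize_name

__all__ = [
    "IngestError",
    "AnnualPresence",
    "parse_event_date",
    "read_occurrences",
    "read_camtrap",
    "annualize_occurrences",
    "annualize_detections",
    "annualize",
    "merge_sources",
]

_DATE_FULL = re.compile(r"^(\d{4})-(\d{2})-(\d{2})")
_DATE_YM = re.compile(r"^(\d{4})-(\d{2})$")
_DATE_Y = re.compile(r"^(\d{4})$")


class IngestError(ValueError):
    """Malformed input table (missing columns, broken referential integrity)."""


def parse_event_date(value) -> tuple[int | None, dt.date | None]:
    """Parse an ISO-8601-ish event date into (year, day-resolution date).

    Full dates (optionally with a time suffix) give both; year-month and
    year-only values give a year but no date — such records still support
    annual presence but are excluded from unique-day counting. Unparseable
    values give ``(None, None)``.
    """
    s = str(value).strip()
    m = _DATE_FULL.match(s)
    if m:
        try:
            d = dt.date(int(m[1]), int(m[2]), int(m[3]))
        except ValueError:
            return None, None
        return d.year, d
    m = _DATE_YM.match(s)
    if m and 1 <= int(m[2]) <= 12:
        return int(m[1]), None
    m = _DATE_Y.match(s)
    if m:
        return int(m[1]), None
    return None, None


@dataclass(frozen=True)
class AnnualPresence:
    """Deduplicated (species, cell_id, year) presences from one source."""

    grid_key: str
    source: str
    triples: frozenset  # of (accepted_species: str, cell_id: int, year: int)

    def __len__(self) -> int:
        return len(self.triples)

    def cells_for(self, species: str, year: int) -> set[int]:
        return {c for s, c, y in self.triples if s == species and y == year}

    def species(self) -> set[str]:
        return {s for s, _, _ in self.triples}

    def to_dataframe(self) -> pd.DataFrame:
        rows = sorted(self.triples)
        return pd.DataFrame(rows, columns=["species", "cell_id", "year"]).assign(
            source=self.source
        )


def _require_columns(df: pd.DataFrame, required: set[str], what: str) -> None:
    missing = required - set(df.columns)
    if missing:
        raise IngestError(f"{what} is missing mandatory columns: {sorted(missing)}")


def read_occurrences(
    path,
    table: SynonymTable,
    grid: GridSpec,
    window: tuple[int, int] = (2010, 2022),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Read a Darwin-Core-style occurrence CSV into analysis-ready records.

    Returns ``(records, ledger)`` where records carry ``accepted_species``,
    ``cell_id``, ``year``, ``date`` (NaT when only year/month resolution) and
    ``day_resolution``; the ledger counts every dropped-row category.
    """
    raw = pd.read_csv(path, dtype={"scientificName": str, "eventDate": str})
    _require_columns(
        raw,
        {"scientificName", "decimalLatitude", "decimalLongitude", "eventDate"},
        "occurrence CSV",
    )
    ledger = {"n_input": len(raw)}

    lat = pd.to_numeric(raw["decimalLatitude"], errors="coerce")
    lon = pd.to_numeric(raw["decimalLongitude"], errors="coerce")
    coord_ok = lat.between(-90, 90) & lon.between(-180, 180)
    ledger["dropped_invalid_coordinate"] = int((~coord_ok).sum())

    parsed = raw["scientificName"].map(
        lambda n: table.lookup(normalize_name(n)) if pd.notna(n) else None
    )
    name_ok = parsed.notna()
    ledger["dropped_unresolved_name"] = int((coord_ok & ~name_ok).sum())

    years, dates = zip(*(parse_event_date(v) for v in raw["eventDate"]))
    years = pd.Series(years, index=raw.index, dtype="Int64")
    dates = pd.Series(dates, index=raw.index, dtype=object)
    date_ok = years.notna()
    ledger["dropped_unparseable_date"] = int((coord_ok & name_ok & ~date_ok).sum())

    in_window = date_ok & years.ge(window[0]) & years.le(window[1])
    ledger["dropped_outside_window"] = int(
        (coord_ok & name_ok & date_ok & ~in_window).sum()
    )

    keep = coord_ok & name_ok & in_window
    cell_ids = np.full(len(raw), -1, dtype=np.int64)
    if keep.any():
        cell_ids[keep.to_numpy()] = grid.point_ids(
            lon[keep].to_numpy(), lat[keep].to_numpy()
        )
    in_extent = pd.Series(cell_ids >= 0, index=raw.index)
    ledger["dropped_outside_grid"] = int((keep & ~in_extent).sum())
    keep &= in_extent
    ledger["n_kept"] = int(keep.sum())

    out = pd.DataFrame(
        {
            "accepted_species": parsed[keep],
            "longitude": lon[keep],
            "latitude": lat[keep],
            "cell_id": cell_ids[keep.to_numpy()],
            "year": years[keep].astype(int),
            "date": pd.to_datetime(dates[keep], errors="coerce"),
        }
    ).reset_index(drop=True)
    out["day_resolution"] = out["date"].notna()
    return out, ledger


_CAMTRAP_DP_RENAMES = {
    "deploymentID": "deployment_id",
    "deploymentStart": "start_date",
    "deploymentEnd": "end_date",
    "scientificName": "species",
    "eventStart": "detection_date",
    "timestamp": "detection_date",
}


def read_camtrap(
    deployments_path,
    detections_path,
    table: SynonymTable,
    grid: GridSpec,
    header_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Read deployment + detection CSVs with referential-integrity checks.

    Deployments need ``deployment_id, longitude, latitude, start_date,
    end_date``; detections need ``deployment_id, species, detection_date``
    (Camtrap-DP column names are accepted and renamed). Deployments with
    ``end < start``, bad dates or out-of-grid coordinates are rejected and
    counted; orphan detections, unresolved names and detections outside
    their deployment's active interval are dropped and counted.
    """
    renames = dict(_CAMTRAP_DP_RENAMES)
    if header_map:
        renames.update(header_map)

    dep = pd.read_csv(deployments_path, dtype={"deployment_id": str}).rename(
        columns=renames
    )
    det = pd.read_csv(detections_path, dtype={"deployment_id": str}).rename(
        columns=renames
    )
    _require_columns(
        dep,
        {"deployment_id", "longitude", "latitude", "start_date", "end_date"},
        "deployments CSV",
    )
    _require_columns(
        det, {"deployment_id", "species", "detection_date"}, "detections CSV"
    )
    dep["deployment_id"] = dep["deployment_id"].astype(str)
    det["deployment_id"] = det["deployment_id"].astype(str)
    if dep["deployment_id"].duplicated().any():
        dup = dep.loc[dep["deployment_id"].duplicated(), "deployment_id"].iloc[0]
        raise IngestError(f"duplicate deployment_id {dup!r}")

    ledger = {"n_deployments_input": len(dep), "n_detections_input": len(det)}

    start = pd.to_datetime(dep["start_date"], errors="coerce")
    end = pd.to_datetime(dep["end_date"], errors="coerce")
    dates_ok = start.notna() & end.notna()
    order_ok = dates_ok & (start <= end)
    ledger["deployments_dropped_bad_dates"] = int((~dates_ok).sum())
    ledger["deployments_dropped_end_before_start"] = int((dates_ok & ~order_ok).sum())

    cell_ids = grid.point_ids(dep["longitude"].to_numpy(), dep["latitude"].to_numpy())
    in_extent = pd.Series(cell_ids >= 0, index=dep.index)
    ledger["deployments_dropped_outside_grid"] = int((order_ok & ~in_extent).sum())
    keep_dep = order_ok & in_extent
    ledger["n_deployments_kept"] = int(keep_dep.sum())

    dep_out = pd.DataFrame(
        {
            "deployment_id": dep["deployment_id"][keep_dep],
            "longitude": dep["longitude"][keep_dep],
            "latitude": dep["latitude"][keep_dep],
            "start_date": start[keep_dep],
            "end_date": end[keep_dep],
            "cell_id": cell_ids[keep_dep.to_numpy()],
        }
    ).reset_index(drop=True)

    # detections: name resolution, orphan check, active-window check
    accepted = det["species"].map(
        lambda n: table.lookup(normalize_name(n)) if pd.notna(n) else None
    )
    name_ok = accepted.notna()
    ledger["detections_dropped_unresolved_name"] = int((~name_ok).sum())

    ddate = pd.to_datetime(det["detection_date"], errors="coerce")
    ddate_ok = ddate.notna()
    ledger["detections_dropped_bad_date"] = int((name_ok & ~ddate_ok).sum())

    dep_idx = dep_out.set_index("deployment_id")
    known = det["deployment_id"].isin(dep_idx.index)
    ledger["detections_dropped_orphan"] = int((name_ok & ddate_ok & ~known).sum())

    keep_det = name_ok & ddate_ok & known
    sub = det[keep_det].copy()
    sub["accepted_species"] = accepted[keep_det]
    sub["detection_date"] = ddate[keep_det].dt.normalize()
    joined = sub.join(
        dep_idx[["start_date", "end_date", "cell_id"]], on="deployment_id"
    )
    in_window = (joined["detection_date"] >= joined["start_date"]) & (
        joined["detection_date"] <= joined["end_date"]
    )
    ledger["detections_dropped_outside_deployment_window"] = int((~in_window).sum())
    joined = joined[in_window]
    ledger["n_detections_kept"] = len(joined)

    det_out = joined[
        ["deployment_id", "accepted_species", "detection_date", "cell_id"]
    ].reset_index(drop=True)
    det_out["year"] = det_out["detection_date"].dt.year
    return dep_out, det_out, ledger


def annualize_occurrences(
    records: pd.DataFrame, grid: GridSpec, source: str = "occ"
) -> AnnualPresence:
    """Collapse occurrence records to unique (species, cell, year) triples."""
    triples = frozenset(
        (str(s), int(c), int(y))
        for s, c, y in zip(
            records["accepted_species"], records["cell_id"], records["year"]
        )
    )
    return AnnualPresence(grid.key(), source, triples)


def annualize_detections(
    detections: pd.DataFrame, grid: GridSpec, source: str = "ct"
) -> AnnualPresence:
    """Collapse camera-trap detections to unique (species, cell, year) triples.

    The image-versus-sequence distinction disappears here: any number of
    records of one species at one deployment in one year yields one triple.
    """
    triples = frozenset(
        (str(s), int(c), int(y))
        for s, c, y in zip(
            detections["accepted_species"], detections["cell_id"], detections["year"]
        )
    )
    return AnnualPresence(grid.key(), source, triples)


def annualize(
    occurrences: pd.DataFrame, detections: pd.DataFrame, grid: GridSpec
) -> dict[str, AnnualPresence]:
    """Annualize both sources; keys ``"occ"`` and ``"ct"``."""
    return {
        "occ": annualize_occurrences(occurrences, grid),
        "ct": annualize_detections(detections, grid),
    }


def merge_sources(a: AnnualPresence, b: AnnualPresence) -> AnnualPresence:
    """Set union of two presence sets defined on the same grid."""
    if a.grid_key != b.grid_key:
        raise IngestError(
            f"cannot merge presences on different grids: "
            f"{a.grid_key!r} != {b.grid_key!r}"
        )
    return AnnualPresence(a.grid_key, f"{a.source}+{b.source}", a.triples | b.triples)
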