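"""Synthetic occurrence and camera-trap worlds with known ground truth.

The real corpora behind the indicator (a global occurrence-record aggregate
and a camera-trap platform) are far beyond desk scale, so every pipeline
stage is exercised against simulated worlds that reproduce the two streams'
contrasting statistical structure:

* occurrence sampling is *idiosyncratic*: a cell-year receives a small,
  spatially biased Poisson number of visit days, and on each visit day each
  locally expected species is recorded independently with probability
  ``p_occ``;
* camera-trap sampling is *continuous*: a deployment occupies one location
  for a long uninterrupted interval, and on each active day each locally
  expected species is detected independently with probability ``p_det``.

Species ranges are connected blobs of grid cells grown by seeded stochastic
accretion. Every stochastic choice flows from one root seed through named
child streams (``ranges``, ``occurrence``, ``camtrap``), so each stage is
independently reproducible.

The generator emits exactly the CSV dialects the ingest module consumes, a
synonym table (a fraction of emitted names are synonym variants, exercising
harmonization), and a :class:`TruthBundle` carrying the exact realized
(species, cell, year) sets per source plus closed-form observation
probabilities — the oracle payload for exact-equality and stochastic tests.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import DEFAULT_CRS_ID, GridSpec
from .taxonomy import SynonymTable, build_synonym_table

__all__ = [
    "WorldConfig",
    "TruthBundle",
    "World",
    "build_world_grid",
    "simulate_ranges",
    "simulate_occurrence_records",
    "simulate_camtrap_surveys",
    "expected_truth",
    "simulate_world",
    "write_world",
    "analytic_occurrence_cell_prob",
    "analytic_camtrap_detection_prob",
]


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of one synthetic world. All randomness derives from `seed`.

    Defaults describe a small study region (40x40 cells of 110 km), 30
    species split evenly between mammals and birds, six years, sparse biased
    occurrence sampling (a handful of visit days per cell-year) against long
    continuous camera-trap deployments — the structural contrast the
    analysis is about.
    """

    seed: int
    n_cols: int = 40
    n_rows: int = 40
    n_mammals: int = 15
    n_birds: int = 15
    range_size_min: int = 4
    range_size_max: int = 60
    year_start: int = 2017
    year_end: int = 2022
    lambda_occ: float = 3.0      # mean occurrence visit days per cell-year
    bias_strength: float = 1.5   # log-scale amplitude of the spatial bias field
    p_occ: float = 0.5           # per-visit-day per-species record probability
    n_deployments: int = 60
    deployment_days_min: int = 30
    deployment_days_max: int = 150
    p_det: float = 0.05          # per-active-day per-species detection probability
    p_synonym: float = 0.1       # fraction of emitted names using a synonym variant
    lon0: float = 0.0
    lat0: float = -20.0
    cell_size: float = 110_000.0
    crs_id: str = DEFAULT_CRS_ID

    def __post_init__(self) -> None:
        for p in (self.p_occ, self.p_det, self.p_synonym):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.lambda_occ < 0:
            raise ValueError("lambda_occ must be >= 0")
        if self.year_end < self.year_start:
            raise ValueError("year_end before year_start")
        if not (1 <= self.range_size_min <= self.range_size_max):
            raise ValueError("range sizes must satisfy 1 <= min <= max")
        if self.range_size_max > self.n_cols * self.n_rows:
            raise ValueError("range_size_max exceeds the number of grid cells")

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)

    @property
    def species_names(self) -> list[str]:
        return [f"Mammalus species{i:03d}" for i in range(self.n_mammals)] + [
            f"Avianus species{i:03d}" for i in range(self.n_birds)
        ]

    def species_class(self, name: str) -> str:
        return "mammal" if name.startswith("Mammalus") else "bird"


def _streams(config: WorldConfig) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(config.seed)
    names = ("ranges", "occurrence", "camtrap")
    return {n: np.random.default_rng(s) for n, s in zip(names, root.spawn(len(names)))}


def build_world_grid(config: WorldConfig) -> GridSpec:
    """Grid with exactly ``n_cols x n_rows`` cells anchored at (lon0, lat0)."""
    spec = GridSpec(config.crs_id, config.cell_size, 0.0, 0.0, config.n_cols,
                    config.n_rows)
    x0, y0 = spec.projection.forward(config.lon0, config.lat0)
    return GridSpec(
        config.crs_id, config.cell_size, float(x0), float(y0),
        config.n_cols, config.n_rows,
    )


def synonym_table_df(config: WorldConfig) -> pd.DataFrame:
    """Synonym CSV rows: each accepted name plus one historical variant."""
    rows = []
    for name in config.species_names:
        genus, epithet = name.split()
        rows.append({"variant": name, "accepted": name,
                     "class": config.species_class(name)})
        rows.append({"variant": f"{genus}oides {epithet}", "accepted": name,
                     "class": config.species_class(name)})
    return pd.DataFrame(rows)


def _variant_of(name: str) -> str:
    genus, epithet = name.split()
    return f"{genus}oides {epithet}"


def simulate_ranges(
    config: WorldConfig, rng: np.random.Generator | None = None
) -> dict[str, set[int]]:
    """Grow one connected cell blob per species by stochastic accretion.

    The blob starts at a uniformly drawn cell and repeatedly annexes a
    uniformly drawn frontier neighbour until it reaches its drawn size, so
    each range is connected with exactly the drawn number of cells.
    """
    rng = rng if rng is not None else _streams(config)["ranges"]
    nc, nr = config.n_cols, config.n_rows
    ranges: dict[str, set[int]] = {}
    for name in config.species_names:
        size = int(rng.integers(config.range_size_min, config.range_size_max + 1))
        start = int(rng.integers(0, nc * nr))
        blob = {start}
        frontier = set()

        def neighbours(cid: int):
            c, r = cid % nc, cid // nc
            if c > 0:
                yield cid - 1
            if c < nc - 1:
                yield cid + 1
            if r > 0:
                yield cid - nc
            if r < nr - 1:
                yield cid + nc

        frontier.update(n for n in neighbours(start))
        while len(blob) < size:
            if not frontier:  # boxed in (cannot happen for size <= n_cells)
                raise ValueError(f"cannot grow range of size {size}")
            pick = sorted(frontier)[int(rng.integers(0, len(frontier)))]
            frontier.discard(pick)
            blob.add(pick)
            frontier.update(n for n in neighbours(pick) if n not in blob)
        ranges[name] = blob
    return ranges


def _bias_field(config: WorldConfig) -> np.ndarray:
    """Smooth exp-gradient accessibility proxy over cells, id-indexed."""
    ids = np.arange(config.n_cols * config.n_rows)
    cols = ids % config.n_cols
    rows = ids // config.n_cols
    denom = max(config.n_cols + config.n_rows - 2, 1)
    u = (cols + rows) / denom  # 0 at one corner, 1 at the opposite
    return np.exp(config.bias_strength * (u - 0.5))


def _jitter_lonlat(
    grid: GridSpec, cell_id: int, rng: np.random.Generator
) -> tuple[float, float]:
    """A point inside the cell, kept off the edges so it round-trips exactly."""
    cell = grid.cell_from_id(cell_id)
    fx, fy = rng.uniform(0.05, 0.95, size=2)
    x = grid.origin_x + (cell.col + fx) * grid.cell_size
    y = grid.origin_y + (cell.row + fy) * grid.cell_size
    lon, lat = grid.projection.inverse(x, y)
    return float(lon), float(lat)


def _species_by_cell(ranges: dict[str, set[int]]) -> dict[int, list[str]]:
    out: dict[int, list[str]] = {}
    for sp in sorted(ranges):
        for cid in ranges[sp]:
            out.setdefault(cid, []).append(sp)
    return out


def simulate_occurrence_records(
    config: WorldConfig,
    ranges: dict[str, set[int]],
    grid: GridSpec | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the occurrence stream.

    Per cell-year the number of visit days is Poisson(lambda_occ * bias);
    on each visit day every locally expected species is recorded with
    probability ``p_occ``. Returns ``(records, truth)``: records in the
    Darwin-Core CSV dialect (names possibly as synonym variants, points
    jittered within the cell), truth rows with the accepted name, cell id,
    year and date of every emitted record.
    """
    rng = rng if rng is not None else _streams(config)["occurrence"]
    grid = grid if grid is not None else build_world_grid(config)
    bias = _bias_field(config)
    by_cell = _species_by_cell(ranges)

    rec_rows, truth_rows = [], []
    for cid in sorted(by_cell):
        local = by_cell[cid]
        for year in config.years:
            n_days_in_year = (dt.date(year, 12, 31) - dt.date(year, 1, 1)).days + 1
            v = int(rng.poisson(config.lambda_occ * bias[cid]))
            v = min(v, n_days_in_year)
            if v == 0:
                continue
            doys = rng.choice(n_days_in_year, size=v, replace=False)
            for doy in sorted(int(d) for d in doys):
                date = dt.date(year, 1, 1) + dt.timedelta(days=doy)
                hits = rng.random(len(local)) < config.p_occ
                for sp, hit in zip(local, hits):
                    if not hit:
                        continue
                    lon, lat = _jitter_lonlat(grid, cid, rng)
                    use_syn = rng.random() < config.p_synonym
                    rec_rows.append(
                        {
                            "scientificName": _variant_of(sp) if use_syn else sp,
                            "decimalLatitude": lat,
                            "decimalLongitude": lon,
                            "eventDate": date.isoformat(),
                        }
                    )
                    truth_rows.append(
                        {"species": sp, "cell_id": cid, "year": year,
                         "date": date.isoformat()}
                    )
    rec_cols = ["scientificName", "decimalLatitude", "decimalLongitude", "eventDate"]
    truth_cols = ["species", "cell_id", "year", "date"]
    return (
        pd.DataFrame(rec_rows, columns=rec_cols),
        pd.DataFrame(truth_rows, columns=truth_cols),
    )


def simulate_camtrap_surveys(
    config: WorldConfig,
    ranges: dict[str, set[int]],
    grid: GridSpec | None = None,
    rng: np.random.Generator | None = None,
    deployment_cells: list[int] | None = None,
    fixed_start: dt.date | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw the camera-trap stream.

    Deployments are placed uniformly among cells intersecting at least one
    species range (cameras target wildlife areas); each is active for a
    drawn number of consecutive days starting on a uniform day of a uniform
    study year; on each active day every locally expected species is
    detected with probability ``p_det``. Returns
    ``(deployments, detections, truth)`` where truth carries accepted names
    and cell ids per detection.

    A fixed survey design can be imposed for calibration studies:
    ``deployment_cells`` places one deployment per listed cell (overriding
    ``n_deployments`` and random placement) and ``fixed_start`` pins every
    deployment's start date, leaving only the per-day detection coin-flips
    random. With ``deployment_days_min == deployment_days_max == d`` the
    probability a locally expected species is detected at a deployment is
    exactly ``1 - (1 - p_det)**d``.
    """
    rng = rng if rng is not None else _streams(config)["camtrap"]
    grid = grid if grid is not None else build_world_grid(config)
    by_cell = _species_by_cell(ranges)
    candidate_cells = sorted(by_cell)
    if not candidate_cells and deployment_cells is None:
        raise ValueError("no cell intersects any species range")

    dep_rows, det_rows, truth_rows = [], [], []
    years = list(config.years)
    n_deployments = (
        len(deployment_cells) if deployment_cells is not None else config.n_deployments
    )
    for i in range(n_deployments):
        dep_id = f"dep{i:04d}"
        if deployment_cells is not None:
            cid = int(deployment_cells[i])
        else:
            cid = candidate_cells[int(rng.integers(0, len(candidate_cells)))]
        if fixed_start is not None:
            start = fixed_start
        else:
            year = years[int(rng.integers(0, len(years)))]
            n_days_in_year = (dt.date(year, 12, 31) - dt.date(year, 1, 1)).days + 1
            start = dt.date(year, 1, 1) + dt.timedelta(
                days=int(rng.integers(0, n_days_in_year))
            )
        duration = int(
            rng.integers(config.deployment_days_min, config.deployment_days_max + 1)
        )
        end = start + dt.timedelta(days=duration - 1)
        lon, lat = _jitter_lonlat(grid, cid, rng)
        dep_rows.append(
            {
                "deployment_id": dep_id,
                "longitude": lon,
                "latitude": lat,
                "start_date": start.isoformat(),
                "end_date": end.isoformat(),
            }
        )
        local = by_cell.get(cid, [])
        for day in range(duration):
            date = start + dt.timedelta(days=day)
            hits = rng.random(len(local)) < config.p_det
            for sp, hit in zip(local, hits):
                if not hit:
                    continue
                use_syn = rng.random() < config.p_synonym
                det_rows.append(
                    {
                        "deployment_id": dep_id,
                        "species": _variant_of(sp) if use_syn else sp,
                        "detection_date": date.isoformat(),
                    }
                )
                truth_rows.append(
                    {"species": sp, "cell_id": cid, "year": date.year,
                     "date": date.isoformat(), "deployment_id": dep_id}
                )
    dep_cols = ["deployment_id", "longitude", "latitude", "start_date", "end_date"]
    det_cols = ["deployment_id", "species", "detection_date"]
    truth_cols = ["species", "cell_id", "year", "date", "deployment_id"]
    return (
        pd.DataFrame(dep_rows, columns=dep_cols),
        pd.DataFrame(det_rows, columns=det_cols),
        pd.DataFrame(truth_rows, columns=truth_cols),
    )


def analytic_occurrence_cell_prob(config: WorldConfig, cell_id: int) -> float:
    """Marginal probability a locally expected species is recorded in a
    cell-year: 1 - exp(-lambda * bias * p_occ) (Poisson-thinned Bernoulli)."""
    lam = config.lambda_occ * float(_bias_field(config)[cell_id])
    return 1.0 - float(np.exp(-lam * config.p_occ))


def analytic_camtrap_detection_prob(config: WorldConfig, duration_days: int) -> float:
    """Probability a locally expected species is detected at least once
    during a deployment of fixed duration d: 1 - (1 - p_det)^d."""
    return 1.0 - (1.0 - config.p_det) ** duration_days


@dataclass(frozen=True)
class TruthBundle:
    """Exact realized presences per source, for oracle-equivalence tests."""

    ranges: dict[str, set[int]]
    observed_occ: frozenset  # (species, cell_id, year)
    observed_ct: frozenset
    occ_truth: pd.DataFrame = field(repr=False)
    ct_truth: pd.DataFrame = field(repr=False)


def expected_truth(
    ranges: dict[str, set[int]],
    occ_truth: pd.DataFrame,
    ct_truth: pd.DataFrame,
) -> TruthBundle:
    """Distil the raw simulated tables into exact realized presence sets."""
    def _triples(df: pd.DataFrame) -> frozenset:
        return frozenset(
            (str(s), int(c), int(y))
            for s, c, y in zip(df["species"], df["cell_id"], df["year"])
        )

    return TruthBundle(ranges, _triples(occ_truth), _triples(ct_truth),
                       occ_truth, ct_truth)


@dataclass(frozen=True)
class World:
    """A fully realized synthetic world: inputs plus ground truth."""

    config: WorldConfig
    grid: GridSpec
    synonyms: pd.DataFrame
    ranges: dict[str, set[int]]
    occurrences: pd.DataFrame
    deployments: pd.DataFrame
    detections: pd.DataFrame
    truth: TruthBundle

    @property
    def synonym_table(self) -> SynonymTable:
        return build_synonym_table(
            self.synonyms[["variant", "accepted", "class"]].itertuples(
                index=False, name=None
            )
        )


def simulate_world(config: WorldConfig) -> World:
    """Run all generator stages under the config's seed-splitting scheme."""
    streams = _streams(config)
    grid = build_world_grid(config)
    ranges = simulate_ranges(config, streams["ranges"])
    occ, occ_truth = simulate_occurrence_records(
        config, ranges, grid, streams["occurrence"]
    )
    dep, det, ct_truth = simulate_camtrap_surveys(
        config, ranges, grid, streams["camtrap"]
    )
    return World(
        config=config,
        grid=grid,
        synonyms=synonym_table_df(config),
        ranges=ranges,
        occurrences=occ,
        deployments=dep,
        detections=det,
        truth=expected_truth(ranges, occ_truth, ct_truth),
    )


def write_world(world: World, outdir) -> dict[str, Path]:
    """Write a world's input CSVs (and range cells) to a directory.

    Emits occurrences.csv, deployments.csv, detections.csv, synonyms.csv and
    ranges_cells.csv — exactly the dialects the ingest and grid readers
    consume.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "occurrences": outdir / "occurrences.csv",
        "deployments": outdir / "deployments.csv",
        "detections": outdir / "detections.csv",
        "synonyms": outdir / "synonyms.csv",
        "ranges": outdir / "ranges_cells.csv",
    }
    world.occurrences.to_csv(paths["occurrences"], index=False)
    world.deployments.to_csv(paths["deployments"], index=False)
    world.detections.to_csv(paths["detections"], index=False)
    world.synonyms.to_csv(paths["synonyms"], index=False)
    range_rows = [
        {"species": sp, "cell_id": cid}
        for sp in sorted(world.ranges)
        for cid in sorted(world.ranges[sp])
    ]
    pd.DataFrame(range_rows, columns=["species", "cell_id"]).to_csv(
        paths["ranges"], index=False
    )
    return paths
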