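"""Coverage metrics: sampling days, taxonomic coverage, SII and boosts.

Four metric families quantify how well two observation streams document
species distributions on an equal-area grid:

* **sampling days** — per grid cell and year, the number of unique calendar
  days with data collection: distinct record dates for occurrence data,
  distinct active-deployment days for camera traps. The two distributions
  are compared with a Welch (unequal-variance) two-sample t-test.
* **taxonomic coverage** — per cell, the percentage of the species expected
  there (from coarsened expert range maps) with at least one observation.
* **SII (Species Information Index)** — per species and year, the proportion
  O/E of its E expected range cells that hold at least one observation that
  year. Annual values are averaged over a multi-year window, with zero-
  observation years contributing 0 (skipping them would inflate the mean).
  The national SII averages species-level window means across all species
  expected in a country, each evaluated on the portion of its range inside
  the national border.
* **boosts** — the complementarity of a second source: percentage-point
  deltas in taxonomic coverage, and the percent difference in mean SII
  between a baseline source and the union of baseline plus the second
  source. A unit whose baseline is exactly zero but whose combined value is
  positive is reported as a "newly covered" sentinel rather than an infinite
  percent gain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import Cell, GridSpec
from .ingest import AnnualPresence

__all__ = [
    "MetricError",
    "NEWLY_COVERED",
    "unique_sampling_days_occurrences",
    "active_deployment_days",
    "WelchResult",
    "compare_day_distributions",
    "taxonomic_coverage_cell",
    "taxonomic_coverage_delta",
    "species_sii_year",
    "species_sii_mean",
    "SIISeries",
    "sii_series",
    "NationalSII",
    "national_sii",
    "coverage_boost_percent",
]


class MetricError(ValueError):
    """Precondition violation in a coverage metric."""


class _NewlyCovered:
    """Sentinel: baseline coverage was zero, combined coverage positive."""

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "NEWLY_COVERED"


NEWLY_COVERED = _NewlyCovered()


# ---------------------------------------------------------------------------
# sampling days
# ---------------------------------------------------------------------------


def unique_sampling_days_occurrences(
    records: pd.DataFrame, grid: GridSpec
) -> pd.DataFrame:
    """Unique days with >=1 occurrence record per (cell, year).

    Only day-resolution records count; year-only and year-month dates cannot
    support a day tally and are excluded upstream. Any species counts — the
    tally measures collection activity, not taxon-specific effort.
    Returns rows (cell_id, year, n_unique_days), emitted only where >=1 day.
    """
    day = records[records["day_resolution"]] if "day_resolution" in records else records
    if not len(day):
        return pd.DataFrame(columns=["cell_id", "year", "n_unique_days"]).astype(
            {"cell_id": int, "year": int, "n_unique_days": int}
        )
    out = (
        day.groupby(["cell_id", "year"])["date"]
        .nunique()
        .rename("n_unique_days")
        .reset_index()
        .sort_values(["cell_id", "year"], ignore_index=True)
    )
    return out


def active_deployment_days(deployments: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Unique days covered by the union of active deployments per (cell, year).

    Each deployment contributes every calendar date in its inclusive
    [start, end] interval; overlapping deployments in one cell do not double
    count. Intervals spanning a year boundary are split by calendar year.
    """
    per_cell_year: dict[tuple[int, int], set] = {}
    for cell_id, start, end in zip(
        deployments["cell_id"], deployments["start_date"], deployments["end_date"]
    ):
        days = np.arange(
            np.datetime64(start, "D"), np.datetime64(end, "D") + 1, dtype="datetime64[D]"
        )
        years = days.astype("datetime64[Y]").astype(int) + 1970
        for y in np.unique(years):
            per_cell_year.setdefault((int(cell_id), int(y)), set()).update(
                days[years == y].tolist()
            )
    rows = [
        {"cell_id": c, "year": y, "n_unique_days": len(s)}
        for (c, y), s in per_cell_year.items()
    ]
    if not rows:
        return pd.DataFrame(columns=["cell_id", "year", "n_unique_days"]).astype(int)
    return (
        pd.DataFrame(rows)
        .sort_values(["cell_id", "year"], ignore_index=True)
        .astype({"cell_id": int, "year": int, "n_unique_days": int})
    )


@dataclass(frozen=True)
class WelchResult:
    """Welch two-sample comparison of day-count distributions.

    Shares report, per sample, the fraction of cell-years at or below
    ``low_threshold`` days and above ``high_threshold`` days.
    """

    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    share_a_low: float
    share_b_low: float
    share_a_high: float
    share_b_high: float
    low_threshold: int
    high_threshold: int


def compare_day_distributions(
    days_a: Sequence[float],
    days_b: Sequence[float],
    low_threshold: int = 30,
    high_threshold: int = 100,
) -> WelchResult:
    """Welch t-test plus descriptive statistics for two day-count samples.

    The statistic is t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b)
    with the Welch-Satterthwaite degrees of freedom
    df = (s_a^2/n_a + s_b^2/n_b)^2 /
         [ (s_a^2/n_a)^2/(n_a-1) + (s_b^2/n_b)^2/(n_b-1) ],
    and a two-sided p-value from the t distribution. The unequal-variance
    form is required: cell-year day counts from the two sources have very
    different spreads.
    """
    a = np.asarray(days_a, dtype=float)
    b = np.asarray(days_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise MetricError("each sample needs at least 2 observations")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0.0 and vb == 0.0 and a.mean() != b.mean():
        raise MetricError("both samples are degenerate (zero variance)")
    sea = va / a.size
    seb = vb / b.size
    denom = math.sqrt(sea + seb)
    if denom == 0.0:
        t_stat, dfree, p = 0.0, float(a.size + b.size - 2), 1.0
    else:
        t_stat = (a.mean() - b.mean()) / denom
        dfree = (sea + seb) ** 2 / (
            sea**2 / (a.size - 1) + seb**2 / (b.size - 1)
        )
        from scipy import stats

        p = 2.0 * stats.t.sf(abs(t_stat), dfree)
    return WelchResult(
        t=float(t_stat),
        df=float(dfree),
        p=float(p),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        share_a_low=float((a <= low_threshold).mean()),
        share_b_low=float((b <= low_threshold).mean()),
        share_a_high=float((a > high_threshold).mean()),
        share_b_high=float((b > high_threshold).mean()),
        low_threshold=low_threshold,
        high_threshold=high_threshold,
    )


# ---------------------------------------------------------------------------
# taxonomic coverage
# ---------------------------------------------------------------------------


def taxonomic_coverage_cell(
    expected_species: set, observed_species: set
) -> tuple[float, set]:
    """Percent of a cell's expected species with >=1 observation there.

    Returns ``(percent, unexpected)`` where *unexpected* are observed species
    absent from the expert-expected list — reported for diagnostics, never
    counted toward coverage.
    """
    if not expected_species:
        raise MetricError("expected species set is empty; skip cell upstream")
    covered = observed_species & expected_species
    unexpected = observed_species - expected_species
    return 100.0 * len(covered) / len(expected_species), unexpected


def taxonomic_coverage_delta(
    expected: set, observed_base: set, observed_combined: set
) -> float:
    """Percentage-point gain in cell coverage from adding a source.

    Requires ``observed_combined ⊇ observed_base`` (the combined stream is a
    union); a violation indicates an upstream merge bug.
    """
    if not observed_combined >= observed_base:
        raise MetricError(
            "combined observations are not a superset of baseline observations"
        )
    base, _ = taxonomic_coverage_cell(expected, observed_base)
    combined, _ = taxonomic_coverage_cell(expected, observed_combined)
    return combined - base


# ---------------------------------------------------------------------------
# SII
# ---------------------------------------------------------------------------


def _expected_ids(expected_cells: Iterable) -> set[int]:
    return {c.id if isinstance(c, Cell) else int(c) for c in expected_cells}


def species_sii_year(
    expected_cells: Iterable,
    presence: AnnualPresence,
    species: str,
    year: int,
) -> tuple[float, int, int, int]:
    """Annual SII for one species: O/E on its expected range cells.

    E is the number of expected range cells, O the number of those cells
    with at least one presence triple for (species, year). Presences outside
    the expected range never enter O; their count is returned as the fourth
    element so range-map omissions stay visible.

    Returns ``(sii, E, O, n_outside_range)``.
    """
    expected = _expected_ids(expected_cells)
    if not expected:
        raise MetricError(
            f"species {species!r} has an empty expected cell set; exclude it "
            f"from the indicator rather than scoring 0"
        )
    observed = presence.cells_for(species, year)
    inside = observed & expected
    return len(inside) / len(expected), len(expected), len(inside), len(
        observed - expected
    )


def species_sii_mean(
    annual_sii: Mapping[int, float], window: tuple[int, int] = (2010, 2022)
) -> float:
    """Unweighted mean of annual SII over every calendar year in the window.

    Years absent from ``annual_sii`` contribute 0, not a missing value: a
    year with no observations is zero coverage, and skipping it would bias
    the mean upward.
    """
    y0, y1 = window
    if y1 < y0:
        raise MetricError(f"empty window {window}")
    years = range(y0, y1 + 1)
    return sum(annual_sii.get(y, 0.0) for y in years) / len(list(years))


@dataclass(frozen=True)
class SIISeries:
    """Annual SII values and their window mean for one species."""

    species: str
    n_expected_cells: int
    annual: Mapping[int, tuple[float, int]]  # year -> (sii, n_observed_cells)
    window: tuple[int, int]
    mean: float


def sii_series(
    expected_cells: Iterable,
    presence: AnnualPresence,
    species: str,
    window: tuple[int, int] = (2010, 2022),
) -> SIISeries:
    """Annual SII across a window plus the window mean, for one species."""
    annual: dict[int, tuple[float, int]] = {}
    e = 0
    for year in range(window[0], window[1] + 1):
        sii, e, o, _ = species_sii_year(expected_cells, presence, species, year)
        annual[year] = (sii, o)
    mean = species_sii_mean({y: v[0] for y, v in annual.items()}, window)
    return SIISeries(species, e, annual, window, mean)


@dataclass(frozen=True)
class NationalSII:
    """Mean species-level SII across all species expected in a country."""

    country_code: str
    species_class: str | None
    n_species: int
    mean_sii: float
    source: str
    per_species: Mapping[str, float] = field(default_factory=dict)


def national_sii(
    country_code: str,
    clipped_ranges: Mapping[str, Iterable],
    presence: AnnualPresence,
    window: tuple[int, int] = (2010, 2022),
    species_class: Mapping[str, str] | None = None,
    class_filter: str | None = None,
) -> NationalSII:
    """National SII: mean of per-species window-mean SII within a country.

    ``clipped_ranges`` maps species to the cells of their range *inside* the
    national border; species whose clipped range is empty are excluded (they
    are not expected in the country). Observations are implicitly restricted
    to the clipped cells because O counts only expected cells.
    """
    per_species: dict[str, float] = {}
    for sp, cells in sorted(clipped_ranges.items()):
        if class_filter and species_class and species_class.get(sp) != class_filter:
            continue
        ids = _expected_ids(cells)
        if not ids:
            continue
        per_species[sp] = sii_series(ids, presence, sp, window).mean
    if not per_species:
        raise MetricError(
            f"no species with a non-empty clipped range in {country_code!r}"
        )
    return NationalSII(
        country_code=country_code,
        species_class=class_filter,
        n_species=len(per_species),
        mean_sii=sum(per_species.values()) / len(per_species),
        source=presence.source,
        per_species=per_species,
    )


def coverage_boost_percent(base_sii: float, combined_sii: float):
    """Percent difference in mean SII from adding the second source.

    ``100 * (combined - base) / base`` for a positive baseline. A zero
    baseline with positive combined coverage returns the
    :data:`NEWLY_COVERED` sentinel — counted separately, never averaged as an
    infinite gain. ``combined < base`` is impossible for a union of sources
    and raises.
    """
    if base_sii < 0:
        raise MetricError("SII cannot be negative")
    if combined_sii < base_sii:
        raise MetricError(
            "combined SII below baseline SII — sources were not merged by union"
        )
    if base_sii == 0.0:
        return NEWLY_COVERED if combined_sii > 0 else 0.0
    return 100.0 * (combined_sii - base_sii) / base_sii
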