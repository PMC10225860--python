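"""End-to-end indicator runs: ingest -> harmonize -> annualize -> metrics.

A run compares coverage under the baseline occurrence source alone against
the union of occurrence plus camera-trap data, and writes one CSV per metric
family plus a JSON manifest (config echo, grid identity, conservation
ledgers, Welch day-count comparison, output hashes). Outputs are fully
deterministic given identical inputs: rows are sorted and floats formatted
with a fixed representation, so repeated runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import metrics
from .grid import GridSpec, load_ranges_cells_csv
from .ingest import (
    AnnualPresence,
    annualize_detections,
    annualize_occurrences,
    merge_sources,
    read_camtrap,
    read_occurrences,
)
from .metrics import NEWLY_COVERED, coverage_boost_percent
from .taxonomy import load_synonym_table

__all__ = ["RunConfig", "PipelineError", "PipelineResult",
           "run_indicator_pipeline", "summarize_complementarity"]

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Inputs and options of one indicator run.

    ``ranges_cells`` is a pre-coarsened CSV of (species, cell_id);
    ``countries_cells`` optionally maps country codes to the grid cells
    inside each border (CSV of country_code, cell_id), enabling national
    aggregation.
    """

    grid: GridSpec
    occurrences: str | Path
    deployments: str | Path
    detections: str | Path
    ranges_cells: str | Path
    synonyms: str | Path
    countries_cells: str | Path | None = None
    window: tuple[int, int] = (2010, 2022)
    low_threshold: int = 30
    high_threshold: int = 100
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.window[1] < self.window[0]:
            raise PipelineError("window start must not exceed window end")


@dataclass
class PipelineResult:
    """In-memory pipeline outputs; `tables` maps file stem to DataFrame."""

    config: RunConfig
    tables: dict[str, pd.DataFrame]
    manifest: dict
    presences: dict[str, AnnualPresence]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for stem, df in self.tables.items():
            p = outdir / f"{stem}.csv"
            df.to_csv(p, index=False, float_format=_FLOAT_FMT)
            paths[stem] = p
        hashes = {
            stem: hashlib.sha256(p.read_bytes()).hexdigest()
            for stem, p in sorted(paths.items())
        }
        manifest = dict(self.manifest, output_sha256=hashes)
        mp = outdir / "manifest.json"
        mp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        paths["manifest"] = mp
        return paths


def _boost_repr(b) -> str:
    # repr round-trips exactly, so boosts re-read from CSV equal the computed value
    return "newly_covered" if b is NEWLY_COVERED else repr(float(b))


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc

        return wrapped

    return deco


def run_indicator_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full indicator computation for one input bundle.

    Metric tables computed: per-cell-year sampling days for both sources,
    annual and window-mean species SII under the baseline source and the
    combined sources with the per-species boost, per-cell taxonomic coverage
    with the percentage-point delta, and (when country membership is given)
    national SII with national boosts. If any stage fails nothing is
    written.
    """
    grid = config.grid
    table = _stage("synonyms")(load_synonym_table)(config.synonyms)
    occ_df, occ_ledger = _stage("occurrences")(read_occurrences)(
        config.occurrences, table, grid, config.window
    )
    dep_df, det_df, ct_ledger = _stage("camtrap")(read_camtrap)(
        config.deployments, config.detections, table, grid
    )
    ranges = _stage("ranges")(load_ranges_cells_csv)(config.ranges_cells, grid)

    presence_occ = annualize_occurrences(occ_df, grid)
    presence_ct = annualize_detections(det_df, grid)
    presence_all = merge_sources(presence_occ, presence_ct)
    presences = {"occ": presence_occ, "ct": presence_ct,
                 "occ+ct": presence_all}

    tables: dict[str, pd.DataFrame] = {}

    # --- sampling days ------------------------------------------------------
    occ_days = metrics.unique_sampling_days_occurrences(occ_df, grid)
    ct_days = metrics.active_deployment_days(dep_df, grid)
    tables["sampling_days"] = (
        pd.concat(
            [occ_days.assign(source="occ"), ct_days.assign(source="ct")],
            ignore_index=True,
        )
        .sort_values(["source", "cell_id", "year"], ignore_index=True)
    )
    welch = None
    if len(occ_days) >= 2 and len(ct_days) >= 2:
        welch = metrics.compare_day_distributions(
            occ_days["n_unique_days"],
            ct_days["n_unique_days"],
            config.low_threshold,
            config.high_threshold,
        )

    # --- species SII + boosts ----------------------------------------------
    annual_rows, species_rows = [], []
    for sp in sorted(ranges):
        cells = ranges[sp]
        if not cells:
            continue
        series = {
            label: metrics.sii_series(cells, pres, sp, config.window)
            for label, pres in (("occ", presence_occ), ("occ+ct", presence_all))
        }
        for label, s in series.items():
            for year, (sii, o) in sorted(s.annual.items()):
                annual_rows.append(
                    {"species": sp, "year": year, "source": label,
                     "n_expected_cells": s.n_expected_cells,
                     "n_observed_cells": o, "sii": sii}
                )
        boost = coverage_boost_percent(series["occ"].mean, series["occ+ct"].mean)
        species_rows.append(
            {
                "species": sp,
                "class": table.class_of.get(sp, ""),
                "n_expected_cells": series["occ"].n_expected_cells,
                "mean_sii_occ": series["occ"].mean,
                "mean_sii_combined": series["occ+ct"].mean,
                "boost_percent": _boost_repr(boost),
            }
        )
    tables["sii_species_annual"] = pd.DataFrame(
        annual_rows,
        columns=["species", "year", "source", "n_expected_cells",
                 "n_observed_cells", "sii"],
    )
    tables["sii_species"] = pd.DataFrame(
        species_rows,
        columns=["species", "class", "n_expected_cells", "mean_sii_occ",
                 "mean_sii_combined", "boost_percent"],
    )

    # --- taxonomic coverage -------------------------------------------------
    expected_by_cell: dict[int, set[str]] = {}
    for sp, cells in ranges.items():
        for cid in cells:
            expected_by_cell.setdefault(int(cid), set()).add(sp)
    y0, y1 = config.window

    def _observed_by_cell(pres: AnnualPresence) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for s, c, y in pres.triples:
            if y0 <= y <= y1:
                out.setdefault(c, set()).add(s)
        return out

    obs_base = _observed_by_cell(presence_occ)
    obs_comb = _observed_by_cell(presence_all)
    cov_rows = []
    for cid in sorted(expected_by_cell):
        exp = expected_by_cell[cid]
        base, _ = metrics.taxonomic_coverage_cell(exp, obs_base.get(cid, set()))
        comb, _ = metrics.taxonomic_coverage_cell(exp, obs_comb.get(cid, set()))
        cov_rows.append(
            {
                "cell_id": cid,
                "n_expected_species": len(exp),
                "coverage_occ_percent": base,
                "coverage_combined_percent": comb,
                "delta_percentage_points": comb - base,
            }
        )
    tables["taxonomic_coverage"] = pd.DataFrame(
        cov_rows,
        columns=["cell_id", "n_expected_species", "coverage_occ_percent",
                 "coverage_combined_percent", "delta_percentage_points"],
    )

    # --- national SII -------------------------------------------------------
    nat_rows = []
    if config.countries_cells is not None:
        cdf = _stage("countries")(pd.read_csv)(config.countries_cells)
        missing = {"country_code", "cell_id"} - set(cdf.columns)
        if missing:
            raise PipelineError(f"[countries] missing columns: {sorted(missing)}")
        for code, sub in cdf.groupby("country_code", sort=True):
            country_cells = set(int(c) for c in sub.cell_id)
            clipped = {
                sp: (set(int(c) for c in cells) & country_cells)
                for sp, cells in ranges.items()
            }
            clipped = {sp: cs for sp, cs in clipped.items() if cs}
            if not clipped:
                continue
            for cls in sorted({table.class_of.get(sp, "") for sp in clipped}):
                sub_ranges = {
                    sp: cs for sp, cs in clipped.items()
                    if table.class_of.get(sp, "") == cls
                }
                if not sub_ranges:
                    continue
                nat_occ = metrics.national_sii(
                    str(code), sub_ranges, presence_occ, config.window
                )
                nat_all = metrics.national_sii(
                    str(code), sub_ranges, presence_all, config.window
                )
                boost = coverage_boost_percent(nat_occ.mean_sii, nat_all.mean_sii)
                nat_rows.append(
                    {
                        "country_code": str(code),
                        "class": cls,
                        "n_species": nat_occ.n_species,
                        "mean_sii_occ": nat_occ.mean_sii,
                        "mean_sii_combined": nat_all.mean_sii,
                        "boost_percent": _boost_repr(boost),
                    }
                )
    tables["sii_national"] = pd.DataFrame(
        nat_rows,
        columns=["country_code", "class", "n_species", "mean_sii_occ",
                 "mean_sii_combined", "boost_percent"],
    )

    manifest = {
        "grid": grid.key(),
        "window": list(config.window),
        "thresholds": {"low": config.low_threshold, "high": config.high_threshold},
        "ledgers": {"occurrences": occ_ledger, "camtrap": ct_ledger},
        "welch_day_comparison": dataclasses.asdict(welch) if welch else None,
        "inputs": {
            k: str(getattr(config, k))
            for k in ("occurrences", "deployments", "detections",
                      "ranges_cells", "synonyms", "countries_cells")
            if getattr(config, k) is not None
        },
    }
    result = PipelineResult(config, tables, manifest, presences)
    if config.outdir is not None:
        result.write(config.outdir)
    return result


def summarize_complementarity(
    result: PipelineResult, min_gain: float = 0.01, big_boost: float = 10.0
) -> pd.DataFrame:
    """Per-class complementarity counts from a pipeline result.

    For each species class: how many species gained any coverage from the
    camera-trap source, how many gained at least ``min_gain`` in mean SII
    (an extra 1% of range covered by default), how many countries improved,
    how many countries improved by more than ``big_boost`` percent, and the
    mean numeric national boost ("newly covered" units counted, not
    averaged).
    """
    sp = result.tables["sii_species"]
    nat = result.tables["sii_national"]
    rows = []
    for cls in sorted(set(sp["class"]) | set(nat["class"] if len(nat) else [])):
        s = sp[sp["class"] == cls]
        gains = s["mean_sii_combined"] - s["mean_sii_occ"]
        n_boosted = int((gains > 0).sum())
        n_big_gain = int((gains >= min_gain).sum())
        n_countries = n_improved = n_big = 0
        boosts = []
        if len(nat):
            nsub = nat[nat["class"] == cls]
            n_countries = len(nsub)
            ngains = nsub["mean_sii_combined"] - nsub["mean_sii_occ"]
            n_improved = int((ngains > 0).sum())
            for b in nsub["boost_percent"]:
                if b == "newly_covered":
                    n_big += 1
                else:
                    val = float(b)
                    boosts.append(val)
                    if val > big_boost:
                        n_big += 1
        rows.append(
            {
                "class": cls,
                "n_species": len(s),
                "n_species_boosted": n_boosted,
                "n_species_gain_ge_min": n_big_gain,
                "n_countries": n_countries,
                "n_countries_improved": n_improved,
                "n_countries_boost_gt_threshold": n_big,
                "mean_national_boost_percent": (
                    sum(boosts) / len(boosts) if boosts else 0.0
                ),
            }
        )
    return pd.DataFrame(rows)
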