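"""Scientific-name harmonization against a synonym table.

Occurrence aggregators and camera-trap platforms report names under differing
taxonomies, spellings and formatting. Downstream metrics require one accepted
name per species, so both observation streams are passed through a synonym
lookup: normalize the raw string, look it up in a many-to-one variant ->
accepted mapping, and either return the accepted binomial or tag the record
unresolved. Matching is exact-after-normalization; no fuzzy matching is
attempted.

Normalization: trim, collapse internal whitespace, fold case to the binomial
convention ("Genus epithet"), and truncate trinomials (subspecies) to the
binomial.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "SynonymConflictError",
    "SynonymTable",
    "HarmonizationReport",
    "normalize_name",
    "load_synonym_table",
    "harmonize_name",
    "harmonize_dataset",
]

_WS = re.compile(r"\s+")


class SynonymConflictError(ValueError):
    """One name variant maps to two different accepted names."""


def normalize_name(raw: str) -> str:
    """Canonical form of a scientific name: "Genus epithet".

    Trims, collapses whitespace, capitalizes the genus, lower-cases the
    epithet, and truncates names with more than two tokens to the binomial.
    """
    tokens = _WS.split(str(raw).strip())
    tokens = [t for t in tokens if t]
    if not tokens:
        return ""
    genus = tokens[0].capitalize()
    if len(tokens) == 1:
        return genus
    return f"{genus} {tokens[1].lower()}"


@dataclass(frozen=True)
class SynonymTable:
    """Many-to-one mapping of normalized name variants to accepted names.

    Every accepted name maps to itself, and each accepted name carries a
    class label (``mammal`` or ``bird``).
    """

    mapping: Mapping[str, str]
    class_of: Mapping[str, str]

    @property
    def accepted_names(self) -> set[str]:
        return set(self.mapping.values())

    def lookup(self, normalized: str) -> str | None:
        return self.mapping.get(normalized)


@dataclass
class HarmonizationReport:
    """Record-level accounting of a harmonization pass."""

    n_input: int = 0
    n_resolved: int = 0
    n_unresolved: int = 0
    unresolved_counts: dict[str, int] = field(default_factory=dict)

    @property
    def resolved_fraction(self) -> float:
        return self.n_resolved / self.n_input if self.n_input else 1.0

    def check(self) -> None:
        assert self.n_resolved + self.n_unresolved == self.n_input


def build_synonym_table(rows: Iterable[tuple[str, str, str]]) -> SynonymTable:
    """Build a table from (variant, accepted, class) rows.

    Identical duplicate rows collapse; a variant mapping to two distinct
    accepted names is a hard error listing the conflicts. Accepted names are
    always entered as self-mappings.
    """
    mapping: dict[str, str] = {}
    class_of: dict[str, str] = {}
    conflicts: list[str] = []
    for variant, accepted, cls in rows:
        v = normalize_name(variant)
        a = normalize_name(accepted)
        if not v or not a:
            continue
        for key, target in ((v, a), (a, a)):
            prior = mapping.get(key)
            if prior is not None and prior != target:
                conflicts.append(f"{key!r} -> {prior!r} and {target!r}")
            else:
                mapping[key] = target
        cls = str(cls).strip().lower()
        prior_cls = class_of.get(a)
        if prior_cls is not None and prior_cls != cls:
            conflicts.append(f"class of {a!r}: {prior_cls!r} and {cls!r}")
        class_of[a] = cls
    if conflicts:
        raise SynonymConflictError(
            "conflicting synonym rows: " + "; ".join(sorted(set(conflicts)))
        )
    return SynonymTable(mapping, class_of)


def load_synonym_table(path) -> SynonymTable:
    """Load a synonym table from a CSV with columns variant, accepted, class."""
    df = pd.read_csv(path, dtype=str)
    missing = {"variant", "accepted", "class"} - set(df.columns)
    if missing:
        raise ValueError(f"synonym CSV missing columns: {sorted(missing)}")
    return build_synonym_table(
        df[["variant", "accepted", "class"]].itertuples(index=False, name=None)
    )


def harmonize_name(raw_name: str, table: SynonymTable) -> str | None:
    """Resolve one raw name to its accepted name, or ``None`` if unresolved."""
    return table.lookup(normalize_name(raw_name))


def harmonize_dataset(
    records: pd.DataFrame,
    table: SynonymTable,
    name_column: str = "scientificName",
) -> tuple[pd.DataFrame, HarmonizationReport]:
    """Harmonize a record table; unresolved rows are dropped and counted.

    Returns the resolved records with an added ``accepted_species`` column
    and a :class:`HarmonizationReport`. Unresolved names are never silently
    dropped: each appears in the report with its record count.
    """
    report = HarmonizationReport(n_input=len(records))
    if not len(records):
        return records.assign(accepted_species=pd.Series(dtype=str)), report
    normalized = records[name_column].map(normalize_name)
    accepted = normalized.map(lambda n: table.lookup(n))
    resolved_mask = accepted.notna()
    report.n_resolved = int(resolved_mask.sum())
    report.n_unresolved = int((~resolved_mask).sum())
    if report.n_unresolved:
        report.unresolved_counts = (
            records.loc[~resolved_mask, name_column].value_counts().to_dict()
        )
    report.check()
    out = records.loc[resolved_mask].copy()
    out["accepted_species"] = accepted.loc[resolved_mask]
    return out, report
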