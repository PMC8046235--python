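"""Species attribute catalog: loading, eligibility filtering, Table-style summaries.

The analysis starts from a Red List-style attribute table of species with
conservation translocation (CT) recommended. A species is an eligible
candidate when it is a terrestrial amphibian, bird or mammal, forest
dependent, has CT among its recommended conservation actions, and is listed
as threatened or Near Threatened (EW/CR/EN/VU/NT — Data Deficient and Least
Concern records are excluded).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

TAXON_CLASSES = ("Amphibia", "Aves", "Mammalia", "other")
REDLIST_CATEGORIES = ("EW", "CR", "EN", "VU", "NT", "DD", "LC", "other")
CT_CATEGORIES = ("reintroduction", "benign_introduction", "unknown")
ACTIONS = ("invasive_species_control", "habitat_restoration", "other")

#: Red List categories that keep a species in the candidate pool.
ELIGIBLE_STATUSES = frozenset({"EW", "CR", "EN", "VU", "NT"})

# Synonyms seen in real Red List exports, folded onto the canonical codes.
_REDLIST_ALIASES = {
    "EXTINCT IN THE WILD": "EW",
    "CRITICALLY ENDANGERED": "CR",
    "ENDANGERED": "EN",
    "VULNERABLE": "VU",
    "NEAR THREATENED": "NT",
    "DATA DEFICIENT": "DD",
    "LEAST CONCERN": "LC",
}
_CLASS_ALIASES = {"AMPHIBIA": "Amphibia", "AVES": "Aves", "MAMMALIA": "Mammalia"}
_CT_ALIASES = {
    "REINTRODUCTION": "reintroduction",
    "BENIGN INTRODUCTION": "benign_introduction",
    "BENIGN_INTRODUCTION": "benign_introduction",
}
_ACTION_ALIASES = {
    "INVASIVE_SPECIES_CONTROL": "invasive_species_control",
    "INVASIVE SPECIES CONTROL": "invasive_species_control",
    "INVASIVE/PROBLEMATIC SPECIES CONTROL": "invasive_species_control",
    "HABITAT_RESTORATION": "habitat_restoration",
    "HABITAT RESTORATION": "habitat_restoration",
    "HABITAT AND NATURAL PROCESSES RESTORATION": "habitat_restoration",
}

_TRUE_STRINGS = {"1", "true", "yes", "y", "t"}
_FALSE_STRINGS = {"0", "false", "no", "n", "f", ""}

#: Default CSV column names; override any entry via the ``schema_config``
#: mapping passed to :func:`load_catalog`.
DEFAULT_SCHEMA = {
    "species_id": "species_id",
    "scientific_name": "scientific_name",
    "taxon_class": "taxon_class",
    "redlist_category": "redlist_category",
    "is_terrestrial": "is_terrestrial",
    "is_forest_dependent": "is_forest_dependent",
    "ct_recommended": "ct_recommended",
    "ct_category": "ct_category",
    "actions_recommended": "actions_recommended",
    "island_dweller": "island_dweller",
    "has_recovery_plan": "has_recovery_plan",
    "has_active_ct_program": "has_active_ct_program",
}


class SchemaError(ValueError):
    """A required catalog column is missing or unmappable."""


@dataclass(frozen=True)
class SpeciesRecord:
    species_id: str
    scientific_name: str
    taxon_class: str
    redlist_category: str
    is_terrestrial: bool
    is_forest_dependent: bool
    ct_recommended: bool
    ct_category: str
    actions_recommended: frozenset[str] = frozenset()
    island_dweller: bool = False
    has_recovery_plan: bool = False
    has_active_ct_program: bool = False

    def __post_init__(self) -> None:
        if self.taxon_class not in TAXON_CLASSES:
            raise ValueError(f"taxon_class {self.taxon_class!r} not in {TAXON_CLASSES}")
        if self.redlist_category not in REDLIST_CATEGORIES:
            raise ValueError(f"redlist_category {self.redlist_category!r} invalid")
        if self.ct_category not in CT_CATEGORIES:
            raise ValueError(f"ct_category {self.ct_category!r} invalid")


@dataclass
class CatalogSummary:
    """Class × Red List status counts with margins (Table-1 layout)."""

    counts: pd.DataFrame  # index: taxon_class; columns: redlist_category

    @property
    def totals_by_class(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def totals_by_status(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def to_frame(self) -> pd.DataFrame:
        """Counts plus a Total row and Total column."""
        out = self.counts.copy()
        out["Total"] = self.totals_by_class
        total_row = out.sum(axis=0)
        total_row.name = "Total"
        return pd.concat([out, total_row.to_frame().T])

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="Class")


def _coerce_enum(raw: str, aliases: dict[str, str], allowed: Sequence[str],
                 fallback: str, context: str) -> str:
    value = (raw or "").strip()
    if value in allowed:
        return value
    canon = aliases.get(value.upper())
    if canon is not None:
        return canon
    logger.warning("unrecognized %s value %r coerced to %r", context, raw, fallback)
    return fallback


def _coerce_bool(raw: str, context: str) -> bool:
    value = (raw or "").strip().lower()
    if value in _TRUE_STRINGS:
        return True
    if value in _FALSE_STRINGS:
        return False
    logger.warning("unrecognized boolean %r in %s treated as False", raw, context)
    return False


def _coerce_actions(raw: str) -> frozenset[str]:
    out = set()
    for token in (raw or "").replace(",", ";").split(";"):
        token = token.strip()
        if not token:
            continue
        out.add(_coerce_enum(token, _ACTION_ALIASES, ACTIONS, "other", "action"))
    return frozenset(out)


def load_catalog(path: str | Path, schema_config: dict[str, str] | None = None) -> list[SpeciesRecord]:
    """Load a species attribute CSV into :class:`SpeciesRecord` objects.

    Parameters
    ----------
    path:
        CSV file with one row per species (UTF-8).
    schema_config:
        Optional mapping from canonical field names (keys of
        :data:`DEFAULT_SCHEMA`) to the column names actually present.

    Raises
    ------
    SchemaError
        If a required mapped column is absent from the header.
    ValueError
        If two rows share a ``species_id``.
    """
    schema = dict(DEFAULT_SCHEMA)
    schema.update(schema_config or {})
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [col for col in schema.values() if col not in header]
        if missing:
            raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
        records: list[SpeciesRecord] = []
        seen: set[str] = set()
        for row in reader:
            sid = row[schema["species_id"]].strip()
            if sid in seen:
                raise ValueError(f"{path}: duplicate species_id {sid!r}")
            seen.add(sid)
            records.append(SpeciesRecord(
                species_id=sid,
                scientific_name=row[schema["scientific_name"]].strip(),
                taxon_class=_coerce_enum(row[schema["taxon_class"]], _CLASS_ALIASES,
                                         TAXON_CLASSES, "other", "taxon_class"),
                redlist_category=_coerce_enum(row[schema["redlist_category"]], _REDLIST_ALIASES,
                                              REDLIST_CATEGORIES, "other", "redlist_category"),
                is_terrestrial=_coerce_bool(row[schema["is_terrestrial"]], "is_terrestrial"),
                is_forest_dependent=_coerce_bool(row[schema["is_forest_dependent"]], "is_forest_dependent"),
                ct_recommended=_coerce_bool(row[schema["ct_recommended"]], "ct_recommended"),
                ct_category=_coerce_enum(row[schema["ct_category"]], _CT_ALIASES,
                                         CT_CATEGORIES, "unknown", "ct_category"),
                actions_recommended=_coerce_actions(row[schema["actions_recommended"]]),
                island_dweller=_coerce_bool(row[schema["island_dweller"]], "island_dweller"),
                has_recovery_plan=_coerce_bool(row[schema["has_recovery_plan"]], "has_recovery_plan"),
                has_active_ct_program=_coerce_bool(row[schema["has_active_ct_program"]], "has_active_ct_program"),
            ))
    return records


def is_candidate(record: SpeciesRecord) -> bool:
    """The five-way eligibility predicate for one species."""
    return (
        record.taxon_class in ("Amphibia", "Aves", "Mammalia")
        and record.is_terrestrial
        and record.is_forest_dependent
        and record.ct_recommended
        and record.redlist_category in ELIGIBLE_STATUSES
    )


def filter_candidates(records: Iterable[SpeciesRecord],
                      exclude_ids: Iterable[str] = ()) -> list[SpeciesRecord]:
    """Keep eligible candidate species, preserving input order.

    ``exclude_ids`` supports dropping species whose source data could not
    separate subspecies (an expert-curated exclusion list, not automated).
    """
    excluded = set(exclude_ids)
    return [r for r in records if r.species_id not in excluded and is_candidate(r)]


def summarize_catalog(records: Iterable[SpeciesRecord]) -> CatalogSummary:
    """Count records by (taxon class, Red List status) with margins."""
    classes = [c for c in TAXON_CLASSES if c != "other"]
    statuses = ["CR", "EN", "EW", "NT", "VU"]
    counts = pd.DataFrame(0, index=classes, columns=statuses, dtype=int)
    for rec in records:
        cls = rec.taxon_class if rec.taxon_class in classes else None
        st = rec.redlist_category if rec.redlist_category in statuses else None
        if cls is None or st is None:
            # Summaries are of already-filtered candidate catalogs; anything
            # else is counted in an explicit overflow row/column.
            cls = cls or "other"
            st = st or "other"
            if cls not in counts.index:
                counts.loc[cls] = 0
            if st not in counts.columns:
                counts[st] = 0
        counts.loc[cls, st] += 1
    return CatalogSummary(counts=counts)


def catalog_to_frame(records: Iterable[SpeciesRecord]) -> pd.DataFrame:
    """One row per species; actions flattened to booleans for analysis."""
    rows = []
    for r in records:
        rows.append({
            "species_id": r.species_id,
            "scientific_name": r.scientific_name,
            "taxon_class": r.taxon_class,
            "redlist_category": r.redlist_category,
            "ct_category": r.ct_category,
            "invasive_control_recommended": "invasive_species_control" in r.actions_recommended,
            "habitat_restoration_recommended": "habitat_restoration" in r.actions_recommended,
            "island_dweller": r.island_dweller,
            "has_recovery_plan": r.has_recovery_plan,
            "has_active_ct_program": r.has_active_ct_program,
        })
    return pd.DataFrame(rows)


def write_catalog_csv(records: Iterable[SpeciesRecord], path: str | Path) -> None:
    """Write records in the same CSV schema :func:`load_catalog` reads."""
    rows = []
    for r in records:
        rows.append({
            "species_id": r.species_id,
            "scientific_name": r.scientific_name,
            "taxon_class": r.taxon_class,
            "redlist_category": r.redlist_category,
            "is_terrestrial": int(r.is_terrestrial),
            "is_forest_dependent": int(r.is_forest_dependent),
            "ct_recommended": int(r.ct_recommended),
            "ct_category": r.ct_category,
            "actions_recommended": ";".join(sorted(r.actions_recommended)),
            "island_dweller": int(r.island_dweller),
            "has_recovery_plan": int(r.has_recovery_plan),
            "has_active_ct_program": int(r.has_active_ct_program),
        })
    pd.DataFrame(rows, columns=list(DEFAULT_SCHEMA.values())).to_csv(path, index=False)
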