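"""Domain types and I/O for individual-level snail survival records.

The experimental unit is one snail with a factorial identity
(species x population x treatment x block), a wet weight in grams, and two
survival flags scored 21 h after each of two 3-h thermal exposures
(the 24-h and 48-h checkpoints of the assay timeline).  Records aggregate
into replicate-level survival proportions, the phenotype used by every
downstream stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

SPECIES_LEVELS = ("littorea", "obtusata", "saxatilis")
POPULATION_LEVELS = ("N", "S")
TREATMENT_LEVELS = ("control", "heat", "cold")
BLOCK_LEVELS = ("A", "B")

CSV_COLUMNS = [
    "snail_id",
    "species",
    "population",
    "treatment",
    "block",
    "wet_weight_g",
    "alive_24h",
    "alive_48h",
]


class SchemaError(ValueError):
    """A CSV is missing a required column."""


class RecordValidationError(ValueError):
    """A row violates the snail-record invariants."""


@dataclass(frozen=True)
class SnailRecord:
    """One snail: factorial identity, wet weight, and the two survival flags.

    Invariants: ``alive_48h <= alive_24h`` (a snail dead at the first
    checkpoint cannot be alive at the second), all factor levels valid,
    weight finite and non-negative.
    """

    snail_id: str
    species: str
    population: str
    treatment: str
    block: str
    wet_weight_g: float
    alive_24h: int
    alive_48h: int

    def __post_init__(self) -> None:
        if self.species not in SPECIES_LEVELS:
            raise RecordValidationError(
                f"invalid species {self.species!r}; expected one of {SPECIES_LEVELS}"
            )
        if self.population not in POPULATION_LEVELS:
            raise RecordValidationError(
                f"invalid population {self.population!r}; expected one of {POPULATION_LEVELS}"
            )
        if self.treatment not in TREATMENT_LEVELS:
            raise RecordValidationError(
                f"invalid treatment {self.treatment!r}; expected one of {TREATMENT_LEVELS}"
            )
        if self.block not in BLOCK_LEVELS:
            raise RecordValidationError(
                f"invalid block {self.block!r}; expected one of {BLOCK_LEVELS}"
            )
        if not math.isfinite(self.wet_weight_g) or self.wet_weight_g < 0:
            raise RecordValidationError(
                f"wet_weight_g must be finite and non-negative, got {self.wet_weight_g}"
            )
        if self.alive_24h not in (0, 1) or self.alive_48h not in (0, 1):
            raise RecordValidationError(
                f"survival flags must be 0/1, got alive_24h={self.alive_24h}, "
                f"alive_48h={self.alive_48h}"
            )
        if self.alive_48h > self.alive_24h:
            raise RecordValidationError(
                "alive_48h > alive_24h: a snail cannot be resurrected between checkpoints"
            )

    @property
    def cell(self) -> tuple[str, str, str, str]:
        return (self.species, self.population, self.treatment, self.block)


@dataclass(frozen=True)
class ReplicateSummary:
    """Per-cell survival tallies: one species x population x treatment x block cell.

    ``prop_surviving`` is the phenotype: the exact fraction of the cell's
    starting snails alive at the chosen endpoint.
    """

    species: str
    population: str
    treatment: str
    block: str
    n_start: int
    n_alive_24h: int
    n_alive_48h: int
    prop_surviving: float
    endpoint: str = "48h"

    def __post_init__(self) -> None:
        if not (0 <= self.n_alive_48h <= self.n_alive_24h <= self.n_start):
            raise RecordValidationError(
                f"count ordering violated: 0 <= {self.n_alive_48h} <= "
                f"{self.n_alive_24h} <= {self.n_start} must hold"
            )
        if self.n_start <= 0:
            raise RecordValidationError("n_start must be positive")

    @property
    def n_alive_endpoint(self) -> int:
        return self.n_alive_48h if self.endpoint == "48h" else self.n_alive_24h

    @property
    def cell(self) -> tuple[str, str, str, str]:
        return (self.species, self.population, self.treatment, self.block)


def records_to_frame(records: Iterable[SnailRecord]) -> pd.DataFrame:
    """Tabulate records as a DataFrame with the canonical column order."""
    return pd.DataFrame([vars(r) for r in records], columns=CSV_COLUMNS)


def summaries_to_frame(summaries: Iterable[ReplicateSummary]) -> pd.DataFrame:
    cols = [
        "species",
        "population",
        "treatment",
        "block",
        "n_start",
        "n_alive_24h",
        "n_alive_48h",
        "prop_surviving",
        "endpoint",
    ]
    return pd.DataFrame([vars(s) for s in summaries], columns=cols)


def read_survival_csv(path: str | Path) -> list[SnailRecord]:
    """Read individual survival records from CSV, validating every row.

    The header must declare all eight canonical columns.  Row order is
    preserved.  Raises :class:`SchemaError` for a missing column and
    :class:`RecordValidationError` (naming the offending row) for an invalid
    level or an ``alive_48h > alive_24h`` breach.
    """
    df = pd.read_csv(path, dtype={"snail_id": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    records: list[SnailRecord] = []
    for idx, row in df.iterrows():
        try:
            records.append(
                SnailRecord(
                    snail_id=str(row["snail_id"]),
                    species=str(row["species"]),
                    population=str(row["population"]),
                    treatment=str(row["treatment"]),
                    block=str(row["block"]),
                    wet_weight_g=float(row["wet_weight_g"]),
                    alive_24h=int(row["alive_24h"]),
                    alive_48h=int(row["alive_48h"]),
                )
            )
        except (RecordValidationError, ValueError) as exc:
            raise RecordValidationError(f"row {idx}: {exc}") from exc
    return records


def write_survival_csv(records: Sequence[SnailRecord], path: str | Path) -> None:
    """Write records to CSV in the canonical schema (booleans as 0/1, UTF-8)."""
    records_to_frame(records).to_csv(path, index=False)


def write_summary_csv(summaries: Sequence[ReplicateSummary], path: str | Path) -> None:
    summaries_to_frame(summaries).to_csv(path, index=False)


def filter_by_weight(
    records: Sequence[SnailRecord], max_weight_g: float = 1.0
) -> list[SnailRecord]:
    """Drop snails *exceeding* the weight threshold (default 1 g).

    The exclusion is strict: a snail weighing exactly the threshold is
    retained.  Body size confounds thermal tolerance, hence the cap.
    Input order is preserved; the number excluded is logged.
    """
    if max_weight_g < 0:
        raise ValueError(f"max_weight_g must be non-negative, got {max_weight_g}")
    kept = [r for r in records if r.wet_weight_g <= max_weight_g]
    n_excluded = len(records) - len(kept)
    if n_excluded:
        logger.info("filter_by_weight: excluded %d of %d records > %g g",
                    n_excluded, len(records), max_weight_g)
    return kept


def aggregate_to_replicates(
    records: Sequence[SnailRecord], endpoint: str = "48h"
) -> list[ReplicateSummary]:
    """Tally individuals into per-cell replicate summaries.

    One summary per observed species x population x treatment x block
    combination, in first-appearance order of the cells.  ``prop_surviving``
    uses the chosen endpoint (``"48h"`` default, ``"24h"`` optional).
    Duplicate snail ids within a cell are an error.
    """
    if endpoint not in ("24h", "48h"):
        raise ValueError(f"endpoint must be '24h' or '48h', got {endpoint!r}")
    if not records:
        logger.warning("aggregate_to_replicates: empty input, empty output")
        return []
    cells: dict[tuple[str, str, str, str], list[SnailRecord]] = {}
    for r in records:
        cells.setdefault(r.cell, []).append(r)
    summaries: list[ReplicateSummary] = []
    for key in sorted(cells):
        members = cells[key]
        ids = [m.snail_id for m in members]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise RecordValidationError(
                f"duplicate snail_id within cell {key}: {dupes}"
            )
        n_start = len(members)
        n24 = sum(m.alive_24h for m in members)
        n48 = sum(m.alive_48h for m in members)
        n_end = n48 if endpoint == "48h" else n24
        summaries.append(
            ReplicateSummary(
                species=key[0],
                population=key[1],
                treatment=key[2],
                block=key[3],
                n_start=n_start,
                n_alive_24h=n24,
                n_alive_48h=n48,
                prop_surviving=n_end / n_start,
                endpoint=endpoint,
            )
        )
    return summaries


# Common column spellings in externally archived survival-assay tables;
# maps them onto the canonical schema.  Override with your own map as needed.
ARCHIVE_COLUMN_MAP = {
    "ID": "snail_id",
    "Species": "species",
    "Population": "population",
    "Treatment": "treatment",
    "Block": "block",
    "Weight": "wet_weight_g",
    "Alive24": "alive_24h",
    "Alive48": "alive_48h",
}


def remap_columns(
    df: pd.DataFrame, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Rename externally named columns onto the canonical schema.

    Helper for ingesting a locally supplied copy of an archived dataset:
    rename with ``column_map`` (default :data:`ARCHIVE_COLUMN_MAP`), matching
    only the columns present; validation happens when the frame is written
    out and re-read through :func:`read_survival_csv`.
    """
    column_map = column_map or ARCHIVE_COLUMN_MAP
    present = {k: v for k, v in column_map.items() if k in df.columns}
    return df.rename(columns=present)
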