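"""Data model and tabular I/O for follicle-maturation screen records.

The raw unit of the screen is a culture well of 20-30 isolated Stage-10B
follicles, cultured overnight in vehicle- or aspirin-treated medium and then
binned by the developmental stage reached: S10B and S11 count as "dumping not
completed", S12 and S13/14 as "completed".  One row of the canonical tidy
table is one well; a screen table bundles the wells of many experiments, each
of which is expected to carry its own wild-type control in both treatments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

VEHICLE = "vehicle"
ASPIRIN = "aspirin"
TREATMENTS = (VEHICLE, ASPIRIN)

#: default column names of the tidy screen table
SCREEN_COLUMNS = (
    "experiment_id",
    "genotype",
    "treatment",
    "aspirin_mM",
    "n_s10b",
    "n_s11",
    "n_s12",
    "n_s13_14",
)

SUMMARY_COLUMNS = (
    "genotype",
    "n",
    "mean_dumping_index",
    "sd_dumping_index",
    "mean_normalized_index",
    "sd_normalized_index",
    "class",
)


class ScreenSchemaError(ValueError):
    """A required column is missing from the input table."""


class ScreenValidationError(ValueError):
    """A row holds a value that cannot be part of a valid screen record."""


@dataclass(frozen=True)
class StageTally:
    """Follicle counts per developmental-stage bucket for one well."""

    n_s10b: int
    n_s11: int
    n_s12: int
    n_s13_14: int

    def __post_init__(self) -> None:
        for name in ("n_s10b", "n_s11", "n_s12", "n_s13_14"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise ScreenValidationError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ScreenValidationError(f"{name} must be non-negative, got {v}")

    def total(self) -> int:
        return self.n_s10b + self.n_s11 + self.n_s12 + self.n_s13_14

    def dumped(self) -> int:
        """Follicles that completed nurse cell dumping (reached S12 or later)."""
        return self.n_s12 + self.n_s13_14

    def not_dumped(self) -> int:
        return self.n_s10b + self.n_s11


@dataclass(frozen=True)
class WellRecord:
    """One culture well: a genotype under one treatment within one experiment."""

    experiment_id: str
    genotype: str
    treatment: str
    tally: StageTally
    aspirin_mM: float = 0.0
    allele_note: str = ""

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ScreenValidationError(
                f"treatment must be one of {TREATMENTS}, got {self.treatment!r}"
            )
        if self.treatment == VEHICLE and self.aspirin_mM not in (0, 0.0):
            raise ScreenValidationError(
                f"vehicle well cannot carry aspirin_mM={self.aspirin_mM}"
            )


@dataclass
class ScreenTable:
    """A validated collection of well records with its control genotype label."""

    records: list[WellRecord]
    control_genotype: str = "yw"
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def experiment_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.experiment_id, None)
        return list(seen)

    def wells_of(self, experiment_id: str) -> list[WellRecord]:
        return [r for r in self.records if r.experiment_id == experiment_id]

    def validate(self) -> list[str]:
        """Check structural invariants; return (and store) warnings.

        Experiments lacking the control genotype in both treatments are
        flagged, never dropped.  Duplicate (experiment, genotype, treatment)
        keys are an error: the scoring rule has no way to combine them.
        """
        seen: set[tuple[str, str, str]] = set()
        for i, r in enumerate(self.records):
            key = (r.experiment_id, r.genotype, r.treatment)
            if key in seen:
                raise ScreenValidationError(
                    f"duplicate well for (experiment={r.experiment_id!r}, "
                    f"genotype={r.genotype!r}, treatment={r.treatment!r}) at record {i}"
                )
            seen.add(key)
        warnings: list[str] = []
        for exp in self.experiment_ids():
            have = {
                r.treatment for r in self.wells_of(exp) if r.genotype == self.control_genotype
            }
            missing = [t for t in TREATMENTS if t not in have]
            if missing:
                warnings.append(
                    f"experiment {exp!r}: missing control genotype "
                    f"{self.control_genotype!r} in treatment(s) {', '.join(missing)}"
                )
        self.warnings = warnings
        for w in warnings:
            logger.warning(w)
        return warnings

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "experiment_id": r.experiment_id,
                    "genotype": r.genotype,
                    "treatment": r.treatment,
                    "aspirin_mM": r.aspirin_mM,
                    "n_s10b": r.tally.n_s10b,
                    "n_s11": r.tally.n_s11,
                    "n_s12": r.tally.n_s12,
                    "n_s13_14": r.tally.n_s13_14,
                }
            )
        return pd.DataFrame(rows, columns=list(SCREEN_COLUMNS))


def _coerce_count(value: object, column: str, row: int) -> int:
    """Parse a stage count; reject negatives and non-integers with row context."""
    try:
        f = float(value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise ScreenValidationError(
            f"row {row}: column {column!r} has non-numeric value {value!r}"
        ) from None
    if f != int(f):
        raise ScreenValidationError(
            f"row {row}: column {column!r} must be an integer count, got {value!r}"
        )
    if f < 0:
        raise ScreenValidationError(
            f"row {row}: column {column!r} must be non-negative, got {value!r}"
        )
    return int(f)


def screen_table_from_dataframe(
    df: pd.DataFrame,
    control_genotype: str = "yw",
    dialect: Mapping[str, str] | None = None,
) -> ScreenTable:
    """Build a validated ScreenTable from a tidy dataframe.

    ``dialect`` maps canonical column names to the names used in ``df``
    (e.g. ``{"n_s13_14": "S13-14"}``); unmapped columns keep their canonical
    name.  Row order is preserved.  Data rows are numbered from 1.
    """
    dialect = dict(dialect or {})
    colmap = {c: dialect.get(c, c) for c in SCREEN_COLUMNS}
    required = [c for c in SCREEN_COLUMNS if c != "aspirin_mM"]
    for canonical in required:
        if colmap[canonical] not in df.columns:
            raise ScreenSchemaError(
                f"missing required column {colmap[canonical]!r} (for {canonical!r})"
            )
    has_mM = colmap["aspirin_mM"] in df.columns

    records: list[WellRecord] = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        treatment = str(row[colmap["treatment"]]).strip().lower()
        if treatment not in TREATMENTS:
            raise ScreenValidationError(
                f"row {i}: treatment must be one of {TREATMENTS}, got {treatment!r}"
            )
        tally = StageTally(
            _coerce_count(row[colmap["n_s10b"]], "n_s10b", i),
            _coerce_count(row[colmap["n_s11"]], "n_s11", i),
            _coerce_count(row[colmap["n_s12"]], "n_s12", i),
            _coerce_count(row[colmap["n_s13_14"]], "n_s13_14", i),
        )
        if has_mM and not pd.isna(row[colmap["aspirin_mM"]]):
            mM = float(row[colmap["aspirin_mM"]])
        else:
            mM = 1.5 if treatment == ASPIRIN else 0.0
        records.append(
            WellRecord(
                experiment_id=str(row[colmap["experiment_id"]]),
                genotype=str(row[colmap["genotype"]]),
                treatment=treatment,
                aspirin_mM=mM,
                tally=tally,
            )
        )
    table = ScreenTable(records, control_genotype=control_genotype)
    table.validate()
    return table


def read_screen_table(
    path: str | Path,
    control_genotype: str = "yw",
    dialect: Mapping[str, str] | None = None,
) -> ScreenTable:
    """Read a screen CSV/TSV (delimiter sniffed from the extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    return screen_table_from_dataframe(df, control_genotype=control_genotype, dialect=dialect)


def write_screen_table(table: ScreenTable, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    table.to_dataframe().to_csv(path, sep=sep, index=False)


def write_summary_table(summaries: Sequence, path: str | Path) -> None:
    """Write genotype summaries as TSV, 6-decimal round-trip safe.

    ``summaries`` are :class:`folliclescreen.scoring.GenotypeSummary` objects
    (duck-typed here to avoid a circular import).  Missing SDs (n = 1) are
    written as empty fields, not zeros.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no summaries to write")
    rows = []
    for s in summaries:
        rows.append(
            {
                "genotype": s.genotype,
                "n": s.n,
                "mean_dumping_index": round(s.mean_di, 6),
                "sd_dumping_index": None if s.sd_di is None else round(s.sd_di, 6),
                "mean_normalized_index": round(s.mean_norm, 6),
                "sd_normalized_index": None if s.sd_norm is None else round(s.sd_norm, 6),
                "class": getattr(s, "interactor_class", None) or "",
            }
        )
    pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_summary_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
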