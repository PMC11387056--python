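"""Individual-plant records for reciprocal-transplant fitness data.

A cohort holds one row per planted seedling with its treatment labels
(site, soil origin, ecotype) and fitness observations (survival to
reproduction, fruit count, and an optional viable-seed count from one
intact mature fruit). Edge-row filler plants are parsed and kept, but
flagged so the analysis filter is an explicit, auditable step.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical column order of the cohort CSV format.
COLUMNS = [
    "plant_id",
    "site",
    "soil",
    "ecotype",
    "survived",
    "fruits",
    "seeds_per_fruit",
    "edge",
]

_TRUE_STRINGS = {"1", "true", "t", "yes"}
_FALSE_STRINGS = {"0", "false", "f", "no"}
#: Only the empty string and the literal "NA" decode to a missing seed count.
_NA_STRINGS = {"", "na"}


class CohortFormatError(ValueError):
    """The file does not have the expected columns or encoding."""


class CohortValidationError(ValueError):
    """One or more rows violate the record invariants.

    Attributes
    ----------
    diagnostics : list of (row, message)
        ``row`` is the 1-based data-row number (header excluded).
    """

    def __init__(self, diagnostics: list[tuple[int, str]]):
        self.diagnostics = list(diagnostics)
        lines = "\n".join(f"  row {r}: {m}" for r, m in self.diagnostics)
        super().__init__(
            f"{len(self.diagnostics)} invalid record(s):\n{lines}"
        )


@dataclass(frozen=True)
class PlantRecord:
    """One planted seedling: treatment labels and fitness observations.

    ``fruits`` is stored as 0 (not missing) for plants that died before
    reproduction, because the overall-fitness proxy needs a zero for every
    planted seedling. ``seeds_per_fruit`` is the viable-seed count from a
    single intact mature fruit, measured only on a subsample of
    reproductive plants.
    """

    plant_id: str
    site: str
    soil: str
    ecotype: str
    survived: bool
    fruits: int
    seeds_per_fruit: Optional[int] = None
    edge: bool = False

    def violations(self) -> list[str]:
        """Return human-readable descriptions of violated invariants."""
        out = []
        if self.fruits < 0:
            out.append(f"fruits must be non-negative, got {self.fruits}")
        if self.seeds_per_fruit is not None and self.seeds_per_fruit < 0:
            out.append(
                "seeds_per_fruit must be non-negative, got "
                f"{self.seeds_per_fruit}"
            )
        if not self.survived:
            if self.fruits != 0:
                out.append(
                    "survived=false requires fruits=0 "
                    f"(got fruits={self.fruits})"
                )
            if self.seeds_per_fruit is not None:
                out.append(
                    "survived=false requires a missing seeds_per_fruit"
                )
        if self.seeds_per_fruit is not None and self.survived and self.fruits < 1:
            out.append("seeds_per_fruit present requires fruits >= 1")
        return out


@dataclass
class Cohort:
    """An ordered collection of :class:`PlantRecord` plus provenance notes.

    The records are stored as a :class:`pandas.DataFrame` with the
    :data:`COLUMNS` layout (``seeds_per_fruit`` is nullable ``Int64``).
    Construction validates every row; a :class:`CohortValidationError`
    listing each offending row is raised rather than silently dropping any.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True)
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise CohortFormatError(f"missing required column(s): {missing}")
        df = df[COLUMNS].copy()
        df["plant_id"] = df["plant_id"].astype(str)
        for c in ("site", "soil", "ecotype"):
            df[c] = df[c].astype(str)
        df["survived"] = df["survived"].astype(bool)
        df["edge"] = df["edge"].astype(bool)
        df["fruits"] = df["fruits"].astype(np.int64)
        df["seeds_per_fruit"] = df["seeds_per_fruit"].astype("Int64")
        self.data = df
        diags = _validate_frame(df)
        if diags:
            raise CohortValidationError(diags)

    # -- construction ---------------------------------------------------
    @classmethod
    def from_records(
        cls, records: Iterable[PlantRecord], metadata: dict | None = None
    ) -> "Cohort":
        rows = [
            {
                "plant_id": r.plant_id,
                "site": r.site,
                "soil": r.soil,
                "ecotype": r.ecotype,
                "survived": r.survived,
                "fruits": r.fruits,
                "seeds_per_fruit": r.seeds_per_fruit,
                "edge": r.edge,
            }
            for r in records
        ]
        df = pd.DataFrame(rows, columns=COLUMNS)
        if df.empty:
            df = _empty_frame()
        return cls(df, metadata or {})

    # -- views ----------------------------------------------------------
    def records(self) -> list[PlantRecord]:
        out = []
        for row in self.data.itertuples(index=False):
            seeds = row.seeds_per_fruit
            out.append(
                PlantRecord(
                    plant_id=row.plant_id,
                    site=row.site,
                    soil=row.soil,
                    ecotype=row.ecotype,
                    survived=bool(row.survived),
                    fruits=int(row.fruits),
                    seeds_per_fruit=None if pd.isna(seeds) else int(seeds),
                    edge=bool(row.edge),
                )
            )
        return out

    @property
    def sites(self) -> list[str]:
        return sorted(self.data["site"].unique())

    def __len__(self) -> int:
        return len(self.data)

    def equals(self, other: "Cohort") -> bool:
        """Field-for-field equality of the record tables (metadata ignored)."""
        return self.data.reset_index(drop=True).equals(
            other.data.reset_index(drop=True)
        )


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "plant_id": pd.Series(dtype=str),
            "site": pd.Series(dtype=str),
            "soil": pd.Series(dtype=str),
            "ecotype": pd.Series(dtype=str),
            "survived": pd.Series(dtype=bool),
            "fruits": pd.Series(dtype=np.int64),
            "seeds_per_fruit": pd.Series(dtype="Int64"),
            "edge": pd.Series(dtype=bool),
        }
    )


def _validate_frame(df: pd.DataFrame) -> list[tuple[int, str]]:
    diags: list[tuple[int, str]] = []
    dup = df["plant_id"].duplicated(keep="first")
    for i in np.flatnonzero(dup.to_numpy()):
        diags.append(
            (int(i) + 1, f"duplicate plant_id {df['plant_id'].iloc[i]!r}")
        )
    surv = df["survived"].to_numpy()
    fruits = df["fruits"].to_numpy()
    seeds_present = df["seeds_per_fruit"].notna().to_numpy()
    for i in np.flatnonzero(fruits < 0):
        diags.append((int(i) + 1, f"fruits must be non-negative, got {fruits[i]}"))
    bad_seed = seeds_present & (df["seeds_per_fruit"].fillna(0).to_numpy() < 0)
    for i in np.flatnonzero(bad_seed):
        diags.append((int(i) + 1, "seeds_per_fruit must be non-negative"))
    for i in np.flatnonzero(~surv & (fruits != 0)):
        diags.append(
            (
                int(i) + 1,
                f"survived=false requires fruits=0 (got fruits={fruits[i]})",
            )
        )
    for i in np.flatnonzero(~surv & seeds_present):
        diags.append((int(i) + 1, "survived=false requires a missing seeds_per_fruit"))
    for i in np.flatnonzero(surv & seeds_present & (fruits < 1)):
        diags.append((int(i) + 1, "seeds_per_fruit present requires fruits >= 1"))
    diags.sort(key=lambda t: t[0])
    return diags


def _parse_int(value: str) -> int:
    """Parse a count; integer-valued decimals like "4.0" are accepted."""
    v = value.strip()
    try:
        return int(v)
    except ValueError:
        f = float(v)  # may raise ValueError for the caller
        if not f.is_integer():
            raise ValueError(f"{value!r} is not an integer")
        return int(f)


def _parse_bool(value: str, column: str, row: int) -> bool:
    v = value.strip().lower()
    if v in _TRUE_STRINGS:
        return True
    if v in _FALSE_STRINGS:
        return False
    raise CohortValidationError(
        [(row, f"cannot parse {column}={value!r} as a boolean")]
    )


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort CSV, validating every row.

    The header must name the :data:`COLUMNS` fields (case-insensitive,
    any order). ``survived``/``edge`` accept 0/1 and true/false; a missing
    ``seeds_per_fruit`` is encoded as an empty cell or the literal "NA".
    Rows violating the record invariants are rejected with row-numbered
    diagnostics (1-based, header excluded); nothing is silently dropped.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw.columns = [c.strip().lower() for c in raw.columns]
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise CohortFormatError(
            f"{path.name}: missing required column(s): {missing}"
        )

    diags: list[tuple[int, str]] = []
    parsed: dict[str, list] = {c: [] for c in COLUMNS}
    seen_ids: set[str] = set()
    for i, row in enumerate(raw.itertuples(index=False), start=1):
        rec = {c: getattr(row, c) for c in COLUMNS}
        try:
            survived = _parse_bool(rec["survived"], "survived", i)
            edge = _parse_bool(rec["edge"], "edge", i)
        except CohortValidationError as exc:
            diags.extend(exc.diagnostics)
            continue
        try:
            fruits = _parse_int(str(rec["fruits"]))
        except ValueError:
            diags.append(
                (i, f"non-integer fruit count {rec['fruits']!r}")
            )
            continue
        seeds_raw = str(rec["seeds_per_fruit"]).strip()
        if seeds_raw.lower() in _NA_STRINGS:
            seeds: Optional[int] = None
        else:
            try:
                seeds = _parse_int(seeds_raw)
            except ValueError:
                diags.append(
                    (i, f"non-integer seeds_per_fruit {seeds_raw!r}")
                )
                continue
        record = PlantRecord(
            plant_id=str(rec["plant_id"]).strip(),
            site=str(rec["site"]).strip(),
            soil=str(rec["soil"]).strip(),
            ecotype=str(rec["ecotype"]).strip(),
            survived=survived,
            fruits=fruits,
            seeds_per_fruit=seeds,
            edge=edge,
        )
        violations = record.violations()
        if record.plant_id in seen_ids:
            violations.append(f"duplicate plant_id {record.plant_id!r}")
        seen_ids.add(record.plant_id)
        if violations:
            diags.extend((i, v) for v in violations)
            continue
        parsed["plant_id"].append(record.plant_id)
        parsed["site"].append(record.site)
        parsed["soil"].append(record.soil)
        parsed["ecotype"].append(record.ecotype)
        parsed["survived"].append(record.survived)
        parsed["fruits"].append(record.fruits)
        parsed["seeds_per_fruit"].append(record.seeds_per_fruit)
        parsed["edge"].append(record.edge)

    if diags:
        raise CohortValidationError(sorted(diags))

    df = pd.DataFrame(parsed, columns=COLUMNS)
    if df.empty:
        df = _empty_frame()
    return Cohort(df, metadata={"source": str(path)})


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort CSV that round-trips through :func:`read_cohort`.

    Booleans are written as 0/1 and missing seed counts as empty cells.
    """
    df = cohort.data.copy()
    df["survived"] = df["survived"].astype(int)
    df["edge"] = df["edge"].astype(int)
    df.to_csv(path, index=False, na_rep="")


def filter_analysis_set(cohort: Cohort) -> Cohort:
    """Restrict a cohort to non-edge records (the analysis set).

    Edge-row filler plants reduce edge effects in the trays but are not
    scored for the analysis. The number of removed records is logged;
    an all-edge cohort yields an empty cohort plus a warning.
    """
    mask = ~cohort.data["edge"].to_numpy()
    removed = int((~mask).sum())
    out = Cohort(
        cohort.data.loc[mask].reset_index(drop=True),
        metadata={**cohort.metadata, "edge_records_removed": removed},
    )
    logger.info("filter_analysis_set: removed %d edge record(s)", removed)
    if len(out) == 0:
        warnings.warn(
            "filter_analysis_set produced an empty cohort", stacklevel=2
        )
    return out
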