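"""Per-cell fitness components for a transplant cohort.

For every (site, soil, ecotype) treatment cell, four summaries are
computed: survival to reproduction (mean over planted seedlings),
fecundity (mean fruits over reproductive plants), seeds per fruit (mean
over the seed-measured subsample), and overall fitness, the expected
seed number per planted seedling. The overall proxy multiplies each
plant's fruit count by the *cell mean* seeds per fruit, so it satisfies
the identity overall = survival x fecundity x seeds_per_fruit exactly
whenever all three are defined.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .records import Cohort

#: Tidy column order of the summaries table.
SUMMARY_COLUMNS = [
    "site",
    "soil",
    "ecotype",
    "n_planted",
    "n_survived",
    "n_seed_measured",
    "survival",
    "fecundity",
    "seeds_per_fruit",
    "overall",
]


@dataclass(frozen=True)
class CellSummary:
    """Fitness summaries of one (site, soil, ecotype) cell.

    ``fecundity`` is missing (NaN) when no plant survived;
    ``seeds_per_fruit`` is missing when no survivor was seed-measured.
    ``overall`` is 0 for an all-dead cell (every planted seedling set no
    seed) and missing when survivors exist but no seed measurement does.
    """

    site: str
    soil: str
    ecotype: str
    n_planted: int
    n_survived: int
    n_seed_measured: int
    survival: float
    fecundity: float
    seeds_per_fruit: float
    overall: float


def summarize_cells(cohort: Union[Cohort, pd.DataFrame]) -> pd.DataFrame:
    """One row of fitness summaries per observed treatment cell.

    Dead plants contribute 0 fruits to overall fitness; survivors whose
    seed count was not measured still contribute their fruit count to
    fecundity and overall. Edge records, if present, are excluded with a
    warning (the explicit analysis filter should normally have removed
    them already).
    """
    df = cohort.data if isinstance(cohort, Cohort) else cohort
    n_edge = int(df["edge"].sum())
    if n_edge:
        warnings.warn(
            f"summarize_cells: excluding {n_edge} edge record(s)",
            stacklevel=2,
        )
        df = df.loc[~df["edge"]]
    if df.empty:
        warnings.warn("summarize_cells: empty cohort", stacklevel=2)
        return pd.DataFrame(columns=SUMMARY_COLUMNS)

    rows = []
    for (site, soil, eco), g in df.groupby(["site", "soil", "ecotype"], sort=True):
        n = len(g)
        survived = g["survived"].to_numpy()
        fruits = g["fruits"].to_numpy(dtype=float)
        seeds = g["seeds_per_fruit"]
        n_surv = int(survived.sum())
        n_meas = int(seeds.notna().sum())
        survival = n_surv / n
        fecundity = float(fruits[survived].sum() / n_surv) if n_surv else math.nan
        spf = (
            float(seeds.dropna().to_numpy(dtype=float).sum() / n_meas)
            if n_meas
            else math.nan
        )
        if n_surv == 0:
            overall = 0.0  # every planted seedling produced zero seeds
        else:
            overall = (fruits.sum() / n) * spf  # NaN when spf is missing
        rows.append(
            {
                "site": site,
                "soil": soil,
                "ecotype": eco,
                "n_planted": n,
                "n_survived": n_surv,
                "n_seed_measured": n_meas,
                "survival": survival,
                "fecundity": fecundity,
                "seeds_per_fruit": spf,
                "overall": overall,
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def cell_summaries(cohort: Union[Cohort, pd.DataFrame]) -> list[CellSummary]:
    """:func:`summarize_cells` as a list of :class:`CellSummary` objects."""
    return [
        CellSummary(**row._asdict())
        for row in summarize_cells(cohort).itertuples(index=False)
    ]


def check_product_identity(summary, rel_tol: float = 1e-12) -> bool:
    """Does overall equal survival x fecundity x seeds_per_fruit?

    ``summary`` is any object with the four component attributes
    (a :class:`CellSummary` or a row from :func:`summarize_cells`).
    All four means must be defined.
    """
    parts = (
        summary.survival,
        summary.fecundity,
        summary.seeds_per_fruit,
        summary.overall,
    )
    if any(x is None or (isinstance(x, float) and math.isnan(x)) for x in parts):
        raise ValueError("all four component means must be defined")
    survival, fecundity, spf, overall = (float(x) for x in parts)
    product = survival * fecundity * spf
    scale = max(abs(overall), abs(product), 1.0)
    return abs(overall - product) <= rel_tol * scale


def write_summaries(summaries: pd.DataFrame, path) -> None:
    """Write the tidy per-cell summary table as CSV."""
    summaries.to_csv(path, index=False)
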