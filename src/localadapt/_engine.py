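"""Vectorized numpy core for stratified bootstrap and soil permutations.

Every record is reduced to a 4-column value matrix
``[survived, fruits, seed_measured, seeds_or_0]``; per-cell sums of those
columns plus the cell count are sufficient statistics for all four
fitness components. Resampling then amounts to recomputing those sums
under row-index resampling (bootstrap) or soil-label reassignment
(permutation), which is done for all replicates at once.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Iterable

import numpy as np
import pandas as pd

from .simulate import COMPONENTS

#: refuse exhaustive enumeration beyond this many assignments per site
MAX_EXHAUSTIVE = 2_000_000


def value_matrix(df: pd.DataFrame) -> np.ndarray:
    """(n, 4) float matrix [survived, fruits, measured, seeds(0-filled)]."""
    seeds = df["seeds_per_fruit"].to_numpy(dtype=float, na_value=np.nan)
    measured = ~np.isnan(seeds)
    return np.column_stack(
        [
            df["survived"].to_numpy(dtype=float),
            df["fruits"].to_numpy(dtype=float),
            measured.astype(float),
            np.where(measured, seeds, 0.0),
        ]
    )


def component_means(n_planted, sums) -> np.ndarray:
    """Fitness-component means from cell counts and value-column sums.

    ``sums[..., :]`` are [n_survived, fruit_sum, n_measured, seed_sum];
    returns an array with a trailing axis of length 4 ordered as
    :data:`~localadapt.simulate.COMPONENTS`. Undefined means are NaN,
    except that an all-dead cell has overall fitness exactly 0.
    """
    n_planted = np.asarray(n_planted, dtype=float)
    sums = np.asarray(sums, dtype=float)
    n_surv = sums[..., 0]
    fruit_sum = sums[..., 1]
    n_meas = sums[..., 2]
    seed_sum = sums[..., 3]
    with np.errstate(divide="ignore", invalid="ignore"):
        survival = np.where(n_planted > 0, n_surv / n_planted, np.nan)
        fecundity = np.where(n_surv > 0, fruit_sum / np.where(n_surv > 0, n_surv, 1.0), np.nan)
        spf = np.where(n_meas > 0, seed_sum / np.where(n_meas > 0, n_meas, 1.0), np.nan)
        overall = np.where(
            n_surv > 0,
            (fruit_sum / np.where(n_planted > 0, n_planted, 1.0)) * spf,
            0.0,
        )
    overall = np.where(n_planted > 0, overall, np.nan)
    return np.stack([survival, fecundity, spf, overall], axis=-1)


def selection_from_means(w_local, w_nonlocal) -> np.ndarray:
    """s = 1 - w_nonlocal / w_local, elementwise; NaN where w_local = 0."""
    w_local = np.asarray(w_local, dtype=float)
    w_nonlocal = np.asarray(w_nonlocal, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = 1.0 - w_nonlocal / np.where(w_local > 0, w_local, np.nan)
    return s


def bootstrap_cell_sums(
    V: np.ndarray, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_boot, 4) value-column sums of within-cell resamples.

    Each replicate draws ``len(V)`` rows with replacement from the cell's
    own rows (stratified bootstrap: cell sizes are preserved).
    """
    n = len(V)
    idx = rng.integers(0, n, size=(n_boot, n))
    return V[idx].sum(axis=1)


def bootstrap_replicates(
    cells: dict, n_boot: int, rng: np.random.Generator
) -> dict:
    """Per-cell component means for every bootstrap replicate.

    ``cells`` maps (site, soil, ecotype) -> value matrix. Returns the
    same keys mapped to (n_boot, 4) component-mean arrays. The strata
    are resampled in sorted-key order so results are reproducible for a
    fixed seed regardless of dict insertion order.
    """
    out = {}
    for cell in sorted(cells):
        V = cells[cell]
        sums = bootstrap_cell_sums(V, n_boot, rng)
        out[cell] = component_means(float(len(V)), sums)
    return out


def _soil_indicator_permutations(
    n: int, k: int, n_perm: int, rng: np.random.Generator | None
) -> np.ndarray:
    """(P, n) 0/1 matrix; each row assigns k records to the first soil.

    With ``rng`` None, enumerate all C(n, k) distinguishable assignments
    (exact test); otherwise draw ``n_perm`` uniform reshuffles.
    """
    if rng is None:
        total = comb(n, k)
        if total > MAX_EXHAUSTIVE:
            raise ValueError(
                f"exhaustive enumeration of C({n},{k})={total} assignments "
                f"exceeds the limit of {MAX_EXHAUSTIVE}"
            )
        S = np.zeros((total, n), dtype=np.float64)
        for r, pos in enumerate(combinations(range(n), k)):
            S[r, list(pos)] = 1.0
        return S
    base = np.zeros(n, dtype=np.float64)
    base[:k] = 1.0
    S = np.tile(base, (n_perm, 1))
    return rng.permuted(S, axis=1)


def permute_site_deltas(
    V: np.ndarray,
    soil_is_ref: np.ndarray,
    eco_is_local: np.ndarray,
    n_perm: int,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Between-soil selection differences under soil-label reshuffles.

    All records of one site enter; each permutation reassigns the soil
    labels uniformly among them (every record keeps its ecotype and
    observations, and the per-soil totals are preserved). Returns a
    (P, 4) array of s(reference soil) - s(other soil) per component.
    ``soil_is_ref`` marks an arbitrary but *fixed* reference soil — the
    caller applies a sign depending on which soil is local, so the
    shuffle stream does not depend on the local-soil labelling. ``rng``
    None triggers exhaustive enumeration.
    """
    n = len(V)
    k = int(soil_is_ref.sum())
    S = _soil_indicator_permutations(n, k, n_perm, rng)
    w = {}
    for eco_flag in (True, False):
        m = eco_is_local == eco_flag
        Ve = V[m]
        tot = Ve.sum(axis=0)
        ne = float(m.sum())
        Se = np.ascontiguousarray(S[:, m])
        sums_ref = Se @ Ve
        cnt_ref = Se.sum(axis=1)
        w[(True, eco_flag)] = component_means(cnt_ref, sums_ref)
        w[(False, eco_flag)] = component_means(ne - cnt_ref, tot - sums_ref)
    s_ref = selection_from_means(w[(True, True)], w[(True, False)])
    s_other = selection_from_means(w[(False, True)], w[(False, False)])
    return s_ref - s_other


def permutation_pvalue(
    observed: float,
    permuted: np.ndarray,
    tail: str = "signed",
    add_one: bool = True,
) -> tuple[float, int, int]:
    """Two-sided permutation p-value for one component at one site.

    Returns ``(p, n_used, n_dropped)``. NaN replicates (a reshuffle that
    left a selection coefficient undefined) are dropped and counted.
    The signed convention doubles the smaller of the two tail
    probabilities (ties counted in both tails), so it is invariant to
    negating the statistic; the absolute convention compares |delta|
    directly. With ``add_one`` the observed statistic is counted as one
    extra exceedance in each tail, which keeps p strictly positive and
    finite-sample valid; without it the plain proportion is returned.
    """
    permuted = np.asarray(permuted, dtype=float)
    valid = permuted[~np.isnan(permuted)]
    n_used = int(valid.size)
    n_dropped = int(permuted.size - n_used)
    if np.isnan(observed) or n_used == 0:
        return float("nan"), n_used, n_dropped
    if tail == "absolute":
        hits = int(np.sum(np.abs(valid) >= np.abs(observed)))
        p = (hits + 1) / (n_used + 1) if add_one else hits / n_used
    elif tail == "signed":
        hi = int(np.sum(valid >= observed))
        lo = int(np.sum(valid <= observed))
        if add_one:
            p = 2.0 * min(hi + 1, lo + 1) / (n_used + 1)
        else:
            p = 2.0 * min(hi, lo) / n_used
    else:
        raise ValueError(f"unknown tail convention {tail!r}")
    return min(1.0, p), n_used, n_dropped


def percentile_interval(
    replicates: Iterable[float], ci_level: float
) -> tuple[float, float, int, int]:
    """Percentile CI bounds plus (n_used, n_dropped) over NaN-dropping."""
    arr = np.asarray(list(replicates), dtype=float)
    valid = arr[~np.isnan(arr)]
    n_used = int(valid.size)
    n_dropped = int(arr.size - n_used)
    if n_used == 0:
        return float("nan"), float("nan"), n_used, n_dropped
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(valid, [alpha, 1.0 - alpha])
    return float(lo), float(hi), n_used, n_dropped
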