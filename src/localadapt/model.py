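"""Selection inference for a site x soil x ecotype transplant experiment.

The central quantity is the selection coefficient against the non-local
ecotype, s = 1 - w_nonlocal / w_local, where w is a cell-mean fitness
component (survival, fecundity, seeds per fruit, or the overall
seed-number proxy). :class:`SelectionModel` wraps a cohort and, on
``fit``, produces a :class:`SelectionResults` carrying

* per site-soil-component selection estimates with percentile bootstrap
  confidence intervals, resampled independently within every
  site-soil-ecotype stratum at its original size; and
* per site-component between-soil contrasts delta_s = s(local soil) -
  s(non-local soil), tested by permuting soil labels among all records
  within each site and recomputing the contrast.

The seeds-per-fruit cell means entering the overall proxy are recomputed
inside every bootstrap and permutation replicate, so the proxy is
treated as part of the estimator rather than frozen at full-data values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from . import _engine
from .components import SUMMARY_COLUMNS, summarize_cells
from .records import Cohort, filter_analysis_set
from .simulate import COMPONENTS


class ConfigurationError(ValueError):
    """The cohort cannot support the requested analysis."""


def selection_coefficient(w_local: float, w_nonlocal: float) -> float:
    """Selection against the non-local ecotype, s = 1 - w_nonlocal/w_local.

    Positive s favours the local ecotype; s = 1 means the non-local
    ecotype left no descendants while the local one did; negative s
    favours the non-local ecotype. Undefined (NaN) when the local mean
    fitness is 0, including the doubly degenerate 0/0 case. Negative
    fitness means are a domain error.
    """
    if w_local < 0 or w_nonlocal < 0:
        raise ValueError("mean fitness values must be non-negative")
    if w_local == 0:
        return math.nan
    return 1.0 - w_nonlocal / w_local


@dataclass(frozen=True)
class ResamplingPlan:
    """How to resample: bootstrap size, permutation count, conventions.

    ``tail`` selects the permutation tail convention: ``"signed"``
    doubles the smaller tail of the signed delta_s null distribution;
    ``"absolute"`` compares |delta_s|. ``add_one`` applies the
    finite-sample correction p = (1 + exceedances)/(n_perm + 1) per
    tail; disable it for plain-proportion replication. ``exhaustive``
    enumerates every distinguishable soil-label assignment instead of
    sampling (small sites only) and implies the plain proportion, which
    is then exact.
    """

    n_boot: int = 1000
    n_perm: int = 1000
    ci_level: float = 0.95
    seed: Optional[int] = None
    tail: str = "signed"
    add_one: bool = True
    exhaustive: bool = False
    drop_warn_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.n_boot < 0 or self.n_perm < 0:
            raise ValueError("n_boot and n_perm must be >= 0")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")
        if self.tail not in ("signed", "absolute"):
            raise ValueError("tail must be 'signed' or 'absolute'")


@dataclass(frozen=True)
class SelectionEstimate:
    """One selection coefficient with its bootstrap interval."""

    site: str
    soil: str
    component: str
    s_hat: float
    ci_low: float
    ci_high: float
    n_boot_used: int
    n_boot_dropped: int
    ci_unreliable: bool = False


@dataclass(frozen=True)
class SoilContrast:
    """Between-soil difference in selection at one site, with its test."""

    site: str
    component: str
    delta_s: float
    p_value: float
    n_perm: int
    n_perm_dropped: int
    tail_convention: str


class SelectionModel:
    """Selection analysis of a two-site reciprocal transplant cohort.

    Parameters
    ----------
    cohort : Cohort or pandas.DataFrame
        Individual-plant records; edge records are removed on entry.
    local_ecotype : mapping site -> ecotype, optional
        Which ecotype is native at each site. Defaults to the ecotype
        whose label equals the site label.
    local_soil : mapping site -> soil, optional
        Which soil is native at each site (defines the sign of the
        between-soil contrast). Defaults to the soil whose label equals
        the site label.
    """

    def __init__(
        self,
        cohort: Union[Cohort, pd.DataFrame],
        local_ecotype: Optional[Mapping[str, str]] = None,
        local_soil: Optional[Mapping[str, str]] = None,
    ):
        if isinstance(cohort, pd.DataFrame):
            cohort = Cohort(cohort)
        analysis = filter_analysis_set(cohort) if cohort.data["edge"].any() else cohort
        df = analysis.data
        if df.empty:
            raise ConfigurationError("cohort has no non-edge records")
        labels = (
            set(df["site"]) | set(df["soil"]) | set(df["ecotype"])
        )
        if len(labels) > 2:
            raise ConfigurationError(
                "site, soil and ecotype must share a two-label universe; "
                f"found {sorted(labels)}"
            )
        self.sites: list[str] = sorted(df["site"].unique())
        self.soils: list[str] = sorted(labels)
        self.ecotypes: list[str] = sorted(labels)
        self.local_ecotype = dict(local_ecotype or {s: s for s in self.sites})
        self.local_soil = dict(local_soil or {s: s for s in self.sites})
        for site in self.sites:
            if site not in self.local_ecotype:
                raise ConfigurationError(f"no local ecotype named for site {site!r}")
            if site not in self.local_soil:
                raise ConfigurationError(f"no local soil named for site {site!r}")
            if self.local_ecotype[site] not in self.ecotypes:
                raise ConfigurationError(
                    f"local ecotype {self.local_ecotype[site]!r} for site "
                    f"{site!r} not among observed labels {self.ecotypes}"
                )
        self.data = df.reset_index(drop=True)
        self.cohort = analysis
        # every site-soil-ecotype cell the estimates reference must exist
        counts = df.groupby(["site", "soil", "ecotype"]).size()
        for site in self.sites:
            for soil in self.soils:
                for eco in self.ecotypes:
                    if (site, soil, eco) not in counts.index:
                        raise ConfigurationError(
                            f"empty required cell (site={site!r}, "
                            f"soil={soil!r}, ecotype={eco!r})"
                        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        local_ecotype: Optional[Mapping[str, str]] = None,
        local_soil: Optional[Mapping[str, str]] = None,
    ) -> "SelectionModel":
        return cls(Cohort(df), local_ecotype, local_soil)

    # -- helpers --------------------------------------------------------
    def _nonlocal(self, label: str, universe: list[str]) -> str:
        others = [x for x in universe if x != label]
        if len(others) != 1:
            raise ConfigurationError(
                f"expected exactly one non-local label besides {label!r}"
            )
        return others[0]

    def _cell_values(self) -> dict:
        cells = {}
        for key, g in self.data.groupby(["site", "soil", "ecotype"], sort=True):
            cells[key] = _engine.value_matrix(g)
        return cells

    def _point_w(self, summaries: pd.DataFrame) -> dict:
        w = {}
        for row in summaries.itertuples(index=False):
            for comp in COMPONENTS:
                w[(row.site, row.soil, row.ecotype, comp)] = getattr(row, comp)
        return w

    # -- fitting --------------------------------------------------------
    def fit(self, plan: ResamplingPlan = ResamplingPlan()) -> "SelectionResults":
        summaries = summarize_cells(self.data)
        w = self._point_w(summaries)
        cells = self._cell_values()
        ss = np.random.SeedSequence(plan.seed)
        boot_seed, perm_seed = ss.spawn(2)

        estimates = self._estimate(summaries, w, cells, plan, boot_seed)
        contrasts = self._contrast(w, plan, perm_seed)
        return SelectionResults(self, plan, summaries, estimates, contrasts)

    def _estimate(
        self,
        summaries: pd.DataFrame,
        w: dict,
        cells: dict,
        plan: ResamplingPlan,
        seed: np.random.SeedSequence,
    ) -> pd.DataFrame:
        boot_w = None
        if plan.n_boot > 0:
            rng = np.random.default_rng(seed)
            boot_w = _engine.bootstrap_replicates(cells, plan.n_boot, rng)

        rows = []
        for site in self.sites:
            eco_l = self.local_ecotype[site]
            eco_n = self._nonlocal(eco_l, self.ecotypes)
            for soil in self.soils:
                for ci, comp in enumerate(COMPONENTS):
                    s_hat = _safe_s(w, site, soil, eco_l, eco_n, comp)
                    if boot_w is not None:
                        s_rep = _engine.selection_from_means(
                            boot_w[(site, soil, eco_l)][:, ci],
                            boot_w[(site, soil, eco_n)][:, ci],
                        )
                        lo, hi, n_used, n_drop = _engine.percentile_interval(
                            s_rep, plan.ci_level
                        )
                    else:
                        lo = hi = math.nan
                        n_used = n_drop = 0
                    unreliable = (
                        plan.n_boot > 0
                        and n_drop > plan.drop_warn_frac * plan.n_boot
                    )
                    if unreliable:
                        warnings.warn(
                            f"CI for ({site}, {soil}, {comp}) unreliable: "
                            f"{n_drop}/{plan.n_boot} bootstrap replicates "
                            "had an undefined selection coefficient",
                            stacklevel=3,
                        )
                    rows.append(
                        {
                            "site": site,
                            "soil": soil,
                            "component": comp,
                            "s_hat": s_hat,
                            "ci_low": lo,
                            "ci_high": hi,
                            "n_boot_used": n_used,
                            "n_boot_dropped": n_drop,
                            "ci_unreliable": unreliable,
                        }
                    )
        return pd.DataFrame(rows)

    def _contrast(
        self, w: dict, plan: ResamplingPlan, seed: np.random.SeedSequence
    ) -> pd.DataFrame:
        rng = None if plan.exhaustive else np.random.default_rng(seed)
        add_one = plan.add_one and not plan.exhaustive
        rows = []
        for site in self.sites:
            eco_l = self.local_ecotype[site]
            eco_n = self._nonlocal(eco_l, self.ecotypes)
            soil_l = self.local_soil[site]
            soil_n = self._nonlocal(soil_l, self.soils)
            obs = {}
            for comp in COMPONENTS:
                s_l = _safe_s(w, site, soil_l, eco_l, eco_n, comp)
                s_n = _safe_s(w, site, soil_n, eco_l, eco_n, comp)
                obs[comp] = s_l - s_n
            g = self.data.loc[self.data["site"] == site]
            V = _engine.value_matrix(g)
            # shuffle a fixed reference-soil indicator so that the
            # permutation stream is identical whichever soil is local
            soil_ref = min(self.soils)
            sign = 1.0 if soil_l == soil_ref else -1.0
            soil_is_ref = (g["soil"] == soil_ref).to_numpy()
            eco_is_local = (g["ecotype"] == eco_l).to_numpy()
            deltas = sign * _engine.permute_site_deltas(
                V, soil_is_ref, eco_is_local, plan.n_perm, rng
            )
            for ci, comp in enumerate(COMPONENTS):
                p, n_used, n_drop = _engine.permutation_pvalue(
                    obs[comp], deltas[:, ci], tail=plan.tail, add_one=add_one
                )
                rows.append(
                    {
                        "site": site,
                        "component": comp,
                        "delta_s": obs[comp],
                        "p_value": p,
                        "n_perm": n_used,
                        "n_perm_dropped": n_drop,
                        "tail_convention": plan.tail,
                    }
                )
        return pd.DataFrame(rows)


def _defined(x) -> bool:
    return x is not None and not (isinstance(x, float) and math.isnan(x))


def _safe_s(w, site, soil, eco_l, eco_n, comp) -> float:
    wl = w[(site, soil, eco_l, comp)]
    wn = w[(site, soil, eco_n, comp)]
    if not (_defined(wl) and _defined(wn)):
        return math.nan
    return selection_coefficient(float(wl), float(wn))


class SelectionResults:
    """Fitted selection estimates, contrasts and diagnostics.

    Attributes
    ----------
    cell_summaries : DataFrame
        Per-cell fitness components (tidy).
    estimates : DataFrame
        site, soil, component, s_hat, ci_low, ci_high, n_boot_used,
        n_boot_dropped, ci_unreliable.
    contrasts : DataFrame
        site, component, delta_s, p_value, n_perm, n_perm_dropped,
        tail_convention.
    """

    def __init__(self, model, plan, cell_summaries, estimates, contrasts):
        self.model = model
        self.plan = plan
        self.cell_summaries = cell_summaries
        self.estimates = estimates
        self.contrasts = contrasts

    # -- views ----------------------------------------------------------
    def selection_estimates(self) -> list[SelectionEstimate]:
        return [
            SelectionEstimate(**row._asdict())
            for row in self.estimates.itertuples(index=False)
        ]

    def soil_contrasts(self) -> list[SoilContrast]:
        return [
            SoilContrast(
                site=row.site,
                component=row.component,
                delta_s=row.delta_s,
                p_value=row.p_value,
                n_perm=row.n_perm,
                n_perm_dropped=row.n_perm_dropped,
                tail_convention=row.tail_convention,
            )
            for row in self.contrasts.itertuples(index=False)
        ]

    def s_hat(self, site: str, soil: str, component: str = "overall") -> float:
        q = self.estimates
        row = q[
            (q["site"] == site) & (q["soil"] == soil) & (q["component"] == component)
        ]
        return float(row["s_hat"].iloc[0])

    def delta_s(self, site: str, component: str = "overall") -> float:
        q = self.contrasts
        row = q[(q["site"] == site) & (q["component"] == component)]
        return float(row["delta_s"].iloc[0])

    def p_value(self, site: str, component: str = "overall") -> float:
        q = self.contrasts
        row = q[(q["site"] == site) & (q["component"] == component)]
        return float(row["p_value"].iloc[0])

    # -- reporting ------------------------------------------------------
    def summary(self) -> str:
        n = len(self.model.data)
        lines = [
            "Reciprocal-transplant selection analysis",
            "=" * 72,
            f"records (non-edge): {n}    sites: {', '.join(self.model.sites)}",
            f"local ecotype: {self.model.local_ecotype}",
            f"local soil:    {self.model.local_soil}",
            f"bootstrap: {self.plan.n_boot} stratified resamples, "
            f"{int(self.plan.ci_level * 100)}% percentile CIs",
            f"permutation: {'exhaustive' if self.plan.exhaustive else self.plan.n_perm} "
            f"within-site soil reshuffles, {self.plan.tail} tail",
            "",
            "Cell fitness components",
            "-" * 72,
            self.cell_summaries.to_string(index=False, float_format="%.4g"),
            "",
            "Selection against the non-local ecotype (s = 1 - w_nl/w_l)",
            "-" * 72,
            self.estimates.drop(columns=["ci_unreliable"]).to_string(
                index=False, float_format="%.4g"
            ),
            "",
            "Between-soil contrasts (delta_s = s_local_soil - s_nonlocal_soil)",
            "-" * 72,
            self.contrasts.to_string(index=False, float_format="%.4g"),
        ]
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> dict:
        """Write summaries/estimates/contrasts CSVs; return their paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "summaries": out / "cell_summaries.csv",
            "estimates": out / "selection_estimates.csv",
            "contrasts": out / "soil_contrasts.csv",
        }
        self.cell_summaries.to_csv(paths["summaries"], index=False)
        self.estimates.to_csv(paths["estimates"], index=False)
        self.contrasts.to_csv(paths["contrasts"], index=False)
        return paths

    def plot_components(self, fig=None):
        from .plotting import plot_components

        return plot_components(self, fig=fig)


# -- spec-level convenience functions ------------------------------------

def estimate_selection(
    cohort: Union[Cohort, pd.DataFrame],
    local_map: Optional[Mapping[str, str]] = None,
    plan: ResamplingPlan = ResamplingPlan(),
) -> list[SelectionEstimate]:
    """Selection coefficients with stratified-bootstrap CIs, per cell pair."""
    return SelectionModel(cohort, local_ecotype=local_map).fit(plan).selection_estimates()


def soil_contrast(
    cohort: Union[Cohort, pd.DataFrame],
    local_map: Optional[Mapping[str, str]] = None,
    plan: ResamplingPlan = ResamplingPlan(),
    local_soil: Optional[Mapping[str, str]] = None,
) -> list[SoilContrast]:
    """Between-soil selection differences with permutation p-values."""
    return (
        SelectionModel(cohort, local_ecotype=local_map, local_soil=local_soil)
        .fit(plan)
        .soil_contrasts()
    )
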