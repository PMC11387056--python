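"""Monte-Carlo operating characteristics of the soil-contrast test.

The question the module answers: if adaptation to soil type produced a
true between-soil difference delta_s in overall-fitness selection at one
site, how often would the within-site soil-permutation test detect it at
a given design size? A known effect is injected into a generator
configuration by rescaling the non-local ecotype's seed mean on the
non-local soil — a one-component perturbation with a closed-form
inverse, so the injected truth is exact — and cohorts are simulated and
analysed on a (delta_s, n) grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .model import ResamplingPlan, SelectionModel
from .simulate import (
    ConfigError,
    GeneratorConfig,
    _read_text_maybe_path,
    derive_true_effects,
    generate_cohort,
)


@dataclass
class PowerScenario:
    """A grid of true soil effects and design sizes to simulate.

    ``base_config`` should carry climate-driven selection per site but no
    soil effect (the default configuration qualifies). ``site`` names
    where the effect is injected and tested. ``n_grid`` entries are
    per-cell sample sizes applied uniformly to all 8 cells.
    """

    base_config: GeneratorConfig = field(default_factory=GeneratorConfig.default)
    site: str = "Italy"
    delta_s_grid: Sequence[float] = (0.0, 0.05, 0.1)
    n_grid: Sequence[int] = (260,)
    n_sims: int = 200
    alpha: float = 0.05
    seed: Optional[int] = None

    def validate(self) -> None:
        self.base_config.validate()
        if self.site not in self.base_config.sites:
            raise ConfigError(f"unknown site {self.site!r}")
        if self.n_sims < 1:
            raise ConfigError("n_sims must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")
        if any(n < 1 for n in self.n_grid):
            raise ConfigError("n_grid entries must be >= 1")

    def to_yaml(self, path: str | Path | None = None) -> str:
        doc = {
            "site": self.site,
            "delta_s_grid": [float(d) for d in self.delta_s_grid],
            "n_grid": [int(n) for n in self.n_grid],
            "n_sims": int(self.n_sims),
            "alpha": float(self.alpha),
            "seed": self.seed,
            "base_config": yaml.safe_load(self.base_config.to_yaml()),
        }
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PowerScenario":
        text = _read_text_maybe_path(source)
        doc = yaml.safe_load(text)
        base = doc.get("base_config")
        cfg = (
            GeneratorConfig.from_yaml(yaml.safe_dump(base))
            if base
            else GeneratorConfig.default()
        )
        out = cls(
            base_config=cfg,
            site=str(doc.get("site", cfg.sites[0])),
            delta_s_grid=[float(d) for d in doc.get("delta_s_grid", [0.0])],
            n_grid=[int(n) for n in doc.get("n_grid", [260])],
            n_sims=int(doc.get("n_sims", 200)),
            alpha=float(doc.get("alpha", 0.05)),
            seed=doc.get("seed"),
        )
        out.validate()
        return out


@dataclass(frozen=True)
class PowerResult:
    """Operating characteristics at one (delta_s, n) grid point."""

    delta_s: float
    n: int
    n_sims: int
    rejection_rate: float
    mc_se: float
    mean_delta_s_hat: float
    sd_delta_s_hat: float


#: tidy column order of the power results table
POWER_COLUMNS = [
    "delta_s",
    "n",
    "n_sims",
    "rejection_rate",
    "mc_se",
    "mean_delta_s_hat",
    "sd_delta_s_hat",
]


def inject_soil_effect(
    base: GeneratorConfig, site: str, delta_s: float
) -> GeneratorConfig:
    """Return a configuration whose true overall delta_s at ``site`` is exact.

    The non-local ecotype's seed mean on the *non-local* soil is rescaled
    so that s(non-local soil) = s(local soil) - delta_s; since overall
    fitness is linear in the seed mean, the required factor is closed
    form and the resulting ``derive_true_effects`` delta equals
    ``delta_s`` to machine precision. Other components and the local
    soil are untouched. A factor that is not strictly positive (the
    implied non-local fitness would vanish or turn negative) is a
    parameter error.
    """
    if site not in base.sites:
        raise ConfigError(f"unknown site {site!r}")
    if delta_s == 0.0:
        return base.copy()
    truth = derive_true_effects(base)
    soil_l = base.local_soil(site)
    (soil_n,) = [s for s in base.sites if s != soil_l]
    eco_l = base.local_ecotype(site)
    (eco_n,) = [s for s in base.sites if s != eco_l]
    s_target = truth.s_true[(site, soil_l, "overall")] - delta_s
    w_local = truth.cell_means[(site, soil_n, eco_l, "overall")]
    w_nl_now = truth.cell_means[(site, soil_n, eco_n, "overall")]
    w_nl_target = (1.0 - s_target) * w_local
    factor = w_nl_target / w_nl_now
    if not factor > 0:
        raise ConfigError(
            f"delta_s={delta_s} would require a non-positive seed mean "
            f"(scale factor {factor:.4g}) in cell {(site, soil_n, eco_n)}"
        )
    out = base.copy()
    out.seed_mean[(site, soil_n, eco_n)] = (
        base.seed_mean[(site, soil_n, eco_n)] * factor
    )
    out.validate()
    return out


def run_power(
    scenario: PowerScenario, plan: Optional[ResamplingPlan] = None
) -> pd.DataFrame:
    """Simulate the soil-contrast test over the scenario grid.

    For each (delta_s, n) grid point, ``n_sims`` cohorts are generated,
    the full analysis pipeline is run, and the rejection rate of the
    overall-fitness contrast at the scenario site at level ``alpha`` is
    recorded together with its Monte-Carlo standard error and the mean
    estimated contrast. The default plan uses reduced resampling
    (no bootstrap, 200 permutations) to keep grid sweeps fast; pass an
    explicit plan for full-fidelity runs. Reproducible under the
    scenario seed.
    """
    scenario.validate()
    if plan is None:
        plan = ResamplingPlan(n_boot=0, n_perm=200)
    root = np.random.SeedSequence(scenario.seed)
    rows = []
    for d in scenario.delta_s_grid:
        for n in scenario.n_grid:
            cfg = inject_soil_effect(
                scenario.base_config.with_n_per_cell(int(n)), scenario.site, float(d)
            )
            point_seed, = root.spawn(1)
            sim_seeds = point_seed.spawn(2 * scenario.n_sims)
            rejections = 0
            delta_hats = []
            for i in range(scenario.n_sims):
                cohort = generate_cohort(cfg, seed=sim_seeds[2 * i])
                sim_plan = ResamplingPlan(
                    n_boot=plan.n_boot,
                    n_perm=plan.n_perm,
                    ci_level=plan.ci_level,
                    seed=int(sim_seeds[2 * i + 1].generate_state(1)[0] % (2**31)),
                    tail=plan.tail,
                    add_one=plan.add_one,
                )
                res = SelectionModel(cohort).fit(sim_plan)
                p = res.p_value(scenario.site, "overall")
                delta_hats.append(res.delta_s(scenario.site, "overall"))
                if p <= scenario.alpha:
                    rejections += 1
            r = rejections / scenario.n_sims
            hats = np.asarray(delta_hats, dtype=float)
            rows.append(
                {
                    "delta_s": float(d),
                    "n": int(n),
                    "n_sims": scenario.n_sims,
                    "rejection_rate": r,
                    "mc_se": float(np.sqrt(r * (1.0 - r) / scenario.n_sims)),
                    "mean_delta_s_hat": float(np.nanmean(hats)),
                    "sd_delta_s_hat": float(np.nanstd(hats, ddof=1))
                    if np.sum(~np.isnan(hats)) > 1
                    else float("nan"),
                }
            )
    return pd.DataFrame(rows, columns=POWER_COLUMNS)


def power_results(df: pd.DataFrame) -> list[PowerResult]:
    """A tidy power table as :class:`PowerResult` objects."""
    return [PowerResult(**row._asdict()) for row in df.itertuples(index=False)]
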