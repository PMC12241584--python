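"""Full factorial stand simulation and stand-level summaries.

For every (species-mixture permutation x planting design) the pipeline
builds the layout, scores its spatial heterogeneity, simulates ten years of
tree growth, predicts the per-pixel litter map and the per-element
decomposition maps, and reduces them to one stand-level summary row. A
linear interaction model (response ~ richness x H) quantifies how species
richness and spatial heterogeneity jointly drive each response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .decomposition import DecompParams, DecompositionMap, decomposition_map
from .designs import (
    HETEROGENEITY_NEIGHBORHOOD,
    Layout,
    MixtureAssignment,
    SpeciesPool,
    heterogeneity,
    make_heterogeneity_gradient,
    make_layout,
    make_mixture_permutations,
)
from .growth import GrowthParams, TreeBiomassField, simulate_growth
from .litterfall import LitterMap, litterfall_map

DEFAULT_RICHNESS_COUNTS: dict[int, int | str] = {2: "all", 4: 1000, 8: 1000}
DEFAULT_DESIGNS = ("gradient", "miniblock", "double_line", "single_line")


@dataclass
class SimulationParams:
    """Coefficient bundle consumed by the stand pipeline."""

    growth: GrowthParams
    litterfall: pd.DataFrame                  # index species, columns b1 b2 b3
    decomposition: Mapping[str, DecompParams]  # element -> params
    element_fractions: Mapping[str, Mapping[str, float]] | None = None
    biomass_scale: float = 1.0                 # growth-model units -> field units


@dataclass
class ExperimentConfig:
    """Factorial experiment: mixtures x designs.

    ``richness_counts`` maps richness to a permutation count or ``"all"``;
    ``designs`` may contain the template labels plus ``"gradient"`` which
    expands into ``gradient_levels`` layouts spanning block -> random.
    """

    pool: SpeciesPool = field(default_factory=SpeciesPool.default)
    richness_counts: Mapping[int, int | str] = field(
        default_factory=lambda: dict(DEFAULT_RICHNESS_COUNTS)
    )
    designs: Sequence[str] = DEFAULT_DESIGNS
    gradient_levels: int = 8
    years: int = 10
    litter_k: int = 12
    seed: int = 0

    def n_designs(self) -> int:
        n = 0
        for d in self.designs:
            n += self.gradient_levels if d == "gradient" else 1
        return n


def summarize_stand(
    biomass: TreeBiomassField,
    litter: LitterMap,
    decomp: Mapping[str, DecompositionMap],
    layout: Layout,
    biomass_scale: float = 1.0,
) -> dict:
    """Stand-level response variables from the per-tree and per-pixel maps.

    Means and SDs are taken over unmasked pixels; biomass is the summed
    final-year tree biomass per m^2 of plot area.
    """
    if litter.total.shape != litter.richness.shape:
        raise ValueError("inconsistent litter map shapes")
    for dm in decomp.values():
        if dm.d.shape != litter.total.shape:
            raise ValueError("decomposition map shape does not match litter map")
    score = heterogeneity(layout, HETEROGENEITY_NEIGHBORHOOD)
    row = {
        "mixture": "|".join(layout.mixture.species),
        "richness": layout.mixture.richness,
        "design_label": layout.design_label,
        "seed": layout.seed,
        "H": score.H,
        "mean_biomass_g_m2": biomass.mean_biomass_per_m2(biomass_scale),
        "mean_litterfall_g_m2": float(litter.total.mean()),
        "sd_litterfall_g_m2": float(litter.total.std()),
        "mean_pixel_litter_richness": float(litter.richness.mean()),
    }
    for element, dm in decomp.items():
        row[f"mean_D_{element}_pct"] = float(np.nanmean(dm.d))
        row[f"sd_D_{element}_pct"] = float(np.nanstd(dm.d))
        row[f"total_{element}_loss_g_m2"] = float(np.nanmean(dm.mass_loss))
    return row


def simulate_stand(
    layout: Layout,
    params: SimulationParams,
    years: int = 10,
    litter_k: int = 12,
) -> dict:
    """Run growth -> litterfall -> decomposition for one stand layout."""
    field_bio = simulate_growth(layout, params.growth, years=years)
    tree_biomass = field_bio.final * params.biomass_scale
    litter = litterfall_map(layout, tree_biomass, params.litterfall, k=litter_k)
    decomp = {}
    for element, dp in params.decomposition.items():
        fractions = None
        if params.element_fractions is not None:
            fractions = dict(params.element_fractions[element])
        decomp[element] = decomposition_map(litter, dp, element_fractions=fractions)
    return summarize_stand(field_bio, litter, decomp, layout)


def _stand_layouts(
    mixture: MixtureAssignment, config: ExperimentConfig, seed: int
) -> list[Layout]:
    layouts: list[Layout] = []
    for d in config.designs:
        if d == "gradient":
            layouts.extend(
                make_heterogeneity_gradient(
                    mixture, levels=config.gradient_levels, seed=seed
                )
            )
        elif d == "random":
            layouts.append(make_layout(mixture, "random", seed=seed))
        else:
            layouts.append(make_layout(mixture, d, seed=seed))
    return layouts


def run_experiment(
    config: ExperimentConfig,
    params: SimulationParams,
    shard: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """One StandSummary row per (mixture permutation x design).

    Deterministic given ``config.seed``. Per-stand failures are recorded in
    an ``error`` column and the run continues. ``shard=(i, k)`` runs only
    every k-th mixture starting at i (0-based); shard outputs concatenate
    to the full table.
    """
    rng = np.random.default_rng(config.seed)
    mixtures: list[MixtureAssignment] = []
    for richness in sorted(config.richness_counts):
        count = config.richness_counts[richness]
        mixtures.extend(
            make_mixture_permutations(
                config.pool, richness, count, seed=int(rng.integers(2**31))
            )
        )
    indexed = list(enumerate(mixtures))
    if shard is not None:
        i, k = shard
        indexed = indexed[i::k]

    rows = []
    for m_idx, mixture in indexed:  # m_idx is global, so shards are consistent
        stand_seed = int(
            np.random.default_rng((config.seed, m_idx)).integers(2**31)
        )
        for layout in _stand_layouts(mixture, config, stand_seed):
            try:
                row = simulate_stand(
                    layout, params, years=config.years, litter_k=config.litter_k
                )
                row["error"] = ""
            except Exception as exc:  # per-stand failures must not kill the run
                row = {
                    "mixture": "|".join(mixture.species),
                    "richness": mixture.richness,
                    "design_label": layout.design_label,
                    "seed": stand_seed,
                    "error": f"{type(exc).__name__}: {exc}",
                }
            rows.append(row)
    return pd.DataFrame(rows)


def interaction_analysis(summaries: pd.DataFrame, response: str) -> dict:
    """Linear model ``response ~ richness * H`` over stand summaries.

    Returns coefficient estimates, the interaction F statistic and p-value,
    and the model R^2. Requires at least two richness levels and spread in
    H.
    """
    if response not in summaries.columns:
        raise KeyError(f"unknown response column {response!r}")
    data = summaries.dropna(subset=[response, "richness", "H"])
    if data["richness"].nunique() < 2:
        raise ValueError("interaction model needs >= 2 species richness levels")
    if data["H"].nunique() < 2:
        raise ValueError("interaction model needs >= 2 heterogeneity levels")
    if float(np.var(data[response])) == 0.0:
        raise ValueError(f"response {response!r} has zero variance")
    model = smf.ols(f"{response} ~ richness * H", data=data).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    inter = "richness:H"
    return {
        "response": response,
        "params": model.params.to_dict(),
        "interaction_coef": float(model.params[inter]),
        "interaction_F": float(anova.loc[inter, "F"]),
        "interaction_p": float(anova.loc[inter, "PR(>F)"]),
        "r_squared": float(model.rsquared),
        "n": int(model.nobs),
    }
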