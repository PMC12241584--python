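"""Individual tree growth with pairwise neighbor interactions.

Annual biomass increments follow a species-specific intrinsic growth term
plus pairwise interactions with the Moore (8-cell) neighborhood::

    B[t+1, i] - B[t, i] = beta_s(i) * B[t, i]**theta
                          + sum_{j in n_i} alpha_{s(i), s(j)} * B[t, j]**b

where ``beta`` scales intrinsic growth, ``alpha`` the directed species x
species interaction, and the allometric exponents ``theta`` and ``b`` allow
sublinear (metabolic) scaling. Stands start from a uniform biomass (100
model units) and are iterated for a fixed number of years. Neighbor sums
truncate at the stand edge; biomass is floored at a small positive constant
so strongly negative interactions cannot drive it below zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .designs import GROWTH_NEIGHBORHOOD, Layout, NeighborhoodSpec, _shift_window

BIOMASS_FLOOR = 1e-6
DEFAULT_START_BIOMASS = 100.0
DEFAULT_YEARS = 10
OVERFLOW_GUARD = 1e12


@dataclass
class GrowthParams:
    """Species-specific growth coefficients.

    beta[k] is the intrinsic growth coefficient of species ``species[k]``;
    alpha[k, l] the directed interaction effect of a neighbor of species
    ``species[l]`` on a focal tree of species ``species[k]``.
    """

    species: tuple[str, ...]
    beta: np.ndarray
    alpha: np.ndarray
    theta: float = 0.75
    b: float = 0.75

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        r = len(self.species)
        if self.beta.shape != (r,):
            raise ValueError("beta must have one entry per species")
        if self.alpha.shape != (r, r):
            raise ValueError("alpha must be square over the species")
        if not (np.isfinite(self.beta).all() and np.isfinite(self.alpha).all()):
            raise ValueError("growth coefficients must be finite")
        if not (np.isfinite(self.theta) and np.isfinite(self.b)):
            raise ValueError("allometric exponents must be finite")

    def index_of(self, labels: np.ndarray) -> np.ndarray:
        lookup = {s: k for k, s in enumerate(self.species)}
        return np.vectorize(lookup.__getitem__)(labels).astype(np.int64)

    @classmethod
    def from_tables(
        cls,
        beta: pd.DataFrame,
        alpha: pd.DataFrame,
        theta: float = 0.75,
        b: float = 0.75,
    ) -> "GrowthParams":
        """Build from long-format tables (species, beta) and
        (species_i, species_j, alpha)."""
        species = tuple(beta["species"])
        bvec = beta.set_index("species").loc[list(species), "beta"].to_numpy()
        amat = (
            alpha.pivot(index="species_i", columns="species_j", values="alpha")
            .loc[list(species), list(species)]
            .to_numpy()
        )
        return cls(species=species, beta=bvec, alpha=amat, theta=theta, b=b)

    def to_tables(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        beta = pd.DataFrame({"species": self.species, "beta": self.beta})
        ii, jj = np.meshgrid(range(len(self.species)), range(len(self.species)), indexing="ij")
        alpha = pd.DataFrame(
            {
                "species_i": np.array(self.species)[ii.ravel()],
                "species_j": np.array(self.species)[jj.ravel()],
                "alpha": self.alpha.ravel(),
            }
        )
        return beta, alpha


@dataclass
class TreeBiomassField:
    """Full biomass trajectory of a simulated stand.

    ``biomass[t]`` is the 16 x 16 biomass grid after ``t`` annual steps
    (``biomass[0]`` is the uniform start state).
    """

    biomass: np.ndarray  # (years + 1, nrow, ncol)
    layout: Layout
    params: GrowthParams

    @property
    def years(self) -> int:
        return self.biomass.shape[0] - 1

    @property
    def final(self) -> np.ndarray:
        return self.biomass[-1]

    def mean_biomass_per_m2(self, scale: float = 1.0) -> float:
        """Summed final biomass per m^2 of plot area, in model units * scale."""
        return float(self.final.sum() * scale / self.layout.plot_area)


def growth_step(
    biomass_t: np.ndarray,
    layout: Layout,
    params: GrowthParams,
    nb: NeighborhoodSpec | None = None,
    floor: float = BIOMASS_FLOOR,
) -> np.ndarray:
    """One annual growth increment for every tree in the stand."""
    if nb is None:
        nb = GROWTH_NEIGHBORHOOD
    B = np.asarray(biomass_t, dtype=float)
    if not np.isfinite(B).all():
        raise ValueError("non-finite biomass in growth step input")
    if (B <= 0).any():
        raise ValueError("biomass must be strictly positive")
    s = params.index_of(layout.grid)
    growth = params.beta[s] * B**params.theta
    Bb = B**params.b
    interaction = np.zeros_like(B)
    for dr, dc in nb.offsets:
        src = _shift_window(B.shape, dr, dc)   # cells with a neighbor at (dr, dc)
        dst = _shift_window(B.shape, -dr, -dc)  # that neighbor's cells
        interaction[src] += params.alpha[s[src], s[dst]] * Bb[dst]
    return np.maximum(B + growth + interaction, floor)


def simulate_growth(
    layout: Layout,
    params: GrowthParams,
    years: int = DEFAULT_YEARS,
    b0: float = DEFAULT_START_BIOMASS,
    nb: NeighborhoodSpec | None = None,
    overflow_guard: float = OVERFLOW_GUARD,
) -> TreeBiomassField:
    """Iterate the growth model from a uniform start biomass.

    Deterministic given its inputs. Raises if any biomass exceeds
    ``overflow_guard`` (divergent parameterisation), naming the step.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    traj = np.empty((years + 1,) + layout.grid.shape, dtype=float)
    traj[0] = b0
    for t in range(years):
        traj[t + 1] = growth_step(traj[t], layout, params, nb=nb)
        if (traj[t + 1] > overflow_guard).any():
            raise FloatingPointError(
                f"biomass exceeded overflow guard {overflow_guard:g} at year {t + 1}"
            )
    return TreeBiomassField(biomass=traj, layout=layout, params=params)
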