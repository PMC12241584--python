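"""Diversity-interaction model of litter decomposition.

Element loss (% of initial carbon or nitrogen) from a litter mixture is
decomposed into species-identity and pairwise diversity effects plus
mixture-level covariates::

    D = sum_i beta_i P_i + sum_{i<j} (alpha_i + alpha_j) P_i P_j + b4 L + b5 S

with ``P_i`` the litter-mass proportion of species *i* (summing to 1),
``L`` the total litter mixture mass and ``S`` the litter species richness.
The pair sum runs over unordered pairs i < j; when the proportions sum to
one it collapses to ``sum_i alpha_i P_i (1 - P_i)``, which is the form used
for both fitting and prediction. Diversity effects are assumed purely
additive (no species-pair-specific interaction coefficients). Predicted
loss rates are clamped to [0, 100] %.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .bayes import sample_linear_model
from .litterfall import LitterMap

PROPORTION_TOL = 1e-6


@dataclass(frozen=True)
class BagRecord:
    """One litterbag observation for a single element (C or N)."""

    bag_id: str
    element: str
    proportions: dict[str, float]   # species -> litter-mass proportion, sums to 1
    total_mass_g: float             # total litter mixture mass covariate L
    loss_pct: float                 # observed element loss D, % of initial content

    def __post_init__(self) -> None:
        p = np.array(list(self.proportions.values()))
        if (p < 0).any() or abs(p.sum() - 1.0) > PROPORTION_TOL:
            raise ValueError("proportions must be non-negative and sum to 1")
        if not 0.0 <= self.loss_pct <= 100.0:
            raise ValueError("loss rate must be within [0, 100] %")

    @property
    def richness(self) -> int:
        return int(sum(v > 0 for v in self.proportions.values()))


def bag_table(records: list[BagRecord]) -> pd.DataFrame:
    """Long-format bag table (bag_id, element, species, proportion, ...)."""
    rows = []
    for rec in records:
        for sp, p in rec.proportions.items():
            rows.append(
                {
                    "bag_id": rec.bag_id,
                    "element": rec.element,
                    "species": sp,
                    "proportion": p,
                    "total_mass_g": rec.total_mass_g,
                    "richness": rec.richness,
                    "loss_pct": rec.loss_pct,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class DecompParams:
    """Fitted coefficients of the decomposition model for one element."""

    element: str
    species: tuple[str, ...]
    beta: np.ndarray    # identity effects, % scale
    alpha: np.ndarray   # additive diversity effects
    b4: float           # effect of total litter mass, % per g
    b5: float           # effect of litter species richness, % per species

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        r = len(self.species)
        if self.beta.shape != (r,) or self.alpha.shape != (r,):
            raise ValueError("one (beta, alpha) pair per species required")
        values = np.concatenate([self.beta, self.alpha, [self.b4, self.b5]])
        if not np.isfinite(values).all():
            raise ValueError("decomposition coefficients must be finite")

    def as_series(self) -> pd.Series:
        idx = (
            [f"beta_{s}" for s in self.species]
            + [f"alpha_{s}" for s in self.species]
            + ["b4", "b5"]
        )
        return pd.Series(
            np.concatenate([self.beta, self.alpha, [self.b4, self.b5]]), index=idx
        )


@dataclass
class DecompositionMap:
    """Per-pixel predicted element loss over a stand.

    ``d`` is the loss rate (%) with NaN at zero-litter pixels; ``mass_loss``
    the element mass processed (g/m^2), i.e. rate x pixel litter element
    density.
    """

    element: str
    d: np.ndarray          # (npix, npix), % in [0, 100], NaN where masked
    mass_loss: np.ndarray  # (npix, npix), g/m^2, NaN where masked
    mask: np.ndarray       # True where litter is present


def predict_decomposition(
    proportions: np.ndarray | dict[str, float],
    total_mass: float,
    richness: int,
    params: DecompParams,
) -> float:
    """Predicted element loss rate (%) for one litter mixture, clamped to [0, 100]."""
    if isinstance(proportions, dict):
        p = np.array([proportions.get(s, 0.0) for s in params.species], dtype=float)
    else:
        p = np.asarray(proportions, dtype=float)
    if total_mass > 0:
        if abs(p.sum() - 1.0) > PROPORTION_TOL:
            raise ValueError(
                f"proportions sum to {p.sum():.8f}, not 1 (tolerance {PROPORTION_TOL})"
            )
        if richness < 1:
            raise ValueError("richness must be >= 1 when litter mass is positive")
    if total_mass < 0:
        raise ValueError("total mass must be non-negative")
    linear = (
        float(params.beta @ p)
        + float(params.alpha @ (p * (1.0 - p)))
        + params.b4 * total_mass
        + params.b5 * richness
    )
    return float(np.clip(linear, 0.0, 100.0))


class DecompositionModel(BaseEstimator):
    """Diversity-interaction regression for one element (scikit-learn style).

    The design matrix holds, per bag, the species proportions ``P_i``
    (identity terms), ``P_i (1 - P_i)`` (additive diversity terms), the
    total litter mass ``L`` and the litter richness ``S``; there is no
    intercept (the identity columns sum to one). Least squares is exact;
    ``method="bayes"`` samples the posterior with the shared linear-model
    sampler.

    Attributes
    ----------
    params_:
        Fitted :class:`DecompParams`.
    coef_sd_, sigma_, diagnostics_:
        Uncertainty and fit metadata.
    """

    def __init__(
        self,
        element: str = "C",
        method: str = "ls",
        chains: int = 4,
        draws: int = 2000,
        warmup: int = 1000,
        prior_scale: float = 100.0,
        random_state: int | None = None,
    ):
        self.element = element
        self.method = method
        self.chains = chains
        self.draws = draws
        self.warmup = warmup
        self.prior_scale = prior_scale
        self.random_state = random_state

    def fit(self, bags: pd.DataFrame) -> "DecompositionModel":
        """Fit from a long-format bag table filtered to this model's element."""
        if self.method not in ("ls", "bayes"):
            raise ValueError("method must be 'ls' or 'bayes'")
        sub = bags[bags["element"] == self.element]
        if sub.empty:
            raise ValueError(f"no bag records for element {self.element!r}")
        wide = sub.pivot_table(
            index="bag_id", columns="species", values="proportion", fill_value=0.0
        )
        meta = sub.drop_duplicates("bag_id").set_index("bag_id")
        meta = meta.loc[wide.index]
        species = tuple(wide.columns)
        P = wide.to_numpy(dtype=float)
        L = meta["total_mass_g"].to_numpy(dtype=float)
        S = meta["richness"].to_numpy(dtype=float)
        y = meta["loss_pct"].to_numpy(dtype=float)

        if len(np.unique(S)) < 2:
            raise ValueError(
                "bags cover a single litter richness level: the richness "
                "coefficient b5 is unidentifiable"
            )
        Q = P * (1.0 - P)
        dead = [f"alpha_{s}" for s, col in zip(species, Q.T) if np.allclose(col, 0.0)]
        if dead:
            raise ValueError(
                "diversity terms unidentifiable (no mixed bags for): " + ", ".join(dead)
            )
        X = np.column_stack([P, Q, L, S])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("rank-deficient decomposition design matrix")

        if self.method == "ls":
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coef
            sd = np.full(X.shape[1], np.nan)
            sigma = float(np.sqrt(np.mean(resid**2)))
            diag = {"n_obs": len(y), "method": "ls", "warnings": []}
        else:
            post = sample_linear_model(
                X,
                y,
                prior_scale=self.prior_scale,
                chains=self.chains,
                draws=self.draws,
                warmup=self.warmup,
                seed=self.random_state,
            )
            coef, sd, sigma = post.mean, post.sd, post.sigma
            diag = {
                "n_obs": len(y),
                "method": "bayes",
                "max_rhat": float(np.max(post.rhat)),
                "warnings": post.warn_if_unconverged(f"decomposition[{self.element}]"),
            }

        r = len(species)
        self.params_ = DecompParams(
            element=self.element,
            species=species,
            beta=coef[:r],
            alpha=coef[r : 2 * r],
            b4=float(coef[2 * r]),
            b5=float(coef[2 * r + 1]),
        )
        self.coef_sd_ = sd
        self.sigma_ = sigma
        self.diagnostics_ = diag
        return self

    def predict(self, bags: pd.DataFrame) -> pd.Series:
        """Predicted loss rate (%) per bag in a long-format bag table."""
        out = {}
        for bag_id, grp in bags.groupby("bag_id"):
            props = dict(zip(grp["species"], grp["proportion"]))
            out[bag_id] = predict_decomposition(
                props,
                float(grp["total_mass_g"].iloc[0]),
                int(grp["richness"].iloc[0]),
                self.params_,
            )
        return pd.Series(out)


def fit_decomposition(bags: pd.DataFrame, element: str = "C", **kwargs) -> DecompositionModel:
    """Functional wrapper over :class:`DecompositionModel`."""
    return DecompositionModel(element=element, **kwargs).fit(bags)


def decomposition_map(
    litter: LitterMap,
    params: DecompParams,
    element_fractions: dict[str, float] | float | None = None,
) -> DecompositionMap:
    """Predict the element loss rate at every pixel of a litter map.

    Per pixel, the species litter masses are converted to proportions and
    the decomposition model evaluated with that pixel's total mass and
    litter richness. Pixels without litter are masked (NaN). ``mass_loss``
    multiplies the rate by the pixel's litter *element* density, using
    per-species element mass fractions (scalar broadcast allowed).
    """
    missing = [s for s in litter.species if s not in params.species]
    if missing:
        raise ValueError(f"no decomposition coefficients for species {missing}")
    idx = [params.species.index(s) for s in litter.species]
    beta = params.beta[idx]
    alpha = params.alpha[idx]
    mass = litter.mass
    total = litter.total
    valid = total > 0

    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(valid, mass / np.where(valid, total, 1.0), 0.0)
    linear = (
        np.tensordot(beta, P, axes=1)
        + np.tensordot(alpha, P * (1.0 - P), axes=1)
        + params.b4 * total
        + params.b5 * litter.richness
    )
    d = np.clip(linear, 0.0, 100.0)
    d = np.where(valid, d, np.nan)

    if element_fractions is None:
        fractions = np.ones(len(litter.species))
    elif np.isscalar(element_fractions):
        fractions = np.full(len(litter.species), float(element_fractions))
    else:
        fractions = np.array([element_fractions[s] for s in litter.species])
    element_density = np.tensordot(fractions, mass, axes=1)
    mass_loss = np.where(valid, d / 100.0 * element_density, np.nan)
    return DecompositionMap(element=params.element, d=d, mass_loss=mass_loss, mask=valid)
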