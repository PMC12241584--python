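"""Distance-decay litterfall model: fitting and per-pixel prediction.

The litter mass of species *i* reaching a point on the forest floor is
modelled from the surrounding trees of that species::

    L_i = b1_i * sum_j B_ij  +  b2_i * sum_j d_ij^-1  +  b3_i * sum_j B_ij * d_ij^-1

where ``B_ij`` and ``d_ij`` are the biomass of and distance (m) to the j-th
surrounding tree of species *i*. The model is calibrated on 1 m^2 litter
traps (each with up to 12 surrounding trees) and then evaluated at every
0.1 x 0.1 m pixel of a simulated stand, each pixel drawing on its 12
nearest trees. Predicted masses are densities (g/m^2) at the pixel center;
negative linear-model output is clamped to zero.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from .bayes import sample_linear_model
from .designs import Layout

COEF_NAMES = ("b1", "b2", "b3")
DEFAULT_K_TREES = 12
DEFAULT_DISTANCE_FLOOR_M = 0.05
PIXELS_PER_SIDE = 150
PIXEL_SIZE_M = 0.1
MAX_TREES_PER_TRAP = 12


@dataclass(frozen=True)
class TrapRecord:
    """One litter trap: observed per-species masses plus surrounding trees."""

    trap_id: str
    litter_mass_g: dict[str, float]            # species -> mass in the 1 m^2 trap
    tree_species: tuple[str, ...]
    tree_biomass: tuple[float, ...]
    tree_distance_m: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.tree_species) > MAX_TREES_PER_TRAP:
            raise ValueError(f"at most {MAX_TREES_PER_TRAP} surrounding trees")
        if any(m < 0 for m in self.litter_mass_g.values()):
            raise ValueError("litter masses must be non-negative")
        if any(d <= 0 for d in self.tree_distance_m):
            raise ValueError("tree distances must be positive")


def trap_tables(records: list[TrapRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format (trap_id, species, litter_mass_g) and tree tables."""
    mass_rows, tree_rows = [], []
    for rec in records:
        for sp, m in rec.litter_mass_g.items():
            mass_rows.append({"trap_id": rec.trap_id, "species": sp, "litter_mass_g": m})
        for k, (sp, b, d) in enumerate(
            zip(rec.tree_species, rec.tree_biomass, rec.tree_distance_m)
        ):
            tree_rows.append(
                {
                    "trap_id": rec.trap_id,
                    "tree_idx": k,
                    "species": sp,
                    "biomass": b,
                    "distance_m": d,
                }
            )
    return pd.DataFrame(mass_rows), pd.DataFrame(tree_rows)


@dataclass
class LitterMap:
    """Per-pixel predicted litter over a stand.

    ``mass`` holds per-species litter mass densities (g/m^2) on the pixel
    grid; ``total`` their sum and ``richness`` the count of species with
    positive (clamped) mass at each pixel.
    """

    species: tuple[str, ...]
    mass: np.ndarray      # (n_species, npix, npix)
    total: np.ndarray     # (npix, npix)
    richness: np.ndarray  # (npix, npix) int
    pixel_size: float = PIXEL_SIZE_M


def _design_sums(trees: pd.DataFrame) -> pd.DataFrame:
    """Per (trap, species) predictor sums of the litterfall design matrix."""
    t = trees.copy()
    t["inv_d"] = 1.0 / t["distance_m"]
    t["b_inv_d"] = t["biomass"] * t["inv_d"]
    sums = (
        t.groupby(["trap_id", "species"])[["biomass", "inv_d", "b_inv_d"]]
        .sum()
        .rename(columns={"biomass": "S1", "inv_d": "S2", "b_inv_d": "S3"})
        .reset_index()
    )
    return sums


class LitterfallModel(BaseEstimator):
    """Species-specific litterfall regression (scikit-learn style).

    Each species is fitted independently: the response is the observed trap
    mass of that species, the three predictors are the per-trap sums of
    neighbor biomass, inverse distance, and their product, restricted to
    trees of that species. The model has no intercept.

    Parameters
    ----------
    method:
        ``"ls"`` (default) — exact least squares; ``"bayes"`` — ensemble
        MCMC with normal(0, prior_scale^2) coefficient priors and Gaussian
        observation noise.
    chains, draws, warmup:
        Sampler settings for ``method="bayes"``.
    random_state:
        Seed for the sampler.

    Attributes
    ----------
    coef_:
        DataFrame indexed by species with columns b1, b2, b3.
    coef_sd_:
        Posterior SDs (NaN for least squares).
    sigma_:
        Residual / posterior noise scale per species.
    diagnostics_:
        Per-species fit metadata (n_obs, max R-hat, warnings).
    """

    def __init__(
        self,
        method: str = "ls",
        chains: int = 4,
        draws: int = 2000,
        warmup: int = 1000,
        prior_scale: float = 10.0,
        random_state: int | None = None,
    ):
        self.method = method
        self.chains = chains
        self.draws = draws
        self.warmup = warmup
        self.prior_scale = prior_scale
        self.random_state = random_state

    def fit(self, traps: pd.DataFrame, trees: pd.DataFrame) -> "LitterfallModel":
        """Fit per-species coefficients from trap mass and tree tables.

        ``traps``: columns (trap_id, species, litter_mass_g).
        ``trees``: columns (trap_id, tree_idx, species, biomass, distance_m).
        """
        if self.method not in ("ls", "bayes"):
            raise ValueError("method must be 'ls' or 'bayes'")
        sums = _design_sums(trees)
        # rows where the species has >= 1 surrounding tree; unobserved masses are 0
        data = sums.merge(traps, on=["trap_id", "species"], how="left")
        data["litter_mass_g"] = data["litter_mass_g"].fillna(0.0)

        species = tuple(sorted(data["species"].unique()))
        coefs, sds, sigmas, diags = {}, {}, {}, {}
        for sp in species:
            sub = data[data["species"] == sp]
            X = sub[["S1", "S2", "S3"]].to_numpy(dtype=float)
            y = sub["litter_mass_g"].to_numpy(dtype=float)
            if len(sub) < 1:
                raise ValueError(f"no trap records for species {sp}")
            rank = np.linalg.matrix_rank(X)
            if rank < 3:
                bad = _collinear_terms(X)
                raise ValueError(
                    f"rank-deficient litterfall design for species {sp}: "
                    f"collinear terms {bad} (e.g. all trees equidistant)"
                )
            if self.method == "ls":
                beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
                resid = y - X @ beta
                coefs[sp] = beta
                sds[sp] = np.full(3, np.nan)
                sigmas[sp] = float(np.sqrt(np.mean(resid**2)))
                diags[sp] = {"n_obs": len(sub), "method": "ls", "warnings": []}
            else:
                seed = None
                if self.random_state is not None:
                    seed = (self.random_state + zlib.crc32(sp.encode()) % 10007) % (2**31)
                post = sample_linear_model(
                    X,
                    y,
                    prior_scale=self.prior_scale,
                    chains=self.chains,
                    draws=self.draws,
                    warmup=self.warmup,
                    seed=seed,
                )
                coefs[sp] = post.mean
                sds[sp] = post.sd
                sigmas[sp] = post.sigma
                diags[sp] = {
                    "n_obs": len(sub),
                    "method": "bayes",
                    "max_rhat": float(np.max(post.rhat)),
                    "warnings": post.warn_if_unconverged(f"litterfall[{sp}]"),
                }

        self.species_ = species
        self.coef_ = pd.DataFrame(coefs, index=COEF_NAMES).T
        self.coef_sd_ = pd.DataFrame(sds, index=COEF_NAMES).T
        self.sigma_ = pd.Series(sigmas)
        self.diagnostics_ = diags
        return self

    def predict(self, trees: pd.DataFrame) -> pd.DataFrame:
        """Predicted per-species trap mass for each trap in ``trees``."""
        sums = _design_sums(trees)
        out = sums.merge(
            self.coef_.rename_axis("species").reset_index(), on="species", how="inner"
        )
        pred = (
            out["b1"] * out["S1"] + out["b2"] * out["S2"] + out["b3"] * out["S3"]
        ).clip(lower=0.0)
        return pd.DataFrame(
            {"trap_id": out["trap_id"], "species": out["species"], "predicted_mass_g": pred}
        )


def _collinear_terms(X: np.ndarray) -> list[str]:
    names = list(COEF_NAMES)
    bad = [names[k] for k in range(X.shape[1]) if np.allclose(X[:, k], 0)]
    if bad:
        return bad
    corr = np.corrcoef(X, rowvar=False)
    pairs = []
    for a in range(3):
        for b in range(a + 1, 3):
            if abs(corr[a, b]) > 1 - 1e-10:
                pairs.extend([names[a], names[b]])
    return sorted(set(pairs)) or names


def fit_litterfall(
    traps: pd.DataFrame, trees: pd.DataFrame, **kwargs
) -> LitterfallModel:
    """Functional wrapper over :class:`LitterfallModel`."""
    return LitterfallModel(**kwargs).fit(traps, trees)


def _pixel_centers(npix: int = PIXELS_PER_SIDE, pixel_size: float = PIXEL_SIZE_M):
    coords = (np.arange(npix) + 0.5) * pixel_size
    xx, yy = np.meshgrid(coords, coords, indexing="xy")
    return np.column_stack([xx.ravel(), yy.ravel()])


def _species_mass_at_points(
    points: np.ndarray,
    layout: Layout,
    biomass: np.ndarray,
    coef: pd.DataFrame,
    k: int = DEFAULT_K_TREES,
    d_floor: float = DEFAULT_DISTANCE_FLOOR_M,
) -> np.ndarray:
    """(n_points, n_species) clamped litter mass densities at given points."""
    positions = layout.positions_m()
    tree_sp = layout.species_indices().ravel()
    B = np.asarray(biomass, dtype=float).ravel()
    if (B <= 0).any():
        raise ValueError("tree biomass must be positive")
    k = int(k)
    if k < 1:
        raise ValueError("k must be >= 1")
    k = min(k, len(B))

    tree_xy = cKDTree(positions)
    dist, idx = tree_xy.query(points, k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    dist = np.maximum(dist, d_floor)

    sp_near = tree_sp[idx]           # (P, k)
    b_near = B[idx]
    inv_d = 1.0 / dist

    species = layout.mixture.species
    out = np.zeros((len(points), len(species)))
    for s, label in enumerate(species):
        if label not in coef.index:
            raise KeyError(f"no litterfall coefficients for species {label!r}")
        b1, b2, b3 = coef.loc[label, ["b1", "b2", "b3"]]
        mask = sp_near == s
        S1 = np.where(mask, b_near, 0.0).sum(axis=1)
        S2 = np.where(mask, inv_d, 0.0).sum(axis=1)
        S3 = np.where(mask, b_near * inv_d, 0.0).sum(axis=1)
        out[:, s] = np.clip(b1 * S1 + b2 * S2 + b3 * S3, 0.0, None)
    return out


def predict_pixel_litterfall(
    pixel_center: tuple[float, float],
    layout: Layout,
    biomass: np.ndarray,
    coef: pd.DataFrame,
    k: int = DEFAULT_K_TREES,
    d_floor: float = DEFAULT_DISTANCE_FLOOR_M,
) -> pd.Series:
    """Per-species litter mass density (g/m^2) at one point.

    Only the ``k`` trees nearest the point contribute, mirroring the
    fitting geometry of the 12-tree trap neighborhoods. Distances are
    center-to-stem with a floor of ``d_floor`` m.
    """
    point = np.asarray(pixel_center, dtype=float)[None, :]
    vals = _species_mass_at_points(point, layout, biomass, coef, k=k, d_floor=d_floor)
    return pd.Series(vals[0], index=list(layout.mixture.species))


def litterfall_map(
    layout: Layout,
    biomass: np.ndarray,
    coef: pd.DataFrame,
    k: int = DEFAULT_K_TREES,
    d_floor: float = DEFAULT_DISTANCE_FLOOR_M,
    npix: int = PIXELS_PER_SIDE,
    pixel_size: float = PIXEL_SIZE_M,
    richness_threshold: float = 0.0,
) -> LitterMap:
    """Predict per-species litter density at every pixel of the stand.

    Pixel litter species richness counts the species with clamped mass
    strictly above ``richness_threshold`` (default 0).
    """
    points = _pixel_centers(npix, pixel_size)
    vals = _species_mass_at_points(points, layout, biomass, coef, k=k, d_floor=d_floor)
    mass = vals.T.reshape(len(layout.mixture.species), npix, npix)
    total = mass.sum(axis=0)
    richness = (mass > richness_threshold).sum(axis=0)
    return LitterMap(
        species=layout.mixture.species,
        mass=mass,
        total=total,
        richness=richness,
        pixel_size=pixel_size,
    )
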