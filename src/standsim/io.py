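"""Reading and writing the package's tabular interchange formats.

All artifacts are plain text: layouts as 16 x 16 CSVs with a JSON sidecar,
coefficient tables and field datasets as CSV, ground truth and experiment
configuration as JSON/YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .decomposition import DecompParams
from .designs import (
    Layout,
    MixtureAssignment,
    SpeciesPool,
    heterogeneity,
)
from .growth import GrowthParams
from .pipeline import ExperimentConfig
from .synthetic import FieldDataset, GroundTruth


def write_layout(layout: Layout, path: str | Path) -> None:
    """Write a layout as CSV plus a JSON sidecar with its metadata and H."""
    path = Path(path)
    pd.DataFrame(layout.grid).to_csv(path, header=False, index=False)
    sidecar = {
        "design_label": layout.design_label,
        "mixture": list(layout.mixture.species),
        "seed": layout.seed,
        "H": heterogeneity(layout).H,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_layout(path: str | Path) -> Layout:
    path = Path(path)
    grid = pd.read_csv(path, header=None).to_numpy(dtype=object)
    meta = json.loads(path.with_suffix(".json").read_text())
    return Layout(
        grid=grid,
        design_label=meta["design_label"],
        mixture=MixtureAssignment(tuple(meta["mixture"])),
        seed=meta.get("seed"),
    )


def write_growth_params(params: GrowthParams, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    beta, alpha = params.to_tables()
    beta.to_csv(directory / "growth_beta.csv", index=False)
    alpha.to_csv(directory / "growth_alpha.csv", index=False)
    (directory / "growth_exponents.json").write_text(
        json.dumps({"theta": params.theta, "b": params.b})
    )


def read_growth_params(directory: str | Path) -> GrowthParams:
    directory = Path(directory)
    beta = pd.read_csv(directory / "growth_beta.csv")
    alpha = pd.read_csv(directory / "growth_alpha.csv")
    exps = json.loads((directory / "growth_exponents.json").read_text())
    return GrowthParams.from_tables(beta, alpha, theta=exps["theta"], b=exps["b"])


def write_field_dataset(data: FieldDataset, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data.traps.to_csv(directory / "traps.csv", index=False)
    data.trees.to_csv(directory / "trees.csv", index=False)
    data.bags.to_csv(directory / "bags.csv", index=False)
    data.tree_table.to_csv(directory / "tree_table.csv", index=False)


def read_field_tables(directory: str | Path) -> dict[str, pd.DataFrame]:
    directory = Path(directory)
    return {
        name: pd.read_csv(directory / f"{name}.csv")
        for name in ("traps", "trees", "bags")
    }


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Serialize a ground truth (for parameter-recovery checks) as JSON."""
    payload = {
        "species": list(truth.pool.species_ids),
        "growth": {
            "beta": truth.growth.beta.tolist(),
            "alpha": truth.growth.alpha.tolist(),
            "theta": truth.growth.theta,
            "b": truth.growth.b,
        },
        "litterfall": truth.litterfall.to_dict(orient="index"),
        "decomposition": {
            el: {
                "beta": dp.beta.tolist(),
                "alpha": dp.alpha.tolist(),
                "b4": dp.b4,
                "b5": dp.b5,
            }
            for el, dp in truth.decomposition.items()
        },
        "allometry": truth.allometry.to_dict(orient="index"),
        "element_fractions": truth.element_fractions,
        "trap_noise_fraction": truth.trap_noise_fraction,
        "bag_noise_pct": truth.bag_noise_pct,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    species = tuple(payload["species"])
    pool = SpeciesPool(species)
    growth = GrowthParams(
        species=species,
        beta=np.array(payload["growth"]["beta"]),
        alpha=np.array(payload["growth"]["alpha"]),
        theta=payload["growth"]["theta"],
        b=payload["growth"]["b"],
    )
    decomposition = {
        el: DecompParams(
            element=el,
            species=species,
            beta=np.array(d["beta"]),
            alpha=np.array(d["alpha"]),
            b4=d["b4"],
            b5=d["b5"],
        )
        for el, d in payload["decomposition"].items()
    }
    return GroundTruth(
        pool=pool,
        growth=growth,
        litterfall=pd.DataFrame.from_dict(payload["litterfall"], orient="index"),
        decomposition=decomposition,
        allometry=pd.DataFrame.from_dict(payload["allometry"], orient="index"),
        element_fractions=payload["element_fractions"],
        trap_noise_fraction=payload["trap_noise_fraction"],
        bag_noise_pct=payload["bag_noise_pct"],
    )


def read_experiment_config(path: str | Path) -> ExperimentConfig:
    """Load an experiment configuration from YAML."""
    cfg = yaml.safe_load(Path(path).read_text())
    pool = SpeciesPool(tuple(cfg.get("pool", SpeciesPool.default().species_ids)))
    richness_counts = {
        int(k): (v if v == "all" else int(v))
        for k, v in cfg.get("richness_counts", {2: "all", 4: 1000, 8: 1000}).items()
    }
    return ExperimentConfig(
        pool=pool,
        richness_counts=richness_counts,
        designs=tuple(cfg.get("designs", ("gradient", "miniblock", "double_line", "single_line"))),
        gradient_levels=int(cfg.get("gradient_levels", 8)),
        years=int(cfg.get("years", 10)),
        litter_k=int(cfg.get("litter_k", 12)),
        seed=int(cfg.get("seed", 0)),
    )
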