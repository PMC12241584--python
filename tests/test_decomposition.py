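import numpy as np
import pandas as pd
import pytest

from standsim import (
    DecompParams,
    MixtureAssignment,
    decomposition_map,
    fit_decomposition,
    litterfall_map,
    make_layout,
    predict_decomposition,
)
from standsim.litterfall import LitterMap


@pytest.fixture
def params2():
    return DecompParams(
        element="C",
        species=("A", "B"),
        beta=np.array([30.0, 50.0]),
        alpha=np.array([4.0, 6.0]),
        b4=0.5,
        b5=2.0,
    )


class TestPredict:
    def test_monospecific_bag_collapses_to_identity_terms(self, params2):
        d = predict_decomposition(np.array([1.0, 0.0]), 3.0, 1, params2)
        assert d == pytest.approx(30.0 + 0.5 * 3.0 + 2.0)

    def test_even_two_species_mixture_direct_substitution(self, params2):
        d = predict_decomposition(np.array([0.5, 0.5]), 2.0, 2, params2)
        # (beta1+beta2)/2 + (alpha1+alpha2)/4 + b4*L + 2*b5 (i<j pair convention)
        assert d == pytest.approx((30 + 50) / 2 + (4 + 6) / 4 + 0.5 * 2 + 2 * 2.0)

    def test_linear_predictor_above_100_is_clamped(self, params2):
        d = predict_decomposition(np.array([0.0, 1.0]), 100.0, 1, params2)
        assert d == 100.0

    def test_bad_proportions_rejected(self, params2):
        with pytest.raises(ValueError, match="proportions"):
            predict_decomposition(np.array([0.7, 0.7]), 2.0, 2, params2)

    def test_species_relabeling_symmetry(self, params2):
        flipped = DecompParams(
            element="C",
            species=("B", "A"),
            beta=params2.beta[::-1].copy(),
            alpha=params2.alpha[::-1].copy(),
            b4=params2.b4,
            b5=params2.b5,
        )
        p = np.array([0.3, 0.7])
        assert predict_decomposition(p, 2.0, 2, params2) == pytest.approx(
            predict_decomposition(p[::-1], 2.0, 2, flipped)
        )

    def test_additivity_limit_without_diversity_terms(self):
        params = DecompParams(
            element="C",
            species=("A", "B", "C"),
            beta=np.array([20.0, 40.0, 60.0]),
            alpha=np.zeros(3),
            b4=0.0,
            b5=0.0,
        )
        p = np.array([0.2, 0.3, 0.5])
        mono = [
            predict_decomposition(np.eye(3)[k], 0.0, 1, params) for k in range(3)
        ]
        assert predict_decomposition(p, 0.0, 2, params) == pytest.approx(p @ mono)


def make_bags(params, proportions, totals, rng=None, noise=0.0):
    rows = []
    for i, (p, L) in enumerate(zip(proportions, totals)):
        p = np.asarray(p, float)
        S = int((p > 0).sum())
        d = predict_decomposition(p, L, S, params)
        if rng is not None and noise > 0:
            d = float(np.clip(d + rng.normal(0, noise), 0, 100))
        for sp, prop in zip(params.species, p):
            rows.append(
                {
                    "bag_id": f"bag{i:04d}",
                    "element": params.element,
                    "species": sp,
                    "proportion": prop,
                    "total_mass_g": L,
                    "richness": S,
                    "loss_pct": d,
                }
            )
    return pd.DataFrame(rows)


class TestFit:
    def test_noise_free_recovery_is_exact(self):
        # per-species alpha needs mixtures of >= 3 species: in two-species
        # bags P_A(1-P_A) = P_B(1-P_B) and only alpha_A + alpha_B is
        # identifiable (the pair term is (alpha_A+alpha_B) P_A P_B)
        params = DecompParams(
            element="C",
            species=("A", "B", "C"),
            beta=np.array([30.0, 50.0, 40.0]),
            alpha=np.array([4.0, 6.0, 3.0]),
            b4=0.5,
            b5=2.0,
        )
        rng = np.random.default_rng(0)
        props = []
        for _ in range(80):
            u = rng.random()
            if u < 0.25:
                props.append(np.eye(3)[rng.integers(3)])
            else:
                p = rng.dirichlet(np.ones(3))
                props.append(p / p.sum())
        totals = rng.uniform(1.0, 10.0, 80)
        bags = make_bags(params, props, totals)
        fitted = fit_decomposition(bags, element="C").params_
        np.testing.assert_allclose(fitted.beta, params.beta, rtol=1e-7)
        np.testing.assert_allclose(fitted.alpha, params.alpha, rtol=1e-7)
        assert fitted.b4 == pytest.approx(0.5)
        assert fitted.b5 == pytest.approx(2.0)

    def test_all_monospecific_bags_error_names_alpha(self, params2):
        rng = np.random.default_rng(1)
        props = [np.eye(2)[i % 2] for i in range(20)]
        bags = make_bags(params2, props, rng.uniform(1, 5, 20))
        # give two richness values artificially impossible -> richness always 1
        with pytest.raises(ValueError, match="richness|alpha"):
            fit_decomposition(bags, element="C")

    def test_single_richness_level_rejected(self, params2):
        rng = np.random.default_rng(2)
        props = [np.array([x, 1 - x]) for x in rng.uniform(0.2, 0.8, 20)]
        bags = make_bags(params2, props, rng.uniform(1, 5, 20))
        with pytest.raises(ValueError, match="richness"):
            fit_decomposition(bags, element="C")


class TestMap:
    def uniform_litter(self, species, mass_per_species, npix=20):
        r = len(species)
        mass = np.full((r, npix, npix), mass_per_species)
        return LitterMap(
            species=tuple(species),
            mass=mass,
            total=mass.sum(axis=0),
            richness=np.full((npix, npix), r, dtype=int),
        )

    def test_uniform_map_gives_constant_d(self, params2):
        litter = self.uniform_litter(("A", "B"), 10.0)
        dmap = decomposition_map(litter, params2)
        assert np.nanstd(dmap.d) == pytest.approx(0.0)
        expected = predict_decomposition(np.array([0.5, 0.5]), 20.0, 2, params2)
        assert np.nanmean(dmap.d) == pytest.approx(expected)

    def test_monoculture_map_varies_only_through_mass(self):
        params = DecompParams(
            element="C", species=("A",), beta=np.array([40.0]),
            alpha=np.array([5.0]), b4=1.0, b5=2.0,
        )
        rng = np.random.default_rng(3)
        mass = rng.uniform(1.0, 5.0, size=(1, 10, 10))
        litter = LitterMap(
            species=("A",), mass=mass, total=mass[0],
            richness=np.ones((10, 10), dtype=int),
        )
        dmap = decomposition_map(litter, params)
        np.testing.assert_allclose(dmap.d, 40.0 + 1.0 * mass[0] + 2.0, rtol=1e-12)

    def test_zero_litter_pixels_are_masked(self, params2):
        mass = np.zeros((2, 5, 5))
        mass[:, 2, 2] = 3.0
        litter = LitterMap(
            species=("A", "B"), mass=mass, total=mass.sum(0),
            richness=(mass > 0).sum(0),
        )
        dmap = decomposition_map(litter, params2)
        assert np.isnan(dmap.d[0, 0])
        assert not np.isnan(dmap.d[2, 2])
        assert dmap.mask.sum() == 1

    def test_matches_pixel_loop_oracle_on_subwindow(self, mix8, truth):
        layout = make_layout(mix8, "random", seed=6)
        litter = litterfall_map(layout, np.full((16, 16), 100.0), truth.litterfall)
        params = truth.decomposition["C"]
        dmap = decomposition_map(litter, params)
        order = [list(litter.species).index(s) for s in params.species]
        for iy in range(70, 80):
            for ix in range(70, 80):
                m = litter.mass[order, iy, ix]
                L = litter.total[iy, ix]
                if L == 0:
                    assert np.isnan(dmap.d[iy, ix])
                    continue
                expected = predict_decomposition(
                    m / L, L, int(litter.richness[iy, ix]), params
                )
                assert dmap.d[iy, ix] == pytest.approx(expected)
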