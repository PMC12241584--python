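import numpy as np
import pandas as pd
import pytest

from standsim import (
    Layout,
    LitterfallModel,
    MixtureAssignment,
    fit_litterfall,
    litterfall_map,
    make_layout,
    predict_pixel_litterfall,
    simulate_growth,
)


def coefs(index, b1, b2, b3):
    return pd.DataFrame({"b1": b1, "b2": b2, "b3": b3}, index=list(index))


def single_tree_layout(species="Sp1"):
    mix = MixtureAssignment((species,))
    return Layout(
        grid=np.array([[species]], dtype=object), design_label="block", mixture=mix
    )


class TestPixelPrediction:
    def test_single_tree_direct_substitution(self):
        layout = single_tree_layout()
        c = coefs(["Sp1"], [0.1], [2.0], [0.05])
        # tree at the origin, pixel 1 m away, biomass 100
        pred = predict_pixel_litterfall((1.0, 0.0), layout, np.array([[100.0]]), c)
        assert pred["Sp1"] == pytest.approx(0.1 * 100 + 2.0 + 0.05 * 100)

    def test_distance_terms_vanish_when_b2_b3_zero(self, mix8):
        layout = make_layout(mix8, "random", seed=1)
        biomass = np.full((16, 16), 80.0)
        c = coefs(mix8.species, np.full(8, 0.02), np.zeros(8), np.zeros(8))
        pred = predict_pixel_litterfall((7.5, 7.5), layout, biomass, c, k=12)
        s = layout.species_indices().ravel()
        pos = layout.positions_m()
        d = np.hypot(pos[:, 0] - 7.5, pos[:, 1] - 7.5)
        nearest = np.argsort(d)[:12]
        for k, sp in enumerate(mix8.species):
            expected = 0.02 * biomass.ravel()[nearest][s[nearest] == k].sum()
            assert pred[sp] == pytest.approx(expected)

    def test_two_equidistant_identical_trees_double_one(self):
        mix = MixtureAssignment(("Sp1",))
        layout = Layout(
            grid=np.array([["Sp1", "Sp1"]], dtype=object),
            design_label="block",
            mixture=mix,
        )
        c = coefs(["Sp1"], [0.1], [2.0], [0.05])
        B = np.array([[100.0, 100.0]])
        # pixel equidistant (d) from both trees: the model sums are additive, so
        # the prediction is exactly twice the single-tree value at distance d
        d = np.hypot(0.5, 1.0)
        both = predict_pixel_litterfall((0.5, 1.0), layout, B, c, k=2)
        single = 0.1 * 100 + 2.0 / d + 0.05 * 100 / d
        assert both["Sp1"] == pytest.approx(2 * single)

    def test_k_below_one_rejected(self, mix8):
        layout = make_layout(mix8, "random", seed=1)
        c = coefs(mix8.species, np.full(8, 0.02), np.zeros(8), np.zeros(8))
        with pytest.raises(ValueError, match="k"):
            predict_pixel_litterfall((1.0, 1.0), layout, np.full((16, 16), 1.0), c, k=0)


class TestLitterMap:
    def test_monoculture_richness_one_everywhere(self, truth):
        mix = MixtureAssignment(("Sp1",))
        layout = make_layout(mix, "random", seed=0)
        field = simulate_growth(layout, truth.growth, years=3)
        litter = litterfall_map(layout, field.final, truth.litterfall, npix=40)
        assert (litter.richness == 1).all()
        assert (litter.mass >= 0).all()

    def test_mirror_symmetric_inputs_give_mirror_symmetric_map(self, pool8, truth):
        mix = MixtureAssignment(pool8.species_ids[:1])
        layout = make_layout(mix, "block")
        litter = litterfall_map(
            layout, np.full((16, 16), 100.0), truth.litterfall, npix=50, pixel_size=0.3
        )
        np.testing.assert_allclose(litter.total, litter.total[:, ::-1], rtol=1e-9)
        np.testing.assert_allclose(litter.total, litter.total[::-1, :], rtol=1e-9)

    def test_matches_per_pixel_loop_oracle_on_subwindow(self, mix8, truth):
        layout = make_layout(mix8, "random", seed=5)
        biomass = np.full((16, 16), 120.0)
        litter = litterfall_map(layout, biomass, truth.litterfall)
        pos = layout.positions_m()
        s = layout.species_indices().ravel()
        B = biomass.ravel()
        for iy in range(40, 50):
            for ix in range(40, 50):
                x, y = (ix + 0.5) * 0.1, (iy + 0.5) * 0.1
                d = np.hypot(pos[:, 0] - x, pos[:, 1] - y)
                order = np.argsort(d)
                if d[order[12]] - d[order[11]] < 1e-9:
                    continue  # 12th-nearest tie: membership of the k-set is ambiguous
                nearest = order[:12]
                dd = np.maximum(d[nearest], 0.05)
                for k, sp in enumerate(mix8.species):
                    m = s[nearest] == k
                    b1, b2, b3 = truth.litterfall.loc[sp, ["b1", "b2", "b3"]]
                    expected = max(
                        b1 * B[nearest][m].sum()
                        + b2 * (1 / dd[m]).sum()
                        + b3 * (B[nearest][m] / dd[m]).sum(),
                        0.0,
                    )
                    assert litter.mass[k, iy, ix] == pytest.approx(expected)

    def test_increasing_b1_never_decreases_total_mass(self, mix8, truth):
        layout = make_layout(mix8, "random", seed=3)
        biomass = np.full((16, 16), 100.0)
        base = litterfall_map(layout, biomass, truth.litterfall, npix=40)
        bumped_coefs = truth.litterfall.copy()
        bumped_coefs["b1"] += 0.01
        bumped = litterfall_map(layout, biomass, bumped_coefs, npix=40)
        assert (bumped.total >= base.total - 1e-12).all()

    def test_block_layout_has_larger_between_pixel_sd_than_random(self, mix8, truth):
        biomass = np.full((16, 16), 100.0)
        block = litterfall_map(make_layout(mix8, "block"), biomass, truth.litterfall)
        rand = litterfall_map(
            make_layout(mix8, "random", seed=0), biomass, truth.litterfall
        )
        assert block.total.std() > rand.total.std()
        assert 1.0 <= rand.richness.mean() <= 8.0


class TestFitting:
    def test_noise_free_least_squares_recovers_truth_exactly(
        self, truth, noise_free_dataset
    ):
        model = fit_litterfall(noise_free_dataset.traps, noise_free_dataset.trees)
        fitted = model.coef_.loc[truth.litterfall.index]
        np.testing.assert_allclose(
            fitted.to_numpy(), truth.litterfall.to_numpy(), rtol=1e-7
        )
        assert (model.sigma_ < 1e-6).all()

    def test_rank_deficient_design_names_collinear_terms(self):
        # every tree at the same distance makes B*d^-1 proportional to B
        traps = pd.DataFrame(
            {
                "trap_id": [f"t{i}" for i in range(6)],
                "species": "Sp1",
                "litter_mass_g": np.linspace(1, 4, 6),
            }
        )
        rng = np.random.default_rng(0)
        rows = []
        for i in range(6):
            for j in range(3):
                rows.append(
                    {
                        "trap_id": f"t{i}",
                        "tree_idx": j,
                        "species": "Sp1",
                        "biomass": rng.uniform(50, 150),
                        "distance_m": 1.0,
                    }
                )
        with pytest.raises(ValueError, match="collinear"):
            fit_litterfall(traps, pd.DataFrame(rows))

    def test_null_distance_components_covered_by_posterior(self):
        # single species, b2 = b3 = 0 truth: the Bayesian fit's credible
        # interval for the distance terms should cover zero
        rng = np.random.default_rng(7)
        rows_t, rows_m = [], []
        for i in range(80):
            n = rng.integers(3, 7)
            B = rng.uniform(50, 200, n)
            d = rng.uniform(0.5, 3.0, n)
            mass = 0.05 * B.sum() + rng.normal(0, 0.3)
            rows_m.append(
                {"trap_id": f"t{i}", "species": "Sp1", "litter_mass_g": max(mass, 0)}
            )
            for j in range(n):
                rows_t.append(
                    {
                        "trap_id": f"t{i}",
                        "tree_idx": j,
                        "species": "Sp1",
                        "biomass": B[j],
                        "distance_m": d[j],
                    }
                )
        model = LitterfallModel(
            method="bayes", draws=800, warmup=400, random_state=1
        ).fit(pd.DataFrame(rows_m), pd.DataFrame(rows_t))
        mean = model.coef_.loc["Sp1"]
        sd = model.coef_sd_.loc["Sp1"]
        for term in ("b2", "b3"):
            assert abs(mean[term]) < 3 * sd[term]
        assert mean["b1"] == pytest.approx(0.05, rel=0.15)
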