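import numpy as np
import pytest

from standsim import (
    MixtureAssignment,
    SpeciesPool,
    generate_field_dataset,
    generate_ground_truth,
)


@pytest.fixture(scope="session")
def pool8():
    return SpeciesPool.default(8)


@pytest.fixture(scope="session")
def mix8(pool8):
    return MixtureAssignment(pool8.species_ids)


@pytest.fixture(scope="session")
def truth(pool8):
    return generate_ground_truth(pool8, seed=20240901)


@pytest.fixture(scope="session")
def noise_free_dataset(truth):
    return generate_field_dataset(
        truth, n_pairs=120, seed=11, trap_noise_fraction=0.0, bag_noise_pct=0.0
    )


@pytest.fixture(scope="session")
def noisy_dataset(truth):
    return generate_field_dataset(truth, n_pairs=180, seed=11)


def brute_force_heterogeneity(grid, connectivity=4, expectation="conspecific"):
    """Independent H oracle: explicit double loop over all position pairs,
    with the null expectation taken from scipy's hypergeometric mean."""
    from scipy.stats import hypergeom

    grid = np.asarray(grid)
    nr, nc = grid.shape
    T = grid.size
    cells = [(r, c) for r in range(nr) for c in range(nc)]
    N = {cell: 0 for cell in cells}
    n_i = {cell: 0 for cell in cells}
    for u in cells:
        for v in cells:
            if u == v:
                continue
            dr, dc = abs(u[0] - v[0]), abs(u[1] - v[1])
            adjacent = (dr + dc == 1) if connectivity == 4 else (max(dr, dc) == 1)
            if adjacent:
                n_i[u] += 1
                if grid[u] == grid[v]:
                    N[u] += 1
    abundance = {}
    for cell in cells:
        sp = grid[cell]
        abundance[sp] = abundance.get(sp, 0) + 1
    H = 0.0
    for cell in cells:
        M = abundance[grid[cell]]
        k = (M - 1) if expectation == "conspecific" else (T - M)
        expected = hypergeom(T - 1, k, n_i[cell]).mean()
        H += N[cell] - expected
    return H
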