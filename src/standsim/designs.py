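"""Plantation layouts and tree-species spatial heterogeneity.

A simulated forest stand is a 16 x 16 planting grid (256 trees, 1 m spacing,
225 m^2 plot). Species mixtures are *ordered* permutations drawn from a
species pool; the order controls which species occupies which role in a
layout template (block, mini-block, double line, single line) or seeds the
fully random arrangement.

Spatial heterogeneity of a layout is scored against a hypergeometric null:
for tree *i* with ``n_i`` grid neighbors, the expected number of conspecific
neighbors under random planting is ``E[X_i] = n_i (M_s - 1) / (T - 1)`` where
``M_s`` is the abundance of *i*'s species and ``T`` the stand total. The
heterogeneity score is ``H = sum_i (N(i) - E[X_i])`` with ``N(i)`` the
observed conspecific neighbor count. ``H`` is large for clustered (block)
plantings and centered on zero for random ones.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

GRID_SIZE = 16
N_TREES = GRID_SIZE * GRID_SIZE
SPACING_M = 1.0
PLOT_AREA_M2 = 225.0

TEMPLATE_DESIGNS = ("block", "miniblock", "double_line", "single_line")
DESIGN_LABELS = TEMPLATE_DESIGNS + ("random",)

# rectangle grid (rows x cols of sub-rectangles) used by the block template
_BLOCK_PARTITION = {1: (1, 1), 2: (2, 1), 4: (2, 2), 8: (2, 4), 16: (4, 4)}


@dataclass(frozen=True)
class SpeciesPool:
    """An ordered pool of distinct species labels."""

    species_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.species_ids) < 2:
            raise ValueError("species pool must contain at least 2 species")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValueError("species labels must be distinct")

    def __len__(self) -> int:
        return len(self.species_ids)

    @classmethod
    def default(cls, size: int = 8) -> "SpeciesPool":
        return cls(tuple(f"Sp{i + 1}" for i in range(size)))


@dataclass(frozen=True)
class MixtureAssignment:
    """An ordered selection of distinct species (a mixture *permutation*).

    Two orderings of the same species set are distinct permutations: the
    order decides which template role (block position, line, ...) each
    species takes.
    """

    species: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ValueError("mixture species must be distinct")

    @property
    def richness(self) -> int:
        return len(self.species)


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Grid adjacency rule, truncated at the stand edge (no wraparound).

    connectivity 4 = rook (orthogonal) neighbors, 8 = Moore (orthogonal +
    diagonal). The heterogeneity null defaults to rook adjacency; the growth
    model uses the Moore rule (a focal tree and its eight neighbors).
    """

    connectivity: int = 4

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def offsets(self) -> tuple[tuple[int, int], ...]:
        if self.connectivity == 4:
            return ((-1, 0), (1, 0), (0, -1), (0, 1))
        return tuple(
            (dr, dc)
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0)
        )

    def neighbor_counts(self, shape: tuple[int, int]) -> np.ndarray:
        """Per-cell neighbor count n_i under edge truncation."""
        n = np.zeros(shape, dtype=int)
        for dr, dc in self.offsets:
            src = _shift_window(shape, dr, dc)
            n[src] += 1
        return n


HETEROGENEITY_NEIGHBORHOOD = NeighborhoodSpec(connectivity=4)
GROWTH_NEIGHBORHOOD = NeighborhoodSpec(connectivity=8)


@dataclass
class Layout:
    """A planted stand: a species label per position on the planting grid."""

    grid: np.ndarray
    design_label: str
    mixture: MixtureAssignment
    seed: int | None = None
    spacing: float = SPACING_M
    plot_area: float = PLOT_AREA_M2

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("layout grid must be 2-D")

    @property
    def T(self) -> int:
        return int(self.grid.size)

    @property
    def species(self) -> tuple[str, ...]:
        return self.mixture.species

    def species_indices(self) -> np.ndarray:
        """Grid of integer indices into the mixture's species order."""
        lookup = {s: k for k, s in enumerate(self.mixture.species)}
        return np.vectorize(lookup.__getitem__)(self.grid).astype(np.int64)

    def positions_m(self) -> np.ndarray:
        """(T, 2) metric stem coordinates (x, y) = (col, row) * spacing."""
        rows, cols = np.indices(self.grid.shape)
        return np.column_stack(
            [cols.ravel() * self.spacing, rows.ravel() * self.spacing]
        )

    def abundances(self) -> dict[str, int]:
        labels, counts = np.unique(self.grid, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


@dataclass
class HeterogeneityScore:
    """Observed vs hypergeometric-null conspecific neighbor counts."""

    observed: np.ndarray        # N(i), per position
    expected: np.ndarray        # E[X_i], per position
    abundance: np.ndarray       # M_s(i), per position
    heterospecific: np.ndarray  # K_i = T - M_s(i), per position
    H: float
    expectation: str = "conspecific"


def _shift_window(shape, dr, dc):
    """Index window of cells that HAVE a neighbor at offset (dr, dc)."""
    nr, nc = shape
    rs = slice(max(0, -dr), nr - max(0, dr))
    cs = slice(max(0, -dc), nc - max(0, dc))
    return rs, cs


def conspecific_neighbor_counts(grid: np.ndarray, nb: NeighborhoodSpec) -> np.ndarray:
    """N(i): number of same-species neighbors of every position."""
    counts = np.zeros(grid.shape, dtype=int)
    for dr, dc in nb.offsets:
        src = _shift_window(grid.shape, dr, dc)
        dst = _shift_window(grid.shape, -dr, -dc)
        counts[src] += grid[src] == grid[dst]
    return counts


def heterogeneity(
    layout: Layout | np.ndarray,
    nb: NeighborhoodSpec | None = None,
    expectation: str = "conspecific",
) -> HeterogeneityScore:
    """Score a layout's spatial heterogeneity against the hypergeometric null.

    Parameters
    ----------
    layout:
        A :class:`Layout` or a raw 2-D array of species labels.
    nb:
        Adjacency rule; defaults to rook (4-neighbor) adjacency.
    expectation:
        ``"conspecific"`` (default) uses ``E[X_i] = n_i (M_s - 1)/(T - 1)``,
        the hypergeometric expectation of *conspecific* neighbors, which is
        the internally consistent null for the observed conspecific counts
        (monocultures score exactly 0 and random layouts are centered on 0).
        ``"heterospecific"`` uses the literal ``n_i K_i / (T - 1)`` with
        ``K_i`` the heterospecific tree count; it shifts H by a constant per
        layout composition and is kept for comparison.
    """
    if nb is None:
        nb = HETEROGENEITY_NEIGHBORHOOD
    grid = layout.grid if isinstance(layout, Layout) else np.asarray(layout)
    T = grid.size
    observed = conspecific_neighbor_counts(grid, nb)
    n_i = nb.neighbor_counts(grid.shape)

    labels, inverse, counts = np.unique(
        grid, return_inverse=True, return_counts=True
    )
    abundance = counts[inverse].reshape(grid.shape)
    heterospecific = T - abundance
    if expectation == "conspecific":
        expected = n_i * (abundance - 1) / (T - 1)
    elif expectation == "heterospecific":
        expected = n_i * heterospecific / (T - 1)
    else:
        raise ValueError("expectation must be 'conspecific' or 'heterospecific'")

    H = float((observed - expected).sum())
    return HeterogeneityScore(
        observed=observed,
        expected=expected,
        abundance=abundance,
        heterospecific=heterospecific,
        H=H,
        expectation=expectation,
    )


def _n_permutations(n: int, r: int) -> int:
    return math.perm(n, r)


def _unrank_permutation(items: Sequence[str], r: int, rank: int) -> tuple[str, ...]:
    """rank -> r-permutation, in lexicographic order of index sequences."""
    pool = list(items)
    out = []
    for pos in range(r):
        block = _n_permutations(len(pool) - 1, r - pos - 1)
        idx, rank = divmod(rank, block)
        out.append(pool.pop(idx))
    return tuple(out)


def make_mixture_permutations(
    pool: SpeciesPool,
    richness: int,
    count: int | str = "all",
    seed: int | None = None,
) -> list[MixtureAssignment]:
    """Enumerate or uniformly sample ordered species-mixture permutations.

    ``count="all"`` enumerates every ordered r-permutation of the pool
    (e.g. 56 two-species permutations from an eight-species pool). An
    integer ``count`` draws that many *distinct* permutations uniformly
    without replacement, reproducibly under ``seed``.
    """
    n = len(pool)
    if richness > n:
        raise ValueError(f"richness {richness} exceeds pool size {n}")
    total = _n_permutations(n, richness)
    if count == "all":
        return [
            MixtureAssignment(p)
            for p in itertools.permutations(pool.species_ids, richness)
        ]
    count = int(count)
    if count > total:
        raise ValueError(
            f"requested {count} permutations but only {total} ordered "
            f"{richness}-permutations exist for a pool of {n}"
        )
    rng = np.random.default_rng(seed)
    ranks = rng.choice(total, size=count, replace=False)
    return [
        MixtureAssignment(_unrank_permutation(pool.species_ids, richness, int(r)))
        for r in ranks
    ]


def _equal_abundance_check(richness: int) -> int:
    if N_TREES % richness != 0:
        raise ValueError(
            f"richness {richness} does not divide {N_TREES}: equal species "
            "abundance cannot be maintained"
        )
    return N_TREES // richness


def _block_grid(species: Sequence[str]) -> np.ndarray:
    r = len(species)
    if r not in _BLOCK_PARTITION:
        raise ValueError(
            f"block template supports richness {sorted(_BLOCK_PARTITION)}, got {r}"
        )
    nrow, ncol = _BLOCK_PARTITION[r]
    h, w = GRID_SIZE // nrow, GRID_SIZE // ncol
    grid = np.empty((GRID_SIZE, GRID_SIZE), dtype=object)
    for k, sp in enumerate(species):
        r0, c0 = (k // ncol) * h, (k % ncol) * w
        grid[r0 : r0 + h, c0 : c0 + w] = sp
    return grid


def _miniblock_grid(species: Sequence[str]) -> np.ndarray:
    r = len(species)
    if 16 % r != 0:
        raise ValueError(f"mini-block template needs richness dividing 16, got {r}")
    grid = np.empty((GRID_SIZE, GRID_SIZE), dtype=object)
    for k in range(16):  # 4x4 grid of 4x4 sub-squares, row-major species cycle
        r0, c0 = (k // 4) * 4, (k % 4) * 4
        grid[r0 : r0 + 4, c0 : c0 + 4] = species[k % r]
    return grid


def _line_grid(species: Sequence[str], width: int) -> np.ndarray:
    r = len(species)
    if (GRID_SIZE // width) % r != 0:
        raise ValueError(
            f"line template (width {width}) needs richness dividing "
            f"{GRID_SIZE // width}, got {r}"
        )
    cols = np.array([species[(c // width) % r] for c in range(GRID_SIZE)], dtype=object)
    return np.tile(cols, (GRID_SIZE, 1))


def make_layout(
    mixture: MixtureAssignment,
    design_label: str,
    seed: int | None = None,
) -> Layout:
    """Build a stand layout from a template or a seeded random shuffle.

    Templates map the mixture's species order onto template roles: ``block``
    fills compact rectangles, ``miniblock`` cycles species over 4x4
    sub-squares, ``single_line`` assigns one species per column (order
    cycled), ``double_line`` per pair of adjacent columns. ``random``
    shuffles an equal-abundance species vector with the given seed.
    """
    per_species = _equal_abundance_check(mixture.richness)
    if design_label == "block":
        grid = _block_grid(mixture.species)
    elif design_label == "miniblock":
        grid = _miniblock_grid(mixture.species)
    elif design_label == "single_line":
        grid = _line_grid(mixture.species, width=1)
    elif design_label == "double_line":
        grid = _line_grid(mixture.species, width=2)
    elif design_label == "random":
        rng = np.random.default_rng(seed)
        vec = np.repeat(np.array(mixture.species, dtype=object), per_species)
        rng.shuffle(vec)
        grid = vec.reshape(GRID_SIZE, GRID_SIZE)
    else:
        raise ValueError(
            f"unknown design label {design_label!r}; expected one of {DESIGN_LABELS}"
        )
    return Layout(grid=grid, design_label=design_label, mixture=mixture, seed=seed)


def make_heterogeneity_gradient(
    mixture: MixtureAssignment,
    levels: int = 8,
    seed: int | None = None,
    nb: NeighborhoodSpec | None = None,
    n_trajectories: int = 50,
    n_swaps: int = 2000,
) -> list[Layout]:
    """Layouts spanning an evenly spaced H gradient from block to random.

    Candidate layouts are produced by applying 1..``n_swaps`` random pairwise
    position swaps to the block layout along ``n_trajectories`` seeded swap
    trajectories; for each evenly spaced target H between H(block) and 0 (the
    random-design null expectation) the candidate with the nearest H is kept.
    The first level is the exact block layout, the last a full random shuffle.
    H is tracked incrementally (a swap only perturbs two neighborhoods).
    """
    if levels < 2:
        raise ValueError("gradient needs at least 2 levels")
    if nb is None:
        nb = HETEROGENEITY_NEIGHBORHOOD
    rng = np.random.default_rng(seed)
    block = make_layout(mixture, "block")
    score = heterogeneity(block, nb)
    h_block = score.H
    # E-sum is layout-independent under equal abundance
    e_sum = float(score.expected.sum())
    targets = np.linspace(h_block, 0.0, levels)[1:-1]

    offsets = nb.offsets
    best: list[tuple[float, np.ndarray | None]] = [(np.inf, None) for _ in targets]
    flat_template = block.grid.ravel()
    nr, nc = block.grid.shape

    def local_conspecific(grid, r, c, sp):
        tot = 0
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and grid[rr, cc] == sp:
                tot += 1
        return tot

    for _ in range(n_trajectories):
        grid = block.grid.copy()
        n_sum = float(score.observed.sum())
        for _k in range(n_swaps):
            i, j = rng.choice(grid.size, size=2, replace=False)
            (r1, c1), (r2, c2) = divmod(int(i), nc), divmod(int(j), nc)
            a, b = grid[r1, c1], grid[r2, c2]
            if a != b:
                before = local_conspecific(grid, r1, c1, a) + local_conspecific(
                    grid, r2, c2, b
                )
                grid[r1, c1], grid[r2, c2] = b, a
                after = local_conspecific(grid, r1, c1, b) + local_conspecific(
                    grid, r2, c2, a
                )
                n_sum += 2.0 * (after - before)
            h = n_sum - e_sum
            for t_idx, target in enumerate(targets):
                diff = abs(h - target)
                if diff < best[t_idx][0]:
                    best[t_idx] = (diff, grid.copy())

    layouts = [
        Layout(
            grid=block.grid,
            design_label="gradient_1",
            mixture=mixture,
            seed=seed,
        )
    ]
    for t_idx, (_, grid) in enumerate(best):
        layouts.append(
            Layout(
                grid=grid,
                design_label=f"gradient_{t_idx + 2}",
                mixture=mixture,
                seed=seed,
            )
        )
    shuffled = make_layout(mixture, "random", seed=None if seed is None else seed + 1)
    layouts.append(
        Layout(
            grid=shuffled.grid,
            design_label=f"gradient_{levels}",
            mixture=mixture,
            seed=seed,
        )
    )
    return layouts
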