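# standsim

Spatially explicit simulation of how the **spatial arrangement of tree
species** in a planted forest stand shapes tree biomass, litterfall
distribution, and litter decomposition.

Reforestation projects must decide not only *which* species to plant but
*where* to plant them: monospecific blocks are easy to manage, fully random
mixtures maximize heterospecific neighborhood interactions. `standsim` is a
toolkit for exploring that trade-off. It simulates forest stands as 16 × 16
planting grids (256 trees at 1 m spacing, 225 m² ≈ 11,378 trees/ha),
generates planting designs spanning the full gradient from blocks to random
mixing (including the practically relevant mini-block, double-line and
single-line designs), and propagates the consequences through three linked
models to stand-level carbon and nitrogen dynamics.

## Models

**Spatial heterogeneity.** A layout is scored against a hypergeometric null
model. For tree *i* with *nᵢ* grid neighbors, species abundance *Mₛ* and
stand total *T*, the expected conspecific neighbor count under random
planting is *E[Xᵢ] = nᵢ(Mₛ − 1)/(T − 1)*, and

&nbsp;&nbsp;&nbsp;&nbsp;*H = Σᵢ (N(i) − E[Xᵢ])*

with *N(i)* the observed count. Blocks score high; random layouts center on
*H = 0*.

**Tree growth.** Annual biomass increments combine species-specific
intrinsic growth with pairwise neighbor interactions and sublinear
allometric scaling:

&nbsp;&nbsp;&nbsp;&nbsp;*B(t+1,i) − B(t,i) = β_s(i) B(t,i)^θ + Σ_{j∈nᵢ} α_{s(i),s(j)} B(t,j)^b*

**Litterfall.** The litter mass density of species *i* at a point on the
forest floor follows a distance-decay model over the *k* = 12 nearest
trees:

&nbsp;&nbsp;&nbsp;&nbsp;*Lᵢ = b₁ᵢ Σⱼ Bᵢⱼ + b₂ᵢ Σⱼ dᵢⱼ⁻¹ + b₃ᵢ Σⱼ Bᵢⱼ dᵢⱼ⁻¹*

evaluated at every 0.1 × 0.1 m pixel of the stand.

**Decomposition.** Element loss (% C or N) of the litter mixture at a pixel
follows an additive diversity-interaction model over litter-mass
proportions *Pᵢ*, total mass *L* and litter richness *S*:

&nbsp;&nbsp;&nbsp;&nbsp;*D = Σᵢ βᵢ Pᵢ + Σ_{i<j} (αᵢ + αⱼ) Pᵢ Pⱼ + b₄ L + b₅ S*

The litterfall and decomposition models are fitted to trap / litterbag
records — exactly (least squares; both models are linear in their
coefficients) or by ensemble MCMC with weakly informative priors. A
synthetic-data module generates field-like datasets with known ground-truth
coefficients so every fitting stage is testable without downloads.

## Worked example

```python
from standsim import (
    SpeciesPool, SimulationParams, generate_ground_truth,
    make_mixture_permutations, make_layout, simulate_stand,
)

pool = SpeciesPool.default(8)
truth = generate_ground_truth(pool, seed=7)
mixture = make_mixture_permutations(pool, richness=8, count=1, seed=7)[0]
params = SimulationParams(
    growth=truth.growth, litterfall=truth.litterfall,
    decomposition=truth.decomposition,
    element_fractions=truth.element_fractions,
)
for design in ("block", "single_line", "random"):
    row = simulate_stand(make_layout(mixture, design, seed=7), params)
    print(f"{design:12s} H={row['H']:7.1f}  "
          f"litterfall SD={row['sd_litterfall_g_m2']:5.2f} g/m2  "
          f"pixel richness={row['mean_pixel_litter_richness']:4.2f}  "
          f"mean C loss={row['mean_D_C_pct']:5.2f} %")
```

prints

```
block        H=  715.3  litterfall SD=17.11 g/m2  pixel richness=1.88  mean C loss=48.49 %
single_line  H=  363.3  litterfall SD=11.96 g/m2  pixel richness=3.93  mean C loss=53.18 %
random       H=  -10.7  litterfall SD=11.64 g/m2  pixel richness=6.36  mean C loss=57.81 %
```

Reading the rows: moving from blocks to random planting dissolves the
spatial clustering (*H*: 715 → ≈0), which mixes the litter layer (pixel
litter richness 1.9 → 6.4 species), evens out the litterfall across the
forest floor (between-pixel SD 17.1 → 11.6 g/m²), and accelerates carbon
loss from the litter layer (48.5 → 57.8%). Single lines of species — a
design foresters can actually manage — recover a large share of the random
design's benefit.

The `standsim` console script exposes the same pipeline from the shell
(`standsim synth`, `standsim fit`, `standsim simulate`, `standsim report`);
see `standsim --help`.

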