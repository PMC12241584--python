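# Methods

This note documents the models implemented in `standsim`, the choices made
where the design was genuinely open, and what the synthetic-data generator
does and does not emulate.

## Stand geometry and planting designs

A stand is a 16 × 16 grid of trees at 1 m spacing on a 225 m² plot
(≈ 11,378 trees/ha); stem coordinates are (col, row) metres, so stems span
15 m × 15 m edge to edge. Species mixtures are *ordered* permutations drawn
from a pool (8 species by default); the order maps species onto template
roles, so two orderings of the same species set are distinct treatments.
All designs hold species abundances exactly equal (256/r trees per species,
r ∈ {2, 4, 8} supported against the templates).

Templates:

- **block** — compact rectangles: two 8 × 16 halves (r = 2), four 8 × 8
  quadrants (r = 4), two rows of four 8 × 4 rectangles (r = 8). Maximal
  compactness is what distinguishes "block" from the line designs.
- **miniblock** — species cycled row-major over the sixteen 4 × 4
  sub-squares.
- **double_line / single_line** — species cycled over pairs of adjacent
  columns / single columns.
- **random** — a seeded uniform shuffle of the equal-abundance species
  vector.
- **gradient** — layouts spanning evenly spaced heterogeneity targets
  between the block layout and the random null (below).

## The heterogeneity score H

For tree *i* with *nᵢ* neighbors, species abundance *Mₛ* and stand total
*T*, random placement makes the conspecific neighbor count hypergeometric
with mean *E[Xᵢ] = nᵢ(Mₛ − 1)/(T − 1)*; the stand score is
*H = Σᵢ(N(i) − E[Xᵢ])*. Monocultures score exactly 0 and random layouts
are centered on 0 (a property test checks the Monte-Carlo mean over 500
seeded layouts); blocks score highest.

Two open choices, and how they were fixed:

- **Adjacency.** The score defaults to rook (4-neighbor) adjacency,
  truncated at the stand edge. Under this rule the single-line design
  closes close to half of the block-to-random heterogeneity gap and the
  double-line design close to an eighth — the characteristic design
  contrast this score is meant to expose. Moore (8-neighbor) adjacency is
  available through `NeighborhoodSpec` and is the default for the *growth*
  model, whose interaction term is defined over a focal tree's eight
  neighbors. Gap-closure ratios are invariant to the per-layout constant in
  E, but do depend on the adjacency rule.
- **Expectation.** The conspecific expectation above is the internally
  consistent null for the observed conspecific counts. An alternative
  "heterospecific" reading, *E[Xᵢ] = nᵢKᵢ/(T − 1)* with *Kᵢ = T − Mₛ*,
  merely shifts H by a composition constant; it is retained behind
  `expectation="heterospecific"` for comparison.

**Gradient construction.** Candidates are produced by 50 seeded trajectories
of up to 2000 random pairwise position swaps starting from the block layout;
H is updated incrementally (a swap perturbs only two neighborhoods), and for
each evenly spaced target between H(block) and 0 the nearest candidate is
kept. The first level is the exact block layout and the last a full
shuffle. Trajectory count and swap budget are arguments.

## Growth model

Annual increments: *B(t+1,i) − B(t,i) = β_s(i)B(t,i)^θ + Σ_j α_{s(i),s(j)}B(t,j)^b*,
with Moore neighborhoods truncated at the stand edge (isolated stands, no
wraparound, no phantom trees). Stands start from a uniform biomass of 100
model units and run 10 years by default. Numerical guards: biomass is
floored at 10⁻⁶ (B^θ is undefined for negative B, and strongly negative
interactions could otherwise flip signs), and any biomass exceeding 10¹²
raises an error naming the step. Biomass units are model units anchored at
the start value; `SimulationParams.biomass_scale` converts to the field
units the litterfall coefficients were fitted in (default 1, i.e. the
synthetic ground truth is self-consistent across stages).

## Litterfall model

*Lᵢ = b₁ᵢΣBᵢⱼ + b₂ᵢΣdᵢⱼ⁻¹ + b₃ᵢΣBᵢⱼdᵢⱼ⁻¹* per species, calibrated on
1 m² trap records with up to 12 surrounding trees, then evaluated at every
0.1 × 0.1 m pixel (predictions are densities, g/m², at the pixel center;
per-pixel absolute mass is density × 0.01 m²). Choices:

- **Contributing trees per pixel:** the 12 nearest, mirroring the fitting
  geometry. This also bounds per-pixel litter richness; `k` is an argument.
- **Distance floor** 0.05 m (half a pixel), so stem-coincident pixels do
  not blow up d⁻¹.
- **Negative predictions** are clamped to 0 before totals and richness; a
  pixel's litter richness counts species with clamped mass strictly above a
  configurable threshold (default 0).

Fitting is per species and intercept-free, on rows where the species has at
least one surrounding tree (absent observed masses default to 0). Least
squares is exact; the Bayesian mode uses Gaussian observation noise,
normal(0, 10²) coefficient priors and a half-normal noise-scale prior,
sampled with an affine-invariant ensemble (emcee), walkers grouped into 4
pseudo-chains of 1000 warmup + 2000 kept steps with a split-R-hat
diagnostic. Rank-deficient designs (e.g. all trees equidistant, which makes
ΣB d⁻¹ proportional to ΣB) raise an error naming the collinear terms.

## Decomposition model

*D = ΣᵢβᵢPᵢ + Σ_{i<j}(αᵢ+αⱼ)PᵢPⱼ + b₄L + b₅S*, per element (C and N are
independent coefficient sets; no cross-element constraint). The pair sum is
over unordered pairs i < j; since ΣPᵢ = 1 it collapses to ΣᵢαᵢPᵢ(1 − Pᵢ),
which is the form used throughout (an ordered-pair reading doubles the term
and is absorbed into α's scale). Predictions are clamped to [0, 100] %.
Zero-litter pixels are masked (NaN), not treated as D = 0. Mass-based
element loss per pixel is rate × litter element density, with constant
per-species element mass fractions (defaults: C 0.45, N 0.015) — a
deliberate simplification standing in for measured litter chemistry.

Identifiability is checked before fitting: per-species diversity terms
require mixtures (all-monospecific data raise an error naming the α terms),
and b₅ requires at least two litter richness levels. With exactly two
species, P₁(1 − P₁) = P₂(1 − P₂) in every bag, so only α₁ + α₂ is
identifiable — per-species diversity effects need mixtures of three or
more.

## Synthetic field data

`generate_ground_truth` draws coefficient sets from documented ranges:
growth β ∈ [0.02, 0.12] with θ = b = 0.75, conspecific α ∈ [−0.008, −0.004]
vs heterospecific α ∈ [−0.003, 0.003] (conspecific competition stronger, so
mixing benefits growth); litterfall b₁ ∈ [0.005, 0.02], b₂ ∈ [0.5, 2.0],
b₃ ∈ [0.01, 0.04] (all positive: positive mass and distance-decay
contributions); decomposition identity effects in a 25–55 % (C) / 20–50 %
(N) band with small positive diversity (α ∈ [2, 8]) and richness
(b₅ ∈ [0.8, 2.0]) effects, so diversity accelerates decomposition.

`generate_field_dataset` emulates a paired trap/litterbag campaign: 180
pairs by default, pair trees 1.28 m apart with ten 1 m-grid neighbors
(stems jittered ±0.25 m around nominal positions), stem sizes lognormal
(CBH ~ lognormal(log 0.3, 0.5) m — young plantations span a wide size
range), biomass through the CBH → basal area (CBH²/4π) → species allometry
chain. Trap masses are the noise-free model values plus Gaussian noise
(SD = 10 % of the dataset mean mass); bags mirror the noisy trap
composition, carry the trap's total litter mass as the mass covariate L
(the quantity that varies between traps and is the prediction-time
covariate), and get losses from the decomposition model plus Gaussian noise
(SD = 3 percentage points), clamped to [0, 100].

**What recovery the design supports.** With zero noise both fits recover
the truth to numerical precision (tested). At the default noise levels the
trap geometry (all trees 0.6–2 m from the trap) makes the three per-species
litterfall predictors strongly collinear, putting a floor of roughly 15 %
on the design-based relative standard error of individual coefficients;
similarly, per-species diversity effects α carry standard errors of ~2 %
points against true values of 2–8. Point recovery of individual weakly
identified coefficients is therefore noise-limited at n = 180, while
identity effects recover within a few percent and posterior uncertainty is
honest (credible intervals cover nulls and truths; tested). Passing tests
on these data show the fitting machinery is correct and calibrated — not
that every coefficient of a comparably noisy field campaign is individually
well determined.

The generator does **not** emulate: wind/topography/animal litter
transport, seasonal litterfall dynamics, mortality or stochastic growth,
mycorrhizal structure of the pool, or measured litter chemistry.

## Experiment pipeline

`run_experiment` crosses mixture permutations (2-species: all 56 of an
8-pool; 4- and 8-species: seeded uniform draws without replacement) with
designs (8 gradient levels + miniblock + double line + single line by
default), simulating growth → litterfall → decomposition per stand and
reducing each to one summary row (means and SDs over unmasked pixels;
biomass per m² of plot area). Runs are deterministic given the config seed;
per-stand failures are recorded in an `error` column without killing the
run; shards (`i/k`) partition mixtures by global index so shard outputs
concatenate to the full table. The default test-scale experiment in this
repository uses ~20 permutations × 4 designs; the full factorial
(2028 permutations × 11 designs = 22,308 stands) is embarrassingly parallel
by stand at roughly 0.1 s per stand.

`interaction_analysis` fits `response ~ richness * H` by OLS (statsmodels)
with H continuous — reporting plumbing, not a contribution; the
design-label factor can be analysed from the same table. Loess smoothing is
presentation, not inference, and is deliberately omitted; summaries export
as CSV.

## Known limitations

- Grid sizes other than 16 × 16 and unequal abundances are untested;
  landscape-scale (multi-stand) heterogeneity is out of scope.
- The growth-model coefficients are user-supplied or synthetic; refitting
  them to inventory data is out of scope.
- The biomass scale linking growth-model units to litterfall's biomass
  covariate is exposed (`biomass_scale`) rather than assumed.
- Ensemble-walker groups are not fully independent MCMC chains; the
  split-R-hat diagnostic is approximate (conservative in practice).
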