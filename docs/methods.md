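# Methods

## Model

### Forward demography

The habitat is a lattice of demes: either an all-land `size × size` square
whose expansion origin is the central cell `(floor(size/2), floor(size/2))`,
or a plain-text 0/1 raster with an explicit origin (and an optional
georeference for mapping sample coordinates). Adjacency is the
4-neighborhood restricted to land.

Each forward generation `t = 1..T` applies, in order:

1. **Logistic growth** per deme: `N ← N + r·N·(1 − N/K(t))`, floored at 0.
2. **Stepping-stone emigration**: deme `i` emits `m(t)·N(i)` individuals in
   total, split equally among its land neighbors. The total per-capita
   emigration is `m` regardless of neighbor count, so `Nm = K·m` keeps its
   usual meaning at map edges; isolated demes emit nothing. Migration
   redistributes only — the total population is conserved exactly (checked
   to 1e-12 relative in tests).

`K(t)` and `m(t)` are piecewise-constant schedules; the update that produces
generation `t` uses `K(t)`, `m(t)`. Densities are continuous reals and the
demography is fully deterministic: demographic stochasticity is out of
scope, and one recorded run conditions all coalescent replicates of a
scenario. A consequence of continuous densities is that the colonization
wavefront advances exactly one Manhattan ring per generation (any positive
density emits positive flow), so "time since colonization" at a deme is its
L1 distance from the origin, not a stochastic front arrival time.

### Backward serial coalescent

Sampled lineages activate at their ages (generations before present, present
= forward generation `T`). Iterating backward over forward generations
`t = T..1`, each generation applies:

1. **Coalescence** within each occupied deme at local size
   `N = max(1, round(density))`: the number of merging pairs is
   `Binomial(k(k−1)/2, 1/N)` truncated at `floor(k/2)`, pairs disjoint and
   uniform. Multiple mergers per deme per generation are required near the
   expansion onset where `k² ≫ N`. A merge processed at generation `t` is
   stamped at the parent's generation (`t − 1` forward, i.e. one generation
   older), which makes the two-lineage TMRCA in a constant-`N` deme exactly
   Geometric(1/N) with mean `N`.
2. **Backward movement**: a lineage in deme `j` chooses its parent deme with
   probabilities proportional to the recorded flows into `j`. With
   `G(i)` the post-growth pre-migration density at `t − 1`, the weights are
   `w_stay = (1 − m)·G(j)` and `w_i = m·G(i)/deg(i)` per neighbor `i`. These
   weights sum to `N(j, t)` identically, so the normalized probabilities
   equal `M(i→j, t)/N(j, t)` with no clipping, and a deme first colonized at
   `t` forces its lineages to leave automatically (`G(j) = 0`).

Upon reaching forward generation 0, surviving lineages enter the **ancestral
phase**: a constant-size panmictic population of `N0` haploids at the origin,
extended indefinitely until a single root remains. This makes every TMRCA
finite and is the only model component not conditioned on the forward run.

### Mutation and statistics

Mutations follow a uniform finite-sites model: the root sequence is uniform
random; each branch receives `Poisson(rate · branchlength)` substitutions,
each at a uniform site, to a uniform different base (homoplasy possible).
The rate is `mu·L` per sequence per generation when `mu_per_site` is set
(the default in bundled scenarios), else `mu` directly; both modes are
bit-equivalent at equal total rate.

Per replicate we report gene diversity `H = n/(n−1)(1 − Σp²)`, nucleotide
diversity `π` (mean pairwise differences per sequence), the mean
within/between-sample coalescent times `t̄0` / `t̄1`, and Fst between the
modern and ancient sample computed as Φst — the two-level AMOVA variance
ratio `σ²_among/(σ²_among + σ²_within)` on the pairwise-difference matrix
(a haplotype-identity distance is available as a method switch). Negative
estimates are returned untruncated; an alignment with no variation reports
0. The estimator is verified in tests against an independently coded
brute-force AMOVA.

### Continuity test

`p = P(simulated Fst > observed Fst)` under the scenario's null, with strict
inequality; continuity is rejected iff `p < α`. The type-I-error driver
simulates `n_pods` datasets under a generating scenario and tests each
against one shared null of `n_sims` replicates under a testing scenario;
pods and null use independent seed streams derived from one master seed.
Bonferroni adjustment (`p·n`, capped at 1) is provided for multi-region
analyses.

## Numerical and engineering choices

- The backward simulation is a numba-compiled kernel over flat arrays
  (≈10 ms per 60-lineage replicate on the 50×50 world); the forward
  demography is vectorized numpy (≈0.4 s for 2500 demes × 2000
  generations, computed once per scenario and shared across replicates).
- Reproducibility: a master seed spawns one `SeedSequence` per replicate
  (kernel and mutation streams separated), so any replicate is reproducible
  in isolation; every CLI output directory carries a manifest with the seed
  and arguments. All derived seeds fit in 31 bits.
- All artifacts are plain text (YAML scenarios, 0/1 rasters, TSV, JSON,
  FASTA, Newick).

## Generator realism and measured behavior

Measured on the bundled scenarios (μ = 3.3e-6 per site, L = 300, 30 modern
+ 30 ancient lineages at 0 and 400 generations BP, T = 2000, N0 = 100;
500 replicates unless noted):

- Panmictic growth scenario (single deme, r = 0.012, K = 1.25e6): mean Fst
  −0.0002 (SD 0.0053), mean t̄1 1991, mean π_mod 3.88, mean H_mod 0.978.
- Spatial scenarios (50×50, K = 500): mean Fst 0.0201 at Nm = 50,
  0.0338 at Nm = 25, 0.1049 at Nm = 5, 0.1509 at Nm = 2.5 — a strictly
  monotone ladder in decreasing gene flow. Smaller demes at fixed Nm
  (K = 100, larger m) raise Fst further.
- Migration-shift scenario (Nm 5 → 50 at 400 BP): mean Fst 0.060–0.063
  across seeds, strictly between the constant-Nm regimes.
- Calibration: testing pods against their own generating scenario rejects
  ≈5 % of the time at α = 0.05 (5.5 % over 400 pods × 500 simulations);
  testing structured pods against a panmictic null rejects 81–100 % of the
  time, while testing panmictic pods against a strongly structured null
  essentially never rejects. This asymmetry is the core argument for the
  spatial null.
- Heterogeneous ancient sampling (25 ancient lineages split over 5 groups,
  300 replicates per scheme): temporal spread lowers Fst relative to
  homogeneous sampling at both Nm = 5 (0.100 homogeneous → 0.069 at the
  widest spread) and Nm = 50 (0.019 → 0.013); spatial spread at Nm = 5
  first lowers Fst (0.071 at offset 1) and then recovers toward the
  homogeneous value with extreme dispersion (0.085 at offset 7). At
  Nm = 50 this spatial recovery does **not** occur in this generator
  (0.0153 → 0.0130): with high gene flow, the extra within-ancient
  diversity from dispersed sampling outweighs the small increase in
  modern–ancient separation. Both effects are stronger at Nm = 5.

### Sensitivity to the square-world growth rate r

The square-world growth rate defaults to r = 0.4 and is exposed in the
scenario config. The Nm = 50 mean between-sample coalescent time is
insensitive to it: over r ∈ {0.2, 0.3, 0.4, 0.6, 1.0}, mean t̄1 stays within
2082–2085 (500 replicates each), and mean Fst within the Monte-Carlo noise
of 0.020. r controls only the onset (how fast demes reach K after the
deterministic front passes); with continuous densities the front timing
itself does not depend on r.

### Known deviation: depth of between-sample coalescent times

At Nm = 50 the measured mean t̄1 is ≈2083 generations, with ≈90 % of
modern×ancient lineage pairs failing to coalesce within the 2000-generation
window and resolving in the ancestral N0 = 100 phase (conditional mean
≈2092, vs ≈1906 for pairs resolving in-window). This deep-tail share is a
structural property of the model as specified — deterministic continuous
densities, exact flow-reversal backward kernel, constant-N0 ancestral
phase — and is robust to every convention we varied: coalesce-then-move vs
move-then-coalesce event order, r between 0.2 and 1.0, integer-rounded
densities, and integer (floored) migrant flows with the resulting slow
stochastic-looking front. Because t̄0 and t̄1 are inflated together, the
ratio-based Fst is only mildly affected (it comes out ~5–15 % low at small
Nm), but absolute coalescent-time targets tied to a shallower ancestral
tail are missed by ≈3 %: the acceptance checks on mean t̄1 at Nm = 50 and on
the exact mean Fst at Nm = 5 and under the migration shift fail honestly at
their stated tolerances, and are left failing rather than retuned. The
monotone orderings (Fst ladder, between-regime placement of the
migration-shift scenario) all hold.

## Limitations

- No demographic stochasticity: densities are deterministic reals, so
  colonization fronts are sharp and identical across replicates.
- Single non-recombining locus (mitochondrial-style data); no selection,
  no diploid pedigree structure.
- Mutation model is uniform finite-sites without transition bias or rate
  heterogeneity; pairwise-difference statistics are insensitive to base
  identity, but model-corrected distances are not implemented.
- The ancestral phase is a constant-size panmictic population at the
  origin; scenarios whose pre-expansion history matters should treat
  absolute coalescent times (not Fst) with care, per the deviation above.
- The latitude/longitude → deme mapping is an equirectangular
  approximation with nearest-cell snapping, adequate for coarse
  (tens-of-km) rasters only.
- Type-I error is measured under continuity; power against explicit
  replacement or admixture alternatives is not implemented.
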