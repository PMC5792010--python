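# Methods

## Survey model

`raftkit` models a paired regional survey design. On each beach two
independent record streams are collected:

* **Standardized quadrat counts** (general litter): two transects along
  the upper and lower tidelines, each of four adjoined 3 × 3 m
  quadrats, 72 m² per beach. Every macro-litter item (> 1.5 cm) is
  recorded as a (object type, material, count) row per quadrat.
  Material is one of hard plastics (HPl), other plastics (OPl),
  synthetic foams (Foam) and non-plastics (NPl); the source category
  (Sewage, Fishing/Aquaculture, Household/Leisure, Not attributable)
  is derived from the object type through a fixed mapping. Unknown
  object types map to Not attributable by design — unidentifiable
  fragments dominate real beach litter — so source assignment is total.
* **Fouled-item inventory** (rafts): every litter object found anywhere
  on the beach with visible attached macrofauna, with per-taxon counts
  of attached individuals over six groups: goose barnacles, acorn
  barnacles, bryozoan/hydrozoan colonies (a colony counts as one
  individual), decapods, molluscs, polychaetes. Terrestrial
  hitch-hikers (e.g. land snails) are outside the vocabulary; readers
  drop an optional `other` column with a notice. A fouled item carries
  at least one individual by definition; all-zero rows are rejected.

Beaches may carry a raft inventory without standardized counts. Beaches
with a non-standard number of quadrats are accepted with a warning —
field data are irregular — and all integrity findings are reported as a
list rather than exceptions.

## Packaged regional fixture

The package ships an item-level reconstruction of a published survey of
15 Cantabrian-coast beaches (Asturias, Spain; February–March 2016),
rebuilt from the printed per-beach summary table: see
`src/raftkit/data/README.md` for the encoding rules (per-beach totals
as `round(density × 72 m²)`, category counts as the integer vectors
whose half-up-rounded percentages match the printed integers, and one
documented exception where no exact integer encoding exists). The
printed percentage table itself (`litter_summary.csv`) is packaged
separately and is the authoritative input for the distance-based
inference; the item-level files exercise the full data path. Per-item
attachment counts and the within-beach quadrat scatter are synthetic:
only their regional and per-beach margins are data.

## Community summaries

* **Compositions** are item fractions per category; for fouled items
  each item counts once regardless of how many individuals it carries.
* **Litter density** is total items over total sampled area, with
  per-quadrat spread statistics.
* **Beach groups**: a beach with fewer than 25 items in the 72 m²
  standardized area (≈ 0.35 items·m⁻²) is "Mix" regardless of
  composition; otherwise the plurality material decides (HPl-dominant /
  OPl-dominant). Plurality, not majority, is used because observed
  groupings include dominance at 45% of items. A foam- or
  non-plastic-led beach above the threshold falls back to Mix (no such
  beach occurs in the regional data); argmax ties break in fixed
  material order with a logged notice. Beaches without standardized
  counts stay unclassified.
* **Biota profiles** per material pool attached individuals over all
  items of that material in the region and normalize rows (default).
  The alternative of averaging each item's own shares
  (`mode="per_item_mean"`) weights small and large rafts equally and is
  exposed as an option; pooled shares are the default because they
  reproduce the published per-material percentages. The packaged NPl
  profile row (goose 0.97, acorn 0.02, molluscs 0.01) encodes the
  published verbal description of that material's fauna. Profile rows
  are renormalized after assembly because printed percentages sum to
  99–101 by rounding.

## Distance-based inference

The General-litter-vs-Rafts comparisons run on the per-beach
**integer percentage tables** (no transformation, no standardization):
group means in the published SIMPER table equal raw column means of the
printed integers, which fixes the dialect. The material comparison uses
five variables — HPl, OPl, Foam, NPl **and the printed sum-of-plastics
column** — which reproduces the published sums of squares and pseudo-F
exactly; the four material categories alone do not. The sum-of-plastics
column is kept as printed (it differs from the category sum by
rounding).

* **Bray–Curtis**: `d(i,j) = scale · Σ|x_ik − x_jk| / Σ(x_ik + x_jk)`,
  reported on a 0–100 scale for percentage inputs. All-zero rows are
  rejected by sample name.
* **PERMANOVA** (one-way) partitions squared dissimilarities:
  `SS_total = (1/N) Σ_{i<j} d²`, `SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²`,
  `pseudo-F = (SS_between/df_b)/(SS_within/df_w)`. Significance comes
  from unrestricted permutation of sample labels with the observed
  statistic counted in numerator and denominator:
  `p = (1 + #{F* ≥ F}) / (1 + n_perm)`. The number of distinct label
  arrangements seen is reported as information only. With Euclidean
  distances on univariate data the statistic equals the classical
  one-way ANOVA F (an oracle test enforces agreement to 1e-10
  relative); an exact-enumeration variant exists for small n.
* **SIMPER** (two groups): for each between-group pair, variable k
  contributes `scale·|x_ik − x_jk| / Σ_m(x_im + x_jm)`; contributions
  average over pairs and sum identically to the mean between-group
  Bray–Curtis dissimilarity. The dissimilarity/SD ratio is reported as
  NaN when the SD is zero rather than infinity.
* **NMDS** is non-metric (Kruskal): isotonic regression of
  configuration distances on dissimilarity ranks alternates with
  SMACOF/Guttman configuration updates; disparities are rescaled to a
  fixed norm each iteration so the majorization keeps raw stress
  non-increasing (the recorded per-iteration stress history is
  monotone by construction). Quality is Kruskal stress-1,
  `sqrt(Σ(d − d̂)² / Σd²)`. Ties in the input dissimilarities follow
  the primary approach: tied dissimilarities may receive unequal
  fitted distances, which on very small, highly tied inputs can admit
  partially degenerate zero-stress configurations — a known property
  of non-metric scaling, mitigated in practice by multiple random
  starts (best of `n_starts`, seed-controlled; default 8). Convergence
  is a relative raw-stress decrease below `tol` (default 1e-7, max 300
  iterations per start).

## Expected-taxa predictor

For taxon B on beach x, `T_B(x) = Σ_i fM(i,x) · fT(B,i) · Nt(x)`.
`fM` comes from the standardized general-litter quadrat counts — the
point of the method is predicting the rafting community from ordinary
litter censuses — while `fT` is the regional pooled biota profile and
`Nt` the beach's total rafting individuals. With normalized inputs the
expected counts conserve the beach total exactly; materials whose
profile row cannot be estimated contribute zero with a warning. The
estimator is exposed sklearn-style (`RaftCommunityPredictor.fit`
learns `profile_`; `predict` maps compositions and totals to expected
counts) and composes with sklearn parameter plumbing.

Validation pools (beach, taxon) pairs within a scope — whole region,
or the coastal halves west/east of Cape Peñas (longitude −5.85°, a
reconstruction from beach coordinates) — and computes Spearman rank
correlation between expected and observed counts (tie-corrected
average ranks). Three p-values are available:

* `asymptotic_t` (default): the conventional t transform with n − 2
  degrees of freedom, as typically reported;
* `permutation`: pairwise permutation of the pooled pairs;
* `block_permutation`: permutes whole beaches, keeping each beach's
  observed taxon vector intact.

The first two treat the pooled pairs as exchangeable, which they are
not: observed counts within a beach share the beach's fixed rafting
total, and expected values share the regional profile across beaches.
Zero-signal simulations show both are anticonservative for this
design. Beaches are the independent survey units, so the beach-block
permutation is the exactly valid scheme and is what the calibration
test uses; the default remains `asymptotic_t` for comparability with
conventional reporting, with this caveat.

Profile estimation is region-wide including the focal beach by
default (matching the published procedure); a leave-one-beach-out mode
quantifies that circularity, and `reference_profile` predicts from a
fixed external profile, which is also the basis of honest null
experiments (even leave-one-beach-out estimation leaks the other
beaches' observations into the pooled correlation). Pairs where both
expected and observed are zero are kept by default
(`drop_double_zeros` exposes the alternative).

## Synthetic surveys

The generator emulates the survey design with known truth:

* per-beach material compositions drawn from a Dirichlet law; default
  concentration (2.7, 1.4, 0.5, 0.5) has mean (0.53, 0.27, 0.10, 0.10),
  the regional mean composition, with realistic between-beach spread
  (zero concentration entries are structural zeros, giving exact
  single-material beaches);
* quadrat totals from a negative binomial with mean 13 items per
  quadrat (≈ 1.4 items·m⁻², the regional mean density) and
  overdispersion 1 (variance = m + a·m²; a = 0 is the Poisson limit),
  reflecting the patchy distribution of stranded litter; materials
  multinomial from the beach composition; object types from a
  per-material source mix dominated by unattributable fragments;
* 8 fouled items per beach (≈ the regional mean of 94/15 ≈ 6, rounded
  up so every material appears often enough to estimate profiles),
  material drawn proportional to the beach composition times an
  optional per-material fouling propensity (default uniform — fouling
  rates per material are plausible but unquantified, so a knob rather
  than a fitted quantity); attachments multinomial from the material's
  profile row with a zero-truncated Poisson total (rate 35 ≈ 3300
  individuals / 94 items), optionally fixed for null experiments.

Identical (config, seed) gives identical datasets. What the generator
does **not** emulate: spatial structure along the coast and
current-driven accumulation, seasonal effects, item size/buoyancy
covariates, species-level composition, and observer error. Passing
recovery tests therefore show the estimators invert the generator's
assumptions, not that real surveys satisfy them.

## Problem sizes and numerical choices

The test suite runs the printed-table comparisons at full size
(24 samples); oracle equivalences use 20–25 randomized small
instances; permutation-calibration uses 1000 simulated 12-sample
datasets at 99 permutations; parameter recovery uses 15 replicates of
~1000 fouled items, and zero-signal calibration 500 replicates at 199
block permutations — sizes chosen so the whole suite completes in a
few minutes while keeping Monte-Carlo error well inside the asserted
bands. Compositions are validated to sum to 1 within 1e-9; packaged
profile tables are renormalized on load (stored at 6 decimals);
percentage tables are rounded half-up, matching the printed tables'
convention (e.g. 87.5 → 88).

## Known limitations

* The fixture's per-item attachments and quadrat scatter are synthetic
  reconstructions; analyses that depend on them (e.g. the fixture's
  expected-vs-observed correlations) characterize the reconstruction,
  not the original specimens.
* One beach's printed raft source split admits no exact integer
  encoding (documented in the data README); the printed percentages
  remain the inference input, so published statistics are unaffected.
* Only one-way PERMANOVA designs are supported (no nesting, factors or
  covariates), SIMPER handles exactly two groups, and the NMDS is
  non-metric only.
* The predictor operates on the six coarse taxon groups; it does not
  score species-level invasion risk.
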