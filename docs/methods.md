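# Methods

`ihcstrat` implements a tile-level prognostic stratification workflow for
PD-L1 immunohistochemistry (IHC) slides of non-small-cell lung cancer, of
the kind used to split anti-PD-1-treated patients into a favourable
(DL-High) and an unfavourable (DL-Low) group from histology alone. This
note records the model, its assumptions, the tunable parameters, what the
synthetic data do and do not emulate, and the numerical choices made where
the design was genuinely open.

## Pipeline model

1. **Tiling.** Tumor regions arrive as polygon annotations in microns
   (GeoJSON). An axis-aligned, non-overlapping grid of `size_um`-square
   cells (default 100 µm) is anchored at the region bounding-box top-left;
   a cell becomes a tile iff the exact polygon/cell intersection area
   (shapely) reaches `coverage_min` (default 0.5). Partial edge cells are
   therefore dropped rather than padded, which keeps tile counts
   deterministic and translation-consistent.

2. **Stain normalization (Macenko).** Pixels are mapped to optical density
   OD = −log((I + ε)/I₀) with ε = 1e−6 and I₀ = 255. Pixels with any
   channel below the tissue threshold β = 0.15 are discarded; the two
   leading right-singular directions of the remaining OD cloud define the
   stain plane; the α = 1st and 99th percentile angle directions inside
   that plane, sign-fixed to nonnegative absorbance and unit norm, become
   the two stain vectors. Column 1 is the hematoxylin-like stain
   (larger red-channel absorbance — hematoxylin absorbs red), column 2 the
   DAB-like chromogen. Robust per-stain maxima are the 99th percentile of
   least-squares concentrations. Normalization re-expresses clipped
   least-squares concentrations in a reference basis after per-stain
   rescaling by the maxima ratio. Stain estimation pools pixels per slide
   by default (a list of tiles can be passed); per-tile estimation is the
   fallback. Failure modes are explicit: fewer than 50 tissue pixels
   raises an insufficient-tissue error, and a second singular value below
   2% of the first raises a degenerate-stain error (single-stain tile).
   The 2% figure was fixed against rendered single-stain tiles, where
   8-bit quantization leaves a residual second direction of ~0.5–1%.

3. **Embedding and reference normalization.** The embedder is pluggable:
   any callable mapping an RGB tile to a fixed-length vector (the study
   used a frozen pathology foundation model with 1,024 features; the
   package never ships or imitates its weights). Every feature of every
   tile — both cohorts — is standardized by the *reference cohort's*
   tile-level mean and sample (n−1) standard deviation. This is an exact
   affine map: the reference cohort becomes mean-0/sd-1 and the other
   cohort retains its batch offset expressed in reference-sd units; the
   package asserts that identity rather than claiming batch removal.
   Zero-variance features are floored at sd = 1e−8 with a warning.
   Patient-level (per-patient-mean) statistics are available as an option.

4. **Discovery (HCPC on extremes).** The k = 5 event-free patients with the
   longest follow-up and the 5 progressed patients with the shortest times
   (ties broken by patient id) form the discovery set. Their tiles are
   reduced by centered PCA — components retained until 80% of variance,
   capped at 50; unit-scaling is togglable and off by default because the
   features are already reference-standardized — with a deterministic sign
   convention (largest-magnitude loading entry positive). Ward-linkage
   agglomeration on the scores is cut at k = 3 clusters and consolidated
   by one k-means pass seeded at the cut means. Consolidation guarantees
   that each training tile's nearest centroid is its own cluster, which is
   what makes the projection rule below coherent. Clusters are renumbered
   by descending size (tie-break: ascending centroid first coordinate).
   The cluster numbering is **not** outcome-derived; the outcome enters
   only through the merge rule.

5. **Classification (frozen projection + vote + merge).** Held-out tiles
   are projected with the frozen center/loadings (no re-estimation; the
   serialized model hash is unchanged by classification), labelled by
   nearest centroid in the full retained-PC space (ties to the lowest
   index), and each patient is assigned the cluster with the most tiles
   (ties to the lowest index, flagged and logged; patients below a
   configurable tile floor, default 1, are reported unclassifiable).
   Clusters merge into two groups either by the shipped default rule
   {1,2}→High, {3}→Low, or by a data-driven rule that unions clusters with
   pairwise log-rank p ≥ 0.05 on the training cohort (optionally forcing
   two blocks by always merging the largest-p pair) and labels the block
   with the longer restricted mean survival "High". The data-driven rule
   mirrors how the published groups were formed ("similar PFS rates") and
   is what the end-to-end pipeline uses by default.

6. **Survival statistics.** Kaplan–Meier curves and medians; two-group
   log-rank tests; Cox proportional-hazards models via lifelines (Efron
   tie handling — all simulated times are continuous, where Efron and
   Breslow coincide; a Breslow cross-check against statsmodels PHReg lives
   in the tests). Proportional hazards are tested with the
   Grambsch–Therneau correlation of Schoenfeld residuals against a
   centered time transform (default: the Kaplan–Meier transform
   1 − S(t−); log, rank, identity and user callables are available);
   per-term statistics reproduce lifelines' implementation to machine
   precision and the global statistic is d·z′V̂z / Σ(g−ḡ)². When
   proportionality fails, an extended Cox model with
   β(t) = β₀ + β₁·f(t) is fitted on data episode-split at event times
   (default f = log t). RMST at τ = 24 months is the area under the KM
   curve with the Greenwood-style variance Σ Aᵢ² dᵢ/(nᵢ(nᵢ−dᵢ)); τ is
   clipped (with a warning) to the shortest maximum follow-up. The
   combined clinical + DL score is the linear predictor Σβx of a Cox model
   whose clinical terms passed a univariate screen at p < 0.1 (terms can
   be force-excluded, e.g. a biomarker collinear with the DL group);
   patients are split at the cohort median of the linear predictor, the
   "threshold adapted to the cohort" policy recomputing the median within
   whatever cohort is scored. Nested models are compared by likelihood
   ratio. Cohort comparison tables use Pearson chi-squared without
   continuity correction when all expected counts are ≥ 5, Fisher's exact
   test otherwise (exact for 2×2, seeded Monte-Carlo for larger tables),
   Wilcoxon rank-sum for continuous variables, and a Benjamini–Hochberg
   adjusted column; "Unknown" levels are excluded from tests but counted.
   Displayed p-values follow the source tables' style (floor "<0.001",
   3 decimals below 0.2, 1 decimal above); raw values are always stored.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical* structure the analysis assumes,
not histology. Tile vectors are isotropic Gaussians (sd `noise_sd`, default
1) around three cluster means placed at the vertices of an equilateral
triangle in a `latent_dim`-dimensional subspace (default 5), with pairwise
distance `cluster_separation × noise_sd`, rotated into feature space
(default 1,024 dims) by a seeded random orthonormal map. Separation 8 is
the well-separated regime used by the recovery suites; separation 0 is the
null. The non-reference cohort receives one shared per-feature offset
drawn from N(0, `cohort_shift_sd`²), default 0.2 — a modest embedding
batch effect, a fifth of the within-cluster noise per feature. Per-patient
cluster proportions are Dirichlet (default (1,1,1), i.e. uniform on the
simplex), tile counts uniform in `tiles_per_patient` (default 10–30).

Event times are exponential: rate ln2/`baseline_median_pfs_months`
(default 2.5 months, the published DL-Low training median) for Low
patients and that times `group_hazard_ratio` (default 0.63, the published
training hazard ratio) for High patients (clusters 1 and 2). Categorical
covariates (smoking 9% never, WHO performance status 17% grade 0,
histology 72/18/10, line of therapy 66/34 — the published whole-cohort
marginals) multiply the hazard through configured log-hazard effects,
defaulting to the published univariate estimates (smoking-ever HR 0.51,
WHO ≥ 1 HR 1.93). Censoring is an independent Uniform(0, c) with c solved
numerically (Brent) so the expected censored fraction equals
`censoring_rate` (default 0.2). Exponential times give closed-form RMST
and hazard-ratio oracles; one global seed expands into independent
named substreams (features / survival / clinical / images).

Rendered tile images follow the Beer–Lambert law I = I₀·exp(−M·C) with
the Ruifrok–Johnston hematoxylin/DAB absorbance matrix, which makes the
generating stain matrix a ground truth for Macenko recovery tests.

Passing tests on these data show that the pipeline's *statistics* behave
as designed (recovery, calibration, invariances). They say nothing about
real histology: no spatial correlation between neighbouring tiles, no
heavy-tailed embedding geometry, no scanner- or antibody-specific stain
variation beyond a global matrix change, and patients' tile mixtures are
exchangeable rather than spatially organized.

## Problem sizes and known limitations

The heavy suites run at desk scale, chosen once as the package's study
conditions: the end-to-end recovery uses 2,000 patients at the generator's
default 10–30 tiles/patient (~40,000 tiles × 1,024 features, ≈ 20 s and
≈ 2 GB); calibration suites use 500 null replicates (log-rank, Schoenfeld,
likelihood ratio); the time-varying-coefficient sign-recovery runs at
n = 250 per replicate. The patient-level recovery invariant (accuracy
≥ 0.98) is evaluated at the published discovery tile density (50–90
tiles/patient, matching the ~70/patient of the published discovery set):
at ~20 tiles/patient, uniform-Dirichlet mixtures make one-tile vote
margins common (~15% of patients), and the irreducible ~0.3% tile error
rate then flips ~2% of votes — a property of majority voting under
near-tied mixtures, not of the classifier.

Further limitations: the Benjamini–Hochberg step-up is monotone but not
idempotent (no procedure of this form is), and the suite asserts
monotonicity plus a direct-formula oracle; with two subjects a Cox partial
likelihood has no interior maximum, so the smallest worked Cox example
uses four subjects; the concordance index is provided only as a labelled
substitute where a published AUC's definition is unspecified, and no
attempt is made to reproduce restricted-data cohort results.
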