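# Methods

## Growth analysis

Radiation use efficiency over a growth window is the ratio of the biomass
increment to the IPAR increment, `RUE = ΔBM / ΔIPAR` (g MJ⁻¹).  Aboveground
biomass per unit ground area is the subsample dry-matter fraction scaled by
the plot's total fresh weight: `BM = (subsample_DW / subsample_FW) ·
total_FW / harvested_area`.  The harvested area divides (it does not
multiply): biomass is reported in g m⁻², and the 0.4 m² (canopy closure) and
0.8 m² (later stages) cut areas normalise the fresh-weight totals.

Daily PAR is 0.45 × daily solar irradiance (MJ m⁻² d⁻¹).  Canopy light
interception is measured with a ceptometer at three stages (canopy closure,
booting, 7 d after anthesis) as `LI% = 100·(PARᵢ − PARᵣ − PAR_g)/(PARᵢ −
PARᵣ)`; between measurements LI is interpolated linearly in calendar time and
held constant before the first and after the last measurement.  The
measurement protocol gives no information about the interpolation shape, so
the simplest monotone-in-data choice is used; the brute-force daily loop is
the reference implementation the vectorised accumulation is tested against.

Grain filling (7 d after anthesis → physiological maturity) receives a
senescence correction: IPAR accumulated over the final 25% of grain-filling
days enters the denominator at half weight, because the yellowing canopy
intercepts and uses light at reduced efficiency.  The grain-filling
denominator is therefore `MJacc_75% + 0.5·MJacc_25%`, and the whole-cycle
denominator is the pre-grain-fill IPAR span plus that quantity — the two
window denominators add exactly, which is asserted numerically in the tests.
The split day is `A7 + 0.75·(PM − A7)` with days at or before the split in
the 75% tranche.  A `rue_slope` alternative (least-squares slope of biomass
against accumulated IPAR across stages) is provided for plots with three or
more harvests.

Negative RUE values are legal (biomass loss between harvests) but flagged.

## Spectra handling

Field spectroradiometers mix 3 nm (VNIR) and 10 nm (SWIR) sampling; all
records are resampled to a common 1 nm grid by linear interpolation on read
so that band lookups and PLSR matrices are rectangular.  Reflectance outside
[0, 1] is an instrument artefact: the default `clip` mode saturates to the
nearest bound (keeping the matrix rectangular), `drop` masks to NaN.  The
PLSR path trims to 350–1800 nm and 1951–2450 nm (closed intervals), removing
the 1801–1950 nm atmospheric water-vapour band; vegetation-index evaluation
uses the untrimmed grid, since the index bands all lie inside well-behaved
regions.  Band lookup is nearest-neighbour with a 3 nm tolerance (the VNIR
instrument resolution); exact ties break toward the higher wavelength.

## Vegetation indices

The registry holds 27 fixed formulas.  Typographically ambiguous printings
were resolved as follows and are kept deliberately:

- **GNDVI-1** `(R810 − m)/(R810 + m)` with `m = (R510 + R561)/2`.
- **SAVI** uses the printed soil factor `L = 0.75` — the common literature
  value is 0.5, but the registry follows its source text.
- **TCARI** binds the `(R700/R670)` ratio to the 0.2 term:
  `3[(R700 − R670) − 0.2(R700 − R550)(R700/R670)]`; same convention for the
  705/750 variant.
- **SIPI-2** is `(R800 − R435)/(R415 − R435)` exactly as printed despite its
  unusual structure.  Note that as a homogeneous ratio it is scale-invariant,
  unlike EVI/SAVI/OSAVI whose additive constants make them sensitive to
  overall spectrum brightness (both behaviours are asserted in tests).
- **RARSb** `R675/(R650·R700)` carries units of 1/reflectance.

Normalized-difference indices are bounded in [−1, 1] for reflectance in
(0, 1]; missing bands or zero denominators propagate as NaN, never as a
silent zero.

## Adjusted means and screening

Trait values are adjusted for replicate (block) effects with the additive
two-way least-squares fit (genotype + replicate); the genotype adjusted mean
is its prediction at the average replicate effect and equals the plain
genotype mean for balanced data.  A uniform shift of one block moves every
adjusted mean by shift/n_rep (the grand mean absorbs it) and leaves genotype
contrasts untouched — that contrast invariance, not literal value invariance,
is what block adjustment can deliver.  Vegetation indices can additionally be
adjusted for phenology (days to a reference stage) as a covariate: residuals
plus grand mean.

Candidate predictors are screened by Pearson correlation with the target at
two-sided raw P < 0.05 on pairwise-complete observations.  No multiplicity
correction is applied by default — the screen is a permissive pre-filter, not
an inference — but Benjamini–Hochberg is available (`method="bh"`).

**R² convention.**  Throughout, R² is the squared Pearson correlation between
predictions and observations (the scatter-plot convention), not 1 − SSE/SST.
The two agree for an in-sample OLS fit and diverge for biased out-of-sample
predictions; squared correlation rewards ranking fidelity and ignores
calibration offset, which is the property of interest when models are used to
rank genotypes.

## Best-subset linear models

`BestSubsetLinear` enumerates every predictor subset of size 1..max_k
(exhaustive, capped at 25 candidate predictors), discards subsets in which
any variance inflation factor `VIF_j = 1/(1 − R²_j)` exceeds the threshold
(default 10 — a conventional multicollinearity bound), and picks the
in-sample R²-best subset of each size.  A larger size displaces a smaller
winner only when the incremental F statistic is significant at a
Bonferroni-corrected level (family-wise 0.05 over the p candidates).  The
gate is essential: raw in-sample R² is non-decreasing in subset size, so
without it the search would always return max_k terms and could never
recover a planted smaller truth; with it, a noise-free tie (F = 0) keeps the
smaller subset, and `max_k=1` reduces to the single best-correlated
predictor.  Exact-subset recovery of a planted 2-of-6 model at signal-to-
noise 20, n = 30 runs at ~97% over 200 simulations.  Both raw and adjusted
R² are reported, plus an optional metrics slice over the 10 rows with the
highest *observed* response.

The published-model registry (26 entries, 13 traits × best-combination-of-
sensors / canopy-VI) stores intercepts and named coefficients; predictor
keys are normalised to `<INDEX><layer><period>` with the canopy layer made
explicit, so the IPAR_PM pair — printed identically for both families — is
coefficient-identical key-for-key.

## Partial least squares regression

Single-response NIPALS on centered spectra (per-band variance scaling is off
by default: reflectance shares units across bands; `scale=True` is
available).  The decomposition collapses to a per-band regression vector
`B = W(PᵀW)⁻¹q` and an intercept, persisted as a two-column text artifact
(wavelength, coefficient) under a JSON header.  At the full component count
the predictions equal ordinary least squares on the same design (asserted to
1e-6), scores are mutually orthogonal, and the implementation matches the
scikit-learn reference on small cases — scikit-learn is used only as an
independent oracle in tests.

Component count is chosen by k-fold cross-validation (10-fold by default;
fold assignment seeded): chosen = argmin RMSEP-CV, ties toward fewer
components, with PRESS = n·RMSEP² reported alongside.  On pure-noise
responses the rule picks ≤ 2 components in ≥ 90% of seeded runs; on a
planted rank-2 signal it picks exactly 2.  Model validation uses a seeded
random 80/20 split (`round(0.8·n)` training rows, no stratification).

## Synthetic trials

The generator emulates a randomized complete block yield-potential trial.
Defaults are the study conditions the package targets: 11 genotypes ×
3 replicates × 1 year; stage days E40 = 40, booting = 61, anthesis + 7 = 83,
maturity = 116 after emergence; genotype-mean RUE centred on 2.03 (E40→InB),
2.69 (InB→A7) and 1.23 (grain filling) g MJ⁻¹ with genotype SDs
0.20/0.22/0.18; starting biomass 201.6 g m⁻²; noise defaults 1% reflectance
SD, 5% biomass CV, 1.5 LI percentage points.  Irradiance is a smooth
deterministic seasonal curve (17 + 7·sin term, MJ m⁻² d⁻¹).

Genotype latents are tied to RUE: a vegetative-vigour axis (from the two
vegetative RUE windows) sets LAI plateau, chlorophyll and canopy water; a
stay-green axis (from grain-filling RUE) sets the post-anthesis decline of
LAI, chlorophyll and water.  Daily LI is `100·(1 − exp(−0.5·LAI(t)))` with a
logistic LAI rise and a linear senescent decline after A7.  Biomass is
constructed as `BM(stage) = BM(prev) + RUE_true·ΔIPAR(window)` with the same
grain-filling weighting the analysis uses, so noise-free trials reproduce
the generating RUE to machine precision in every window — the construction
identity the recovery tests assert.  Measurement noise is multiplicative on
harvested biomass plus an additive replicate (block) effect, additive on LI
and on reflectance bands; all of it switches off exactly at zero.

The forward spectral model is a fixed smooth soil baseline mixed with a leaf
spectrum via Beer–Lambert cover `f = 1 − exp(−0.5·LAI)`; the leaf spectrum
has chlorophyll absorptions at 430/680 nm (saturating in chlorophyll), water
absorptions at 970/1240/1450/1940 nm, a red edge that retreats with
senescence, and visible brightening on yellowing.  It is **not** a
radiative-transfer model: it guarantees monotone, physically signed
trait–index links (deeper 970 nm absorption with more water, so WI rises and
the NDWI family falls; NDVI rises and saturates with chlorophyll; bare soil
has NDVI ≈ 0.18) and the cross-genotype correlation structure the prediction
models exploit — no hot-spot, BRDF, or multiple-scattering effects, no
measured soil library.  Passing tests therefore demonstrate that the
estimation machinery is correct and that the qualitative water-index /
stay-green prediction structure is attainable; they do not certify accuracy
on real canopies.

The packaged genotype-mean fixture (11 genotypes × 16 numeric columns of
phenology, IPAR, biomass and RUE) is a reference table for summary-statistic
checks.  Its RUE columns are multi-year adjusted means, so they are close to
— but not exactly — the ratios of its own biomass/IPAR columns; tests
compare column statistics, not per-genotype ratio identities.

## Pipeline

`build_predictor_table` evaluates all 27 indices on every (plot, layer,
period) spectrum and names columns `<INDEX><layer><period>`; scalar sensor
columns come from the trait table.  For each RUE window the grid compares
bcs / cVI / PLSR, each direct (RUE as the response) or via components
(biomass and IPAR endpoints predicted separately, RUE derived with the
window formula).  Linear families are fitted on Pearson-screened candidates
(P < 0.05, |r|-ranked, capped at 12 to keep the exhaustive search bounded);
PLSR uses the vegetative canopy matrix for vegetative windows and the
horizontally stacked vegetative + grain-filling matrices for GF/Total.
Evaluation is on a seeded 80/20 hold-out; `compare_all` writes a tidy CSV,
fitted model specs as JSON and a manifest (seed, input hash) so every row is
reproducible from its logged configuration.

Problem sizes in the shipped tests: trials of 33–66 plots, spectra of 2151
bands (1951 after trimming), 200-replicate recovery simulations — sizes at
which every stochastic guarantee is comfortably resolved while the whole
suite runs in under a minute.

## Known limitations

- The forward spectral model is phenomenological (see above); PLSR
  coefficients learned on synthetic spectra will not transfer to real
  instruments.
- LI interpolation is linear between three stage measurements; fast canopy
  dynamics (lodging, disease) are not representable.
- The grain-filling correction applies one fixed 50% weight over the final
  25% of days; the true senescence trajectory varies by genotype.
- Replicate-only adjustment (no year term) matches the intended single-trial
  analysis; multi-year tables are adjusted per year and pooled.
- Best-subset search is exhaustive and intentionally capped at 25
  candidates; it is a model-selection audit tool, not a sparse-regression
  replacement.
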