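# Methods

`phytosdm` reconstructs global monthly phytoplankton species richness and
species turnover from biased presence-only occurrence records via stacked
ensembles of species distribution models (SDMs), and analyses the resulting
maps against the metabolic theory of ecology.  Because no global occurrence
compilation ships with the package, a virtual-species simulator generates
worlds with known niches so every stage can be validated against ground
truth.  This note records the models, the parameter choices that matter, and
the places where the design was genuinely open.

## 1. The modelling pipeline

### Occurrence cleaning and binning

Records are removed, in a fixed order, when they are (1) flagged as fossil
or preserved specimens, (2) collected before 1800 or after 2015, (3) at
negative depth, (4) at nonsensible coordinates (|lat| > 90, longitude
outside [−360, 360], or non-numeric; retained longitudes are normalized to
[−180, 180)), or (5) below the monthly climatological mixed-layer depth
(MLD) at the record's cell.  Rows without a depth are kept when their
species has at least one retained record inside the mixed layer (the
mixed-layer-species assumption); otherwise they are counted under a separate
rule.  Each dropped row is attributed to exactly one first-failing rule, so
the filter report always sums to the input size.  The open-ocean mask then
removes records over bathymetry shallower than 200 m or surface salinity
below 20.  Cleaned records are binned to monthly 1° cells — half-open
`[lat, lat+1) × [lon, lon+1)` boxes, assignment by floor — and multiple
records of a species in the same monthly cell, regardless of year, count as
a single presence.  The below-MLD rule uses the record's exact month; an
annual-mean variant would be a sensitivity test, not the default.

### Target-group background sampling

Presence-only data carry the collectors' survey effort.  Pseudoabsences
("background") are therefore drawn from the pooled monthly 1° presence
cells of a broad target group, so the absences inherit the same spatial and
seasonal bias as the presences.  Group-specific pools exist for diatoms
(Bacillariophyceae), dinoflagellates and haptophytes; all other species
draw from the pool of all species excluding diatoms (whose sampling is
strongly north–south imbalanced); a "total" mode gives every species the
all-species pool.  The pool is stratified into 9 × 9 = 81 equal-width
temperature × MLD strata spanning the pool's own ranges (maximum edge
inclusive; a degenerate axis collapses to one bin with a warning).  Each
species receives ten background cells per presence; stratum quotas are
proportional to the number of monthly cells the pool provides per stratum,
rounded by largest-remainder apportionment so the total is conserved, and
cells are drawn uniformly without replacement within strata.  A species'
own presence cells are never drawn; quota deficits from exhausted strata are
redistributed proportionally to strata with spare cells, and if the whole
pool runs short the realized size is reported with a warning.

### Predictors

Raw monthly fields: temperature T, salinity S, NO3, PO4, Si(OH)4, MLD, PAR,
chlorophyll, wind stress, pCO2, plus static bathymetry.  Derived fields:
N* = NO3 − 16·PO4 (nitrate excess over Redfield), Si* = Si(OH)4/NO3
(undefined where NO3 = 0), mixed-layer-averaged light
MLPAR = PAR·(1 − e^(−kd·MLD))/(kd·MLD) with the chlorophyll-dependent
attenuation kd = 0.04 + 0.0088·Chl + 0.054·Chl^(2/3) m⁻¹, centred monthly
tendencies dX/dt = (X[m+1] − X[m−1])/2 with December–January wrap-around
(so the tendencies of any cell telescope to zero over the year), and log10
transforms of MLD, Chl and the nutrients (undefined for non-positive
values).  The default candidate list has 23 predictors.

Per species, every candidate is scored as a single-predictor classifier of
presence versus background: a weighted logistic regression with linear and
quadratic terms and a generalized additive model (GAM; penalized regression
splines, five basis dimensions) scored by adjusted
D² = 1 − ((n−1)/(n−p))·(1 − (D_null − D_res)/D_null), and a random forest
scored by out-of-bag skill (1 − OOB error).  Per-algorithm ranks (ties
averaged) are combined into a mean rank.

### Member models, evaluation, ensembles

Five member models per species each use a distinct set of four predictors,
drawn at random without replacement from the species' top-10 ranked
candidates subject to two constraints: no pair within a set with global
monthly Spearman |ρ| > 0.7, and no predictor in more than two of the five
sets.  When the constraints exhaust the top ten, lower-ranked candidates
are admitted; greedy draws that dead-end are retried with fresh
permutations, including whole-plan restarts, before the species is reported
as unsatisfiable.

Member algorithms (presence = 1, background = 0):

* **GLM** — weighted logistic regression with linear + quadratic terms and
  bidirectional AIC stepwise selection (from the null model, full
  linear+quadratic scope).  Background rows carry weight
  n_presences/n_background so both classes have equal total weight.
* **GAM** — `statsmodels` penalized regression splines, five basis
  dimensions per predictor, a mild fixed smoothing penalty (escalated
  automatically if the fit encounters complete separation), never shrunk to
  zero; same class weighting.  Projection clamps predictors to the training
  range (B-spline bases are undefined beyond it).
* **RF** — 4000 trees, terminal node size 1, per-tree balanced subsampling
  of background to presence counts (scikit-learn
  `class_weight="balanced_subsample"`).

Skill is the mean true skill statistic (TSS = sensitivity + specificity − 1)
over a repeated (4×) split-sample cross-validation: data are split into
four random parts, the member is refit — including its stepwise selection —
on three parts and predicts the fourth; the fold's binarization threshold
is the max-TSS threshold of the training predictions and the fold TSS is
evaluated on the held-out quarter.  Folds with a single class are redrawn.
Thresholds are searched over the unique predicted values (presence when
probability ≥ threshold); ties resolve to the lowest threshold via an exact
integer criterion.  Members with cross-validated TSS < 0.35 are discarded;
species with no surviving member are excluded and reported.  The deployed
threshold of a retained member is refit on the full calibration
predictions.  Retained members are projected onto the monthly climatology,
binarized at their thresholds, and averaged: the ensemble value of a
monthly cell is the fraction of retained members projecting presence, and
is undefined wherever any retained member's predictor is missing.

The hot path (stepwise AIC × 4 folds × 5 sets × hundreds of species) runs
on a small weighted-logistic IRLS core that reproduces
`statsmodels.GLM(Binomial, freq_weights)` coefficients, deviance and AIC to
1e-6 (pinned by a unit test); statsmodels and scikit-learn provide the GAM
and RF paths.

### Richness, turnover, Monte Carlo

Monthly richness per cell is the sum of ensemble values over species —
the expected number of species present — optionally weighted per taxon by
(known species)/(modeled species), normalized so weights average one, to
balance taxonomic coverage.  The annual mean averages the months with data;
cells covered in fewer than 12 months are flagged.  Turnover uses the
species-replacement component of Jaccard dissimilarity,
2·min(b,c)/(a + 2·min(b,c)), on communities thresholded at ensemble value
> 0.5 (strict), for the twelve consecutive month pairs including
December→January, averaged per cell over defined pairs (a wrap-free
11-pair variant is switchable).  Predictor-set uncertainty is quantified by
re-stacking with one of each species' five member projections drawn at
random per run (default 1000 runs, configurable); because member fits are
deterministic given their set, the five projections are fitted once and
cached, which is equivalent to refitting every run.

### Macroecology

The Boltzmann-axis analysis regresses ln(annual-mean richness) on inverse
thermal energy x = 1/(kT), k = 8.617×10⁻⁵ eV K⁻¹, T in kelvin, by ordinary
least squares — globally and within three thermal regimes split at annual
means of 11 °C and 19 °C (a grid-search for data-driven breakpoints is
provided for sensitivity).  Single-variable explanatory power for richness
is the R² of a linear+quadratic Gaussian fit on the untransformed richness,
comparable across predictors.  Rarefied raw-data richness draws equal
numbers of samples — unique (lat, lon, depth, year, month, day) events —
per stratum and counts pooled distinct species.  Species' observed
environmental ranges are the min/max/median of their records' monthly 1°
matchups; the expected-maximum-richness curve counts overlapping ranges at
each gradient value and the range-size curve averages (max − min) over the
covering species.  The null model shuffles species labels across records
(conserving per-species record counts and the pooled environmental
distribution), recomputes both curves per run (default 100), and flags
gradient values where the null 95% interval excludes the null curve's mean
level over the central 50% of the observed span — the regions where edge
effects distort observed ranges.

## 2. The virtual world

The simulator produces the statistical structure the pipeline assumes, not
ocean physics.  On an n_lat × n_lon grid of 1° cells with twelve monthly
fields: temperature falls from ~32 °C at the equator-analogue to −1.8 °C at
the poleward edge (the observed global span; values are clipped to the
configured bounds with a warning), with seasonal amplitude growing poleward
(default 3 °C at the edge, zero at the equator) and opposite hemispheric
phase.  Nutrients track monthly temperature inversely with small positive
floors mimicking analytical detection limits; MLD deepens and PAR dims in
cold water with additional winter/solstice phase terms; chlorophyll, wind,
pCO2 and salinity are noise-dominated with their own seasonal phases.  The
distinct phases matter: they keep the tendency fields and the
"filler" predictors mutually weakly correlated (|Spearman ρ| ≤ 0.7 for
many pairs), which is what makes five four-predictor sets per species
satisfiable — as in real climatologies, where the candidate suite is far
from collinear.  A smooth random land mask (5% of cells), random shallow
shelves (5%) and brackish patches (1%) exercise the masking rules.

Species have Gaussian suitability per predictor (product across predictors,
scaled by a maximum occurrence probability p_max); pools draw optima and
breadths from configurable uniform ranges.  The metabolic-theory pool gives
every species a fixed-width thermal range (default 10 °C, niche breadth =
width/4) whose midpoints are drawn with density ∝ exp(−E/kT) on the grid's
temperature span padded by half a range width.  The count of ranges
covering a temperature is then n·∫ density over T ± w/2, i.e. log-linear in
1/kT with slope −E up to a smoothing factor that is constant over the
ocean's span to ~0.3%; the continuous-limit regression slope of the
construction is −0.3193 for E = 0.32.  (A derivative-density construction
was considered and rejected: for two-sided ranges the overlap count is the
window integral of the midpoint density itself, so density ∝ exp(−E/kT)
is what yields ln S = c − E/kT.)  An optional flag adds broad secondary
responses in MLD and PAR centred on ambient conditions within the thermal
range; it is off by default because steeply temperature-coupled secondary
fields narrow effective cold-edge ranges and tilt the cold regime.

Sampling draws n visits — (month, cell) events, coordinates uniform within
the cell — proportional to an effort field in which a northern-basin
analogue (≈15% of ocean cells) holds 49% of total intensity, matching the
North Atlantic's share of historical records.  Each pool species is
recorded at a visit with probability equal to its suitability.  Records get
years ~N(1984, 17) clipped to 1950–2000, depths ~|N(5.4, 7)| m (15%
missing), and small configurable rates of fossil/preserved flags, bad years
and bad coordinates to exercise the cleaning rules.

What the simulator does **not** emulate: circulation and fronts, depth
structure of effort (a single surface layer is sampled), taxonomic noise
(synonymy, misidentification), abundance and detectability differences
among species, and interannual change.  Passing recovery tests therefore
demonstrates that the statistical machinery is unbiased under its own
assumptions — niches real, environment known, bias expressible through the
target group — not that those assumptions hold for any real compilation.

## 3. The recovery experiments and their sizes

The headline validation builds a 500-species metabolic pool at the
reference activation energy E = 0.32 eV on a 40 × 60 grid, samples 5000
biased visits (p_max = 0.2; roughly 10⁵ records and ~190 monthly-cell
presences per species), runs the full pipeline (total target group, 10:1
backgrounds, GLM-ranking, five GLM members per species with 4× CV and
TSS ≥ 0.35, max-TSS binarization, unit-weight stacking) and regresses
ln(annual-mean richness) on 1/kT over all cells.  Problem sizes are chosen
so one world fits in a few minutes on a single core; GLM members stand in
for the GAM standard here because richness maps are insensitive to the
member algorithm while GAM and RF are an order of magnitude slower — both
remain available and unit-tested.  The finite 500-species pool realizes
its generative slope with a standard deviation of ≈0.036 across worlds, so
recovered slopes are averaged over several independent seeds (five in
`scripts/acceptance.py`, three in the test suite); per-world recovered
slopes track the same world's true-range oracle to within ~0.01.  The
thermal-optimum recovery check uses 100 Gaussian species and asks the
ensemble response (mean ensemble value in 1 °C temperature bins) to peak
within 2 °C of the truth for ≥80% of species.

## 4. Numerical choices and degenerate inputs

* Boltzmann constant from `scipy.constants` (8.617333262×10⁻⁵ eV/K);
  temperatures converted with 273.15.
* IRLS: tiny ridge (1e-10) on the normal equations, step-halving on
  likelihood decreases, linear predictor clipped at ±35; stepwise caches
  subsets and warm-starts candidate fits.
* Max-TSS threshold comparisons use the integer score n0·tp + n1·tn, so
  ties are exact and resolve to the lowest threshold.
* Quota rounding: largest remainder, stable order for remainder ties.
* Degenerate cases: constant predictions return the constant with TSS 0 and
  a warning; a degenerate stratification axis collapses to one bin; empty
  communities on both sides of a month pair are excluded from the turnover
  mean; regimes with fewer than 3 cells are reported unfitted; species with
  zero retained members are excluded and counted.
* Background sampling without replacement (the unstated alternative,
  with replacement, was not implemented); month is retained on background
  keys so environmental matchups are monthly, like presences.
* The label-shuffling null model is the default reading of "randomized the
  species' presences"; resampling locations instead is config-switchable
  in spirit (shuffling preserves both marginals, which is the stricter
  null).

## 5. Known limitations

* With purely thermal virtual niches, members anchored on weakly
  temperature-coupled predictors project ranges wider than truth; the
  ensemble inherits a mild occupancy inflation (~10–30%) that is nearly
  flat in temperature and thus barely moves the Boltzmann slope, but
  absolute richness values are not calibrated.
* GAM smoothing uses a fixed mild penalty rather than data-driven smoothing
  selection; per-member smoothing optimization would be closer to mgcv but
  is far slower.
* The Monte Carlo over predictor sets treats member fits as deterministic
  (true for GLM/GAM; RF would need per-run reseeding to capture tree
  stochasticity).
* Cross-validation thresholds come from training folds; thresholds
  optimized on held-out folds would inflate shuffled-label TSS and were
  rejected.
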