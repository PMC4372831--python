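# Methods

`frugnet` analyses quantitative plant–frugivore seed-dispersal webs: it asks
how much of the pairwise interaction structure is explained by phenotypic
trait matching (fruit size vs gape width, fruit nutrient composition, species
identity) versus neutral abundance processes (population densities and
phenological co-occurrence), and whether a statistical model built from those
predictors can reproduce the web's aggregate network architecture.

## Data model

A community is a plants × birds system observed over a study period
(default 730 days). The quantitative web `F` has entries

    F_ij = (seeds of plant i recovered from faeces of bird j) / s_i,

where `s_i` is plant *i*'s mean seeds per fruit, so `F_ij` estimates
fruit-handling visits rather than raw seed counts. Unobserved pairs are
explicit zeros. Sampling completeness is checked with a link accumulation
curve: the cumulative number of distinct pairs after each netting session,
with an OLS slope over the last `tail_sessions` (default 10) sessions;
a slope well below ~0.03 links/session indicates saturation.

## Pairwise predictors

For every pair the table carries eight explanatory variables:

* **Size overlap** `S` (%): the fraction of the fruit diameter range
  (mean ± 1 SD, lower bound clamped at 0 mm) at or below the bird's maximum
  gape width. Pairs whose fruit is entirely too large get the placeholder
  `1e-5` so the column stays strictly positive; a zero-width fruit range is
  resolved as the SD → 0 limit (100 if swallowable, else the placeholder).
  Only the upper gape bound enters the rule; the lower bound is stored but
  unused.
* **Temporal overlap** `T` (%): days the two phenophases coincide, divided
  by the study length. Phenophases are explicit half-open day-interval sets,
  so the intersection is exact and invariant to splitting intervals.
* **Abundance product** `A`: plant share of the cumulative community fruit
  crop (as a proportion, 0–1) × bird density (individuals/m²). Bird density
  can be derived from mist-net capture rates via a linear calibration
  (default `density = 2.15 + 4.117 · (100 · capture rate)`), exposed as
  parameters because capture-effort units vary between studies. Any monotone
  rescaling of `A` only rescales its coefficient, never model ranking.
* **Nutrients** (% of fruit mass): fibre, proteins, lipids are assayed;
  sugars are estimated from the residual organic fraction,
  `NFES = 100 − RH − proteins − lipids − fibre` and
  `sugars = NFES·100/(100 − RH)`. The arithmetic is implemented exactly as
  printed on the reported percentages; whether those percentages are on a
  fresh- or dry-mass basis is the caller's responsibility, as assay reports
  differ.
* **Bird identity**: a categorical factor (treatment coding, alphabetically
  first species as reference — this affects coefficients, never
  likelihood or AIC).

The response is `y = ln(F + offset)` with offset 1.0 by default. The offset
handles zero cells; it is configurable and recorded in the table metadata,
because no universal convention exists and the back-transform
`F̂ = max(exp(ŷ) − offset, 0)` depends on it.

## Interaction model

Each candidate model is a Gaussian linear model with variance proportional
to a strictly positive covariate (default: size overlap):

    y_p = x_p'β + ε_p,   ε_p ~ N(0, σ² v_p).

Estimation is by maximum likelihood — weighted least squares with weights
`1/v_p` and `σ̂² = (Σ r_p²/v_p)/n` — and the reported log-likelihood is the
exact Gaussian one including the `Σ ln v_p` term, so models are comparable
on AIC. ML rather than REML is used deliberately: candidate models differ in
their fixed effects, for which REML likelihoods are not comparable. AIC
counts the variance scale as a parameter (`k = #coefficients + 1`); ties are
broken by fewer parameters, then name, making the ranking deterministic.
Akaike weights are `w_i = exp(−Δ_i/2)/Σ_j exp(−Δ_j/2)`.

Variable importance is the *averaged* weight sum: the summed weight of
models containing a variable divided by the number of such models. The
candidate set is deliberately unbalanced (variables appear in 3–14 of the
24 models, on natural-history grounds), so raw weight sums would conflate
support with representation.

The default 24-model set contains an intercept-only null, singles for every
variable, abundance-hypothesis combinations, bird-identity interactions with
the matching and abundance variables, and nutrient blocks — "non-energetic"
(fibre, proteins) and "highly energetic" (sugars, lipids) — alone, with bird
identity, with identity interactions, and with the abundance variables,
capped at five terms per model against overfitting on 36 pairs. The exact
composition is a reconstruction constrained by the published per-variable
membership counts (size overlap 3, temporal overlap 7, abundance 7, bird
identity 14, each nutrient 5) and by every model the source text names; the
count constraints force single-nutrient models and one asymmetric
fibre×identity variant. The set is fully overridable via a YAML list of
`{name, terms}` entries.

## Network metrics

All six aggregate parameters are computed from first principles on the
plants × birds matrix:

* **Connectance**: positive cells / all cells.
* **NODF** (binary, 0–100): for every ordered pair of rows (and columns)
  with strictly decreasing fill, the percentage of the emptier line's links
  shared with the fuller line; mean over all row and column pairs. Equal
  fills contribute zero, which makes the statistic order-invariant, so no
  resorting is needed. Binarisation threshold is `cell > 0`.
* **Weighted nestedness** (≈0 random … 1 maximally packed): the matrix is
  packed by descending marginal totals and scored by the interaction-weighted
  mean Euclidean distance of filled cells from the generalist–generalist
  corner. The score is normalised between (a) the Monte-Carlo mean over
  seeded random webs with the same dimensions and fill — each replicate is
  packed before scoring, exactly like the observed web, otherwise random webs
  would not centre on zero — and (b) the maximal arrangement of the same
  weights (largest weights in the nearest cells). Default 1000 replicates;
  bit-reproducible for a fixed seed.
* **Interaction evenness** (0–1): Shannon entropy of cell proportions over
  the positive cells divided by `ln(cells)` (default) or `ln(links)`; both
  denominators are in use in the literature, so the convention is explicit
  config.
* **Interaction asymmetry** per guild (−1…1): from the mutual dependences
  `d_ij = F_ij/row_i` (plant on bird) and `d'_ji = F_ij/col_j` (bird on
  plant), each realized link contributes `(d_ij − d'_ji)/max(d_ij, d'_ji)`;
  links are averaged within species (sign flipped for the bird perspective)
  and species averaged within the guild. Species without links are excluded
  with a warning.

## Probability-matrix null model

The best model's predicted web is normalised by its grand total into a cell
probability matrix. Each randomization is a single multinomial draw of
`n_interactions` events (default: the observed web's rounded total) over the
cells; each draw's six metrics are summarised by their mean and percentile
2.5/97.5 interval over `n_replicates` draws (default 1000), and the observed
metric is flagged as inside or outside that interval. Draws producing
degenerate webs for a given metric (e.g. an all-zero or single-line matrix)
are skipped and counted; more than 10 % failures for any metric aborts the
run. Optionally draws can be constrained so every species keeps at least one
event (bounded redraws); the default is unconstrained.

## Synthetic communities

The generator emulates the study conditions the analysis assumes: 9 plants ×
4 birds over 730 days and 54 netting sessions; log-normal fruit diameters
(a few mm to ~1.5 cm) with per-species SD 10–30 % of the mean; proximate
compositions sampled uniformly within feasibility (RH 55–85 %, proteins
1–8 %, lipids 0.5–10 %, fibre 4–20 %, NFES ≥ 0); seasonal fruiting windows
(90–330 days) and resident or wintering birds; Dirichlet fruit-crop shares;
bird densities from capture rates 0–0.02 through the calibration. These are
caricature laws chosen once as plausible for a small Mediterranean-scrub
community — configuration, not claims about any real site.

Interaction records are generated from the fitted model class itself:
`y = x'β_true + ε`, `ε ~ N(0, σ² v)` with `v` = size overlap
(`σ² = 0.004`), `F = max(exp(y) − 1, 0)`, seed counts Poisson(`F·s_i`)
split multinomially across sessions. `β_true` defaults to intercept −1.0,
size 0.022 per %, temporal 0.010 per %, abundance 0.25 per unit, and bird
offsets of a few tenths — scaled so matched, co-occurring, abundant pairs
reach tens of visits while mismatched pairs stay near zero, giving webs with
connectance strictly between 0 and 1.

Two deliberate departures from a literal reading of the model are built into
the default trait laws:

* Every pair keeps a strictly positive size overlap (gapes are anchored just
  above the largest fruit's lower diameter bound). A placeholder (`1e-5`)
  pair would carry an assumed residual variance of `σ²·1e-5 ≈ 4e-9`; the
  Poisson discretisation of seed counts injects noise many orders of
  magnitude larger at such rows, which would dominate every candidate's
  likelihood and make AIC comparisons meaningless. The placeholder path is
  fully implemented for real data; the generator simply does not manufacture
  data that contradict its own variance law.
* The clamp `F = max(exp(y) − 1, 0)` plus Poisson rounding makes the
  realised response a mildly censored version of the Gaussian one. In
  consequence, estimator-calibration checks (Wald-interval coverage) are run
  by redrawing Gaussian responses from the model on a fixed community —
  the model the estimator actually assumes — while full-pipeline checks
  assert model selection (the generating specification wins the AIC ranking
  in a majority of replicates) and 3-SE coefficient recovery. Coverage
  measured through the clamped pipeline sits a few points below nominal,
  concentrated in the intercept and size slope; this mirrors what
  zero-inflated field data would do to the same model and is a known
  limitation, not a target.

What passing tests do **not** show about real data: the generator draws
traits independently across species (no phylogenetic signal), phenology as
single blocks (no within-season fruit dynamics), and observation as
homogeneous Poisson sampling (no observer effort or capture bias). Field
webs violate all three.

## Numerical and reproducibility choices

* All randomness flows through `numpy.random.Generator`; every public
  stochastic operation takes a seed or generator, and the CLI derives
  per-stage seeds from the run seed via `SeedSequence`. Identical seeds give
  bit-identical outputs, including the observed-vs-simulated report.
* Rank-deficient designs raise an error naming the collinear columns
  (detected via SVD) rather than silently pseudo-inverting.
* The weighted-nestedness normalisation denominator can vanish (e.g. a full
  uniform matrix); the estimator then returns NaN with a warning, and the
  null-model loop counts it as a metric failure.
* Percentile confidence intervals use linear interpolation (numpy default);
  with 1000 replicates the 2.5/97.5 percentiles are stable to well under the
  Monte-Carlo noise of the metrics themselves.

## A note on the bundled observed-web fixture

`frugnet.fixtures` ships a small 9 × 4 web labelled *synthetic*: it is a
constructed stand-in, searched and calibrated so that the package's metric
conventions reproduce a reference set of observed aggregate statistics for a
community of this shape (connectance 28/36, cells-denominator evenness,
species-then-guild asymmetry averaging). It pins conventions in regression
tests; it is not field data and supports no ecological conclusions.
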