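# Methods

`paleodiv` analyses family-level taxon ranges — tables of first and last
occurrences binned to geological stages — the data structure behind classic
compendium-style palaeodiversity studies of groups such as fossil hexapods.
This note records the models, conventions and numerical choices behind each
component, what the synthetic data do and do not emulate, and the known
limitations.

## Time model

The canonical time axis is the ordinal index of stage-rank intervals,
increasing toward the present; ages in Ma are metadata used for durations,
midpoints and plotting. Stages must tile time exactly (each stage's top age
equals the next stage's base age, to 1e-6 Ma); epochs, periods and eras must
resolve to contiguous stage runs via the parent chain. A terminal **Recent**
pseudo-stage (0.0117–0 Ma, recognized by name) closes the scale so that
extant taxa become ordinary boundary-crossers ranging "to the present";
rate estimation excludes it by default because its duration is geologically
negligible and every extant taxon terminates there by construction.

The packaged table (`data/gts2008_stages.csv`) transcribes the 2008-era ICS
chart, Lochkovian → Recent (the span with a continental arthropod record).
Exact stage boundaries have shifted in later charts; the packaged ages are a
configurable assumption — any CSV with the same schema
(`name,rank,base_age,top_age,parent`) can be substituted, and all derived
quantities (Δt, midpoints, window selections) follow the active table.
Spot values on the packaged table: Serpukhovian midpoint 323.2 Ma,
Piacenzian 3.094 Ma, Kungurian 273.1 Ma, Carnian 222.6 Ma.

## Range semantics and coarse-resolution assumptions

A range is the closed interval of stage indices `[first, last]`; a taxon is
"present" at every stage of the span (range-through semantics). Extant
records always terminate at the Recent pseudo-stage. Taxon names are
normalized (trim, collapse whitespace, casefold) for joins; no fuzzy
matching, since that could silently merge distinct families.

Records resolved only to epoch/period level are mapped to stages under:

* **maximum** — origination in the oldest stage of the first interval,
  extinction in the youngest stage of the last interval;
* **minimum** — the converse narrow reading; a coarse record confined to a
  single interval is *removed* (it has no defensible stage span), with the
  removal count logged;
* **literal** — endpoints must already be stages (error otherwise).

Span nesting (minimum ⊆ literal ⊆ maximum) is enforced by construction and
property-tested.

## Richness series

With per-stage classes FL (single-interval), bL (enters and ends), Ft
(starts and leaves), bt (ranges through):

* `RT = bt + Ft + bL + FL` — taxa observed or inferred present;
* `BC_bottom = bt + bL`, `BC_top = bt + Ft` — faunal cohorts at boundary
  instants, excluding single-interval taxa and hence immune to bin-length
  variation; the per-stage convenience series is the geometric mean
  `sqrt(BC_bottom · BC_top)`, defined as 0 when either boundary count is 0
  (the continuous limit; keeps series plottable);
* `MIN = Ft + FL + bL` — documented events only, no interpolation; a
  truncated stand-in for sampled-in-bin counts, which first/last-occurrence
  data cannot support.

Both boundary-indexed and per-stage BC series are exposed rather than
guessing a single plotting convention for series ends.

## Per-capita turnover rates

Foote's estimators, per stage *i* with duration Δt (Myr):

    p̂ = −ln(N_bt / N_t) / Δt      q̂ = −ln(N_bt / N_b) / Δt

with `N_b = bt + bL`, `N_t = bt + Ft`, `N_bt = bt`. They disregard
single-interval taxa (invariance is tested) and are robust to interval
length. Stages with `N_bt = 0` or an empty denominator count get explicit
missing values with reason codes — never 0 or ∞ — so downstream
correlations drop rather than absorb them. The first and last real stages
are flagged `edge`: their boundary counts touch the limits of the data's
extent. A `unit_durations` flag gives rates per stage for method
comparison.

**Known bias.** Both estimators are consistent but finite-sample biased:
`−ln(x)` is convex, so for `N_bt | N_b ~ Binomial(N_b, e^{−qΔt})` the
extinction estimator carries an upward Jensen bias of roughly
`(1 − s)/(2 N s Δt)` with `s = e^{−qΔt}` — about +1.4e-4 /Myr (0.3%
relative) at N ≈ 200, q = 0.05/Myr, Δt = 5 Myr, confirmed here by
simulation (+1.9e-4 ± 0.4e-4 over 2000 replicates). The origination
estimator's corresponding terms largely cancel (measured bias consistent
with zero). Consequence: a recovery test that compares the Monte-Carlo
mean of q̂ against the truth at ±2 standard errors becomes marginal once
enough replicates are averaged; the recovery test in the acceptance suite
is kept at exactly its stated conditions and its outcome documents this
estimator property rather than an implementation defect.

## Compendium revision diffing

Families in the union of two dataset versions are categorized exhaustively:
`no_change`, `new_in_list`, `contraction` (fewer stages), `extension` (more
stages — non-overlapping replacements included, matching how wholesale
redatings are scored), `shift` (same count, different set), `removed`
(absent from the new list: synonymized, subsumed, or no longer with a
fossil record; an explicit synonymy mapping can redirect old names).
Proportions are reported over taxa present in the new dataset, with
`removed` tallied separately.

Old datasets with coarse records use the `confirm` policy: `no_change`
when the new stage set equals the maximal reading of the old coarse span
(the new data confirm presence throughout), else an unsubtyped
`range_change` — stage-level sub-typing against an epoch-level record is
not meaningful. How a mixed-resolution predecessor "should" be sub-typed
is genuinely open; the unsubtyped category keeps the tally exhaustive.

## Correlation protocol

Richness and rate series are trended and autocorrelated, so parametric
p-values are invalid. The protocol: optional detrending (first differences,
or generalized differencing = first differences of OLS residuals against
time), Spearman rank correlation (mid-ranks), and a BCa bootstrap
(default 9999 replicates, 95%/99% intervals; significance = interval
excludes zero). Resampling is of (x, y) pairs — the standard choice for a
correlation; block bootstrapping for serial dependence is out of scope, and
bootstrap intervals on time series should be read with that caveat.

Implementation details: z₀ from the share of replicates below the observed
statistic (clamped to (0,1) open interval); acceleration from jackknife
skewness; replicates with undefined statistics (zero rank variance) are
dropped and counted, with a warning above 5%; an all-identical replicate
distribution yields the degenerate point interval. Generalized differencing
regresses on stage midpoint age (negated Ma, so time increases) by default;
ordinal stage index is the exposed alternative — identical on uniform
stages. The default analysis window is Serpukhovian → Piacenzian, the span
with a usable hexapod-type record; windows are inclusive stage runs.
Spearman values within a few ulp of ±1 are snapped to exact ±1 so that
degenerate bootstrap distributions collapse cleanly.

## Synthetic data

`simulate_ranges` is a stage-wise branching process: a lineage alive at a
stage's bottom boundary survives to the top with probability `e^{−qΔt}`;
originations are Poisson with mean `N_b (e^{(p−q)Δt} − e^{−qΔt})`, making
the expected top-boundary count `N_b e^{(p−q)Δt}` — i.e. the generator's
`p` and `q` are exactly the per-capita rates the estimators target.
Originations are placed at stage granularity only (all downstream counting
is bin-wise). Lineages alive at the end are marked extant (or killed, for
closed-history tests). The founding cohort first-occurs in stage 0, so the
ground-truth ledger records `N_b = N_bt = 0` there, matching what range
data can ever show. Ledger boundary counts equal the richness module's
recomputed counts exactly under perfect preservation (tested end-to-end).

`apply_preservation` thins each lineage to its sampled stages (per-stage
probability `r`), truncating ranges inward the way incomplete sampling
drags last occurrences backward in time; never-sampled lineages are
dropped and counted; extant lineages keep the Recent endpoint but still
need one sampled stage to have a fossil record. The gap between true and
observed last occurrence is geometric with mean `(1−r)/r` stages (tested).
`coarsen` degrades an exact fraction of records to epoch endpoints.
`perturb_dataset` manufactures revision pairs realizing exact category
counts (largest-remainder apportionment; feasibility-aware assignment with
re-draws) for round-trip testing of the diff machinery.

The study scripts use one fixed configuration (`analysis/study.py`): 5
founding lineages at the base of the Devonian, p = 0.030/Myr,
q = 0.017/Myr (net growth chosen to reach order-10³ extant families, the
order of magnitude of a modern family-level compendium), preservation 0.7
per stage, 15% of records coarsened, and group tags drawn with fixed
proportions. Problem sizes elsewhere (20 uniform 5-Myr stages, n0 = 200,
200 replicates for rate recovery; ≤100-taxon datasets for oracle checks)
are the package's standard test conditions.

**What the generator does not emulate:** Lagerstätten-driven sampling
spikes, secular preservation trends, the Pull of the Recent beyond the
extant-endpoint convention, taxonomic oversplitting/lumping dynamics,
within-lineage phylogeny, or occurrence-level data. Passing tests
demonstrate the counting, estimation and comparison machinery is correct
under the stated sampling model — not that any biological inference from a
real compendium is unbiased.

## Numerical conventions

* Counts are exact integers; identities (RT = FL+bL+Ft+bt = MIN+bt,
  BC_top(i) = BC_bottom(i+1)) are asserted without tolerance.
* Stage-boundary meeting uses 1e-6 Ma absolute tolerance.
* Missing rates/correlation inputs are NaN with reason codes; aligned
  series drop NaN rows and log the count.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  configs and outputs; fixed seeds give bit-identical results.

## Limitations

* No occurrence/collection-level model; ranges only.
* No sample standardization, three-timer/gap-filler rates, or
  Pull-of-the-Recent correction — deliberately out of scope.
* The revision differ trusts names (plus an optional synonymy map); it
  does not detect synonymy.
* Bootstrap intervals assume exchangeable pairs; serial dependence in real
  richness series means they understate uncertainty.
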