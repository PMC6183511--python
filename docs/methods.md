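# Methods

## The counting model

`raricount` models the census of a population partitioned into S categories
("taxa") with relative abundances p₁ ≥ p₂ ≥ … ≥ p_S, Σp_i = 1, observed by
scanning specimens one at a time. Specimens are treated as i.i.d. draws from
the multinomial defined by p — no spatial clustering, patchiness or
detection-probability structure is modelled (those are explicit non-goals).
Observational effort is measured in *tracks*: one track = a fixed number of
specimens scanned. The per-track specimen rate is configurable
(`specimens_per_track`, default 100 in the simulator and the CLI); the value
is arbitrary — effort only ever enters the estimator through the *ratio*
T_rare/T_full, so any constant rate gives identical estimates.

### Two-phase counting and the combination estimator

Phase 1 ("full") records every specimen. At the switch point the taxa whose
full-phase share n_i/N_full exceeds a threshold τ are frozen into an
exclusion set E; phase 2 ("rare") records only taxa ∉ E while effort keeps
accruing. The combined count estimate is

- excluded i ∈ E: n̂_i = n_i · (1 + T_rare/T_full) — a per-track rate
  extrapolation of the full-phase count over the rare-phase effort;
- retained j ∉ E: n̂_j = n_full_j + n_rare_j (raw totals);
- proportions p̂ = n̂ / Σ n̂.

The per-track (rather than per-specimen) rate is the simplest estimator
consistent with tracks being a linear measure of effort; raw counts are
always stored separately from the (possibly fractional) estimates so the
combination is recomputable and an alternative rate model could be swapped
in. The estimator is a ratio of multinomial quantities, so it carries an
O(1/N) finite-sample bias; in the simulation suite (full count 2,000,
T_rare = 2·T_full, τ = 5%) the mean absolute relative bias of dominant-taxon
proportions measures well under 1%.

### Choosing the threshold

The guidance encoded in `relative_error`/`error_landscape` is the binomial
rule: a proportion p counted among N specimens has relative standard error
ε = z·√(p(1−p)/N)/p. z defaults to 1 (a standard error); at p = 5%,
N = 2,000, ε ≈ 9.7% — an abundance band of roughly 4.5–5.5% — which is the
classical justification for stopping the full count at 1,000–2,000 specimens
and skipping taxa above ~5%. The z convention (one σ vs a wider band) is
deliberately exposed as a parameter rather than fixed. `threshold_summary`
evaluates a candidate τ against a whole dataset: the fraction of samples
with at least one excludable species (τ is only workable where this is 1),
the fraction of species ever crossing τ, and the distribution of the
specimen fraction eliminated.

## Diversity feedback

The collector's curve is the exact running count of distinct taxa per
specimen. Expected richness under subsampling uses the hypergeometric
closed form E[S_n] = Σ_i [1 − C(N−N_i, n)/C(N, n)] with log-space binomial
coefficients (stable to N ~ 10⁵), and a Monte-Carlo route (subsampling
without replacement) kept separate as a cross-check; the suite verifies
3-standard-error agreement between the two on random count vectors.

The asymptote fit uses the hyperbolic saturation form S(n) = S_max·n/(b+n)
— S_max the richness at infinite sampling, b the half-saturation count —
fitted by bounded nonlinear least squares (`scipy.optimize.least_squares`)
with analytic start values S_max⁰ = 2·max S and b⁰ = the n at which S first
reaches half its maximum. A fit is reported `converged=False` when the
optimizer fails or when the solution runs far beyond the data
(S_max > 20·max S or b > 100·max n), which is how a curvature-free
(e.g. strictly linear) curve is flagged as having an unidentifiable
asymptote. A constant curve S ≡ k > 1 is the exact limit (S_max = k, b = 0)
and is returned directly.

### Improvement attributable to rare-mode counting

`improvement_percent` answers: *how many more species did the two-phase
session observe than a single-phase count of the same total size would
have?* The counterfactual assemblage is the reconstructed one — combined
estimates rounded to the nearest integer count (taxa rounding to 0 drop
out) — rarefied down to the number of specimens actually recorded, by Monte
Carlo with a caller-supplied replicate count (default 1,000) and seed. The
return value is 100·(S_obs − S_norare)/S_norare, and 0 by definition when no
rare phase or no exclusions exist. Rounding before subsampling is required
because rarefaction operates on integer specimen pools; its effect is
negligible at the count sizes involved.

## The counting engine

Sessions are event-sourced: state is a pure function of the initial taxa
list plus the ordered action log (count, track, rare-switch, add-taxon),
and replaying a log byte-reproduces the session — this is also the basis of
checkpoint/resume, which serializes the log as versioned JSON (an internal
format, deliberately distinct from SOD). Undo treats counts and track
increments as one linear history and inverts the most recent one; the
rare-mode switch and taxon additions are barriers (undo refuses rather than
un-freezing the exclusion set — whether one *should* be able to un-enter
rare mode is ambiguous, and refusing is the conservative reading). The
exclusion set is fixed exactly once per session; counting an excluded taxon
is a hard error, mirroring a disabled button, rather than a silent skip.

## SOD files

The Stratigraphic Occurrence Data format is described in the `raricount.sod`
module docstring: four blocks (file metadata / per-sample metadata /
per-taxon metadata / counts), every value cell adjacent to a label cell,
version and file type in the leading metadata fields. Design choices made
here: physical encoding is UTF-8 tab-delimited text (spreadsheet-openable);
per-phase track counts, the exclusion threshold and per-taxon exclusion
flags are stored in metadata while block D keeps raw integer totals, so the
effort-scaled estimates are recomputable from the file alone
(`estimates_from_sod`, exercised to 1e-9 agreement in the suite); error
coordinates are 1-based row/column in spreadsheet convention. The v1 field
definitions for the O and L dialects ship as an editable data table
(`data/sod_fields_v1.tsv`) — a reconstruction written for this package, with
field sets chosen to cover deep-sea-drilling (Site-Hole-Core-Section-
Interval) and land-section (region/section/formation/lithology/level)
sample naming; new types or versions are added by editing the table (or
pointing `load_definitions` at a replacement), not by changing code.

## The synthetic-assemblage generator

The generator exists so that every part of the pipeline is testable against
known truth. Abundance families: geometric (p_i ∝ kⁱ), log-series
(p_i ∝ xⁱ/i; alpha is validated but cancels under normalization), lognormal
(deterministic quantile spacing exp(σ·Φ⁻¹((i−½)/S)), so no RNG is consumed),
uniform, and explicit weights. The composite `uneven_assemblage` (defaults:
6 dominants jointly holding 75% over 200 rarities, geometric within each
block) reproduces the regime where rare-mode counting pays off — a few
percent of species above a 5% cut-off, and a majority of specimens
eliminable. `synthetic_survey` draws a heterogeneous collection of such
samples (2–8 dominants at 45–80% cumulative share, 150–250 rarities, counts
lognormal around a median of ~4,000) as a stand-in for a real multi-sample
census.

What the simulator does *not* emulate: within-slide spatial structure,
observer identification error, taxon-specific detectability, and temporal /
stratigraphic autocorrelation between samples. Passing tests therefore
demonstrate the correctness of the estimators under the i.i.d. sampling
model, not robustness to those field realities.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run simulations at desk scale
chosen to keep the whole pipeline fast while leaving Monte-Carlo error well
inside the asserted tolerances: 200 seeds × (2,000 full + 4,000 rare-phase
scans) for estimator bias, 15 seeds × three full-count sizes × 200
rarefaction replicates for the improvement trend, 107 samples for the survey
summaries, 50 random vectors × 500 replicates for the rarefaction
cross-check, 100 seeds for the noisy-fit recovery. Every random stream
derives from an explicit integer seed (`numpy.random.default_rng`; no global
state), so all reported numbers are exactly reproducible.
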