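# Methods

`reefsync` implements the statistical core of an among-habitat
synchrony/stability analysis of coral reef communities: how differently
the coral assemblages of neighbouring reef habitats (a fringing reef, a
back reef, and two fore-reef depths) change through time, and whether
that asynchrony is associated with stability of the pooled, reef-wide
community. Because quadrat-level survey data of this kind are rarely
redistributable, the package pairs the statistics with a seeded
simulator of the whole observational design, so every stage is testable
end to end.

## Community synchrony and variability

Let `x_i(t)` be the mean percent cover of community element `i` in survey
year `t`, and `x_T = Σ_i x_i` the total cover. The two community-level
statistics are

    phi = Var(x_T) / (Σ_i sd(x_i))²          (community-wide synchrony)
    CV  = sd(x_T) / mean(x_T)                (temporal variability)

`phi` is 1 when all elements rise and fall in proportion and 0 when
fluctuations cancel exactly (perfect compensation); `CV` is an inverse
proxy for stability. Temporal variances use the sample (n−1) convention
throughout; the choice cancels in `phi` but not in `CV`.

*Elements.* The default element is a taxon-by-habitat series: each
taxon's trajectory in each habitat enters separately, so compensation
between habitats (one habitat's loss offset by another's gain in the same
taxon) registers as asynchrony. A `pooled` mode (taxon summed over
habitats) is provided for reef-wide dynamics. Both are exposed because
the element definition is a genuine modelling choice, not something the
statistics dictate.

*Windows.* Metrics are evaluated in sliding windows of consecutive
surveys, default length 2, so 14 annual surveys yield 13 windows
(e.g. 2006–2007 … 2018–2019) — enough resolution to see synchrony change
around discrete disturbances. For a 2-point window `phi` reduces to the
closed form `(Σ_i d_i)² / (Σ_i |d_i|)²` with `d_i` the between-year
change of element i; the implementation is tested against this form and
against a brute-force transcription of the general formula. Windows with
missing habitat-year cells, or on which a statistic is undefined (all
series constant for `phi`, zero mean total for `CV`), are carried as
flagged rows and excluded pairwise only at the regression stage, with the
exclusion count reported.

## Multivariate community structure

Quadrat-level cover matrices are compared with **zero-adjusted
Bray–Curtis** dissimilarity: a constant dummy taxon (value 1) is appended
to every sample before `d(j,k) = Σ|x_j − x_k| / Σ(x_j + x_k)`, so two
quadrats that have both lost all coral are identical (d = 0) rather than
undefined — the standard treatment for zero-inflated cover data.

**NMDS** minimises Kruskal stress-1 over a 2-d configuration. Each
iteration fits disparities to configuration distances by isotonic
regression on dissimilarity order (primary tie treatment: ties are
ordered by current configuration distance) and updates the configuration
with a Guttman majorization step; a step-halving line search guarantees
the recorded stress is non-increasing within a start. Starts are one
metric-scaling (Torgerson) configuration plus seeded random starts, up to
20, stopping early when the best stress falls below 0.02; the per-start
cap is 300 iterations with convergence at a stress change below 1e-6.

**PERMANOVA** partitions the Gower-centred distance matrix into
sequential (Type I) sums of squares in the order habitat, year,
habitat×year — equal to marginal SS for balanced designs, which the
simulated survey is. Year is treated as categorical with all levels.
Pseudo-F uses the residual mean square; p-values come from unrestricted
permutation of sample rows, `p = (1 + #{F* ≥ F}) / (1 + n_perm)`, with
999 permutations by default. Restricted/residual permutation schemes for
the interaction are deliberately out of scope: with thousands of quadrats
and large effects the choice is immaterial here, and the unrestricted
scheme is exact under the global null (verified by a type-I error
simulation in the tests). Analyses run at quadrat level (thousands of
samples), not on habitat means.

## Physical covariates

Temperature loggers (nominal 20-minute cadence) reduce to daily mean,
Tmax, Tmin and the diurnal temperature range DTR = Tmax − Tmin. Days are
calendar days in local standard time (no DST in French Polynesia). A day
needs ≥ 80% of its expected records to count; readings outside
20–35 °C are dropped and counted. Gaps in a primary logger may be filled
from a donor logger at the same depth only after a concordance check on
their overlap (mean and sd difference reported; filling is refused above
a 0.1 °C mean offset by default).

Wave records convert to energy flux `P = ρ g² H_sig² T_w / (64π)` with
ρ = 1028 kg m⁻³ and g = 9.8 m s⁻², reported in kW m⁻¹. Seasonal
aggregation uses a configurable month-day window that may span the year
boundary, labelled by start year; the default window is 1 September –
31 January (spawning plus pelagic larval duration), with the shorter
September–December variant available, and both `sum` and `mean` modes are
exposed (default `mean`). Seasons below a 50% record-coverage threshold
are flagged not-estimated rather than reported.

Between-habitat synchrony of annual mean temperature and of annual mean
DTR is computed with the same `phi` statistic applied to habitat pairs.

## Major-axis regression

The association between per-window `CV` and `phi` is fitted with model II
major-axis regression — both variables are random, dimensionless and on
comparable scales, so minimising perpendicular distances is appropriate.
The slope is the leading eigenvector of the 2×2 covariance matrix,

    b = (s_yy − s_xx + sqrt((s_yy − s_xx)² + 4 s_xy²)) / (2 s_xy),

the line passes through the centroid, and significance is the two-sided
Pearson t-test, `t = r sqrt(df/(1−r²))`, df = n−2. Degenerate clouds
(zero variance, or a circular cloud with `s_xy = 0` and `s_xx = s_yy`)
are errors rather than silent output; the pipeline downgrades them to a
flagged missing fit.

## The simulator

The generator emulates the four-habitat survey design the statistics were
built for, with annual surveys 2006–2019:

- **Cover.** Each taxon×habitat series has a baseline mean cover (%) and
  a geometric per-year trend; disturbance events multiply the expectation
  by a survival fraction, per elapsed year for a press (a multi-year
  corallivore outbreak) or once for a pulse (a cyclone), composing
  multiplicatively and applied before noise. Quadrat draws are
  logit-normal around the expectation with a configurable logit-scale sd
  (default 0.35), with the location mean-corrected by Gauss–Hermite
  quadrature so that habitat means recover the configured expectation
  exactly — the surveyed literature reports no quadrat-level
  distribution, so the overdispersion level is a documented free
  parameter. The back reef nests 20 quadrats in each of 5 bommies with a
  bommie-level logit-scale random effect (sd 0.15); standard errors there
  are computed over the 5 bommie means. Expectations summing above 100%
  of the substratum are a configuration error naming the habitat/year;
  the rare quadrat whose independent taxon draws total above 100% is
  rescaled down proportionally.
- **Preset.** The Moorea-style preset starts the four habitats at
  30–46% cover. The lagoon habitats (Porites-dominated) decline
  monotonically to a few percent; the fore-reef habitats crash under a
  2007–2009 press (survival 0.38/yr) followed by a 2010 pulse (survival
  0.12) to ~1% cover, then recover — led by a fast-growing Pocillopora —
  to ~80% (10 m) and ~33% (17 m) by 2019. This makes the crash years
  synchronous across habitats and the recovery years compensatory, the
  pattern the synchrony statistics are designed to detect.
- **Temperature.** Per habitat: annual mean + seasonal sinusoid (maximum
  in early March, the southern-hemisphere convention) + diurnal sinusoid
  + AR(1) noise (stationary sd), at a 20-minute cadence. Diurnal
  amplitudes in the preset are 0.535 °C (fringing) down to 0.13 °C (deep
  fore reef), i.e. noise-free daily ranges of 1.07 to 0.26 °C. A yearly
  regional anomaly (sd 0.15 °C) is shared across habitats, reproducing
  the observed ordering that annual-mean temperature is nearly perfectly
  synchronous between habitats while DTR is only moderately so.
- **Waves.** H_sig sits at a base value except during storm episodes;
  storm counts per September–December season are Poisson (mean 0.9
  /season, so storm seasons recur at one-to-several-year intervals), each
  storm multiplying H_sig by 2.5 for 72 h. Optional date-range gaps in
  either instrument series emulate logger outages and exercise the
  not-estimated flags downstream.

All randomness flows from a single integer seed (split per stream), and
identical configurations produce byte-identical outputs.

### What the simulator does and does not capture

It reproduces the study design (habitat/taxon structure, quadrat and
bommie replication, disturbance timing, cadence and gap structure of the
instruments) and first- and second-moment behaviour of cover. It does not
simulate larval dispersal, hydrodynamics, spatial structure within
habitats, taxon interactions, or observation error in image annotation.
Passing tests therefore demonstrate that the statistics behave correctly
and that the qualitative synchrony-stability association emerges under
the intended disturbance regime — not that any particular field estimate
is reproduced.

## Numerical choices and problem sizes

- `phi` is clipped into [0, 1] against rounding at the Cauchy–Schwarz
  boundary; undefined statistics are NaN plus a flag, never exceptions in
  batch paths.
- PERMANOVA permutes an orthonormalised design basis (QR of the nested
  model matrices) against the fixed centred Gower matrix, so each
  permutation costs one symmetric matmul; the full quadrat-level run
  (3,080 samples, 999 permutations) takes well under a minute.
- The acceptance checks run the pattern-recovery experiment at 200
  simulator replicates, the PERMANOVA type-I simulation at 200 null
  datasets × 199 permutations, and the phi/CV oracle battery at 1,000
  random matrices.

## Known limitations

- Only the one synchrony index and the major-axis variant of model II
  regression are implemented (no ranged or standardized major axis).
- The interaction permutation scheme is unrestricted only.
- Seasonal flux coverage is judged against the series' median cadence,
  which misjudges expected counts for irregularly sampled instruments.
- Simulated storms have fixed duration and multiplier; real storm
  spectra co-vary H_sig and T_w.
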