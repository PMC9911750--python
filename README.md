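# reefsync

Statistics for asking whether neighbouring coral reef habitats change in
the same way at the same time — and whether habitats changing
*differently* (asynchrony) stabilises the reef-wide community. The
package is aimed at community ecologists working with repeated
percent-cover surveys (annual photoquadrats across a fringing reef, back
reef, and fore-reef depths) plus the physical context from in-situ
instruments (temperature loggers, a wave meter).

## What it computes

For element series `x_i(t)` (taxon-by-habitat mean cover) and total
`x_T = Σ_i x_i`:

- **Community synchrony** `phi = Var(x_T) / (Σ_i sd(x_i))²` — 1 when all
  elements fluctuate in proportion, 0 under perfect compensation.
- **Community variability** `CV = sd(x_T) / mean(x_T)` — the temporal
  coefficient of variation of total cover, an inverse proxy for
  stability.

Both are evaluated in sliding windows of consecutive annual surveys
(default 2), and their association is tested with **model II major-axis
regression** (slope = leading eigenvector of the covariance matrix;
Pearson t-test for significance). Around this core the package provides
zero-adjusted **Bray–Curtis** dissimilarities, **NMDS** ordination
(Kruskal stress-1, monotone regression, multiple restarts), two-factor
**PERMANOVA** (habitat × year, permutation p-values), daily temperature
statistics with **DTR** (diurnal temperature range) and donor gap-fill,
and **wave energy flux** `P = ρ g² H_sig² T_w / (64π)` with seasonal
aggregation. A seeded simulator generates the whole four-habitat survey
design — cover tables, logger series, wave records — so every stage runs
without field data. See `docs/methods.md` for the model details.

## Worked example

```python
from reefsync import moorea_preset, generate_cover_surveys
from reefsync import aggregate_cover, windowed_metrics
from reefsync.association import ma_regression_from_metrics

cover = generate_cover_surveys(moorea_preset(seed=1))   # quadrat rows
metrics = windowed_metrics(aggregate_cover(cover)).frame
print(metrics.round(3).to_string(index=False))
fit = ma_regression_from_metrics(metrics)
print(f"MA slope={fit.slope:.3f} r={fit.r:.3f} "
      f"r2={fit.r2:.3f} df={fit.df} p={fit.p:.2g}")
```

```
 window_start  window_end   phi    cv  defined
         2006        2007 0.970 0.286     True
         2007        2008 0.987 0.237     True
         2008        2009 0.891 0.172     True
         2009        2010 0.960 0.256     True
         2010        2011 0.157 0.032     True
         2011        2012 0.126 0.026     True
         2012        2013 0.268 0.103     True
         2013        2014 0.304 0.076     True
         2014        2015 0.113 0.064     True
         2015        2016 0.607 0.132     True
         2016        2017 0.425 0.150     True
         2017        2018 0.736 0.219     True
         2018        2019 0.831 0.279     True
MA slope=0.252 r=0.933 r2=0.871 df=11 p=3.2e-06
```

Reading this: during 2007–2010 every habitat loses coral together
(a seastar outbreak then a cyclone on the simulated fore reef, slow
decline in the lagoon), so synchrony is high (phi ≈ 0.9–0.99) and total
cover swings hard (high CV). Once the fore reef recovers while the lagoon
keeps declining, the habitats compensate: phi drops to ≈ 0.11–0.3 and the
reef-wide community is correspondingly stable (CV ≈ 0.03–0.1). Across the
13 windows, synchrony and variability are strongly positively associated
(r = 0.93, p ≪ 0.01) — the signature consistent with spatial insurance.

The same flow is available from a shell:

```bash
reefsync run-all --seed 1 --outdir out/      # whole pipeline, one command
reefsync simulate --seed 1 --outdir out/     # or stage by stage
reefsync metrics --cover out/cover.csv --outdir out/
reefsync associate --metrics out/metrics.csv --outdir out/
```

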