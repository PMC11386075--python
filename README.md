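# towgrow

Quantitative analysis of microbial growth in spacecraft dust under constant
and cycling moisture, built around the **time-of-wetness (ToW)** framework:
qPCR-based quantification, exponential growth-rate modeling with
activation/deactivation-limited classification, and moisture-driven
community-composition statistics — exercised end to end on a calibrated
synthetic-data generator that emulates an ISS-dust incubation experiment.

## Who this is for

Researchers modeling unintended microbial (especially fungal) growth in
closed built environments — spacecraft, space stations, or terrestrial
buildings — from equilibrium-relative-humidity (ERH) exposure histories,
and anyone who needs a tested reference implementation of the ToW growth
model and the accompanying community statistics.

## The model

Dust holds a microbial community that grows when the surrounding air's ERH
exceeds a wetness threshold (80% ERH). Under constant wet exposure, the
concentration C (spore equivalents or cells per mg dust) grows
exponentially at an intrinsic rate *k* (day⁻¹), estimated by ordinary
least squares of ln C on time. Under a daily cycle with *t_w* wet hours
per day, the effective rate *R* depends on the organisms' response to
re-wetting and drying. With an activation lag *t_a* (hours lost after each
re-wetting) and a deactivation persistence *t_d* (hours of growth
continuing into each dry period), the relative growth rate is

    activation-limited:    R/k = max(0, t_w − t_a) / 24
    deactivation-limited:  R/k = min(24, t_w + t_d) / 24

reducing to proportionality R/k = t_w/24 when the parameter is zero. The
package estimates per-bag *R* and *k* from concentration time series,
averages R/k across dust bags, fits both one-parameter families by exact
piecewise least squares, and classifies the regime by the smaller residual
sum of squares.

qPCR concentrations come from a standard dilution-series curve
(Cq = intercept + slope·log₁₀ copies/µL; efficiency = 10^(−1/slope) − 1),
scaled by the ×50 dilution and 50 µL extraction volume and divided by dust
mass. Community analyses follow standard amplicon practice on absolute
abundances asinh(relative abundance × qPCR total): 10% prevalence
filtering, richness and Shannon diversity, Bray–Curtis dissimilarity with
principal-coordinate ordination, one-factor PERMANOVA, and per-taxon
Welch–Satterthwaite *t* tests with Benjamini–Hochberg FDR.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (seed 0). `python analysis/01_simulate.py` generates the two
experiments; `python analysis/03_tow_model.py` then prints:

```
time-of-wetness model classification:
  bacterial @  85% ERH: activation_limited     parameter  2.01 h  SSE 0.0829
  bacterial @ 100% ERH: activation_limited     parameter  1.27 h  SSE 0.0128
     fungal @  85% ERH: activation_limited     parameter  2.02 h  SSE 0.0105
     fungal @ 100% ERH: deactivation_limited   parameter  3.37 h  SSE 0.0380

fungal growth vs time-elevated: Spearman rho = 0.714 (p = 4.38e-06, n = 32 bag-level rates)
```

The elevated (85% ERH) condition classifies as activation-limited — each
daily re-wetting costs about two hours of growth — while the saturated
(100% ERH) condition is deactivation-limited, with growth persisting about
three hours into each dry period. Growth increases with hours elevated per
day (rank correlation 0.71 across bag-level rates).
`python analysis/02_growth_rates.py` shows the constant-ERH dose response
(fungal concentrations rising from ~4×10⁶ per mg below the threshold to
~10¹⁰–10¹¹ per mg at 85–100% ERH, significant from 80% ERH upward), and
`python analysis/04_community.py` the accompanying diversity collapse
(mean richness 26 → 8.5, Shannon 2.56 → 1.67 from 50% to 100% ERH;
PERMANOVA by condition R² = 0.63, p = 0.001) and differential abundance
(26 taxa more abundant at non-elevated vs 5 at elevated conditions).

A `towgrow` command-line interface exposes the same stages
(`simulate`, `quantify`, `growth`, `tow-fit`, `community`, `diffabund`,
`stats`, `report`, `all`); see `towgrow --help`.

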