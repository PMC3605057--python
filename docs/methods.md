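# Methods notes

This note documents the models, statistical procedures, parameter choices
and known limitations of `ploidypheno`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## 1. Growth model and synthetic experiments

### Curve model

A well's population signal is modelled on the log2 (doublings) scale with
the Zwietering reparameterization of the Gompertz function,

    l(t) = E · exp(−exp(e·s/E·(λ − t) + 1)),

chosen because its three parameters are exactly the quantities the
extraction stage is defined to measure: the maximum slope of `l` is
`s = 1/doubling time` (doublings/h), the tangent through the inflection
crosses zero at `t = λ` (the lag, h), and `l(∞) = E = log2((N0+A)/N0)`
encodes the total density change `A` (ΔOD) on inoculum `N0`. Observed OD
is `blank + N0·2^l(t)` plus additive Gaussian noise truncated at zero; an
optional multiplicative noise component exists but is off by default. OD
nonlinearity at high density is deliberately **not** simulated
(plate-reader calibration curves are instrument-specific), nor are
diauxic shifts, flocculation or evaporation.

### Default study conditions

The generator's defaults reproduce the design of a two-species
natural-isolate screen: 24 *S. cerevisiae* + 27 *S. paradoxus* strains
(one *S. cerevisiae* lab strain flagged as the internal reference), 33
environments, per strain and environment two haploid mating types at
n = 2 each plus the a/α autodiploid at n = 4 (figure legends of such
screens sometimes quote the transposed counts; both are `DesignSpec`
parameters), 8 reference wells per run, OD every 20 min for 72 h. This
yields 51 × 8 × 33 = 13,464 sample cultures plus standards.

Latent parameters compose additively on the log2 scale:

| term | default sd (log2 units) | meaning |
|---|---|---|
| species | 0.30 | species-level phenotype offset |
| population | 0.10 | population offset within species |
| strain | 0.20 | strain deviation |
| environment | 0.30 | environment main effect |
| culture noise | 0.10 | biological replicate noise |
| run offset | 0.05 | shared by all wells of a run, standards included |

Baselines: lag 4 h, doubling time 2 h, efficiency 1.2 ΔOD, inoculum
0.1 OD, blank 0.05 OD, measurement noise 0.01 OD — typical magnitudes for
microcultivation of *Saccharomyces* in synthetic media.

### Ploidy-effect architecture

A fraction `prob_env_affected` (default 0.7) of environments carries true
ploidy effects; within an affected environment each component's
species-level effect pair (δ_cer, δ_par) is bivariate normal with sd
0.5 and correlation ρ (`rho_conservation`, default 0.9). Per-strain
effects add population- (sd 0.1) and strain-level (sd 0.1) deviations,
which is what gives strain pairs of the same species/population more
similar ploidy-effect profiles. The sign of the half-effect applied to
each ploidy is chosen per component so that the haploid-minus-diploid
difference **on the LSC scale** equals δ for lag, rate and efficiency
alike. Per-curve noise streams are seeded by a CRC of (run, well)
combined with the master seed, so any subset of the design is
reproducible independently of generation order.

## 2. Extraction of fitness components

`preprocess` subtracts the blank, floors at ε = 10⁻³ OD (keeping log2
finite) and applies a 3-point running median (robust to single-sample
spikes; monotone-preserving — property-tested).

**Rate.** Sliding-window OLS of `log2(corrected)` vs time; the maximal
slope `s` gives `doubling time = 1/s`. The base window is 5 samples
(~80 min at 20-min sampling). A fixed narrow window is statistically poor
for slow growers: the max-over-windows of noisy slopes is upward-biased
(picking the noisiest window), which at 0.01 OD noise produces ~15%
median doubling-time error. A fixed wide window instead biases fast
growers through curvature (the log2 Gompertz bends within the window).
The implementation therefore adapts: after the base-window pass, the
window widens to ~40% of the detected exponential-phase span
`E/(s·Δt)` samples (cap 21), iterated twice. Slow growers get long,
nearly straight fits; fast growers keep the 5-sample window.
`extract_rate(..., adaptive=False)` restores the fixed-window behaviour.
Measured on the generator (acceptance study, 200 curves, noise 0.01 OD,
DT ∈ [1.5, 4] h): median relative errors ≈ 3% (DT), 4% (lag), 1.3%
(efficiency); noiseless DT=1.5 h error 1.6%.

**Lag.** Tangent construction in log2 space: the line through the
maximal-slope window intersects the baseline level `log2(mean of first 3
corrected readings)`; the crossing, clamped to [0, duration], is the
lag. Lag is the most bias-prone component (early growth below detection
inflates it); a `lag_near_start` flag marks curves whose rate window
starts within one window of t = 0, and a shifted curve's lag shifts by
exactly the same amount (tested).

**Efficiency.** Maximum of the smoothed corrected series minus the mean
of its first 3 readings, floored at 0; the maximum (not the final
reading) is used for robustness to late decline.

**Growth call.** `grew` requires efficiency ≥ 0.05 ΔOD and a positive
maximal slope. Non-growers report doubling time as missing and lag
censored at the assay duration; censored values propagate as *missing*
LSC, never as extreme values.

## 3. Internal-standard normalization

`LSC = log2(x) − mean_k log2(wt_k)` over the K same-run reference wells
of the matching component, with the efficiency axis inverted so that
larger LSC = worse performance for every component (a `flip_sign` switch
outputs the opposite, figure-style orientation). Mean-of-logs is the
default standards aggregation (a `log_mean` switch exists); the
normalization is strictly per run. Because a run-wide multiplicative
effect enters sample and standards identically, it cancels exactly — the
acceptance study measures the residual at ~10⁻¹⁵ (float round-off), and
the standards' own LSC values average exactly zero per run by
construction. Replicates are averaged per (strain, ploidy, mating type,
environment, component) cell with counts recorded.

## 4. Ploidy effects and factor dissection

The unit of replication for species-level tests is the **strain**
(n = 24 / 27), not the well: per strain, the haploid score is the mean of
its two mating-type means (a single measured mating type is used as-is
and flagged), the diploid score the mean of the heterozygous a/α diploid
replicates. Per trait, a two-tailed pooled-variance t-test compares the
two score vectors across strains; BH-FDR at α = 0.05 runs over all traits
within one species (the FDR family; within-species is a choice — the
family is not dictated by the test itself). Zero pooled variance returns
a flagged sentinel (p = 1 for equal means, p = 0 otherwise) rather than
raising. The haploid and diploid scores of a strain share its strain ×
trait effect, so the two-sample test is conservative under the generator's
defaults; the suite verifies FDR control under the global null and near-α
behaviour when strain effects are removed.

Conservation: a trait's effect is conserved iff significant in both
species with the same sign; traits untested in one species are
unclassified. The "fraction of affected environments" summary supports
two aggregations (any component significant — default — or all
components), since either reading is defensible; both are reported by
the pipeline.

Cell-size calls require the large-vs-small comparison to pass FDR in
haploids *and* diploids **with concordant direction** (discordant joint
calls would be uninterpretable as size effects). Mating-type-locus calls
require ≥ 1 MAT-hemizygous diploid to differ from the heterozygous
diploid after FDR over all traits × comparisons. Note the FDR correction
costs power: for a 3σ hemizygote shift at n = 4 the exact power of the
call is 0.86 (noncentral-t closed form, matched by simulation), versus
0.93 for an uncorrected α = 0.05 test.

## 5. Similarity, variance partitioning, clustering

Strain-pair similarity is the Pearson correlation of two strains'
per-strain ploidy-effect profiles (haploid score − diploid, per trait),
pairwise-complete over shared traits (≥ 3 required), after scaling each
trait to unit variance across strains. Signed `r` is the default
response (an `r2` switch squares it). One-way ANOVA of pair similarity
on the two-level within/between label reports F, p and adjusted
R² = 1 − (1−R²)(N−1)/(N−2). Pairs sharing a strain are treated as
independent, which is standard for this design but anti-conservative;
the result object carries that caveat. Population and source partitions
default to *S. cerevisiae* pairs only; the strain universe is a
parameter. Note that the adjusted R² of such partitions depends strongly
on the noise of individual pair correlations: with the generator's
defaults (many traits, strong planted effects) species separation is
much crisper than in typical experimental data, so partition values are
validated against planted-truth two-group simulations with an analytic
expectation rather than against any particular dataset's percentages.

Clustering is average-linkage (UPGMA) on `1 − r` with the centered
Pearson correlation; invalid pair distances are imputed at the maximum
observed distance and counted. Merge heights are non-decreasing
(ultrametric); Newick export uses node height = merge distance / 2, so
leaf-to-leaf path length equals the merge distance (round-trip-tested
with an independent parser).

## 6. Validation studies and problem sizes

The acceptance runner uses: 200 curves for parameter recovery; 500
replicates of a 24-strain × 100-trait effect-calling run for null FDR
(simulated at the trait level via `simulate_trait_dataset` — the
curve → component → LSC stages are validated separately by the recovery
and cancellation studies, so trait-level simulation composes); 200
two-group simulations at the study's pair counts (627/648) for the
variance partition, compared to the analytic two-group R²
`p(1−p)Δ²/(p(1−p)Δ²+σ²)`; and one full curve-level pipeline run at study
scale (≈14,000 curves) for planted-fraction recovery. These sizes keep
the whole validation under a minute while leaving Monte-Carlo error well
below each tolerance.

## 7. What passing tests do and do not show

The generator emulates design structure, additive log2 effect
architecture, run effects and measurement noise. It does not emulate OD
calibration nonlinearity, spatial plate gradients beyond the run offset,
multi-phase (diauxic) growth, evaporation, condensation artefacts, or
mating-type switching during culture. Passing recovery tests therefore
demonstrate correctness of the algorithms under the stated model, not
robustness to every instrument artefact; the lag component in particular
should be treated with caution on real data, where early sub-threshold
growth biases it upward.
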