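# Methods

This note documents the statistical models, the defaults and the design
choices behind screenomics, and what the synthetic-data tests do and do
not demonstrate about real screens.

## Screen scoring model

A pooled shRNA dropout screen measures, for each hairpin, a read count at
a reference time point (shortly after transduction and selection) and at
a final time point (after several population doublings). Hairpins
targeting genes required for proliferation or survival drop out of the
pool, so the fold-depletion score

    F = (n_ref + c) / (n_final + c)

is large for essential genes. The pseudocount `c` (default 1, applied to
both counts) guards hairpins whose final count is zero while perturbing
large-count ratios negligibly. Scores are analysed as log2(F); the base
only rescales the log axis and cannot change hit calls.

**Gene summary.** Each gene's hairpins give an empirical distribution of
log depletion scores, summarised by its 80th percentile (`QuantLog`).
An upper quantile (rather than a mean) avoids bias from the varying
number of hairpins per gene and from the right-skew caused by strong
but inconsistent hairpins. Genes with fewer than `min_shrnas = 2` scores
are reported as skipped: a quantile of one value carries no within-gene
evidence. Ranks are 1-based by descending score, ties broken
lexicographically for reproducibility.

**Quantile convention.** The per-gene quantile defaults to the discrete
lower order statistic (numpy's `method="lower"`): for k hairpins the
score is the order statistic at index ⌊0.8·(k−1)⌋, which is never above
the 2nd-largest hairpin score for k ≥ 2. This gives the hit caller a
structural guarantee: a gene can only be called a hit if at least two of
its hairpins individually exceed the threshold, so no call ever rests on
a single outlier hairpin. Under linear interpolation
(`quantile_method="linear"`, also exposed) the gene score can exceed the
2nd-largest hairpin score, and simulation shows that a stable fraction
(roughly a quarter to a third, independent of the noise scale) of the
false-positive hits inherent in a 95th-percentile cut would then carry
only one supporting hairpin. The two-hairpin support count is also
computed explicitly as a diagnostic (`hit_shrna_support`).

**Null model.** Most genes (>95%) are assumed non-essential with
normally distributed gene scores. The null N(μ, σ²) is fitted robustly:
μ = median of all gene scores; σ = (q97.5 − q2.5)/4, because 95% of a
normal's mass lies within ±2σ of its mean. These population quantiles
use linear interpolation (at 10⁴-10⁵ genes the convention is
immaterial). Hits are genes with score strictly above μ + 1.6449·σ, the
null's 95th percentile; the constant 1.6449 is pinned to four decimals
for cross-platform reproducibility. Degenerate inputs (all scores
equal, or fewer than `min_scores = 40` genes) raise errors rather than
returning a meaningless fit.

**Calibration bias.** For i.i.d. normal scores the inter-quantile σ
estimator is slightly biased low (the sample 97.5/2.5 percentile span
underestimates the population span at finite n, and the spread of the
estimator interacts with the tail nonlinearly). The effective cut sits
near 1.612σ rather than 1.645σ, so the expected exceedance is
P(Z > 1.612) ≈ 5.35% and the expected non-hit percentage ≈ 94.65%,
which is what both the acceptance script and the calibration test
measure (tolerance ±1 percentage point around 95%).

**CERES rule.** For CRISPR screens summarised as CERES gene-effect
scores (more negative = more essential), hits are genes with score
≤ −0.5. The comparison is inclusive and the threshold configurable.

## Omics store and alteration calls

The store joins per-(cell line, gene) layers: log2 copy-number ratios
versus a normal reference, expression, point mutations with COSMIC
occurrence counts, screen hit calls, oncogene annotations, a gene→drug
map and RPPA protein values. Gene identity is the case-preserved symbol
string; alias resolution is out of scope.

* **Expression dialects.** Values are either log2 ratios versus normal
  cells or median-centred within a panel (each gene's panel median
  subtracted, missing cells ignored and left missing — zero-filling
  would bias the centring). The dialect is a store-level attribute and
  two dialects are never mixed in one store.
* **Mutation filter.** Only mutations observed in COSMIC strictly more
  than 5 times are reported (configurable); for panels whose mutation
  data come pre-curated, a hotspot mode retains only flagged hot-spot
  mutations instead.
* **Amplification.** A gene is amplified when its log2 ratio is ≥ 0.8
  (inclusive, configurable). No published cut accompanies the data this
  mirrors; 0.8 sits just below the smallest amplification reported in
  comparable signature tables and is deliberately exposed as a
  parameter.
* **Genomically altered** = amplified OR ≥ 1 retained mutation.
  Deletions are excluded on purpose: the signature definitions concern
  activation by amplification or point mutation.

## Signatures

Candidate = altered ∩ oncogenes; overall = altered ∩ hits; functional =
the three-way intersection (= candidate ∩ overall); druggable = hits
with ≥ 1 mapped drug. Every row field is copied from the store — the
signature module recomputes nothing. Signature rows are ordered by
expression log-fold-change descending (ties by symbol), matching how
such tables are conventionally presented; the druggable signature is
ordered by screen rank so the most essential targets lead.

## Pathway essentialness

KGML gene entries become gene nodes (an entry naming k genes expands to
k nodes inheriting the entry's relations; groups are flattened to their
components; map/compound/ortholog entries are dropped since only gene
nodes can carry hits). Relations collapse to undirected simple edges —
subtypes and directions are ignored because only adjacency enters the
weighting.

For a cell line with hit set H and screen universe U (all genes the
screen actually measured — the proportion needs a measured
denominator), a pathway P restricted to U is scored

    w(g) = α + λ · h(g) / max(1, d(g))        for g in H ∩ P ∩ U
    score = ( Σ w(g) ) × |H ∩ P ∩ U| / |P ∩ U|

with α = λ = 1 by default; h(g) counts hit neighbours and d(g) the
degree of g inside P ∩ U. The formula keeps the three stated
ingredients — enrichment, hit proportion, and a bonus for hits directly
linked to other hits — independently testable, and lives behind a single
function so alternates can be swapped. Provable properties (tested):
score = 0 ⟺ no hits; adding hits never lowers the score; adding an edge
between two hit nodes never lowers it; genes outside U never affect
anything. Ranking is by descending score, ties by proportion then
pathway id. For map export, each hit gene gets a colour intensity
`1 − (rank − 1)/(n_screen − 1)` clipped to [0, 1] (strongest hit
darkest); drawing on pathway images is out of scope.

## Drug response

**4PL fit.** Surviving fraction y versus log10 concentration x is fitted
by least squares to `y = bottom + (top − bottom)/(1 + 10^(hill·(x − m)))`;
IC50 = 10^m, with the standard error of m propagated to concentration
units. The fit requires ≥ 4 distinct concentrations and a response
spanning the half-maximal level; otherwise a non-sigmoid error tells the
caller to fall back to LOESS.

**LOESS inversion.** Local linear regression with tricube weights over
the span·n nearest neighbours (span = 1 by default), evaluated on a
1,000-point log-spaced grid across the tested range. The implementation
is hand-written because the inversion needs the linear-smoother vector
l(x) (ŷ(x) = l(x)ᵀy) at arbitrary grid points; it reproduces R's
`loess(span=1, degree=1, surface="direct")` to machine precision (a
cross-check against Rscript is part of the test suite). The IC50 is the
first grid concentration where the fitted curve crosses 0.5; the 95%
prediction interval, `t₀.₉₇₅,n₋₂ · s · √(1 + ‖l(x)‖²)` with s² the
in-sample residual variance on n − 2 degrees of freedom, is inverted at
the crossing and half its concentration-width reported as the error
(band crossings outside the tested range clamp to the range ends).

**Z-scores.** For a panel of IC50s, z = (ln IC50 − ln GM)/s where GM is
the panel's geometric mean and s the sample standard deviation (n − 1)
of the log IC50s. Standardising on the log scale is what makes a
"geometric mean" reference coherent and gives unit invariance
(rescaling all IC50s changes no z); a raw-scale variant is kept behind
`log_scale=False` for comparison. "Standard deviation of the mean" is
read as the panel standard deviation, not a standard error — a standard
error would shrink with panel size and make a fixed ±1.5 cut
meaningless. Sensitivity is z ≤ −1.5, inclusive. External panel
statistics (e.g. from a large reference panel) can be supplied instead
of the panel itself.

## Synthetic data

`simulate_screen` draws reference counts from a negative binomial
(mean = depth, variance = m + α·m², dispersion α configurable, Poisson
at α = 0) because pooled-screen counts are overdispersed; essential
genes' final-count means are divided by 2^effect, the effect applied to
all of a gene's hairpins with an optional per-hairpin efficacy jitter.
Defaults (15,000 genes × 5 hairpins, 2% essential, effect 4 log2 units,
depth 500, dispersion 0.05) give a realistic genome-scale screen whose
planted truth is recovered at ≥ 95%. `simulate_omics` plants per-line
drivers satisfying all three signature predicates while every background
gene gets at most two of them, so the functional signature provably
equals the planted set. `make_toy_kgml` emits valid KGML for a requested
topology (including multi-gene entries to exercise expansion), and
`simulate_dose_response` draws from a 4PL with truncated Gaussian noise.
Every generator is a pure function of its parameters including the seed.

What the synthetic tests do **not** show: real screens have off-target
hairpins, gene-length and GC biases, heterogeneous hairpin efficacies
and batch effects; real mutation data have calling artefacts; KEGG
topologies are scale-free rather than Erdős–Rényi; and real
dose-response noise is heteroscedastic. Passing tests demonstrate the
estimators implement their definitions and are calibrated under the
stated noise model, not that the biology of any particular cell line is
reproduced.

## Problem sizes

The calibration and spike-in checks run at full screen scale (15,000
genes; 20 replicates for calibration); signature and pathway property
suites use 100 random fixtures of 30-40 genes and 4-16-node pathways,
sizes at which the brute-force oracles remain exact and instantaneous.

## Known limitations

* Gene joins are symbol-based; no Entrez/alias mapping.
* Pathway relations are undirected and untyped; inhibition is not
  distinguished from activation.
* The overall/functional signatures admit only amplification or
  retained point mutation as "altered"; expression-only outliers are
  surfaced by queries but never enter signatures.
* The LOESS error bar inherits the homoscedastic residual assumption;
  with very few points it is wide and should be read as indicative.
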