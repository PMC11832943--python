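# Methods

`dendrotrend` analyzes within-stand growth decline in tree-ring data: it
reconstructs basal area increment (BAI) per tree, splits a stand into
divergent growth-trajectory groups, tests the dependence of long-term growth
trends on crown damage and other tree traits, and quantifies how the climate
sensitivity of growth changes with crown vitality. The pipeline was built
around the situation of an old, drought-stressed *Nothofagus pumilio* stand
in northern Patagonia — a monospecific southern-beech forest near the xeric
margin where heavily crown-damaged trees coexist with healthy ones — but
every stage is generic tree-ring methodology.

## Pipeline stages and their models

### Ring input and cross-dating validation

Ring widths enter as Tucson `.rwl` (0.01 mm units; `999`/`-9999`
terminators) or long CSV. A southern-hemisphere ring spanning one October to
the following March is labeled by the calendar year in which the growing
season *ends* (the 2020–2021 season ring is year 2021); this labeling is
used everywhere, most importantly in the climate-window mapping below.

Cores of one tree are averaged arithmetically per year into a tree series.
Dating quality is scored per core against a leave-one-out master chronology
after normalizing both with the proportion-of-last-two-years log transform

    p_t = ln( 2 w_t / (w_t + w_{t-1}) ),

which removes level and trend and leaves the year-to-year signal that
cross-dating relies on. The transform's exact algebraic form is a package
convention (the method name alone does not pin it down); it is recorded here
and in output metadata. A core passes when the Pearson correlation with the
master exceeds 0.32 *and* Student's t = r sqrt((n−2)/(1−r²)) exceeds 3.5,
both strict. Failing cores are reported, not dropped — the caller decides.

### BAI geometry

With ring widths w_t (mm) and the diameter at breast height D (mm), the
outermost ring's outer radius is anchored at D/2 and radii proceed inward,
r_{t−1} = r_t − w_t. Then

    BAI_t = pi (r_t² − r_{t−1}²)   [mm² yr⁻¹].

No bark correction is applied (bark thickness is not measured in the target
protocol). Cores rarely hit the pith and D includes bark, so the cumulative
width sum rarely equals D/2 exactly: a residual inner radius acts as the
innermost ring's inner boundary and produces no BAI record. If the width sum
*exceeds* D/2 the anchor is clamped to the width sum; beyond a 25 % relative
excess an error is raised. Optionally (`rescale=True`) widths are first
scaled proportionally so their sum equals D/2 exactly; both behaviors exist
because field protocols differ and the correct choice is data-dependent.
Missing rings encoded as width 0 are kept and contribute zero increment.

The Hegyi competition index for tree i with neighbors j is
CI_i = Σ_j (dbh_j/dbh_i)/dist_ij, over the five nearest neighbors when more
are supplied (distances in m). It is dimensionless and invariant under a
common rescaling of all diameters.

### Detrending and chronologies

Two standardization families, both ratio-based (index = value / fit):

* `spline32` — a cubic smoothing spline whose frequency response is 50 % at
  a 32-year wavelength. For unit-spaced years this fixes the roughness
  penalty at λ = (32/2π)⁴ ≈ 672.8 (verified numerically: the realized
  response at a 32-yr sinusoid is 0.500). This removes age/size trends and
  slow disturbance effects and is used for the signal-strength statistics.
* `mean_line` — division by the series mean. It keeps *all* low-frequency
  variation and is the standardization used before climate-correlation
  analysis, where long-term climate trends are part of the signal of
  interest.

Chronologies are per-year Tukey biweight robust means (tuning constant
c = 9 in units of the MAD, location iterated 10 times from the median,
median fallback when the MAD is zero). Sample depth is recorded per year and
the chronology's "reliable" span starts at the first year with at least five
trees.

Signal strength: Rbar is the mean pairwise Pearson correlation over
pairwise-common years (pairs with fewer than 30 shared years are skipped);
the Expressed Population Signal is

    EPS = n rbar / (n rbar + 1 − rbar),

with n the mean sample depth over the period (not per-year), and 0.85 the
conventional adequacy threshold.

### Growth-trajectory groups

The years × trees BAI matrix over the common overlap period (default
1879–2014) is decomposed by PCA on the correlation scale — each tree's
column is standardized first, because BAI levels differ by an order of
magnitude among trees and covariance-scale PCA would reduce to the biggest
trees. Component signs are fixed so the mean loading is positive. Each tree
is then assigned to the retained component (two by default) whose score
series its BAI correlates with most strongly *in magnitude*; using |r| makes
the assignment invariant to the arbitrary component sign, and exact ties
break toward the lower component and are flagged. Group trait differences
use a Welch t-test for DBH and Mann-Whitney rank-sum tests for the other
traits (height, minimum age, crown damage, Hegyi index, mean ring width),
following the variance/sample-size structure typical of a 17-vs-6 split.

### Trends and damage thresholds

The Mann-Kendall statistic S counts concordant minus discordant pairs
against time; the reported Tau is the tie-corrected tau-b
(S / sqrt(D₀(D₀−T)) with D₀ = n(n−1)/2 and T the tie term — time itself has
no ties). Significance: exact null distribution for n ≤ 10 without ties;
otherwise the tie-corrected variance

    Var(S) = [n(n−1)(2n+5) − Σ t(t−1)(2t+5)] / 18

with a continuity-corrected normal approximation. A constant series returns
Tau = 0, p = 1.

Per-tree Tau values (default window 1941–2021) are regressed on each trait
by OLS. The damage value where the fitted Tau crosses zero is reported only
when the slope is distinguishable from zero at the 0.1 level — a zero
crossing of a flat line is noise. Two crown-damage thresholds are derived:
the Tau~damage zero crossing (damage beyond which the expected trend is
negative) and the smallest damage among trees whose individual negative
trend is significant at 0.05.

The turning point of a chronology is the year of the global maximum of a
local-quadratic loess smooth (tricube weights, span 0.75 — the span is a
config knob because no canonical value exists), reported only when the
smooth ends below that maximum; monotone or flat smooths have no turning
point. statsmodels' lowess is local-linear only, so the local-quadratic
smoother is implemented in-package.

### Climate departures

Station series are converted to z-scores per calendar month against a
common reference period (default 1992–2021, at least 20 valid years per
month required): z_{y,m} = (x_{y,m} − mean_m)/sd_m. Per-month
standardization removes the seasonal cycle so departures are comparable
across months. Station departures are averaged with equal weight into
regional means (temperature: 3 stations; precipitation: 6), cells missing at
some stations use the stations present. The moisture index is

    MI = P_departure − T_departure,

so strongly negative values mark hot-and-dry years. Zero-precipitation
months participate as ordinary values.

A ring of growth year y integrates 19 monthly slots across three calendar
years: the previous growing season's October (calendar year y−2) through the
current season's April (year y) — previous-season Oct–Apr (7 slots), winter
May–Sep (5), current-season Oct–Apr (7). This mapping is centralized in
`season_window` and locked by an enumeration test, because an off-by-one in
the year offset is the classic southern-hemisphere dendro bug.

### Climate sensitivity and its damage dependence

For each of the 19 slots, the Pearson correlation between the (mean-line
standardized) chronology and the slot's regional departure is computed over
the analysis window (default 1931–2021). Significance uses a paired
bootstrap: years are resampled with replacement (default 1000 draws, seeded
— the seed is mandatory), and a slot is significant when the percentile 95 %
interval of r excludes zero. On white noise this flags about 5 % of slots.

Per-tree seasonal sensitivity is the arithmetic *mean of the per-slot r
values* (current-season DJF for temperature and precipitation, JFM for the
moisture index), not the correlation with a seasonal mean — the two differ,
and the mean-of-r convention matches how per-tree values are then compared
across trees. Its dependence on crown damage is fitted as a Gaussian GAM:
a B-spline basis of dimension 5 (only 23 trees), penalty weight chosen by
GCV, reported as deviance explained = 1 − residual/null deviance together
with the smooth's effective degrees of freedom. The smooth-term p-value is
an *exact* F-test of the unpenalized basis against the intercept-only model:
testing on the GCV-selected effective df proved strongly anticonservative
(59 % null rejections at the 5 % level in simulation, because a fully
penalized-away smooth drives the numerator df toward zero, and because the
smoothness was chosen from the same data), whereas the fixed-basis F-test is
calibrated (6 % null rejections) at a negligible power cost for effect sizes
of interest. Both the penalized fit and the exact p are reported.

## The synthetic stand generator

The generator (`dendrotrend.synthetic`) produces stands with the structure
the analysis assumes, plus ground truth for recovery testing. Expected BAI
of tree i in year t:

    BAI_it = growth_i(age) · decline_i(t) ·
             exp( βT_i·T_DJF(t) + βMI_i·MI_JFM(t) + a_g(i)(t) ) · ε_it

* **Ages and growth curves.** 23 trees, ages 150–220 yr (two cores each,
  5 % lognormal measurement noise per core). Stable-group trees follow a
  very slowly saturating curve (τ = 500 yr — effectively a near-linear
  mature BAI rise, as old southern beeches keep expanding their basal
  area). Declining trees follow an early-peaking curve (τ = 40 yr,
  asymptote 900 mm²): they raced to a growth peak and plateaued decades
  before the divergence — the structural-overshoot trajectory of trees that
  later decline. The distinct pre-divergence shapes matter: with identical
  growth curves the two groups' series correlate so strongly that
  correlation-based group assignment cannot separate them, which is itself
  informative about when the PCA method works.
* **Decline.** From 1934 the declining subgroup's expectation is multiplied
  by exp(−r(t−1934)) with r = ln2/100. Combined with the climate trend
  below this roughly halves the group's growth rate between 1941 and 2021
  (measured ratio ≈ 0.54 over seeds).
* **Group anomalies.** Each group shares a smooth AR(1) log-scale anomaly
  (φ = 0.9): sd 0.08 for the stable majority (the stand's common history)
  and sd 0.15 for the declining subgroup (a rougher disturbance-legacy path
  — incomplete recovery from episodic stress).
* **Climate.** Monthly temperature (3 stations) and precipitation (6) =
  seasonal climatology (MAT 5.2 °C, summer-peaking; 754 mm yr⁻¹,
  winter-peaking) + a shared regional AR(1) monthly anomaly (φ = 0.5) +
  station noise (expected inter-station anomaly correlation 0.8) + a linear
  post-1976 trend of +1.0 sd (temperature) and −0.5 sd (precipitation),
  emulating the documented regional warming/drying shift. The trend is
  essential: it gives climate-sensitive trees a climate-*driven* decline
  component and produces the strong trend-on-trend correlations seen in
  per-tree sensitivity when low frequencies are retained.
* **Sensitivities.** βT = −0.18 and βMI = +0.18 per sd, scaled per tree by
  an amplitude a ~ U(0.05, 0.7) for stable trees and a + 1.1 for declining
  trees: healthy trees are nearly climate-decoupled, damaged trees strongly
  coupled. The per-tree DJF-temperature mean r then spans about +0.05 to
  −0.6 across the damage range.
* **Damage.** damage = 15 + 20·[declining] + 150·|βT_i| + N(0, 8), clipped
  to [0, 100] and rounded to the 5 % classes of the visual field protocol.
  Stand mean ≈ 40 %.
* **Noise.** Multiplicative lognormal, σ = 0.15 — ring widths are positive
  and right-skewed.
* **Invertibility.** Widths are back-computed through the stem geometry
  (r_t = sqrt(Σ BAI/π), w_t = r_t − r_{t−1}) and DBH set to twice the width
  sum, so `bai_from_dbh` recovers the generated BAI to well within 0.5 %.

Emergent statistics at the defaults (across seeds): PC1/PC2 variance
≈ 57 %/22 %, stable-group Tau ≈ +0.26, declining-group Tau ≈ −0.40, site
Tau ≈ 0, damage-GAM deviance ≈ 0.7, group recovery by the full PCA route
≈ 100 %.

**What the generator does not emulate** — and hence what a green recovery
test does not establish: dating errors and locally absent rings; bark and
rotten-heartwood biases in the BAI geometry; mast/defoliator event years
(e.g. discrete moth outbreaks); autocorrelated measurement error within
cores; any damage–*precipitation* decoupling (the generated moisture-index
sensitivity makes the DJF-precipitation GAM significant too, unlike field
expectations where precipitation alone often carries no damage signal);
spatial structure among trees (neighbor lists are random, so Hegyi indices
are uninformative about the groups).

## Numerical choices and degenerate inputs

* Biweight: c = 9·MAD, 10 iterations, median fallback at MAD = 0 (which
  also makes {1,1,1,1,100} resolve to 1 exactly).
* Correlation-based statistics cap t at 10⁶ when r is numerically ±1.
* Constant series: Tau = 0 with p = 1; CV undefined (NaN) at zero mean;
  constant per-tree sensitivities give deviance explained 0 and p = 1
  without fitting.
* Zero-variance traits are reported as errors by `trait_trend_regression`
  and recorded (not fatal) by the pipeline stage.
* All stochastic steps (bootstrap, generator, GCV search) are seeded; the
  GCV search uses Nelder-Mead rather than basinhopping specifically because
  basinhopping draws from the global RNG and would break run-to-run
  reproducibility. A pipeline rerun with the same config is byte-identical.

## Known limitations

* The pipeline assumes gap-free annual series after core merging; it does
  not impute missing years.
* Rbar uses the pairwise-complete estimator; with very uneven series spans
  the effective n for EPS (mean sample depth) can differ from the tree
  count.
* The loess turning point is a descriptive statistic, not a change-point
  test; its location depends mildly on the span.
* The replication-data reproduction path (`reproduce_replication`) expects
  the deposited tables re-expressed in the package's CSV schemas; the
  original archive's column layout may need a mapping config.
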