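# Methods

## Problem and data model

The package estimates the current week's suicide death count for a US state
from proxy streams that are available in near real time, then rolls the
weekly estimates up to an annual crude rate. Six weekly streams exist:
search-trend popularity scores from two platforms (each a 0–100 score,
max-normalized over the observation window by the platform), a
suicide-related social-media post count, an ED-visit count for suicidal
ideation/attempt, a mean PHQ-9 score (0–27), and the death count itself.
Deaths are the outcome; they may appear as a *predictor* only at a lag of at
least 52 weeks, reflecting how long death certification takes in practice.

Panels are indexed by ISO-8601 weeks (Monday start). The week convention is a
package choice: MMWR and ISO weeks differ at year boundaries, and ISO weeks
are unambiguous and library-supported. Weekly indices must be gap-free;
alignment across states offers a strict policy (any gap is an error, the
default) and an interpolation policy that linearly fills gaps of at most two
weeks, rounding count-valued streams to integers. Anything longer is treated
as a data problem, not something to paper over.

The population denominator is a single per-state scalar supplied through
configuration, since crude rates need only an annual denominator.

## Synthetic worlds

Real inputs of this kind are restricted (vital statistics, syndromic
surveillance, screening platforms) or API-bound (trend and social-media
services), so the generator produces panels with the same statistical
anatomy:

* **Latent intensity.** `λ_t = exp(a + b·t + A·sin(2πt/52 + φ) + u_t)` with
  `u_t = ρ·u_{t−1} + ε_t`. The log link keeps the intensity positive and makes
  trend and seasonality multiplicative, which is how mortality seasonality is
  usually modelled. Defaults: `a = log 15` (≈15 deaths/week, a mid-size
  state), `b = 0.0005` (≈5% annual growth, mirroring the rising national
  trend), `A = 0.3`, `ρ = 0.6`, `σ_ε = 0.15`.
* **Deaths.** `y_t ~ Poisson(λ_t)`. Weekly state-level counts are small
  enough that zero-death weeks occur; Poisson noise keeps that behaviour.
* **Proxies.** Clean signal `s_t = baseline + gain·λ_{t−lag}`; observation
  noise per family — Poisson for counts, clipped Gaussian for the PHQ-9 mean,
  Gaussian followed by max-normalization to 0–100 for trend scores
  (`100·x/max(x)`, peak exactly 100, order preserved — the score the trend
  platforms publish).
* **Defaults** form the "informative" scenario: every proxy carries the
  latent signal with gain ≥ 1 (PHQ-9 uses gain 0.5 because its 0–27 domain
  cannot absorb a unit gain at λ≈15; its additive noise is still ≤10% of the
  signal sd), lags 0, 208 weeks starting 2015-W02 (so the panel ends exactly
  at 2018-W52; 2015 has 53 ISO weeks), population 4,000,000 per state.

What the generator does **not** emulate: keyword-level search dynamics, text
content, platform sampling artefacts, reporting-policy changes, or real
inter-source correlation structure (sources are conditionally independent
given the latent intensity; the coupling is exposed as configuration rather
than asserted). Passing tests on these worlds therefore demonstrate that the
pipeline recovers signal *when the proxies carry it*, not that real streams
carry comparable signal.

## Geographic attribution

Social-media posts are attributed to states through their author's free-text
profile location. Instead of geocoding web services (non-reproducible test
dependencies), a packaged offline gazetteer (50 states + DC, full names,
USPS codes, and a list of unambiguous major cities) resolves text with
explicit precedence: (1) standalone USPS code token, (2) full state-name
substring, (3) unambiguous city lookup; any ambiguity yields no label.
Code tokens must be uppercase: several USPS codes (IN, OR, ME, OK, LA)
collide with English words, and fully case-insensitive code matching would
label "somewhere in Louisiana" as Indiana. State names and cities match
case-insensitively. Attribution is per author — one resolution reused for
all their posts — and unresolved authors are dropped. Weekly counts are
zero-filled so the resulting series always passes panel gap validation.

## Windowing and splits

One supervised sample per eligible target week: a `w × S` feature block of
the `w = 2` most recent weeks (including the target week) of the selected
sources, plus, when enabled, a lagged-death column holding deaths at weeks
`t−L−w+1 … t−L` with `L = 52`. "More than one year" is operationalised as 52
ISO weeks; the lag floor is enforced by construction and the invariant is
asserted structurally in tests. Sample counts are `T−w+1` (no lag feature)
or `T−L−w+1` (with it).

Splits are by the target week's ISO year (2016/2017/2018); feature context
may cross year boundaries, so the first week of a year is predicted from the
last week of the previous year plus itself. Features are z-scored per column
with statistics from training windows only; targets are never scaled;
zero-variance features get unit scale with a warning.

## The LSTM nowcaster

Stacked LSTM (sigmoid gates, tanh cell), Xavier/Glorot-initialized, dropout
0.2 between stacked layers only (inert for one layer), single linear unit on
the final hidden state, MSE loss, Adam at learning rate 0.001 with L2 weight
decay 0.01 applied to weight matrices (not biases). The network and
backpropagation through time are written directly on NumPy: sequences are two
steps long and datasets are ≤ ~52 windows per year, so the unrolled graph is
tiny, a full training run takes well under a second on one CPU core, and the
implementation is verified against central finite differences in the test
suite.

Two numerical choices matter with a fixed small learning rate and a few
hundred epochs:

* **Mini-batch steps** (default batch 8, seeded shuffling). Adam's per-step
  parameter displacement is on the order of the learning rate; with one
  full-batch step per epoch, at most ≈0.3 of cumulative movement per
  parameter is available over 300 epochs — not enough to reach count targets
  of magnitude ~15 from a zero start. Mini-batching provides the standard
  several-updates-per-epoch regime.
* **Readout-bias initialization at the training-target mean**, standard for
  regression on counts; the network then learns deviations around the mean
  rather than the mean itself.

Negative raw predictions are clamped to zero at predict time. All
randomness (initialization, shuffling, dropout masks) derives from the config
seed, so training is bitwise-reproducible on one device.

Hyperparameter search: layers {1, 2} × hidden dims {16, 32, 64} × epochs
{150, 200, 250, 300}, all 24 trained with a shared seed, selected by lowest
validation RMSE. Ties (exact float equality, essentially never) break toward
fewer layers, then smaller dimension, then fewer epochs — the simplest model.
The search runs once per state on the all-sources stream and the selected
configuration is reused for every source combination of that state;
per-combination search is available as an option. Loss (MSE) and batch
handling are package choices where the training protocol was underspecified.

Source combinations mirror the reported model grid: online-only,
health-services-only, each of those plus the lagged-death baseline feature,
health+online, all sources (five proxies + lagged deaths), the
historical-only baseline (lagged deaths alone — the autoregressive
gold-standard stand-in), and each single source.

## Comparators

* **Two-phase ensemble.** Phase 1 fits six regression families (elastic net,
  LASSO, linear, random forest, ridge, SVR; library defaults, fixed seed) to
  each stream's flattened window features and keeps the family with the
  lowest validation RMSE per stream; a zero-variance stream falls back to a
  train-mean predictor with a warning. Phase 2 trains a one-hidden-layer
  (width 8) feed-forward network on the validation-period per-stream
  predictions. The same six-family pool serves both comparators — a single
  stated candidate set keeps them consistent and testable.
* **PCA fusion.** All streams' windowed features are concatenated per
  sample, standardized, and projected onto principal components fit on
  training samples only; the smallest component count reaching 90% explained
  variance is retained (a package choice — no retention rule was prescribed);
  the six families then compete on component scores by validation RMSE.

## Evaluation

`ESR = 100000·Σŷ_t/population` over the test year; annual error
`100·(ESR−ASR)/ASR` (negative = underestimate); weekly RMSE; MAD as the
*median* absolute weekly difference; Pearson correlation of weekly pairs,
reported as NA when either series is constant rather than fabricating 0.
All metrics are checked against independently coded brute-force
implementations at 1e-10.

## Problem sizes and degenerate inputs

Test and acceptance runs use one to four synthetic states of 208 weeks
(≈51/52/52 train/val/test windows with the lag feature), five seeded
replicates for the multi-source-vs-baseline comparison, and reduced grids
where only the selection mechanics are under test; one test exercises the
full 24-cell grid. Degenerate inputs have defined behaviour: empty panels
are refused on write, too-short panels name the required length,
non-stationary AR coefficients and family/domain mismatches are
configuration errors, all-zero trend series cannot be normalized, training
divergence raises with the epoch index, and an empty year split is an error.

## Known limitations

* Nowcasts are single-week point estimates; no multi-step forecasting and no
  predictive intervals.
* The Poisson/log-linear world is stationary in structure; regime changes,
  reporting artefacts and platform-policy shifts are out of scope.
* Gazetteer city coverage is deliberately small and unambiguous; recall on
  real profile strings would be lower than on the fixtures.
* Crude rates only — no age adjustment.
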