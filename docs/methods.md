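# Methods

## The experimental system being modelled

A mutation-accumulation (MA) experiment in liquid culture propagates
many independent lines of a unicellular organism through repeated
single-cell bottlenecks (here every 14 days), so that new mutations fix
by drift essentially regardless of their fitness effect. Control
populations are re-inoculated at ~100 cells to keep selection
effective. Fitness is read out by flow-cytometry cell counts: the
number of divisions per day over an interval, and — because many
mutational effects are invisible in benign medium — by 7-day growth
assays in stressful conditions (herbicides, altered salinity) where
genotype-by-environment (GxE) interactions reveal them.

## Line-loss model

The transfer draws a volume calculated to contain N̄ cells; the actual
count is `N ~ Poisson(N̄)` under the assumption that cells are uniformly
suspended. A fraction q of the sample is ultimately discarded, and each
cell lands in the discard independently, so

    P(loss) = Σ_N Poisson(N; N̄) q^N = exp(−N̄ (1 − q)).

Pipetting error is modelled as a multiplicative volume factor
`α ~ Gamma(mean 1, shape β = 1/CV²)`; marginally the cell count is then
negative binomial with mean N̄ and shape β, and

    P(loss) = (1 + N̄ (1 − q)/β)^(−β),

evaluated in log space (`exp(−β·log1p(·))`) so that very large β (small
CV) does not overflow; CVs small enough that CV² underflows are treated
as exactly Poisson. The closed forms are the implementation; adaptive
quadrature of the gamma-mixture integral exists only as an independent
oracle in the test suite and agrees to ≤ 1e−8.

Experiment-level quantities treat every line × bottleneck as an
independent Bernoulli trial: expected losses
`L_exp = n_lines × n_bottlenecks × p`, and the probability of observing
at least k losses is the binomial tail
`1 − BinomCDF(k−1; n_lines·n_bottlenecks, p)`. The trial count uses
lines *started*, a deliberate simplification: lines that die early stop
being at risk, so the binomial slightly overstates both L_exp and the
tail. For the loss probabilities relevant to design (p < 0.03) the
effect is below the table's print precision.

The 6-replicate rescue structure (the sampled cells are split across
six wells and any surviving well continues the line) does not change
the loss probability — survival requires ≥ 1 kept cell in total, wherever
it lands — so the analytic model ignores wells; the simulator implements
the allocation explicitly and the two agree.

## Fitness and selection coefficients

Divisions/day is the geometric-mean daily fold change
`G = exp(ln(N_t/N_0)/t)`, with the inoculum N₀ explicit (1 for MA
transfers, 100 for controls, ~50,000 for stress assays). A zero final
count is recorded as a loss observation (NaN growth), never silently
dropped, because loss accounting feeds the loss model and the
lethal-rate bound. Relative fitness divides each MA observation by the
mean control G *at the same bottleneck*, removing slow drift of the
experimental set-up.

The selection coefficient scaled by generation time is

    S_T = (ln G_MA − ln G_control) · ln 2 / ln G_control,

the difference of log daily growth rates per control generation
(generations/day = ln G / ln 2 since G is a daily fold change). An
alternative reading that divides by `ln(G_control)·ln 2` is selectable
(`variant="product"`); the two differ only by the factor `(ln 2)²` and
share sign and zero, but the default is the generation-scaled reading
because it makes S_T the per-generation log-fitness difference. Note
the useful identity: a multiplier m on divisions/day gives
`S_T = (m − 1)·ln 2` regardless of the control rate, which is what the
parameter-recovery tests assert.

Effective population size over an interval is the harmonic mean of the
census sizes, the standard choice because drift is dominated by the
narrow part of the bottleneck.

## Statistical battery

- **Control drift:** one-way ANOVA of control G on bottleneck index,
  computed from sums of squares so degenerate inputs have defined
  behaviour (all-constant → F = 0, p = 1; zero within-group variance
  with real between-group differences → error). Cross-checked against
  `scipy.stats.f_oneway` in the tests.
- **Trends:** Pearson correlation of G_r against *cumulative
  generations* (bottleneck index × generations per interval) rather
  than raw bottleneck index — proportional under constant growth, and
  the natural axis for mutation accumulation. Zero-variance series are
  flagged undefined rather than returning NaN silently. α = 0.05.
- **Selection tests:** per line × condition, a two-sample t-test of
  per-well growth factors against the control wells. Welch's form is
  the default (replicate variances need not match); pooled variance is
  available. Holm correction is applied within each condition across
  lines (family scope configurable to global); α = 0.01 for S_T flags.
  All tests are two-sided.
- **Variance ratio:** F = var(condition)/var(reference) with two-sided
  p = 2·min(sf, cdf) capped at 1; identical samples return exactly
  (F = 1, p = 1).
- **Stress confirmation:** Wilcoxon rank-sum of control growth in a
  condition vs the standard condition. A condition counts as stressful
  only when the difference is significant *and* growth is lower — a
  significantly faster condition (as mild salinity changes can be) is
  a benign environmental shift, not stress.
- **Line classification** counts, per line, the conditions with
  significantly negative / positive / non-significant S_T; a line can
  appear in both direction aggregates across conditions.

## Mutation-rate bounds

Each line with a significant fitness difference from the control in at
least one condition is credited exactly one mutation, so
`U_min = n_significant / (n_lines × generations)` is a lower bound (no
deconvolution of multiple mutations is attempted, and epistasis within
a line is absorbed into its single credited effect). Per-site rates are
computed only when a genome size is supplied; genome sizes are user
inputs. The lethal-rate screen
`(lines lost / lines started)/generations` attributes every loss to a
lethal mutation and is therefore an upper bound; sampling losses and
division-failure losses inflate it, which is why the simulator records
a cause for every loss event.

## Simulator

The generator's defaults mirror the study conditions: 40 lines,
14-day intervals, transfers of N̄ = 10 cells with q = 0.4 split across
6 replicate wells, controls re-inoculated at 100 cells (24 replicates),
base rate 1 division/day (14 generations per interval, inside the
10–20 range typical of these algae), stress assays from ~50,000 cells
for 7 days with 3 MA / 4 control replicates.

Choices where the design was open:

- **Deterministic growth within intervals.** Division is near-daily and
  light-entrained, so demographic noise in a 14-day expansion from one
  cell is small relative to measurement noise; a deterministic core
  keeps the analytic loss oracle exact. (A stochastic birth process was
  considered and left out for exactly that reason.)
- **Mutation effects** act multiplicatively on divisions/day; benign
  effect sizes are exponential on the log scale (deleterious exp(−e),
  beneficial exp(+e)). Condition-specific log-effects are
  `correlation · l₀ + sd_condition · N(0,1)`, which spans all three
  stress-interaction categories (unconditionally deleterious,
  conditionally neutral, conditionally beneficial).
- **Lethal mutations** terminate the lineage at the bottleneck of the
  interval in which they arise (per-generation hazard λ·fraction_lethal
  via the Poisson mutation count), recorded as a zero-count observation
  with cause "lethal"; sampling failures record cause "sampling", so
  causes partition total losses.
- **Rescue rule:** the lowest-indexed well with ≥ 1 cell continues the
  line — deterministic for reproducibility.
- **Noise:** multiplicative log-normal with mean exactly 1 at the
  configured CV (σ² = ln(1+CV²), μ = −σ²/2).
- **Randomness:** one seed feeds named `SeedSequence` substreams
  (sampling, mutation, noise, reserved growth, assay), so e.g. the
  mutation history can be held fixed while noise varies.

What the simulator does *not* emulate: cell clumping or sedimentation
(the Poisson sampling assumption is exact by construction), volume-
dependent division failure, within-interval selection among replicate
wells, and measurement error structure beyond log-normal scatter.
Passing parameter-recovery tests therefore shows the pipeline is
correct under its own assumptions, not that real cultures satisfy them.

## Problem sizes and numerical checks

The test suite validates the closed forms against quadrature (≤ 1e−8),
binomial tails against exhaustive enumeration (≤ 12 trials), the
negative binomial against 10⁶ Monte-Carlo gamma-mixed Poisson draws
(3 SE), simulator loss frequencies against the analytic model over
~10⁴ transfer trials (3 binomial SE), planted DFE/GxE effects against
`(m−1)·ln 2` (3 SE of replicate noise), and family-wise error control
under a global null over 500 simulated mutation-free experiments
(≤ α + 3 SE at α = 0.01). These sizes keep the full suite under a
minute of compute while leaving the binomial standard errors small
relative to the effects asserted.

## Known limitations

- The binomial loss accounting uses lines started, not lines at risk
  (see above); exact accounting would require the survival trajectory.
- The minimum mutation rate collapses any number of mutations per line
  to one and so saturates at `1/generations` per line tested; it is
  informative only when most lines carry few detectable mutations.
- The lethal-rate screen is meaningful only if other loss causes have
  been bounded independently (e.g. via the sampling model).
- S_T assumes the control grows (G_control > 1); assays where the
  control fails to grow are rejected rather than extrapolated.
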