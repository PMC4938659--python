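"""Probability models for line loss at a single-cell bottleneck transfer.

In a liquid-culture mutation-accumulation (MA) experiment a line is
propagated by drawing a small volume calculated to contain on average
``N̄`` cells, splitting it across replicate wells and discarding the rest
of the culture.  Because the number of cells actually captured in the
volume is Poisson distributed, there is a non-zero probability that every
cell ends up in the discarded fraction ``q`` and the line is lost.

Two sampling models are provided:

* pure Poisson sampling — loss probability ``exp(-N̄ (1 - q))``;
* gamma-mixed Poisson sampling, where the pipetted volume deviates from
  its target by a multiplicative factor ``α ~ Gamma(mean 1, shape β)``
  with ``β = 1/CV²``.  The marginal cell count is then negative binomial
  and the loss probability has the closed form
  ``(1 + N̄ (1 - q) / β)^(-β)``.

On top of the per-transfer loss probability the module computes design
quantities for a whole experiment: the expected number of line losses
over ``n_lines × n_bottlenecks`` transfer trials and the binomial tail
probability of seeing at least ``k`` losses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "SamplingScheme",
    "ExperimentDesign",
    "LossModelResult",
    "loss_prob_poisson",
    "loss_prob_gamma",
    "negbin_pmf",
    "expected_losses",
    "prob_at_least_k_losses",
    "loss_model_result",
    "design_table",
]


@dataclass(frozen=True)
class SamplingScheme:
    """Parameters of the single-cell transfer protocol.

    Parameters
    ----------
    mean_cells_sampled:
        N̄, the expected number of cells in the extracted volume.
    discard_fraction:
        q, the proportion of the sample ultimately discarded.
    cv_volume:
        Coefficient of variation of the gamma-distributed volume factor α
        (mean 1, shape β = 1/CV²).  0 means exact pipetting.
    n_replicate_wells:
        Number of wells inoculated per line at each transfer.
    """

    mean_cells_sampled: float = 10.0
    discard_fraction: float = 0.4
    cv_volume: float = 0.0
    n_replicate_wells: int = 6

    def __post_init__(self) -> None:
        if self.mean_cells_sampled <= 0:
            raise ValueError("mean_cells_sampled must be > 0")
        if not 0.0 <= self.discard_fraction <= 1.0:
            raise ValueError("discard_fraction must be in [0, 1]")
        if self.cv_volume < 0:
            raise ValueError("cv_volume must be >= 0")
        if self.n_replicate_wells < 1:
            raise ValueError("n_replicate_wells must be >= 1")

    @property
    def shape(self) -> float:
        """Gamma shape β = 1/CV² of the volume factor (inf for CV = 0)."""
        cv_sq = self.cv_volume**2
        if cv_sq == 0.0:  # includes denormal CVs whose square underflows
            return math.inf
        return 1.0 / cv_sq


@dataclass(frozen=True)
class ExperimentDesign:
    """An MA experiment layout: lines, transfers, and the transfer scheme."""

    n_lines: int
    n_bottlenecks: int
    interval_days: float = 14.0
    scheme: SamplingScheme = field(default_factory=SamplingScheme)

    def __post_init__(self) -> None:
        if self.n_lines < 1 or self.n_bottlenecks < 1:
            raise ValueError("n_lines and n_bottlenecks must be >= 1")
        if self.interval_days <= 0:
            raise ValueError("interval_days must be > 0")

    @property
    def n_trials(self) -> int:
        """Transfer trials in the experiment: lines started × transfers."""
        return self.n_lines * self.n_bottlenecks


@dataclass(frozen=True)
class LossModelResult:
    """Per-bottleneck loss probability plus experiment-level expectations."""

    p_loss: float
    expected_losses: float
    tail_prob: float
    observed_losses: int | None = None


def loss_prob_poisson(mean_cells_sampled: float, discard_fraction: float) -> float:
    """Per-transfer line-loss probability under pure Poisson sampling.

    The cell count in the extracted volume is ``N ~ Poisson(N̄)`` and every
    cell is independently discarded with probability ``q``, so the line is
    lost when all cells are discarded:

        P(loss) = Σ_N Poisson(N; N̄) q^N = exp(-N̄ (1 - q))

    Examples
    --------
    >>> round(loss_prob_poisson(10, 0.4), 4)
    0.0025
    >>> round(loss_prob_poisson(1, 0.0), 2)
    0.37
    """
    if mean_cells_sampled <= 0:
        raise ValueError("mean_cells_sampled must be > 0")
    if not 0.0 <= discard_fraction <= 1.0:
        raise ValueError("discard_fraction must be in [0, 1]")
    return math.exp(-mean_cells_sampled * (1.0 - discard_fraction))


def loss_prob_gamma(scheme: SamplingScheme) -> float:
    """Per-transfer loss probability with gamma-distributed pipetting error.

    The sampled volume is off-target by a factor α ~ Gamma(mean 1,
    shape β = 1/CV²); marginally the cell count is negative binomial and

        P(loss) = Σ_N NegBin(N; N̄, β) q^N = (1 + N̄ (1 - q) / β)^(-β)

    which reduces to the Poisson result as CV → 0 and is always ≥ it:
    overdispersion puts extra mass on small samples.
    """
    beta = scheme.shape
    if math.isinf(beta):
        return loss_prob_poisson(scheme.mean_cells_sampled, scheme.discard_fraction)
    effective = scheme.mean_cells_sampled * (1.0 - scheme.discard_fraction)
    # log-space for numerical robustness at large beta
    return math.exp(-beta * math.log1p(effective / beta))


def negbin_pmf(n: int, mean_cells_sampled: float, shape: float) -> float:
    """Negative binomial pmf of the sampled cell count, mean N̄ and shape β.

    This is the marginal distribution of a Poisson count whose mean is
    scaled by a Gamma(mean 1, shape β) volume factor.  Parameterised so
    that ``scipy.stats.nbinom(β, β / (β + N̄))`` carries the mass.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if mean_cells_sampled <= 0:
        raise ValueError("mean_cells_sampled must be > 0")
    if shape <= 0:
        raise ValueError("shape must be > 0")
    p = shape / (shape + mean_cells_sampled)
    return float(stats.nbinom.pmf(n, shape, p))


def expected_losses(p_loss: float, n_lines: int, n_bottlenecks: int) -> float:
    """Expected number of line losses over ``n_lines × n_bottlenecks`` trials.

    Each line × transfer is treated as an independent Bernoulli trial with
    success (loss) probability ``p_loss``; lines are counted as started,
    not as surviving, so the trial count is lines × transfers.
    """
    if not 0.0 <= p_loss <= 1.0:
        raise ValueError("p_loss must be in [0, 1]")
    if n_lines < 1 or n_bottlenecks < 1:
        raise ValueError("n_lines and n_bottlenecks must be >= 1")
    return p_loss * n_lines * n_bottlenecks


def prob_at_least_k_losses(
    p_loss: float, n_lines: int, n_bottlenecks: int, k: int
) -> float:
    """P(L ≥ k) where L ~ Binomial(n_lines × n_bottlenecks, p_loss).

    Returns 1 for ``k = 0`` and 0 when ``k`` exceeds the trial count.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    n_trials = n_lines * n_bottlenecks
    if k == 0:
        return 1.0
    if k > n_trials:
        return 0.0
    return float(stats.binom.sf(k - 1, n_trials, p_loss))


def loss_model_result(
    design: ExperimentDesign, observed_losses: int | None = None
) -> LossModelResult:
    """Bundle p_loss, expected losses and the observed-loss tail for a design."""
    p = loss_prob_gamma(design.scheme)
    l_exp = expected_losses(p, design.n_lines, design.n_bottlenecks)
    tail = (
        prob_at_least_k_losses(p, design.n_lines, design.n_bottlenecks, observed_losses)
        if observed_losses is not None
        else float("nan")
    )
    return LossModelResult(p, l_exp, tail, observed_losses)


def design_table(
    base_scheme: SamplingScheme,
    cv_values: Sequence[float],
    designs: Iterable[tuple[str, int, int]],
    observed_losses: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Loss-design table across pipetting-error levels.

    One row per CV value; per design (label, n_lines, n_bottlenecks) two
    columns: the expected loss count and, if observed losses are supplied
    for the label, the binomial tail P(L ≥ L_obs).
    """
    designs = list(designs)
    observed_losses = observed_losses or {}
    rows = []
    for cv in cv_values:
        scheme = SamplingScheme(
            base_scheme.mean_cells_sampled,
            base_scheme.discard_fraction,
            cv,
            base_scheme.n_replicate_wells,
        )
        p = loss_prob_gamma(scheme)
        row: dict[str, float] = {"cv": cv, "p_loss": p}
        for label, n_lines, n_bn in designs:
            row[f"L_exp_{label}"] = expected_losses(p, n_lines, n_bn)
            if label in observed_losses:
                row[f"P_tail_{label}"] = prob_at_least_k_losses(
                    p, n_lines, n_bn, observed_losses[label]
                )
        rows.append(row)
    return pd.DataFrame(rows)
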