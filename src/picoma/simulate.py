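"""Synthetic MA experiments with a configurable DFE and GxE structure.

The simulator reproduces the statistical structure the analysis modules
assume, so every pipeline stage can be exercised without laboratory
data:

* lines founded from one cell, grown deterministically for a fixed
  interval at their current divisions/day rate, then bottlenecked by the
  single-cell transfer protocol (gamma volume factor, Poisson cell
  count, discard fraction, allocation across replicate wells);
* per-generation mutations drawn from a mixture DFE
  (lethal / deleterious / neutral / beneficial) whose non-lethal effects
  act multiplicatively on divisions/day, with condition-specific effect
  sizes correlated with the benign effect (GxE);
* control populations re-inoculated at 100 cells each interval;
* multiplicative log-normal measurement noise on cytometry counts.

Growth within an interval is deterministic exponential: these cultures
divide roughly once per day on a light cycle, and a deterministic core
keeps the analytic line-loss oracle exact.  All randomness flows from a
single seed through named substreams (growth, sampling, mutation,
noise), so one component can be varied with the others held fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lineloss import ExperimentDesign, SamplingScheme

__all__ = [
    "DFE",
    "GxE",
    "SimulationParams",
    "Mutation",
    "LossEvent",
    "SimulatedExperiment",
    "sample_dfe",
    "simulate_ma_experiment",
    "simulate_stress_assay",
]


@dataclass(frozen=True)
class DFE:
    """Mixture distribution of fitness effects of new mutations.

    Fractions are of all new mutations; the remainder is neutral.
    Non-lethal effect sizes are exponential on the log scale: a
    deleterious draw multiplies divisions/day by exp(-e) and a beneficial
    draw by exp(+e), with e ~ Exponential(mean effect).  Lethal
    mutations set divisions/day to zero in every condition.
    """

    fraction_lethal: float = 0.0
    fraction_deleterious: float = 0.0
    fraction_beneficial: float = 0.0
    mean_effect_deleterious: float = 0.1
    mean_effect_beneficial: float = 0.02

    def __post_init__(self) -> None:
        fractions = (
            self.fraction_lethal,
            self.fraction_deleterious,
            self.fraction_beneficial,
        )
        if any(not 0.0 <= f <= 1.0 for f in fractions) or sum(fractions) > 1.0 + 1e-12:
            raise ValueError("DFE fractions must be in [0,1] and sum to <= 1")
        if self.mean_effect_deleterious < 0 or self.mean_effect_beneficial < 0:
            raise ValueError("mean effects must be >= 0")

    @property
    def fraction_neutral(self) -> float:
        return 1.0 - (
            self.fraction_lethal + self.fraction_deleterious + self.fraction_beneficial
        )


@dataclass(frozen=True)
class GxE:
    """Condition-specific mutation effects and condition baselines.

    For each non-lethal mutation with benign log-effect l0, the
    log-effect in condition c is drawn as

        l_c = correlation * l0 + sd_condition * z_c,   z_c ~ N(0, 1)

    so correlation = 1, sd = 0 means effects transfer unchanged, while
    correlation <= 0 with sd > 0 produces conditionally beneficial or
    conditionally neutral mutations.  ``condition_baseline`` multiplies
    the base divisions/day of *every* genotype (controls included) in a
    condition — a value < 1 makes the condition stressful.
    """

    conditions: tuple[str, ...] = ()
    correlation: float = 1.0
    sd_condition: float = 0.0
    condition_baseline: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not -1.0 <= self.correlation <= 1.0:
            raise ValueError("correlation must be in [-1, 1]")
        if self.sd_condition < 0:
            raise ValueError("sd_condition must be >= 0")
        unknown = set(self.condition_baseline) - set(self.conditions)
        if unknown:
            raise ValueError(f"baselines for unknown conditions: {sorted(unknown)}")

    def baseline(self, condition: str) -> float:
        if condition not in self.conditions:
            raise KeyError(f"unknown condition label: {condition!r}")
        return self.condition_baseline.get(condition, 1.0)


@dataclass(frozen=True)
class SimulationParams:
    """Everything that drives a synthetic MA experiment.

    ``base_divisions_per_day`` is the wild-type division rate; 1.0 gives
    14 generations per 14-day interval, inside the 10–20 range typical
    of these cultures.  ``mutation_rate`` is U, mutations per genome per
    generation.  ``count_noise_cv`` is the CV of the multiplicative
    log-normal measurement noise applied to every recorded cell count.
    """

    design: ExperimentDesign = field(
        default_factory=lambda: ExperimentDesign(n_lines=40, n_bottlenecks=21)
    )
    base_divisions_per_day: float = 1.0
    mutation_rate: float = 0.0
    dfe: DFE = field(default_factory=DFE)
    gxe: GxE = field(default_factory=GxE)
    count_noise_cv: float = 0.0
    n_controls: int = 24
    control_inoculum: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_divisions_per_day <= 0:
            raise ValueError("base_divisions_per_day must be > 0")
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be >= 0")
        if self.count_noise_cv < 0:
            raise ValueError("count_noise_cv must be >= 0")
        if self.n_controls < 1 or self.control_inoculum < 1:
            raise ValueError("controls must number >= 1 at inoculum >= 1")


@dataclass(frozen=True)
class Mutation:
    """One mutation: its category and per-condition effect multipliers."""

    category: str  # lethal | deleterious | neutral | beneficial
    benign_effect: float  # multiplier on divisions/day in benign conditions
    condition_effects: dict[str, float]
    generation_acquired: float = 0.0
    line_id: str = ""

    def effect_in(self, condition: str | None) -> float:
        if self.category == "lethal":
            return 0.0
        if condition is None:
            return self.benign_effect
        try:
            return self.condition_effects[condition]
        except KeyError:
            raise KeyError(f"unknown condition label: {condition!r}") from None


@dataclass(frozen=True)
class LossEvent:
    line_id: str
    bottleneck: int
    cause: str  # "sampling" | "lethal"


@dataclass
class SimulatedExperiment:
    """A simulated MA experiment with full ground truth retained."""

    params: SimulationParams
    ma_records: pd.DataFrame
    control_records: pd.DataFrame
    mutations: dict[str, list[Mutation]]
    losses: list[LossEvent]
    n_transfer_trials: int

    @property
    def surviving_lines(self) -> list[str]:
        lost = {e.line_id for e in self.losses}
        return [l for l in self.mutations if l not in lost]

    def loss_counts(self) -> dict[str, int]:
        counts = {"sampling": 0, "lethal": 0}
        for event in self.losses:
            counts[event.cause] += 1
        return counts

    def to_bottleneck_table(self) -> pd.DataFrame:
        """MA and control records in the standard bottleneck-table layout."""
        return (
            pd.concat([self.ma_records, self.control_records], ignore_index=True)
            .sort_values(["is_control", "line_id", "bottleneck", "replicate"])
            .reset_index(drop=True)
        )


def _noise_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Multiplicative log-normal factors with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


def _draw_mutations(
    rng: np.random.Generator,
    dfe: DFE,
    gxe: GxE,
    n: int,
    generation: float = 0.0,
    line_id: str = "",
) -> list[Mutation]:
    categories = rng.choice(
        ["lethal", "deleterious", "beneficial", "neutral"],
        size=n,
        p=[
            dfe.fraction_lethal,
            dfe.fraction_deleterious,
            dfe.fraction_beneficial,
            dfe.fraction_neutral,
        ],
    )
    out: list[Mutation] = []
    for category in categories:
        if category == "lethal":
            out.append(
                Mutation(
                    "lethal",
                    0.0,
                    {c: 0.0 for c in gxe.conditions},
                    generation,
                    line_id,
                )
            )
            continue
        if category == "deleterious":
            log_effect = -rng.exponential(dfe.mean_effect_deleterious)
        elif category == "beneficial":
            log_effect = rng.exponential(dfe.mean_effect_beneficial)
        else:
            log_effect = 0.0
        condition_effects = {}
        for condition in gxe.conditions:
            l_c = gxe.correlation * log_effect + gxe.sd_condition * rng.standard_normal()
            condition_effects[condition] = math.exp(l_c)
        out.append(
            Mutation(
                category, math.exp(log_effect), condition_effects, generation, line_id
            )
        )
    return out


def sample_dfe(
    params: SimulationParams, n: int, seed: int | None = None
) -> list[Mutation]:
    """Draw n mutations from the configured DFE/GxE, independent of the run.

    With ``seed=None`` the draw uses a substream of ``params.seed`` so
    repeated calls with the same arguments are reproducible.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    base = params.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(base).spawn(1)[0])
    return _draw_mutations(rng, params.dfe, params.gxe, n)


def _transfer(
    rng: np.random.Generator, scheme: SamplingScheme
) -> tuple[bool, int]:
    """One single-cell transfer; returns (survived, continuing well index).

    Draws the volume factor, the Poisson cell count, the binomial discard
    and the allocation of kept cells to replicate wells.  The line
    survives when any well receives >= 1 cell; the continuing well is the
    lowest-index well with a cell (deterministic rescue rule).
    """
    alpha = (
        1.0
        if scheme.cv_volume == 0
        else rng.gamma(shape=scheme.shape, scale=1.0 / scheme.shape)
    )
    n_cells = rng.poisson(alpha * scheme.mean_cells_sampled)
    kept = rng.binomial(n_cells, 1.0 - scheme.discard_fraction) if n_cells else 0
    if kept == 0:
        return False, -1
    wells = rng.multinomial(
        kept, [1.0 / scheme.n_replicate_wells] * scheme.n_replicate_wells
    )
    return True, int(np.flatnonzero(wells)[0])


def simulate_ma_experiment(params: SimulationParams) -> SimulatedExperiment:
    """Run a full synthetic MA experiment.

    Per line and bottleneck: deterministic growth from one cell for the
    interval at the line's current (mutation-modified) divisions/day,
    Poisson-distributed new mutations over the generations elapsed, then
    the stochastic single-cell transfer.  A lethal mutation acquired in
    an interval terminates the line at that bottleneck (recorded cell
    count 0, cause "lethal"); sampling zero kept cells records cause
    "sampling".  Controls are re-inoculated at ``control_inoculum`` cells
    each interval and accumulate no mutations.  Fully reproducible from
    ``params.seed``.
    """
    design = params.design
    scheme = design.scheme
    streams = np.random.SeedSequence(params.seed).spawn(4)
    rng_sampling = np.random.default_rng(streams[0])
    rng_mutation = np.random.default_rng(streams[1])
    rng_noise = np.random.default_rng(streams[2])
    # streams[3] reserved for the optional stochastic-growth mode

    days = design.interval_days
    ma_rows: list[dict] = []
    mutations: dict[str, list[Mutation]] = {}
    losses: list[LossEvent] = []
    n_trials = 0

    for i in range(design.n_lines):
        line_id = f"L{i + 1:03d}"
        line_muts: list[Mutation] = []
        mutations[line_id] = line_muts
        multiplier = 1.0
        cum_gens = 0.0
        replicate = "w1"
        for b in range(1, design.n_bottlenecks + 1):
            rate = params.base_divisions_per_day * multiplier
            gens = rate * days
            final = 2.0**gens  # from one founding cell
            n_new = (
                rng_mutation.poisson(params.mutation_rate * gens)
                if params.mutation_rate > 0
                else 0
            )
            new_muts = _draw_mutations(
                rng_mutation, params.dfe, params.gxe, n_new, cum_gens + gens, line_id
            )
            line_muts.extend(new_muts)
            cum_gens += gens
            if any(m.category == "lethal" for m in new_muts):
                ma_rows.append(
                    {
                        "line_id": line_id,
                        "bottleneck": b,
                        "replicate": replicate,
                        "cells": 0,
                        "days": days,
                        "is_control": False,
                    }
                )
                losses.append(LossEvent(line_id, b, "lethal"))
                break
            observed = final * _noise_factors(rng_noise, params.count_noise_cv, 1)[0]
            ma_rows.append(
                {
                    "line_id": line_id,
                    "bottleneck": b,
                    "replicate": replicate,
                    "cells": int(round(observed)),
                    "days": days,
                    "is_control": False,
                }
            )
            for m in new_muts:
                multiplier *= m.benign_effect
            n_trials += 1
            survived, well = _transfer(rng_sampling, scheme)
            if not survived:
                losses.append(LossEvent(line_id, b, "sampling"))
                break
            replicate = f"w{well + 1}"

    control_rate = params.base_divisions_per_day
    control_final = params.control_inoculum * 2.0 ** (control_rate * days)
    control_rows: list[dict] = []
    for b in range(1, design.n_bottlenecks + 1):
        noise = _noise_factors(rng_noise, params.count_noise_cv, params.n_controls)
        for j in range(params.n_controls):
            control_rows.append(
                {
                    "line_id": f"C{j + 1:02d}",
                    "bottleneck": b,
                    "replicate": "w1",
                    "cells": int(round(control_final * noise[j])),
                    "days": days,
                    "is_control": True,
                }
            )

    columns = ["line_id", "bottleneck", "replicate", "cells", "days", "is_control"]
    return SimulatedExperiment(
        params=params,
        ma_records=pd.DataFrame(ma_rows, columns=columns),
        control_records=pd.DataFrame(control_rows, columns=columns),
        mutations=mutations,
        losses=losses,
        n_transfer_trials=n_trials,
    )


def simulate_stress_assay(
    experiment: SimulatedExperiment,
    conditions: list[str],
    params: SimulationParams | None = None,
    *,
    n_ma_replicates: int = 3,
    n_control_replicates: int = 4,
    inoculum_cells: float = 50_000,
    elapsed_days: float = 7.0,
) -> pd.DataFrame:
    """Grow surviving lines and controls in stress conditions for 7 days.

    Per condition × line × replicate, cells grow from ~50,000 at the
    line's condition-specific rate: base divisions/day × condition
    baseline multiplier × the product of the line's per-mutation effects
    in that condition.  Controls (no mutations) grow at baseline.
    Multiplicative log-normal count noise of the configured CV is applied
    per well.  Returns a table with columns condition, line_id,
    replicate, cells, is_control.
    """
    params = params or experiment.params
    for condition in conditions:
        params.gxe.baseline(condition)  # raises on unknown label
    rng = np.random.default_rng(
        np.random.SeedSequence(params.seed).spawn(5)[4]
    )
    rows: list[dict] = []
    for condition in sorted(conditions):
        baseline = params.gxe.baseline(condition)
        control_rate = params.base_divisions_per_day * baseline
        control_cells = inoculum_cells * 2.0 ** (control_rate * elapsed_days)
        noise = _noise_factors(rng, params.count_noise_cv, n_control_replicates)
        for r in range(n_control_replicates):
            rows.append(
                {
                    "condition": condition,
                    "line_id": "control",
                    "replicate": f"r{r + 1}",
                    "cells": control_cells * noise[r],
                    "is_control": True,
                }
            )
        for line_id in experiment.surviving_lines:
            multiplier = 1.0
            for m in experiment.mutations[line_id]:
                multiplier *= m.effect_in(condition)
            rate = params.base_divisions_per_day * baseline * multiplier
            line_cells = inoculum_cells * 2.0 ** (rate * elapsed_days)
            noise = _noise_factors(rng, params.count_noise_cv, n_ma_replicates)
            for r in range(n_ma_replicates):
                rows.append(
                    {
                        "condition": condition,
                        "line_id": line_id,
                        "replicate": f"r{r + 1}",
                        "cells": line_cells * noise[r],
                        "is_control": False,
                    }
                )
    return pd.DataFrame(
        rows, columns=["condition", "line_id", "replicate", "cells", "is_control"]
    )
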