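"""Fitness estimation from cell-count trajectories.

Fitness of a culture is summarised as the daily multiplicative growth
factor G ("divisions/day"): growth from a known inoculum to a final count
``N_t`` over ``t`` days gives ``G = exp(ln(N_t / N_0) / t)``, i.e. the
geometric mean daily fold change.  G = 2 means one division per day.

MA-line fitness is normalised per bottleneck against the mean control
growth factor measured at the same bottleneck (removing drift of the
experimental set-up through time), and differences are expressed as a
selection coefficient scaled by the control generation time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BottleneckRecord",
    "divisions_per_day",
    "relative_fitness",
    "selection_coefficient",
    "harmonic_mean_ne",
    "fitness_table",
    "relative_fitness_table",
]

STVariant = Literal["ratio", "product"]


@dataclass(frozen=True)
class BottleneckRecord:
    """One line × bottleneck × replicate cell-count observation."""

    line_id: str
    bottleneck_index: int
    replicate_id: str
    final_cells: int
    elapsed_days: float = 14.0
    is_control: bool = False
    inoculum_cells: int = 1

    def __post_init__(self) -> None:
        if self.final_cells < 0:
            raise ValueError("final_cells must be >= 0")
        if self.elapsed_days <= 0:
            raise ValueError("elapsed_days must be > 0")
        if self.inoculum_cells < 1:
            raise ValueError("inoculum_cells must be >= 1")

    @property
    def is_loss(self) -> bool:
        return self.final_cells == 0


def divisions_per_day(
    final_cells: float, elapsed_days: float, inoculum_cells: float = 1
) -> float:
    """Daily growth factor G = exp(ln(N_t / N_0) / t).

    Returns NaN for ``final_cells == 0`` (a loss observation, not an
    error); warns when the culture shrank below its inoculum (G < 1).

    >>> divisions_per_day(16384, 14)   # 2**14 cells from one cell
    2.0
    """
    if elapsed_days <= 0:
        raise ValueError("elapsed_days must be > 0")
    if inoculum_cells <= 0:
        raise ValueError("inoculum_cells must be > 0")
    if final_cells < 0:
        raise ValueError("final_cells must be >= 0")
    if final_cells == 0:
        return float("nan")
    if final_cells < inoculum_cells:
        warnings.warn(
            "final_cells below inoculum: growth factor < 1", stacklevel=2
        )
    return math.exp(math.log(final_cells / inoculum_cells) / elapsed_days)


def relative_fitness(g_ma: float, g_control_mean: float) -> float:
    """Relative fitness G_r = G_MA / mean control G at the same bottleneck."""
    if g_ma <= 0 or g_control_mean <= 0:
        raise ValueError("growth factors must be > 0")
    return g_ma / g_control_mean


def selection_coefficient(
    g_ma: float, g_control: float, variant: STVariant = "ratio"
) -> float:
    """Selection coefficient scaled by the control generation time, S_T.

    Default (``variant="ratio"``) reading:

        S_T = (ln G_MA - ln G_control) * ln 2 / ln G_control

    i.e. the difference of log daily growth rates per control generation
    (generations/day = ln G / ln 2 since G is the daily fold change).
    ``variant="product"`` instead divides by ``ln(G_control) * ln 2``.
    Both readings are zero at equality and share the sign of
    ``G_MA - G_control``.
    """
    if g_ma <= 0:
        raise ValueError("g_ma must be > 0")
    if g_control <= 1:
        raise ValueError("g_control must be > 1 (controls must grow)")
    diff = math.log(g_ma) - math.log(g_control)
    if variant == "ratio":
        return diff * math.log(2) / math.log(g_control)
    if variant == "product":
        return diff / (math.log(g_control) * math.log(2))
    raise ValueError(f"unknown S_T variant: {variant!r}")


def harmonic_mean_ne(census_sizes: Sequence[float]) -> float:
    """Harmonic-mean effective population size over a growth interval.

    N_e between bottlenecks is dominated by the smallest census sizes, so
    the harmonic mean n / Σ(1/N_i) is the appropriate average; it is
    always ≤ the arithmetic mean.
    """
    sizes = np.asarray(census_sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("census_sizes must be non-empty")
    if np.any(sizes <= 0):
        raise ValueError("census sizes must be > 0")
    return float(sizes.size / np.sum(1.0 / sizes))


def fitness_table(records: pd.DataFrame) -> pd.DataFrame:
    """Attach a divisions/day column ``g`` to a bottleneck-record table.

    Expects columns line_id, bottleneck, replicate, cells, days,
    is_control and optionally inoculum (default 1 for MA lines, 100 for
    controls).  Rows with cells = 0 keep NaN in ``g`` and are flagged
    ``is_loss``.
    """
    df = records.copy()
    if "inoculum" not in df.columns:
        df["inoculum"] = np.where(df["is_control"], 100, 1)
    df["is_loss"] = df["cells"] == 0
    with np.errstate(divide="ignore"):
        ratio = df["cells"].to_numpy(dtype=float) / df["inoculum"].to_numpy(dtype=float)
        g = np.exp(np.log(ratio) / df["days"].to_numpy(dtype=float))
    g[df["is_loss"].to_numpy()] = np.nan
    df["g"] = g
    return df


def relative_fitness_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-bottleneck control-normalised fitness for MA lines.

    Controls are averaged per bottleneck; each MA observation at that
    bottleneck is divided by that mean.  Returns the MA rows with columns
    ``g``, ``g_control_mean`` and ``g_r``, sorted by line and bottleneck.
    Bottlenecks without any control observation get NaN ``g_r``.
    """
    df = fitness_table(records)
    controls = df[df["is_control"] & ~df["is_loss"]]
    if controls.empty:
        warnings.warn("no control observations: relative fitness undefined")
    control_mean = controls.groupby("bottleneck")["g"].mean().rename("g_control_mean")
    ma = df[~df["is_control"]].merge(
        control_mean, left_on="bottleneck", right_index=True, how="left"
    )
    ma["g_r"] = ma["g"] / ma["g_control_mean"]
    return ma.sort_values(["line_id", "bottleneck", "replicate"]).reset_index(drop=True)
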