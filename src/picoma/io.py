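"""Readers, writers and the end-to-end report runner.

All tables are plain CSV (comma-separated, UTF-8, '.' decimal).  The two
input layouts are:

bottleneck table — one row per line × bottleneck × replicate:
    line_id, bottleneck, replicate, cells, days, is_control

stress-assay table — one row per condition × line × replicate:
    condition, line_id, replicate, cells, is_control

Rows with ``cells = 0`` are retained as loss observations, never
dropped.  Validation failures are hard errors naming the offending rows
(1-based data row numbers, header excluded).
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitness import fitness_table, relative_fitness_table
from .lineloss import ExperimentDesign, SamplingScheme, design_table
from .mutation_rates import min_mutation_rate
from .stats import (
    classify_lines,
    control_drift_anova,
    mean_trend,
    per_line_trend,
    st_significance_battery,
    variance_ratio_test,
)

__all__ = [
    "RunConfig",
    "read_bottleneck_table",
    "read_stress_table",
    "write_table",
    "run_report",
]

logger = logging.getLogger("picoma")

BOTTLENECK_COLUMNS = ["line_id", "bottleneck", "replicate", "cells", "days", "is_control"]
STRESS_COLUMNS = ["condition", "line_id", "replicate", "cells", "is_control"]


@dataclass
class RunConfig:
    """Configuration for a full analysis run.

    Loadable from YAML (``RunConfig.from_yaml``); CLI flags override file
    values.  ``st_variant`` selects the selection-coefficient reading and
    ``holm_family`` the multiple-testing family scope.
    """

    bottleneck_table: str | None = None
    stress_table: str | None = None
    output_dir: str = "picoma_report"
    mean_cells_sampled: float = 10.0
    discard_fraction: float = 0.4
    cv_values: tuple[float, ...] = (0.0, 0.05, 0.4, 0.5)
    n_replicate_wells: int = 6
    interval_days: float = 14.0
    alpha_selection: float = 0.01
    alpha_trend: float = 0.05
    st_variant: str = "ratio"
    holm_family: str = "condition"
    stress_inoculum_cells: float = 50_000.0
    stress_elapsed_days: float = 7.0
    reference_condition: str = "standard"
    genome_size_bp: int | None = None
    seed: int = 0
    precision_probability: int = 4
    precision_losses: int = 1

    def __post_init__(self) -> None:
        for alpha in (self.alpha_selection, self.alpha_trend):
            if not 0 < alpha < 1:
                raise ValueError("alpha levels must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "cv_values" in raw:
            raw["cv_values"] = tuple(raw["cv_values"])
        return cls(**raw)


def _validate(df: pd.DataFrame, required: list[str], key: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad = df.index[df["cells"] < 0]
    if len(bad):
        rows = [i + 1 for i in bad.tolist()]
        raise ValueError(f"{path}: negative cell counts at data rows {rows}")
    duplicated = df.duplicated(subset=key, keep=False)
    if duplicated.any():
        rows = [i + 1 for i in df.index[duplicated].tolist()]
        raise ValueError(f"{path}: duplicate {tuple(key)} keys at data rows {rows}")


def read_bottleneck_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a bottleneck-record CSV.

    Rows with cells = 0 are retained (loss events).  Missing columns,
    negative counts or duplicate (line, bottleneck, replicate) keys are
    hard errors with row numbers.
    """
    df = pd.read_csv(path)
    _validate(df, BOTTLENECK_COLUMNS, ["line_id", "bottleneck", "replicate"], path)
    if (df["days"] <= 0).any():
        rows = [i + 1 for i in df.index[df["days"] <= 0].tolist()]
        raise ValueError(f"{path}: non-positive days at data rows {rows}")
    df["is_control"] = df["is_control"].astype(bool)
    return df[list(dict.fromkeys(BOTTLENECK_COLUMNS + list(df.columns)))]


def read_stress_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a stress-assay CSV (same dialect, per-condition key)."""
    df = pd.read_csv(path)
    _validate(df, STRESS_COLUMNS, ["condition", "line_id", "replicate"], path)
    df["is_control"] = df["is_control"].astype(bool)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a CSV deterministically (no index, '\\n' line endings)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n")


def configure_logging(level: int = logging.INFO) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(level)


def run_report(config: RunConfig) -> dict[str, Path]:
    """Run the full pipeline and write the report bundle.

    Always emits the loss-design table; emits fitness series, trend
    tests, selection battery, variance tests and mutation-rate bounds
    when the corresponding inputs are present.  Outputs are sorted so a
    rerun with the same config and seed is byte-identical.  Returns a
    mapping of artefact names to paths.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artefacts: dict[str, Path] = {}

    def _stage(name):
        logger.info("stage: %s", name)

    scheme = SamplingScheme(
        config.mean_cells_sampled,
        config.discard_fraction,
        0.0,
        config.n_replicate_wells,
    )

    records = None
    if config.bottleneck_table:
        _stage("read bottleneck table")
        records = read_bottleneck_table(config.bottleneck_table)

    _stage("design table")
    designs = []
    if records is not None and not records.empty:
        ma = records[~records["is_control"]]
        if not ma.empty:
            designs.append(
                ("experiment", ma["line_id"].nunique(), int(ma["bottleneck"].max()))
            )
    if not designs:
        designs = [("experiment", 40, 21)]
        if records is not None:
            logger.warning("empty MA table: design table uses default 40 x 21 layout")
    design_df = design_table(scheme, list(config.cv_values), designs)
    design_df["p_loss"] = design_df["p_loss"].round(config.precision_probability)
    for col in design_df.columns:
        if col.startswith("L_exp_"):
            design_df[col] = design_df[col].round(config.precision_losses)
    artefacts["design"] = out / "design_table.csv"
    write_table(design_df, artefacts["design"])

    n_significant_lines = 0
    n_lines_tested = 0
    if records is not None and not records.empty:
        try:
            _stage("control drift ANOVA")
            controls = fitness_table(records[records["is_control"]])
            f_stat, p_val = control_drift_anova(controls)
            write_table(
                pd.DataFrame([{"f_statistic": f_stat, "p_value": p_val}]),
                out / "control_anova.csv",
            )
            artefacts["control_anova"] = out / "control_anova.csv"
        except ValueError as exc:
            logger.warning("control ANOVA skipped: %s", exc)

        _stage("fitness series")
        ma_table = relative_fitness_table(records)
        if ma_table.empty:
            logger.warning("no MA observations: fitness and trend sections empty")
        artefacts["fitness"] = out / "fitness_series.csv"
        write_table(ma_table, artefacts["fitness"])

        if not ma_table.empty:
            _stage("trend tests")
            ma_valid = ma_table.dropna(subset=["g_r"]).copy()
            # cumulative generations: control divisions/day x days x intervals elapsed
            ma_valid["generations"] = (
                np.log2(ma_valid["g_control_mean"])
                * ma_valid["days"]
                * ma_valid["bottleneck"]
            )
            trend_rows = []
            for line_id, sub in ma_valid.groupby("line_id", sort=True):
                if len(sub) < 3:
                    continue
                res = per_line_trend(sub["generations"], sub["g_r"], line_id)
                trend_rows.append(
                    {
                        "line_id": res.line_id,
                        "rho": res.rho,
                        "p_value": res.p_value,
                        "n_points": res.n_points,
                        "undefined": res.undefined,
                    }
                )
            if len(ma_valid["bottleneck"].unique()) >= 3:
                res = mean_trend(ma_valid)
                trend_rows.append(
                    {
                        "line_id": res.line_id,
                        "rho": res.rho,
                        "p_value": res.p_value,
                        "n_points": res.n_points,
                        "undefined": res.undefined,
                    }
                )
            artefacts["trends"] = out / "trend_tests.csv"
            write_table(pd.DataFrame(trend_rows), artefacts["trends"])

    if config.stress_table:
        _stage("stress battery")
        assay = read_stress_table(config.stress_table)
        selection = st_significance_battery(
            assay,
            alpha=config.alpha_selection,
            inoculum_cells=config.stress_inoculum_cells,
            elapsed_days=config.stress_elapsed_days,
            st_variant=config.st_variant,  # type: ignore[arg-type]
            family=config.holm_family,  # type: ignore[arg-type]
        )
        artefacts["selection"] = out / "selection_results.csv"
        write_table(selection, artefacts["selection"])
        classes = classify_lines(selection)
        artefacts["classification"] = out / "line_classification.csv"
        write_table(classes, artefacts["classification"])

        _stage("variance tests")
        ref = config.reference_condition
        conditions = sorted(selection["condition"].unique())
        if ref in conditions:
            var_rows = []
            by_cond = {c: g["s_t"].to_numpy() for c, g in selection.groupby("condition")}
            for cond in conditions:
                if cond == ref or len(by_cond[cond]) < 2 or len(by_cond[ref]) < 2:
                    continue
                res = variance_ratio_test(by_cond[cond], by_cond[ref], cond, ref)
                var_rows.append(
                    {
                        "condition": res.condition,
                        "reference": res.reference_condition,
                        "f_statistic": res.f_statistic,
                        "p_value": res.p_value,
                    }
                )
            artefacts["variance"] = out / "variance_tests.csv"
            write_table(pd.DataFrame(var_rows), artefacts["variance"])
        else:
            logger.warning("reference condition %r absent: variance tests skipped", ref)

        _stage("mutation rate bounds")
        if not classes.empty:
            per_line_sig = (classes["n_negative"] > 0) | (classes["n_positive"] > 0)
            n_significant_lines = int(per_line_sig.sum())
            n_lines_tested = int(len(classes))
            if records is not None and not records.empty:
                ma = fitness_table(records[~records["is_control"]])
                gens = (
                    ma.dropna(subset=["g"])
                    .assign(gen=lambda d: np.log2(d["g"]) * d["days"])
                    .groupby("line_id")["gen"]
                    .sum()
                    .mean()
                )
            else:
                gens = float("nan")
            if gens and gens == gens:
                estimate = min_mutation_rate(
                    n_significant_lines, n_lines_tested, gens, config.genome_size_bp
                )
                artefacts["mutation_rate"] = out / "mutation_rate.csv"
                write_table(
                    pd.DataFrame(
                        [
                            {
                                "u_genome": estimate.u_genome,
                                "u_site": estimate.u_site,
                                "n_implied_mutations": estimate.n_implied_mutations,
                                "n_lines": estimate.n_lines,
                                "generations_per_line": estimate.generations_per_line,
                                "is_lower_bound": estimate.is_lower_bound,
                            }
                        ]
                    ),
                    artefacts["mutation_rate"],
                )

    _stage("run log")
    log_lines = [f"picoma {__version__}", f"seed {config.seed}"]
    log_lines += [f"{k} = {v}" for k, v in sorted(vars(config).items())]
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    artefacts["run_log"] = out / "run_log.txt"
    return artefacts
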