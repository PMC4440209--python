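"""End-to-end analysis pipeline.

Simulate (or ingest) a cohort table, fit the critical-power model per
participant, build one correlation-thresholded network per effort
intensity, compute influence metrics and the across-intensity group
statistics, and assemble everything into a deterministic report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .cp import CPParameters, PowerTimeSeries, fit_hyperbolic, fit_linearized
from .group_stats import compare_variable, comparisons_to_frame
from .metrics import compute_metrics, rank_nodes
from .network import DEFAULT_THRESHOLDS, build_network, records_to_frame
from .synthetic import GeneratorConfig, generate_cohort
from .variables import ALL_VARIABLES, ID_COLUMNS, INTENSITY_VARIABLES, canonical_column

__all__ = ["PipelineConfig", "read_cohort", "write_cohort", "run_pipeline", "write_report"]

logger = logging.getLogger("fatiguenet")


@dataclass(frozen=True)
class PipelineConfig:
    """Run-wide settings; ``generator`` is used when input is simulated."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    weight_mode: str = "raw"
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
    betweenness_counting: str = "fractional"
    cp_method: str = "hyperbolic"  # hyperbolic | linearized
    alpha: float = 0.05
    stats_variables: tuple[str, ...] = INTENSITY_VARIABLES
    #: node set for the networks; None means every canonical variable present
    variables: tuple[str, ...] | None = None

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        gen_raw = raw.pop("generator", {})
        if "correlation_targets" in gen_raw and gen_raw["correlation_targets"]:
            gen_raw["correlation_targets"] = {
                int(i): np.asarray(m, dtype=float)
                for i, m in gen_raw["correlation_targets"].items()
            }
        if "intensity_stats" in gen_raw:
            gen_raw["intensity_stats"] = {
                int(i): {v: tuple(ms) for v, ms in s.items()}
                for i, s in gen_raw["intensity_stats"].items()
            }
        if "subject_stats" in gen_raw:
            gen_raw["subject_stats"] = {
                v: tuple(ms) for v, ms in gen_raw["subject_stats"].items()
            }
        if "intensities" in gen_raw:
            gen_raw["intensities"] = tuple(gen_raw["intensities"])
        generator = GeneratorConfig(**gen_raw)
        if "thresholds" in raw:
            raw["thresholds"] = tuple(raw["thresholds"])
        if "stats_variables" in raw:
            raw["stats_variables"] = tuple(raw["stats_variables"])
        if raw.get("variables") is not None:
            raw["variables"] = tuple(raw["variables"])
        return cls(generator=generator, **raw)

    def provenance(self) -> dict:
        blob = json.dumps(
            {
                "generator": self.generator.to_json(),
                "weight_mode": self.weight_mode,
                "thresholds": list(self.thresholds),
                "betweenness_counting": self.betweenness_counting,
                "cp_method": self.cp_method,
                "alpha": self.alpha,
                "stats_variables": list(self.stats_variables),
                "variables": None if self.variables is None else list(self.variables),
            },
            sort_keys=True,
        )
        return {
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "seed": self.generator.seed,
            "weight_mode": self.weight_mode,
            "thresholds": list(self.thresholds),
            "version": __version__,
        }


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format cohort CSV.

    Headers are mapped through the documented aliases; the table must form
    a complete participant x intensity grid with numeric measurements.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    df = df.rename(columns={c: canonical_column(c) for c in df.columns})
    missing = [c for c in list(ID_COLUMNS) + list(ALL_VARIABLES) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ALL_VARIABLES:
        values = pd.to_numeric(df[col], errors="coerce")
        if values.isna().any():
            row = int(values.index[values.isna()][0])
            raise ValueError(f"{path}: non-numeric value at row {row}, column {col!r}")
        df[col] = values.astype(float)
    _check_complete_grid(df)
    return df[list(ID_COLUMNS) + list(ALL_VARIABLES)]


def _check_complete_grid(df: pd.DataFrame) -> None:
    participants = df["participant_id"].unique()
    intensities = df["intensity"].unique()
    counts = df.groupby(["participant_id", "intensity"], sort=False).size()
    for p in participants:
        for i in intensities:
            if (p, i) not in counts.index:
                raise ValueError(f"missing cell: participant {p!r} at intensity {i!r}")
            if counts[(p, i)] > 1:
                raise ValueError(f"duplicate cell: participant {p!r} at intensity {i!r}")


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def _fit_cp_per_participant(
    cohort: pd.DataFrame, method: str
) -> dict[str, CPParameters | None]:
    """Fit the power-duration hyperbola to each participant's trials."""
    fits: dict[str, CPParameters | None] = {}
    for pid, rows in cohort.groupby("participant_id", sort=True):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                series = PowerTimeSeries(
                    tuple(rows["power_mean"]), tuple(rows["time_limit"])
                )
                if method == "linearized":
                    fits[str(pid)] = fit_linearized(series)
                else:
                    fits[str(pid)] = fit_hyperbolic(series)
        except (ValueError, RuntimeError) as exc:
            logger.warning("CP fit failed for participant %s: %s", pid, exc)
            fits[str(pid)] = None
    return fits


def run_pipeline(
    config: PipelineConfig | None = None,
    input: str | Path = "simulate",
    outdir: str | Path | None = None,
) -> dict:
    """Execute all stages and return the report dictionary.

    ``input`` is either the string ``"simulate"`` (use the configured
    generator) or a cohort CSV path. When ``outdir`` is given, the report
    JSON, a full-precision sidecar, and per-intensity link/metric CSVs are
    written there. Identical config and seed give byte-identical outputs.
    """
    config = config or PipelineConfig()
    if isinstance(input, (str, Path)) and str(input) == "simulate":
        cohort = generate_cohort(config.generator)
        source = "simulate"
    else:
        cohort = read_cohort(input)
        source = str(input)
    intensities = list(dict.fromkeys(cohort["intensity"]))
    logger.info("cohort: %d rows, %d intensities", len(cohort), len(intensities))

    cp_fits = _fit_cp_per_participant(cohort, config.cp_method)

    summaries = []
    artifacts: dict[str, pd.DataFrame] = {}
    n_participants = cohort["participant_id"].nunique()
    if n_participants <= 12:
        logger.warning(
            "n=%d participants: |r| >= %.2f arises easily by chance; "
            "expect spurious links",
            n_participants,
            config.thresholds[0],
        )
    for intensity in intensities:
        block = cohort[cohort["intensity"] == intensity]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            matrix, records = build_network(
                block,
                mode=config.weight_mode,
                thresholds=config.thresholds,
                variables=config.variables,
                intensity=intensity,
            )
        table = compute_metrics(matrix, counting=config.betweenness_counting)
        ranks = rank_nodes(table)
        logger.info(
            "intensity %s: %d links, hub=%s", intensity, matrix.n_links, ranks["hub"]
        )
        summaries.append(
            {
                "intensity": intensity,
                "n_links": matrix.n_links,
                "mean_time_limit": float(block["time_limit"].mean()),
                "hub_nodes": list(ranks["hub"]),
                "max_eigen_nodes": list(ranks["max_eigen"]),
                "max_betweenness_nodes": list(ranks["max_betweenness"]),
                "spectral_radius": table.spectral_radius,
                "stability": table.stability,
            }
        )
        artifacts[f"links_intensity_{intensity}.csv"] = records_to_frame(records)
        artifacts[f"metrics_intensity_{intensity}.csv"] = table.per_node.rename_axis(
            "node"
        ).reset_index()

    comparisons = [
        compare_variable(
            var,
            [
                cohort.loc[cohort["intensity"] == i, var].to_numpy()
                for i in intensities
            ],
            alpha=config.alpha,
        )
        for var in config.stats_variables
    ]
    artifacts["group_stats.csv"] = comparisons_to_frame(comparisons)

    report = {
        "provenance": {**config.provenance(), "input": source},
        "intensity_summaries": summaries,
        "cp_parameters": {
            pid: (
                None
                if fit is None
                else {
                    "critical_power_w": fit.critical_power,
                    "anaerobic_work_capacity_kj": fit.anaerobic_work_capacity / 1000.0,
                    "fit_method": fit.fit_method,
                    "rss": fit.residual_sum_squares,
                }
            )
            for pid, fit in cp_fits.items()
        },
        "group_stats": [
            {
                "variable": c.variable,
                "F": c.F_statistic,
                "p": c.p_value,
                "letters": list(c.posthoc_letters),
            }
            for c in comparisons
        ],
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_report(report, outdir / "report.json")
        for name, frame in artifacts.items():
            frame.to_csv(outdir / name, index=False, float_format="%.10g")
    return report


def _round_floats(obj, sig: int = 6):
    if isinstance(obj, float):
        if obj != obj or obj in (float("inf"), float("-inf")):
            return repr(obj)
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    return obj


def write_report(report: Mapping, path: str | Path) -> None:
    """Write the report JSON (6 significant digits) plus a full-precision sidecar."""
    path = Path(path)
    path.write_text(json.dumps(_round_floats(dict(report)), indent=2, sort_keys=True))
    sidecar = path.with_suffix(".full.json")
    sidecar.write_text(json.dumps(dict(report), indent=2, sort_keys=True))
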