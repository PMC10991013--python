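"""File interfaces and the end-to-end analysis pipeline.

All inputs and outputs are plain delimited text (TSV), the lingua franca of
clinical-research data exchange:

* **item configuration** — one row per item with columns ``item_id``,
  ``item_type``, ``n_doors``, ``correct_door``, ``updating_doors``,
  ``rotation_doors`` (door sets as semicolon-separated 1-based integers) and
  optional ``is_main``;
* **responses** — long format ``participant_id, item_id, chosen_door``;
* **covariates** — wide table keyed by ``participant_id`` with empty cells
  for missing values (missingness is preserved, never filled).

Report writers round half-up to two decimals; machine-readable JSON outputs
keep full precision.  Every report directory carries a run log with the
seed, a configuration hash, and package versions, so reruns are
reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .association import association_battery
from .diagnostics import adjusted_boxplot, describe, floor_ceiling, sd_rule_outliers
from .item_analysis import item_analysis_table
from .model_selection import aic_backward, reduce_by_p
from .reliability import alpha_pipeline
from .scoring import ConfigurationError, ItemConfig, expected_item_score, score_participant

__all__ = [
    "AnalysisConfig",
    "read_item_config",
    "write_item_config",
    "read_responses",
    "read_covariates",
    "write_cohort",
    "score_table",
    "round_half_up",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of the printed reports)."""
    if not math.isfinite(x):
        return x
    factor = 10**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def _parse_door_set(cell) -> frozenset[int]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
        return frozenset()
    return frozenset(int(tok) for tok in str(cell).split(";") if tok.strip())


def read_item_config(path: str | Path) -> tuple[ItemConfig, ...]:
    """Read and validate an item-configuration TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"item_id", "item_type", "n_doors", "correct_door"}
    if not required <= set(df.columns):
        raise ConfigurationError(f"missing columns: {sorted(required - set(df.columns))}")
    configs = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            configs.append(
                ItemConfig(
                    item_id=row.item_id,
                    item_type=row.item_type,
                    n_doors=int(row.n_doors),
                    correct_door=int(row.correct_door),
                    updating_doors=_parse_door_set(getattr(row, "updating_doors", None)),
                    rotation_doors=_parse_door_set(getattr(row, "rotation_doors", None)),
                    is_main=str(getattr(row, "is_main", "true")).lower()
                    in ("true", "1", "yes"),
                )
            )
        except (ValueError, ConfigurationError) as exc:
            raise ConfigurationError(f"{path}, line {lineno}: {exc}") from exc
    return tuple(configs)


def write_item_config(configs: Sequence[ItemConfig], path: str | Path) -> None:
    rows = [
        {
            "item_id": c.item_id,
            "item_type": c.item_type.value,
            "n_doors": c.n_doors,
            "correct_door": c.correct_door,
            "updating_doors": ";".join(map(str, sorted(c.updating_doors))),
            "rotation_doors": ";".join(map(str, sorted(c.rotation_doors))),
            "is_main": str(c.is_main).lower(),
        }
        for c in configs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_responses(path: str | Path) -> pd.DataFrame:
    """Long-format responses; duplicate (participant, item) rows are rejected."""
    df = pd.read_csv(path, sep="\t", dtype={"participant_id": str, "item_id": str})
    required = {"participant_id", "item_id", "chosen_door"}
    if not required <= set(df.columns):
        raise ValueError(f"missing columns: {sorted(required - set(df.columns))}")
    dup = df.duplicated(["participant_id", "item_id"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            f"duplicate response: participant {first.participant_id!r}, "
            f"item {first.item_id!r}"
        )
    df["chosen_door"] = df["chosen_door"].astype(int)
    return df


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Wide covariate battery; empty cells stay missing (NaN)."""
    df = pd.read_csv(path, sep="\t", dtype={"participant_id": str})
    if "participant_id" not in df.columns:
        raise ValueError("covariate table needs a participant_id column")
    if df["participant_id"].duplicated().any():
        raise ValueError("duplicate participant_id rows in covariate table")
    return df.set_index("participant_id")


def write_cohort(cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated cohort in the same formats the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "items": out / "items.tsv",
        "responses": out / "responses.tsv",
        "covariates": out / "covariates.tsv",
    }
    write_item_config([ip.config for ip in cohort.config.items], paths["items"])
    cohort.responses.to_csv(paths["responses"], sep="\t", index=False)
    cohort.covariates.reset_index().to_csv(paths["covariates"], sep="\t", index=False)
    return paths


def score_table(
    configs: Sequence[ItemConfig], responses: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a long response table.

    Returns (participant summary with total and error counts,
    participants x items score matrix).
    """
    from .scoring import score_response

    by_id = {c.item_id: c for c in configs}
    main_ids = [c.item_id for c in configs if c.is_main]
    part_rows, score_rows = [], []
    for pid, grp in responses.groupby("participant_id", sort=False):
        pairs = list(zip(grp["item_id"], grp["chosen_door"]))
        ps = score_participant(configs, pairs, pid)
        part_rows.append(
            {
                "participant_id": pid,
                "total": ps.total,
                "n_updating": ps.n_updating,
                "n_rotation": ps.n_rotation,
                "n_items_scored": ps.n_items_scored,
            }
        )
        row = {"participant_id": pid}
        for item_id, door in pairs:
            if by_id[item_id].is_main:
                row[item_id] = score_response(by_id[item_id], door, pid).points
        score_rows.append(row)
    summary = pd.DataFrame(part_rows).set_index("participant_id")
    scores = pd.DataFrame(score_rows).set_index("participant_id")
    return summary, scores.reindex(columns=main_ids)


@dataclass
class AnalysisConfig:
    """Configuration of a full pipeline run."""

    items_path: str
    responses_path: str
    covariates_path: str | None = None
    out_dir: str = "vienna_out"
    seed: int = 0
    variance_threshold: float | None = 0.05
    n_boot: int = 200
    outlier_method: str = "sd_rule"  # for the total score
    bh_family: str = "per_column"
    sign_map: dict[str, int] = field(default_factory=dict)
    battery: list[str] = field(default_factory=list)
    composite_components: list[str] = field(default_factory=list)
    predictors: list[str] = field(default_factory=list)
    outcome: str = "vienna_total"

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if pd.api.types.is_float_dtype(out[c]):
            out[c] = out[c].map(lambda v: round_half_up(v, 2))
    return out


def run_pipeline(config: AnalysisConfig) -> dict[str, object]:
    """Score -> diagnostics -> item analysis -> reliability -> associations
    -> regression, writing one report per stage plus a run log.

    Stages that need inputs the configuration does not provide (e.g. no
    covariate battery) are skipped with a log entry rather than failing.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, object] = {}

    configs = read_item_config(config.items_path)
    responses = read_responses(config.responses_path)
    summary, scores = score_table(configs, responses)
    summary.to_csv(out / "scores.tsv", sep="\t")
    results["scores"] = summary

    # Table-1-style distribution diagnostics
    diag_rows = {}
    for name, col in (
        ("vienna_total", summary["total"]),
        ("rotation_errors", summary["n_rotation"]),
        ("updating_errors", summary["n_updating"]),
    ):
        diag_rows[name] = dataclasses.asdict(describe(col.to_numpy()))
    diag = pd.DataFrame(diag_rows).T
    _fmt(diag).to_csv(out / "table1_descriptives.tsv", sep="\t")
    results["diagnostics"] = diag

    max_possible = 2 * sum(c.is_main for c in configs)
    results["floor_ceiling"] = floor_ceiling(summary["total"], 0, max_possible)
    if config.outlier_method == "adjusted_boxplot":
        rep = adjusted_boxplot(summary["total"], ids=summary.index)
    else:
        rep = sd_rule_outliers(summary["total"], ids=summary.index)
    results["outliers"] = rep

    expected = {c.item_id: float(expected_item_score(c)) for c in configs if c.is_main}
    typology = {c.item_id: c.item_type for c in configs if c.is_main}
    items_tab = item_analysis_table(scores, typology, expected)
    order = ["item_type", "difficulty_ratio", "mean", "expected",
             "freq0", "freq1", "freq2", "variance", "wilson_e"]
    _fmt(items_tab[order]).to_csv(out / "table2_items.tsv", sep="\t")
    results["items"] = items_tab

    rel = {}
    try:
        rel["all_items"] = alpha_pipeline(
            scores, None, n_boot=config.n_boot, seed=config.seed
        )
        if config.variance_threshold is not None:
            rel["variance_filtered"] = alpha_pipeline(
                scores, config.variance_threshold,
                n_boot=config.n_boot, seed=config.seed,
            )
    except ValueError as exc:
        logger.warning("reliability stage skipped: %s", exc)
    results["reliability"] = rel
    with open(out / "reliability.json", "w") as fh:
        json.dump(
            {k: dataclasses.asdict(v) for k, v in rel.items()}, fh, indent=2
        )

    if config.covariates_path:
        cov = read_covariates(config.covariates_path)
        data = cov.join(summary[["total"]].rename(columns={"total": config.outcome}),
                        how="inner") if config.outcome not in cov.columns else cov
        battery = config.battery or [
            c for c in data.columns
            if c not in (config.outcome, "rotation_errors", "updating_errors")
            and pd.api.types.is_numeric_dtype(data[c])
        ]
        table3 = association_battery(
            data,
            outcome=config.outcome,
            variables=battery,
            age="age" if "age" in data.columns else None,
            composite_components=config.composite_components or None,
            sign_map=config.sign_map,
            bh_family=config.bh_family,
        )
        _fmt(table3).to_csv(out / "table3_associations.tsv", sep="\t")
        results["associations"] = table3

        predictors = config.predictors or [
            c for c in battery if c in data.columns and c != config.outcome
        ]
        X = data[predictors].astype(float)
        y = data[config.outcome].astype(float)
        trace = reduce_by_p(y, X)
        aic_model = aic_backward(y, X)
        _fmt(trace.final.coef).to_csv(out / "table4_regression.tsv", sep="\t")
        with open(out / "regression_trace.json", "w") as fh:
            json.dump(
                {
                    "steps": [dataclasses.asdict(s) for s in trace.steps],
                    "stop_reason": trace.stop_reason,
                    "final_predictors": list(trace.final.predictors),
                    "final_r_squared": trace.final.r_squared,
                    "aic_predictors": list(aic_model.predictors),
                    "selection_paths_agree": set(trace.final.predictors)
                    == set(aic_model.predictors),
                },
                fh,
                indent=2,
            )
        results["regression"] = trace
        results["regression_aic"] = aic_model
    else:
        logger.info("no covariate table configured; association and "
                    "regression stages skipped")

    log = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "stages": sorted(results.keys()),
    }
    with open(out / "run_log.jsonl", "w") as fh:
        fh.write(json.dumps(log, sort_keys=True) + "\n")
    results["run_log"] = log
    return results
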