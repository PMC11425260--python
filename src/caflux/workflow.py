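"""End-to-end orchestration, trace I/O, and run configuration.

A run ties the stages together: generate (or load) a cohort of traces,
featurize every cell, and compare conditions with the gated statistics.
Every artifact is stamped with the resolved configuration hash, the seed,
and the package version; identical configurations yield byte-identical
CSV/JSON artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .errors import FormatError, ValidationError
from .features import FeaturizerSettings, Trace, featurize_cohort
from .stats import ComparisonResult, compare_conditions
from .synth import CellCohort, GeneratorConfig, generate_cohort

__all__ = [
    "RunConfig",
    "run_pipeline",
    "read_traces",
    "write_traces",
    "write_cohort",
    "resolved_config_dict",
    "config_hash",
]

logger = logging.getLogger("caflux")

TRACE_COLUMNS = ("cell_id", "condition", "t_s", "value")


@dataclass(frozen=True)
class RunConfig:
    """Fully explicit pipeline configuration.

    All defaults are materialized at construction, so hashing the dict form
    captures every setting that can influence an artifact.
    """

    generator: GeneratorConfig
    featurizer: FeaturizerSettings = FeaturizerSettings()
    cohort_mode: str = "parametric"
    alpha: float = 0.05
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("RunConfig.seed is mandatory")
        if self.generator.seed is None:
            object.__setattr__(
                self, "generator", dataclasses.replace(self.generator, seed=self.seed)
            )
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        gen = GeneratorConfig(**d.get("generator", {}))
        feat = FeaturizerSettings(**d.get("featurizer", {}))
        return cls(
            generator=gen,
            featurizer=feat,
            cohort_mode=d.get("cohort_mode", "parametric"),
            alpha=d.get("alpha", 0.05),
            seed=d.get("seed"),
        )


def resolved_config_dict(config: RunConfig) -> dict:
    return {
        "package": "caflux",
        "version": __version__,
        "seed": config.seed,
        "cohort_mode": config.cohort_mode,
        "alpha": config.alpha,
        "generator": config.generator.to_dict(),
        "featurizer": dataclasses.asdict(config.featurizer),
    }


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(resolved_config_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_traces(traces: list[Trace], path: Path | str) -> None:
    """Write traces as a long-format CSV (cell_id, condition, t_s, value).

    Time is written with 6-decimal precision; values use shortest-repr
    serialization so a read round-trips to the same float64 bits.
    """
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "condition": tr.condition if tr.condition is not None else "",
                    "t_s": [f"{t:.6f}" for t in tr.times],
                    "value": [repr(float(v)) for v in tr.values],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_cohort(cohort: CellCohort, directory: Path | str) -> None:
    """Write a cohort as traces CSV + ground-truth JSON + config JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_traces(cohort.traces, directory / "cohort.csv")
    _json_dump([gt.to_dict() for gt in cohort.ground_truth], directory / "ground_truth.json")
    _json_dump(cohort.config.to_dict(), directory / "generator_config.json")


def read_traces(path: Path | str) -> list[Trace]:
    """Read a long-format trace CSV back into a list of traces.

    Validates the column set, per-cell uniform sampling, and uniqueness of
    (cell_id, t_s); errors name the first offending row or cell.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise FormatError(f"empty input file: {path}")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if df.empty:
        raise FormatError(f"input file {path} contains no data rows")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    dup = df.duplicated(subset=["cell_id", "t_s"])
    if dup.any():
        row = int(np.nonzero(dup.to_numpy())[0][0])
        raise FormatError(f"{path}: duplicate (cell_id, t_s) at data row {row}")
    traces = []
    for cell_id, sub in df.groupby("cell_id", sort=False):
        cond = sub["condition"].iloc[0]
        cond = None if (pd.isna(cond) or cond == "") else str(cond)
        try:
            traces.append(
                Trace(
                    sub["t_s"].to_numpy(float),
                    sub["value"].to_numpy(float),
                    cell_id=str(cell_id),
                    condition=cond,
                )
            )
        except (ValidationError, FormatError) as exc:
            raise FormatError(f"{path}: cell {cell_id!r}: {exc}") from exc
    return traces


def _comparison_report(results: list[ComparisonResult]) -> str:
    lines = ["caflux comparison report", "=" * 40]
    for res in results:
        lines.append(f"\nfeature: {res.feature}")
        lines.append(f"  omnibus: {res.omnibus['test']} p={res.omnibus['p']:.4g}")
        for _, row in res.pairwise.iterrows():
            mark = "*" if row["reject"] else " "
            lines.append(
                f"  {mark} {row['group_a']} vs {row['group_b']}: p_adj={row['p_adj']:.4g}"
            )
        for entry in res.procedure_log:
            lines.append(f"    log: {entry}")
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig, out_dir: Path | str) -> Path:
    """Run cohort generation → featurization → comparison; return the run dir.

    The run directory is named from the config hash and is never reused: a
    numeric suffix is appended when it already exists.  Artifacts:
    cohort.csv, ground_truth.json, features.csv, comparison.json, report.txt,
    config.json, run.log.
    """
    chash = config_hash(config)
    base = Path(out_dir)
    run_dir = base / f"run-{chash}"
    suffix = 0
    while run_dir.exists():
        suffix += 1
        run_dir = base / f"run-{chash}-{suffix}"
    run_dir.mkdir(parents=True)

    log_path = run_dir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        resolved = resolved_config_dict(config)
        resolved["config_hash"] = chash
        _json_dump(resolved, run_dir / "config.json")
        logger.info("resolved config: %s", json.dumps(resolved, sort_keys=True))

        stage = "cohort generation"
        try:
            cohort = generate_cohort(config.generator, mode=config.cohort_mode)
            write_cohort(cohort, run_dir)
            logger.info("generated %d traces", len(cohort))

            stage = "featurization"
            table = featurize_cohort(cohort.traces, config.featurizer)
            table.insert(0, "config_hash", chash)
            table.to_csv(run_dir / "features.csv", index=False)
            logger.info("featurized %d cells", len(table))

            stage = "comparison"
            results = compare_conditions(table, alpha=config.alpha)
            _json_dump(
                {
                    "config_hash": chash,
                    "version": __version__,
                    "results": [r.to_dict() for r in results],
                },
                run_dir / "comparison.json",
            )
            (run_dir / "report.txt").write_text(_comparison_report(results))
            logger.info("compared %d features", len(results))
        except Exception as exc:
            logger.error("stage %r failed: %s", stage, exc)
            raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    return run_dir
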