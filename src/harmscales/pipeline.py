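"""Configured pipeline: simulate -> prepare -> impute -> score -> evaluate ->
report, plus the count-level entry point.

``run`` executes the whole evaluation from a :class:`PipelineConfig` (YAML or
programmatic) and writes delimited-text artefacts: category-by-outcome count
tables, accuracy tables for both outcomes, the subgroup AUC table with
homogeneity p-values, per-scale ROC point files, a text summary and a JSON
sidecar with full-precision values and a config echo.

``table_from_counts`` bypasses episode data entirely: category-by-outcome
counts go straight through the two-by-two construction and the accuracy
battery, which is how published count tables can be re-analysed exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .accuracy import (
    WILSON,
    Comparison,
    accuracy_metrics,
    build_two_by_two,
)
from .evaluation import (
    ABSENT_RULE_MICE,
    ScaleAccuracy,
    ScaleAccuracyResults,
    default_comparisons,
)
from .missingness import ImputationConfig
from .scales import ScaleDefinition, builtin_definitions, load_definitions
from .synthetic import CohortParams, default_params, generate

logger = logging.getLogger("harmscales")


def table_from_counts(
    counts: Mapping[str, tuple[int, int]],
    scale: str | ScaleDefinition,
    comparisons: Sequence[Comparison] | None = None,
    ci_level: float = 0.95,
    proportion_ci: str = WILSON,
) -> pd.DataFrame:
    """Accuracy table straight from category-by-outcome counts.

    ``counts`` maps category -> ``(outcome_positive, outcome_negative)``
    episode counts.  The counts are expanded to pseudo-episodes and fed
    through :func:`build_two_by_two` and :func:`accuracy_metrics`, so the
    result is bit-identical to an episode-level analysis with these margins.
    """
    name = scale if isinstance(scale, str) else scale.name
    for cat, (pos, neg) in counts.items():
        if pos < 0 or neg < 0:
            raise ValueError(f"negative count in category {cat!r}")
    if comparisons is None:
        defs = builtin_definitions()
        if name not in defs:
            raise ValueError(f"no default comparisons for scale {name!r}")
        comparisons = default_comparisons({name: defs[name]})[name]
    categories: dict[str, str] = {}
    outcomes: dict[str, bool] = {}
    i = 0
    for cat, (pos, neg) in counts.items():
        for k in range(pos + neg):
            categories[f"c{i}"] = cat
            outcomes[f"c{i}"] = k < pos
            i += 1
    rows = []
    for comp in comparisons:
        t = build_two_by_two(categories, outcomes, comp)
        rep = accuracy_metrics(t, ci_level=ci_level, proportion_ci=proportion_ci)
        rows.append(
            {"scale": name, "comparison": comp.convention, **rep.as_dict(),
             "tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn,
             "excluded": t.excluded}
        )
    return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one input source.

    Either ``simulate`` holds generator parameters, or ``cohort_path`` (and
    optionally ``deaths_path``/``linked_path``/``attendances_path``) point to
    delimited-text inputs.
    """

    output_dir: str = "harmscales_out"
    seed: int = 0
    simulate: CohortParams | None = None
    cohort_path: str | None = None
    deaths_path: str | None = None
    linked_path: str | None = None
    attendances_path: str | None = None
    scales: tuple[str, ...] = ("MSHR", "ReACT", "SPS", "MSPS")
    scale_definitions_path: str | None = None
    strategy: str = ABSENT_RULE_MICE
    imputation: ImputationConfig = field(
        default_factory=lambda: ImputationConfig(m=5, m_pool=5)
    )
    window_days: int = 183
    ci_level: float = 0.95
    proportion_ci: str = WILSON
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.cohort_path is None):
            raise ValueError("exactly one of simulate / cohort_path is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            sim = raw["simulate"]
            raw["simulate"] = default_params(**sim) if isinstance(sim, dict) else sim
        if "imputation" in raw and isinstance(raw["imputation"], dict):
            raw["imputation"] = ImputationConfig(**raw["imputation"])
        for tuple_key in ("scales",):
            if tuple_key in raw and raw[tuple_key] is not None:
                raw[tuple_key] = tuple(raw[tuple_key])
        return cls(**raw)


def _config_echo(config: PipelineConfig) -> dict:
    echo = asdict(config)
    if config.simulate is not None:
        sim = asdict(config.simulate)
        sim["start"] = config.simulate.start.isoformat()
        echo["simulate"] = sim
    return echo


def run(config: PipelineConfig) -> tuple[ScaleAccuracyResults, dict[str, str]]:
    """Execute the pipeline; returns the fitted results and artefact paths.

    Any stage failure propagates with a stage-labelled message.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    logger.addHandler(handler)
    logger.setLevel(config.log_level)
    try:
        return _run_stages(config, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_stages(config: PipelineConfig, out: Path):
    stage = "input"
    try:
        if config.simulate is not None:
            params = config.simulate
            if params.seed != config.seed:
                from dataclasses import replace

                params = replace(params, seed=config.seed)
            logger.info("simulating cohort (seed=%d)", config.seed)
            gc = generate(params)
            builder = lambda **kw: ScaleAccuracy.from_generated(gc, **kw)  # noqa: E731
        else:
            logger.info("reading cohort from %s", config.cohort_path)
            from .cohort import read_cohort, read_deaths

            episodes = read_cohort(config.cohort_path)
            deaths = read_deaths(config.deaths_path) if config.deaths_path else []
            linked = None
            if config.linked_path:
                with open(config.linked_path) as fh:
                    linked = frozenset(
                        line.strip() for line in fh if line.strip()
                    ) - {"person_id"}
            attendances = (
                read_cohort(config.attendances_path)
                if config.attendances_path
                else ()
            )
            builder = lambda **kw: ScaleAccuracy(  # noqa: E731
                episodes, deaths, linked, attendances, **kw
            )

        stage = "configure"
        definitions = (
            load_definitions(config.scale_definitions_path)
            if config.scale_definitions_path
            else builtin_definitions()
        )
        definitions = {k: v for k, v in definitions.items() if k in config.scales}
        from dataclasses import replace as _replace

        imputation = _replace(config.imputation, seed=config.seed)

        stage = "evaluate"
        model = builder(
            definitions=definitions,
            strategy=config.strategy,
            imputation=imputation,
            window_days=config.window_days,
            ci_level=config.ci_level,
            proportion_ci=config.proportion_ci,
        )
        logger.info(
            "fitting: %d episodes, strategy=%s", len(model.episodes), config.strategy
        )
        results = model.fit()

        stage = "report"
        paths = _write_artefacts(results, config, out)
        logger.info("artefacts written to %s", out)
        return results, paths
    except Exception as exc:  # noqa: BLE001 - stage labelling contract
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _write_artefacts(
    results: ScaleAccuracyResults, config: PipelineConfig, out: Path
) -> dict[str, str]:
    paths: dict[str, str] = {}

    def save(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False)
        paths[name] = str(p)

    save(results.counts, "counts.csv")
    save(results.accuracy[results.accuracy["outcome"] == "repeat"],
         "accuracy_repeat.csv")
    save(results.accuracy[results.accuracy["outcome"] == "suicide"],
         "accuracy_suicide.csv")
    save(results.auc_overall, "auc_overall.csv")
    save(results.auc_subgroups, "auc_subgroups.csv")
    for name, roc in results.roc_curves.items():
        df = pd.DataFrame(roc.points, columns=["fpr", "sensitivity"])
        save(df, f"roc_{name}.csv")
    (out / "summary.txt").write_text(results.summary() + "\n")
    paths["summary.txt"] = str(out / "summary.txt")
    sidecar = {
        "config": _config_echo(config),
        "n_episodes": results.n_episodes,
        "n_suicide_analysed": results.n_suicide_analysed,
        "n_lost_episodes": results.n_lost_episodes,
        "n_absent_rule_cells": results.n_absent_rule_cells,
        "m": results.m,
        "m_pool": results.m_pool,
        "accuracy": results.accuracy.to_dict(orient="records"),
        "auc_overall": results.auc_overall.to_dict(orient="records"),
    }
    (out / "results.json").write_text(json.dumps(sidecar, indent=2, default=str))
    paths["results.json"] = str(out / "results.json")
    return paths
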