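"""End-to-end pipeline: simulate/ingest -> derive -> screen -> search -> validate.

Configuration is a YAML/JSON mapping with sections ``cohorts`` (training and
testing sources: a builtin/YAML generator spec or a CSV path), ``screening``
(alpha), ``search`` (component and weight bounds) and a global ``seed``.  A
fixed seed makes every numeric field of the written artifacts reproducible
byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .cohort import Cohort, default_registry, infer_registry, read_cohort
from .errors import DeliriScoreError, PipelineError
from .screening import DEFAULT_ALPHA, screen_cohort, screening_table
from .search import ScoreDefinition, SearchConfig, SearchResult, search_best
from .simulate import generate_cohort, resolve_spec
from .validation import build_report, write_report

logger = logging.getLogger(__name__)


@dataclass
class CohortSource:
    """Either a generator spec (builtin name or YAML path) or a cohort CSV."""

    spec: Optional[str] = None
    path: Optional[str] = None
    n: Optional[int] = None

    def __post_init__(self):
        if (self.spec is None) == (self.path is None):
            raise PipelineError("config", "cohort source needs exactly one of spec/path")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSource":
        return cls(spec=d.get("spec"), path=d.get("path"), n=d.get("n"))


@dataclass
class PipelineConfig:
    training: CohortSource
    testing: CohortSource
    seed: int = 1
    screening_alpha: float = DEFAULT_ALPHA
    search: SearchConfig = field(default_factory=SearchConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cohorts = d.get("cohorts", {})
        if "training" not in cohorts or "testing" not in cohorts:
            raise PipelineError("config", "config must define cohorts.training and cohorts.testing")
        search_d = d.get("search", {})
        return cls(
            training=CohortSource.from_dict(cohorts["training"]),
            testing=CohortSource.from_dict(cohorts["testing"]),
            seed=int(d.get("seed", 1)),
            screening_alpha=float(d.get("screening", {}).get("alpha", DEFAULT_ALPHA)),
            search=SearchConfig(
                min_components=int(search_d.get("min_components", 2)),
                max_components=int(search_d.get("max_components", 4)),
                weight_min=int(search_d.get("weight_min", 1)),
                weight_max=int(search_d.get("weight_max", 3)),
            ),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def load_cohort(source: CohortSource, seed: int, label: str) -> Cohort:
    """Materialize a cohort from its source (generate or read CSV)."""
    if source.spec is not None:
        spec = resolve_spec(source.spec, n=source.n)
        spec.label = spec.label or label
        return generate_cohort(spec, seed=seed)
    path = Path(source.path)
    try:
        return read_cohort(path, default_registry(), label=label)
    except DeliriScoreError:
        df = pd.read_csv(path, nrows=50)
        return read_cohort(path, infer_registry(df), label=label)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage and write the report artifacts.

    Returns a dict with the in-memory results and the written paths.  Any
    stage failure is re-raised as :class:`PipelineError` naming the stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kw):
        logger.info("stage %s: start", name)
        try:
            return fn(*args, **kw)
        except PipelineError:
            raise
        except DeliriScoreError as e:
            raise PipelineError(name, str(e)) from e

    training = stage("ingest-training", load_cohort, config.training, config.seed, "training")
    testing = stage("ingest-testing", load_cohort, config.testing, config.seed + 1, "testing")
    logger.info("cohorts: training n=%d (prev %.3f), testing n=%d (prev %.3f)",
                training.n, training.outcome().mean(),
                testing.n, testing.outcome().mean())

    results, selected = stage("screen", screen_cohort, training, config.screening_alpha)
    if not selected:
        raise PipelineError("screen", "no candidates selected")
    logger.info("screen: selected %s", selected)

    search_result: SearchResult = stage("search", search_best, training, selected, config.search)
    logger.info("search: %d scores tested; best %s (AUC %.4f)",
                search_result.n_tested, search_result.best.components,
                search_result.best_auc.value)

    report_train = stage("validate-training", build_report, training, search_result.best)
    report_test = stage("validate-testing", build_report, testing, search_result.best)

    paths = {}
    screening_path = out_dir / "screening.csv"
    screening_table(results).to_csv(screening_path, index=False)
    paths["screening"] = screening_path

    search_path = out_dir / "search.json"
    search_path.write_text(json.dumps(
        {
            "best": search_result.best.to_dict(),
            "best_auc": search_result.best_auc.to_dict(),
            "n_tested": search_result.n_tested,
            "candidates": list(selected),
            "ranking": [
                {"definition": d.to_dict(), "auc": a.to_dict()}
                for d, a in search_result.ranking
            ],
        },
        indent=2,
    ) + "\n")
    paths["search"] = search_path

    paths["report_training"] = write_report(report_train, out_dir, "report_training")
    paths["report_testing"] = write_report(report_test, out_dir, "report_testing")

    return {
        "paths": paths,
        "screening": results,
        "selected": selected,
        "search": search_result,
        "report_training": report_train,
        "report_testing": report_test,
    }


def load_score(path: str | Path) -> ScoreDefinition:
    """Read a ScoreDefinition from a search.json (or bare score) file."""
    with open(path) as fh:
        d = json.load(fh)
    return ScoreDefinition.from_dict(d.get("best", d))
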