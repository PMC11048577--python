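"""Cohort/spec serialization and the end-to-end analysis pipeline.

The interchange format is plain UTF-8 CSV with a fixed header (one column
per patient field, booleans as 0/1, '.' decimal, MD on the 1e-3 mm^2/s
scale).  Cohort generative specs and custom scorecards round-trip through
flat JSON.  ``run_pipeline`` chains generate -> screen -> ROC -> score ->
evaluate and writes every stage artifact plus a manifest sufficient to
reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    BINARY_MARKERS,
    CONTINUOUS_MARKERS,
    BinaryMarkerSpec,
    CohortSpec,
    ContinuousMarkerSpec,
    PatientRecord,
    cohort_to_frame,
    default_spec,
    generate_cohort,
)
from .roc import youden_cutoff
from .scorecard import Scorecard, ScoreRule, default_scorecard, evaluate_scorecard, score_patient
from .screening import screen_parameters

__all__ = [
    "COHORT_COLUMNS",
    "RunConfig",
    "read_cohort",
    "write_cohort",
    "spec_to_json",
    "spec_from_json",
    "scorecard_to_json",
    "scorecard_from_json",
    "load_scorecard",
    "run_pipeline",
]

logger = logging.getLogger("idhscore")

_BOOL_COLUMNS = ("male",) + tuple(c for c in BINARY_MARKERS if c != "male")

#: Fixed cohort CSV header, in order.
COHORT_COLUMNS: tuple[str, ...] = (
    ("patient_id", "idh_status", "age") + _BOOL_COLUMNS + ("fa", "md", "met_tn", "cho_tn", "fdg_tn")
)


def write_cohort(cohort: Sequence[PatientRecord], path: str | Path) -> None:
    """Write a cohort as CSV with the documented header; booleans become 0/1."""
    frame = cohort_to_frame(cohort)[list(COHORT_COLUMNS)]
    for col in _BOOL_COLUMNS:
        frame[col] = frame[col].astype(int)
    frame.to_csv(path, index=False)


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read a cohort CSV, validating every row against the record invariants.

    Errors carry the 1-based data row number and the offending column or
    invariant.  An empty file with a valid header yields an empty cohort
    (with a warning).
    """
    path = Path(path)
    frame = pd.read_csv(
        path, dtype={"patient_id": str, "idh_status": str}, float_precision="round_trip"
    )
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if frame.empty:
        warnings.warn(f"{path}: no data rows", stacklevel=2)
        return []

    records: list[PatientRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        kwargs: dict = {}
        for col in COHORT_COLUMNS:
            raw = getattr(row, col)
            try:
                if col in ("patient_id", "idh_status"):
                    kwargs[col] = str(raw)
                elif col in _BOOL_COLUMNS:
                    val = int(raw)
                    if val not in (0, 1):
                        raise ValueError(f"expected 0/1, got {raw!r}")
                    kwargs[col] = bool(val)
                else:
                    kwargs[col] = float(raw)
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}: row {i}, column {col!r}: {exc}") from None
        try:
            records.append(PatientRecord(**kwargs))
        except ValueError as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from None
    logger.info("read %d records from %s", len(records), path)
    return records


# --- spec and scorecard serialization ---------------------------------------


def spec_to_json(spec: CohortSpec, path: str | Path | None = None) -> str:
    """Serialize a cohort spec to flat JSON (optionally writing ``path``)."""
    payload = {
        "n_mut": spec.n_mut,
        "n_wt": spec.n_wt,
        "continuous": [dataclasses.asdict(s) for s in spec.continuous.values()],
        "binary": [dataclasses.asdict(s) for s in spec.binary.values()],
    }
    if spec.copula is not None:
        payload["copula"] = {
            "markers": list(spec.copula.index),
            "matrix": spec.copula.to_numpy(float).tolist(),
        }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def _read_json_source(source: str | Path) -> str:
    """Accept either a filesystem path or a literal JSON string."""
    text = str(source)
    if not text.lstrip().startswith(("{", "[")):
        return Path(source).read_text()
    return text


def spec_from_json(source: str | Path) -> CohortSpec:
    """Inverse of :func:`spec_to_json`; accepts a path or a JSON string."""
    payload = json.loads(_read_json_source(source))
    copula = None
    if "copula" in payload:
        cop = payload["copula"]
        copula = pd.DataFrame(cop["matrix"], index=cop["markers"], columns=cop["markers"])
    return CohortSpec.from_lists(
        continuous=[ContinuousMarkerSpec(**s) for s in payload["continuous"]],
        binary=[BinaryMarkerSpec(**s) for s in payload["binary"]],
        n_mut=int(payload["n_mut"]),
        n_wt=int(payload["n_wt"]),
        copula=copula,
    )


def scorecard_to_json(card: Scorecard, path: str | Path | None = None) -> str:
    payload = {
        "name": card.name,
        "mut_band": list(card.mut_band),
        "wt_band": list(card.wt_band),
        "indeterminate_band": (
            list(card.indeterminate_band) if card.indeterminate_band else None
        ),
        "rules": [dataclasses.asdict(r) for r in card.rules],
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def scorecard_from_json(source: str | Path) -> Scorecard:
    payload = json.loads(_read_json_source(source))
    return Scorecard(
        name=payload["name"],
        rules=tuple(ScoreRule(**r) for r in payload["rules"]),
        mut_band=tuple(payload["mut_band"]),
        wt_band=tuple(payload["wt_band"]),
        indeterminate_band=(
            tuple(payload["indeterminate_band"]) if payload.get("indeterminate_band") else None
        ),
    )


def load_scorecard(name_or_path: str | Path) -> Scorecard:
    """Resolve a builtin card name (mri5/pet3/full9) or a custom card JSON file."""
    if str(name_or_path) in ("mri5", "pet3", "full9"):
        return default_scorecard(str(name_or_path))  # type: ignore[arg-type]
    path = Path(name_or_path)
    if not path.is_file():
        raise KeyError(f"unknown scorecard {name_or_path!r} (not a builtin name or a file)")
    return scorecard_from_json(path)


# --- end-to-end pipeline -----------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    seed: int
    out_dir: str | Path
    spec: CohortSpec | str | Path | None = None  # None -> published defaults
    scorecard: str | Path = "full9"
    alpha: float = 0.05
    n_reps: int = 200

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("significance level must lie in (0, 1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    def resolve_spec(self) -> CohortSpec:
        if self.spec is None:
            return default_spec()
        if isinstance(self.spec, CohortSpec):
            return self.spec
        return spec_from_json(self.spec)


def _screen_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                marker=r.marker,
                method=r.method,
                statistic=r.statistic,
                p_value=r.p_value,
                direction=r.direction,
                significant=r.significant,
            )
            for r in results
        ]
    )


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Generate a cohort, screen it, run ROC analysis, score and evaluate it.

    Writes ``cohort.csv``, ``screen.csv``, ``roc.csv``, ``scores.csv``,
    ``accuracy.json`` and ``manifest.json`` into ``config.out_dir`` and
    returns the artifact paths.  Two runs with the same config produce
    byte-identical numeric outputs.
    """
    # resolve everything (and fail on config errors) before writing any output
    spec = config.resolve_spec()
    card = load_scorecard(config.scorecard)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    logger.info("stage generate: n_mut=%d n_wt=%d seed=%d", spec.n_mut, spec.n_wt, config.seed)
    cohort = generate_cohort(spec, config.seed)
    paths["cohort"] = out / "cohort.csv"
    write_cohort(cohort, paths["cohort"])

    logger.info("stage screen: %d records, alpha=%g", len(cohort), config.alpha)
    screen = screen_parameters(cohort, alpha=config.alpha)
    paths["screen"] = out / "screen.csv"
    _screen_frame(screen).to_csv(paths["screen"], index=False)

    logger.info("stage roc: %d continuous markers", len(CONTINUOUS_MARKERS))
    frame = cohort_to_frame(cohort)
    labels = frame["idh_status"].to_numpy()
    roc_rows = []
    for marker in CONTINUOUS_MARKERS:
        cspec = spec.continuous[marker]
        orientation = "wt_high" if cspec.mu_wt >= cspec.mu_mut else "wt_low"
        roc_rows.append(
            dataclasses.asdict(
                youden_cutoff(frame[marker].to_numpy(), labels, orientation, marker=marker)
            )
        )
    paths["roc"] = out / "roc.csv"
    pd.DataFrame(roc_rows).to_csv(paths["roc"], index=False)

    logger.info("stage score: card=%s", card.name)
    score_rows = []
    for record in cohort:
        res = score_patient(record, card)
        score_rows.append(
            dict(patient_id=res.patient_id, total=res.total, call=res.call, **res.per_rule_points)
        )
    paths["scores"] = out / "scores.csv"
    pd.DataFrame(score_rows).to_csv(paths["scores"], index=False)

    logger.info("stage evaluate")
    table = evaluate_scorecard(cohort, card)
    paths["accuracy"] = out / "accuracy.json"
    paths["accuracy"].write_text(
        json.dumps(
            dict(
                scorecard=table.scorecard,
                decided_n=table.decided_n,
                correct_n=table.correct_n,
                accuracy_decided=table.accuracy_decided,
                accuracy_overall=table.accuracy_overall,
                per_score_counts=table.per_score_counts.reset_index().to_dict("records"),
                band_composition=table.band_composition.reset_index().to_dict("records"),
            ),
            indent=2,
        )
    )

    spec_json = spec_to_json(spec)
    manifest = dict(
        package="idhscore",
        version=__version__,
        seed=config.seed,
        alpha=config.alpha,
        n_reps=config.n_reps,
        scorecard=scorecard_to_json(card),
        spec=spec_json,
        spec_sha256=hashlib.sha256(spec_json.encode()).hexdigest(),
        library_versions=dict(numpy=np.__version__, pandas=pd.__version__),
        artifacts=sorted(p.name for p in paths.values()),
    )
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete: %d artifacts in %s", len(paths), out)
    return paths
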