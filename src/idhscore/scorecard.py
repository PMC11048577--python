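"""Additive point scorecards for predicting IDH status.

The composite diagnosis works by dichotomizing each significant parameter at
a fixed cutoff, awarding one point per wildtype-indicating finding, and
mapping the total to a call via score bands:

* ``mri5`` — thalamus invasion, contralateral-hemisphere invasion, location
  adjacent to the ventricle walls, FA >= 0.18, MD <= 1.28 (1e-3 mm^2/s);
  totals 0-2 call IDH-mut, 3-5 call IDH-wt.
* ``pet3`` — MET T/N >= 1.29, CHO T/N >= 2.02, FDG T/N >= 0.82; totals 0-1
  call IDH-mut, 2-3 call IDH-wt.
* ``full9`` — the five MRI rules, the three PET rules, and age >= 48 years;
  totals 0-4 call IDH-mut, 6-9 call IDH-wt, and a total of exactly 5 is
  indeterminate.

All thresholds are inclusive on the wildtype side: a patient exactly at a
cutoff scores the point (fixed by the worked case aged exactly 48).
``derive_scorecard`` rebuilds a card of the same shape from any labelled
cohort — screen, keep the significant markers, set thresholds by Youden's J.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .cohort import PatientRecord, cohort_to_frame
from .roc import Orientation, youden_cutoff
from .screening import screen_parameters

__all__ = [
    "ScoreRule",
    "Scorecard",
    "ScoreResult",
    "AccuracyTable",
    "default_scorecard",
    "score_patient",
    "evaluate_scorecard",
    "derive_scorecard",
]

Band = tuple[int, int]  # inclusive [lo, hi] range of totals


@dataclass(frozen=True)
class ScoreRule:
    """One dichotomization: a binary flag, or a thresholded continuous marker."""

    marker: str
    kind: Literal["binary_flag", "threshold"]
    direction: Orientation | None = None
    threshold: float | None = None
    inclusive: bool = True

    def __post_init__(self) -> None:
        if self.kind == "threshold":
            if self.threshold is None or not math.isfinite(self.threshold):
                raise ValueError(f"{self.marker}: threshold rule needs a finite threshold")
            if self.direction not in ("wt_high", "wt_low"):
                raise ValueError(f"{self.marker}: threshold rule needs a direction")
        elif self.kind == "binary_flag":
            if self.threshold is not None or self.direction is not None:
                raise ValueError(f"{self.marker}: binary rule carries no threshold/direction")
        else:
            raise ValueError(f"unknown rule kind {self.kind!r}")

    def is_satisfied(self, record: PatientRecord) -> bool:
        """True when the record shows this rule's wildtype-indicating finding."""
        try:
            value = getattr(record, self.marker)
        except AttributeError:
            raise ValueError(f"record is missing marker {self.marker!r}") from None
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise ValueError(f"record has no value for marker {self.marker!r}")
        if self.kind == "binary_flag":
            return bool(value)
        if self.direction == "wt_high":
            return value >= self.threshold if self.inclusive else value > self.threshold
        return value <= self.threshold if self.inclusive else value < self.threshold


@dataclass(frozen=True)
class Scorecard:
    """An ordered rule set plus decision bands over the total score."""

    name: str
    rules: tuple[ScoreRule, ...]
    mut_band: Band
    wt_band: Band
    indeterminate_band: Band | None = None

    def __post_init__(self) -> None:
        bands = [self.mut_band, self.wt_band]
        if self.indeterminate_band is not None:
            bands.append(self.indeterminate_band)
        covered: list[int] = []
        for lo, hi in bands:
            if lo > hi:
                raise ValueError(f"{self.name}: empty band ({lo}, {hi})")
            covered.extend(range(lo, hi + 1))
        if sorted(covered) != list(range(len(self.rules) + 1)):
            raise ValueError(
                f"{self.name}: bands must partition totals 0..{len(self.rules)}"
            )

    def call(self, total: int) -> Literal["mut", "wt", "indeterminate"]:
        if self.mut_band[0] <= total <= self.mut_band[1]:
            return "mut"
        if self.wt_band[0] <= total <= self.wt_band[1]:
            return "wt"
        return "indeterminate"


@dataclass(frozen=True)
class ScoreResult:
    """Per-patient scoring outcome: one 0/1 point per rule plus the call."""

    patient_id: str
    per_rule_points: dict[str, int]
    total: int
    call: Literal["mut", "wt", "indeterminate"]


@dataclass(frozen=True)
class AccuracyTable:
    """Stratified diagnostic accuracy of a scorecard on a labelled cohort.

    ``accuracy_decided`` follows the published convention: indeterminate
    totals are dropped from the denominator.  ``accuracy_overall`` counts
    them as errors instead.  ``band_composition`` gives, per decision band,
    how many patients fell in it and what fraction were of the called class.
    """

    scorecard: str
    per_score_counts: pd.DataFrame  # index: total; columns: n_mut, n_wt
    decided_n: int
    correct_n: int
    accuracy_decided: float
    accuracy_overall: float
    band_composition: pd.DataFrame  # index: band; columns: n, n_matching, fraction


_MRI5_RULES = (
    ScoreRule("thalamus", "binary_flag"),
    ScoreRule("contralateral", "binary_flag"),
    ScoreRule("ventricle_adjacent", "binary_flag"),
    ScoreRule("fa", "threshold", "wt_high", 0.18),
    ScoreRule("md", "threshold", "wt_low", 1.28),
)
_PET3_RULES = (
    ScoreRule("met_tn", "threshold", "wt_high", 1.29),
    ScoreRule("cho_tn", "threshold", "wt_high", 2.02),
    ScoreRule("fdg_tn", "threshold", "wt_high", 0.82),
)


def default_scorecard(name: Literal["mri5", "pet3", "full9"]) -> Scorecard:
    """The three published scorecards with their printed cutoffs and bands."""
    if name == "mri5":
        return Scorecard("mri5", _MRI5_RULES, mut_band=(0, 2), wt_band=(3, 5))
    if name == "pet3":
        return Scorecard("pet3", _PET3_RULES, mut_band=(0, 1), wt_band=(2, 3))
    if name == "full9":
        rules = _MRI5_RULES + _PET3_RULES + (ScoreRule("age", "threshold", "wt_high", 48.0),)
        return Scorecard(
            "full9", rules, mut_band=(0, 4), wt_band=(6, 9), indeterminate_band=(5, 5)
        )
    raise ValueError(f"unknown scorecard {name!r}; expected mri5, pet3 or full9")


def score_patient(record: PatientRecord, scorecard: Scorecard) -> ScoreResult:
    """Apply every rule of ``scorecard`` to one patient and band the total."""
    points = {rule.marker: int(rule.is_satisfied(record)) for rule in scorecard.rules}
    total = sum(points.values())
    return ScoreResult(
        patient_id=record.patient_id,
        per_rule_points=points,
        total=total,
        call=scorecard.call(total),
    )


def evaluate_scorecard(
    cohort: Sequence[PatientRecord], scorecard: Scorecard
) -> AccuracyTable:
    """Stratified accuracy of a scorecard on a fully labelled cohort."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    unlabeled = [r.patient_id for r in cohort if r.idh_status == "unknown"]
    if unlabeled:
        raise ValueError(f"unlabeled records: {unlabeled[:5]}")

    totals = np.array([score_patient(r, scorecard).total for r in cohort])
    truth = np.array([r.idh_status for r in cohort])
    calls = np.array([scorecard.call(int(t)) for t in totals])

    counts = pd.DataFrame(
        {
            "n_mut": [(totals[truth == "mut"] == s).sum() for s in range(len(scorecard.rules) + 1)],
            "n_wt": [(totals[truth == "wt"] == s).sum() for s in range(len(scorecard.rules) + 1)],
        },
        index=pd.Index(range(len(scorecard.rules) + 1), name="total"),
    )

    decided = calls != "indeterminate"
    decided_n = int(decided.sum())
    correct_n = int((calls[decided] == truth[decided]).sum())
    if decided_n == 0:
        warnings.warn(
            f"{scorecard.name}: every patient fell in the indeterminate band; "
            "decided-cases accuracy is undefined",
            stacklevel=2,
        )
        accuracy_decided = float("nan")
    else:
        accuracy_decided = correct_n / decided_n
    accuracy_overall = correct_n / len(cohort)

    band_rows = {}
    for band_call in ("mut", "wt", "indeterminate"):
        in_band = calls == band_call
        n = int(in_band.sum())
        n_matching = int((truth[in_band] == band_call).sum())
        band_rows[band_call] = dict(
            n=n, n_matching=n_matching, fraction=(n_matching / n if n else float("nan"))
        )
    composition = pd.DataFrame.from_dict(band_rows, orient="index")
    composition.index.name = "band"

    return AccuracyTable(
        scorecard=scorecard.name,
        per_score_counts=counts,
        decided_n=decided_n,
        correct_n=correct_n,
        accuracy_decided=accuracy_decided,
        accuracy_overall=accuracy_overall,
        band_composition=composition,
    )


def derive_scorecard(
    cohort: Sequence[PatientRecord], alpha: float = 0.05, name: str = "derived"
) -> Scorecard:
    """Rebuild a composite scorecard from a labelled cohort, end to end.

    Mirrors the published construction: screen all markers, keep those
    significant at ``alpha``, turn significant binary flags into flag rules
    and significant continuous markers into Youden-cutoff threshold rules
    (orientation = the side on which the wildtype group lies).  Decision
    bands are a documented generalization of the published ones: the totals
    0..k are split at the midpoint, with the exact middle total declared
    indeterminate when k is even; for odd k the split is clean.
    """
    if len({r.idh_status for r in cohort} & {"mut", "wt"}) < 2:
        raise ValueError("cohort must contain both IDH classes")
    if min(
        sum(r.idh_status == "mut" for r in cohort), sum(r.idh_status == "wt" for r in cohort)
    ) < 2:
        raise ValueError("need at least two patients per class to derive a card")

    frame = cohort_to_frame(cohort)
    labels = frame["idh_status"].to_numpy()
    results = {r.marker: r for r in screen_parameters(cohort, alpha=alpha)}

    rules: list[ScoreRule] = []
    for marker, res in results.items():
        if not res.significant:
            continue
        if res.method == "pearson_chi2":
            rules.append(ScoreRule(marker, "binary_flag"))
        else:
            orientation: Orientation = "wt_high" if res.direction == "wt" else "wt_low"
            roc = youden_cutoff(frame[marker].to_numpy(), labels, orientation, marker=marker)
            rules.append(ScoreRule(marker, "threshold", orientation, roc.cutoff))
    if not rules:
        raise ValueError(f"no marker significant at alpha={alpha}; cannot build a card")

    # deterministic rule order: binary flags first, then thresholds, each by name
    rules.sort(key=lambda r: (r.kind != "binary_flag", r.marker))

    k = len(rules)
    if k % 2 == 0 and k >= 2:
        mid = k // 2
        return Scorecard(
            name, tuple(rules), mut_band=(0, mid - 1), wt_band=(mid + 1, k),
            indeterminate_band=(mid, mid),
        )
    return Scorecard(
        name, tuple(rules), mut_band=(0, (k - 1) // 2), wt_band=((k + 1) // 2, k)
    )
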