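"""Fold-change computation, strain-specific positivity calls, toxicity flags,
and maximum fold-change (radar) summaries.

A study arm is called positive when the mean revertant count at any
non-toxic concentration reaches the strain-specific multiple of the
concurrent vehicle-control mean: 2-fold for TA98, TA100 and
WP2uvrA(pKM101), 3-fold for TA1535 and TA1537.  The comparison is
inclusive (a ratio of exactly 2.0 in TA100 is positive).  Concentrations
flagged toxic are excluded from the decision; an arm whose every
concentration is toxic is inconclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plate_io import Design, DoseResponseArm, STRAINS

__all__ = [
    "DEFAULT_THRESHOLDS",
    "FoldChangeProfile",
    "ArmCall",
    "CallMatrix",
    "fold_changes",
    "flag_toxicity",
    "call_arm",
    "max_fold_change",
    "study_call_matrix",
]

#: strain-specific positivity thresholds (fold over concurrent control)
DEFAULT_THRESHOLDS = {
    "TA98": 2.0,
    "TA100": 2.0,
    "WP2uvrA_pKM101": 2.0,
    "TA1535": 3.0,
    "TA1537": 3.0,
}

#: mean count below this fraction of control triggers the advisory
#: toxicity heuristic (the visual criterion is unquantified; this repo
#: default never overturns explicit annotations)
HEURISTIC_CONTROL_FRACTION = 0.5


@dataclass(frozen=True)
class FoldChangeProfile:
    """Per-dose mean treated/control ratios for one arm."""

    design: Design
    per_dose: tuple  # (dose, mean_treated, mean_control, ratio) per dose
    control_mean: float

    def ratios(self) -> dict:
        return {dose: ratio for dose, _, _, ratio in self.per_dose}


@dataclass(frozen=True)
class ArmCall:
    """Positivity decision for one arm."""

    design: Design
    threshold: float
    call: str  # "positive" | "negative" | "toxic_inconclusive"
    max_fold: float | None  # max ratio over non-toxic doses
    first_positive_dose: float | None
    toxic_doses: frozenset
    advisory_toxic_doses: frozenset = frozenset()


@dataclass(frozen=True)
class ToxicityFlags:
    """Doses flagged toxic; advisory flags come from the count heuristic only."""

    annotated: frozenset
    advisory: frozenset

    @property
    def all(self) -> frozenset:
        return self.annotated | self.advisory


def fold_changes(arm: DoseResponseArm) -> FoldChangeProfile:
    """Mean treated count over mean concurrent vehicle-control count per dose.

    Arithmetic means of plate counts; raises for a degenerate (zero)
    control mean.
    """
    control_mean = float(np.mean(arm.control_counts))
    if control_mean == 0:
        raise ZeroDivisionError(
            f"{arm.design}: vehicle-control mean is zero; fold change undefined"
        )
    rows = []
    for dose in arm.doses:
        tmean = float(np.mean(arm.treated_counts[dose]))
        rows.append((dose, tmean, control_mean, tmean / control_mean))
    return FoldChangeProfile(arm.design, tuple(rows), control_mean)


def flag_toxicity(
    arm: DoseResponseArm, policy: str = "annotation_only"
) -> ToxicityFlags:
    """Doses considered toxic under the chosen policy.

    ``annotation_only`` returns doses whose plates carry a toxicity note
    (lawn thinning or absence, assessed by eye).  The
    ``annotation_plus_heuristic`` policy additionally flags doses whose
    mean count falls below half the control mean; such flags are advisory.
    """
    if policy not in ("annotation_only", "annotation_plus_heuristic"):
        raise ValueError(f"unknown toxicity policy {policy!r}")
    annotated = frozenset(d for d, notes in arm.toxicity_notes.items() if notes)
    advisory = frozenset()
    if policy == "annotation_plus_heuristic":
        control_mean = float(np.mean(arm.control_counts))
        if control_mean > 0:
            advisory = frozenset(
                d
                for d in arm.doses
                if d not in annotated
                and float(np.mean(arm.treated_counts[d]))
                < HEURISTIC_CONTROL_FRACTION * control_mean
            )
    return ToxicityFlags(annotated=annotated, advisory=advisory)


def _strain_threshold(strain: str, thresholds: dict | None) -> float:
    table = DEFAULT_THRESHOLDS if thresholds is None else thresholds
    try:
        return table[strain]
    except KeyError:
        raise ValueError(f"no positivity threshold for strain {strain!r}") from None


def call_arm(
    arm: DoseResponseArm,
    thresholds: dict | None = None,
    toxicity_policy: str = "annotation_only",
) -> ArmCall:
    """Strain-specific positivity call for one arm.

    Positive iff any non-toxic dose's mean-count ratio meets the strain
    threshold (inclusive).  Toxic doses are excluded from the decision;
    if every dose is toxic the call is ``toxic_inconclusive``.
    """
    threshold = _strain_threshold(arm.design.strain, thresholds)
    flags = flag_toxicity(arm, toxicity_policy)
    toxic = flags.all
    profile = fold_changes(arm)
    usable = [(d, r) for d, r in profile.ratios().items() if d not in toxic]
    if not usable:
        return ArmCall(
            design=arm.design,
            threshold=threshold,
            call="toxic_inconclusive",
            max_fold=None,
            first_positive_dose=None,
            toxic_doses=frozenset(toxic),
            advisory_toxic_doses=flags.advisory,
        )
    max_fold = max(r for _, r in usable)
    hits = sorted(d for d, r in usable if r >= threshold)
    return ArmCall(
        design=arm.design,
        threshold=threshold,
        call="positive" if hits else "negative",
        max_fold=max_fold,
        first_positive_dose=hits[0] if hits else None,
        toxic_doses=frozenset(toxic),
        advisory_toxic_doses=flags.advisory,
    )


def max_fold_change(
    arm: DoseResponseArm, toxicity_policy: str = "annotation_only"
) -> tuple:
    """Largest per-dose ratio over non-toxic doses and the dose where it occurs.

    This is the radar-plot summary: the maximum response per study design
    regardless of the concentration at which it occurred.
    """
    toxic = flag_toxicity(arm, toxicity_policy).all
    profile = fold_changes(arm)
    usable = [(d, r) for d, r, in profile.ratios().items() if d not in toxic]
    if not usable:
        raise ValueError(f"{arm.design}: all doses toxic; maximum fold undefined")
    dose, ratio = max(usable, key=lambda item: item[1])
    return ratio, dose


_CALL_SYMBOLS = {"positive": "+", "negative": "-", "toxic_inconclusive": "Toxic"}


@dataclass(frozen=True)
class CallMatrix:
    """Strain-by-condition call table for one compound (the Tables 2-4 layout)."""

    compound: str
    frame: pd.DataFrame  # rows (method, s9, vehicle), columns strains + overall

    def cell(self, method: str, s9: str, vehicle: str, strain: str) -> str:
        return self.frame.loc[(method, s9, vehicle), strain]


def study_call_matrix(
    arms: list,
    thresholds: dict | None = None,
    toxicity_policy: str = "annotation_only",
) -> CallMatrix:
    """Call every arm of one compound and pivot into a strain-by-row matrix.

    One row per (method, s9, vehicle); the overall result is Positive iff
    any strain in the row is positive; toxic-inconclusive cells render as
    ``Toxic``.
    """
    compounds = {arm.design.compound for arm in arms}
    if len(compounds) != 1:
        raise ValueError(f"arms span multiple compounds: {sorted(compounds)}")
    compound = compounds.pop()

    cells: dict = {}
    for arm in arms:
        d = arm.design
        call = call_arm(arm, thresholds, toxicity_policy)
        cells.setdefault((d.method, d.s9, d.vehicle), {})[d.strain] = (
            _CALL_SYMBOLS[call.call]
        )

    rows = []
    for key in sorted(cells):
        row = {strain: cells[key].get(strain, "") for strain in STRAINS}
        row["overall"] = (
            "Positive" if any(v == "+" for v in row.values()) else "Negative"
        )
        rows.append(row)
    frame = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(
            sorted(cells), names=["method", "s9", "vehicle"]
        ),
        columns=list(STRAINS) + ["overall"],
    )
    return CallMatrix(compound=compound, frame=frame)
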