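"""FACT-F based fatigue dichotomization.

The Functional Assessment of Cancer Therapy-Fatigue (FACT-F) is a 13-item
patient-reported instrument; lower total scores mean worse fatigue, and total
scores range from 16 to 53.  A subject is classed as *fatigued* when the score
drops by at least 3 points between the baseline assessment (before
radiotherapy) and the 1-year follow-up — the minimal clinically important
difference for this instrument.  These binary labels are the phenotype every
downstream classification stage consumes.
"""
from __future__ import annotations

import logging

import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

FACTF_MIN = 16
FACTF_MAX = 53

#: Minimal clinically important decrease in FACT-F total score.
FATIGUE_THRESHOLD = 3

FATIGUED = "fatigued"
NON_FATIGUED = "non-fatigued"


def _check_score(score: float, name: str) -> float:
    score = float(score)
    if not (FACTF_MIN <= score <= FACTF_MAX):
        raise ValidationError(
            f"{name} = {score} outside the FACT-F total-score range "
            f"[{FACTF_MIN}, {FACTF_MAX}]"
        )
    if score != int(score):
        # The instrument totals integer item scores; fractional inputs are
        # accepted (e.g. imputed values) but flagged.
        logger.warning("fractional FACT-F score %s for %s", score, name)
    return score


def classify_fatigue(factf_baseline: float, factf_1yr: float) -> str:
    """Dichotomize one subject from a (baseline, 1-year) FACT-F pair.

    Returns ``"fatigued"`` iff the score decreased by >= 3 points; a boundary
    decrease of exactly 3 counts as fatigued.  Scores outside [16, 53] raise
    :class:`~fatiguesig.errors.ValidationError`.
    """
    baseline = _check_score(factf_baseline, "factf_baseline")
    year1 = _check_score(factf_1yr, "factf_1yr")
    return FATIGUED if baseline - year1 >= FATIGUE_THRESHOLD else NON_FATIGUED


def labels_from_assessments(assessments: pd.DataFrame) -> pd.Series:
    """Apply :func:`classify_fatigue` row-wise.

    Parameters
    ----------
    assessments
        Columns ``subject_id``, ``factf_baseline``, ``factf_1yr`` (extra
        columns are ignored).

    Returns
    -------
    pandas.Series of class labels indexed by ``subject_id``.
    """
    required = {"subject_id", "factf_baseline", "factf_1yr"}
    missing = required - set(assessments.columns)
    if missing:
        raise ValidationError(f"assessment table missing columns: {sorted(missing)}")
    labels = [
        classify_fatigue(row.factf_baseline, row.factf_1yr)
        for row in assessments.itertuples()
    ]
    return pd.Series(labels, index=pd.Index(assessments["subject_id"], name="sample_id"), name="class")


def cohort_summary(assessments: pd.DataFrame) -> pd.DataFrame:
    """Per-class counts and percentages for a cohort of FACT-F assessments.

    Percentages are reported to one decimal place and sum to 100 within
    rounding.
    """
    if len(assessments) == 0:
        raise ValidationError("cohort_summary requires a non-empty cohort")
    labels = labels_from_assessments(assessments)
    counts = labels.value_counts().reindex([FATIGUED, NON_FATIGUED], fill_value=0)
    percent = (100.0 * counts / counts.sum()).round(1)
    return pd.DataFrame({"count": counts, "percent": percent}).rename_axis("class")
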