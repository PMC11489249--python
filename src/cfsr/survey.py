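"""Survey table loading and validation.

The survey is a wide table, one row per respondent: ``respondent_id``,
``community``, then one column per question id.  Yes/No answers are the
literals ``yes``/``no`` (case-insensitive), Likert answers are integers
1-4, proportions are decimals in [0, 1], counts are non-negative
integers, categories must appear in the question's ordinal map, and
missing answers are empty cells.  Validation flags out-of-range answers
and treats them as missing rather than dropping the respondent:
community indicators are per-question summaries, so exclusion is
complete-case per question.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cfsr.registry import QuestionSpec, Registry

ID_COLUMNS = ("respondent_id", "community")


@dataclass(frozen=True)
class ValidationIssue:
    respondent_id: object
    question_id: str
    problem: str
    value: object = None


@dataclass(frozen=True)
class ValidationReport:
    issues: tuple[ValidationIssue, ...]
    missing_counts: dict[str, int]  # per question, after flagged values removed

    @property
    def n_issues(self) -> int:
        return len(self.issues)


class SurveyValidationError(ValueError):
    """Structural problem that prevents scoring the survey at all."""


def load_survey(path) -> pd.DataFrame:
    """Read a survey CSV, keeping raw answers as strings for validation."""
    table = pd.read_csv(path, dtype=str)
    return table


def _coerce(value: object, spec: QuestionSpec):
    """Return (coerced value, problem or None); NaN marks missing."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan, None
    text = str(value).strip()
    if text == "" or text.lower() in {"nan", "na"}:
        return np.nan, None
    if spec.qtype == "yes_no":
        low = text.lower()
        # accept the already-coerced 1/0 form so validation is idempotent
        if low in {"yes", "1", "1.0"}:
            return 1.0, None
        if low in {"no", "0", "0.0"}:
            return 0.0, None
        return np.nan, "not a yes/no answer"
    if spec.qtype == "likert_1_4":
        try:
            x = float(text)
        except ValueError:
            return np.nan, "non-numeric Likert answer"
        if x != int(x) or not 1 <= x <= 4:
            return np.nan, "Likert answer outside 1-4"
        return x, None
    if spec.qtype == "proportion":
        try:
            x = float(text)
        except ValueError:
            return np.nan, "non-numeric proportion"
        if not 0.0 <= x <= 1.0:
            return np.nan, "proportion outside [0,1]"
        return x, None
    if spec.qtype == "count":
        try:
            x = float(text)
        except ValueError:
            return np.nan, "non-numeric count"
        if x != int(x) or x < 0:
            return np.nan, "not a non-negative integer count"
        return x, None
    if spec.qtype == "category":
        if text in spec.category_map:
            return text, None
        return np.nan, "category not in the registry's ordinal map"
    return np.nan, f"unscoreable question type {spec.qtype!r}"


def validate_survey(
    table: pd.DataFrame, registry: Registry
) -> tuple[pd.DataFrame, ValidationReport]:
    """Type-check survey answers against the registry.

    Returns the table with answers coerced to numeric scores-ready values
    (invalid answers replaced by NaN) and a report listing every flagged
    cell plus per-question missingness counts.  Raises
    :class:`SurveyValidationError` for structural problems: an empty
    table, unknown columns, unknown community labels, or a configured
    community with no respondents.
    """
    if table.empty:
        raise SurveyValidationError("survey table is empty")
    for col in ID_COLUMNS:
        if col not in table.columns:
            raise SurveyValidationError(f"survey table lacks required column {col!r}")

    known_qids = set(registry.question_ids)
    unknown_cols = [
        c for c in table.columns if c not in ID_COLUMNS and c not in known_qids
    ]
    if unknown_cols:
        raise SurveyValidationError(
            f"unknown question ids not in the registry: {sorted(unknown_cols)}"
        )

    labels = set(table["community"].astype(str))
    unknown = labels - set(registry.communities)
    if unknown:
        raise SurveyValidationError(
            f"unknown community labels: {sorted(unknown)} "
            f"(configured: {list(registry.communities)})"
        )
    empty = set(registry.communities) - labels
    if empty:
        raise SurveyValidationError(f"communities with no respondents: {sorted(empty)}")

    out = table.copy()
    issues: list[ValidationIssue] = []
    missing: dict[str, int] = {}
    for col in out.columns:
        if col in ID_COLUMNS:
            continue
        _, qspec = registry.question(col)
        coerced = []
        for rid, raw in zip(out["respondent_id"], out[col]):
            value, problem = _coerce(raw, qspec)
            if problem is not None:
                issues.append(ValidationIssue(rid, col, problem, raw))
            coerced.append(value)
        if qspec.qtype == "category":
            out[col] = pd.array(coerced, dtype=object)
            # valid categories are strings; NaN (a float) marks missing
            missing[col] = sum(1 for v in coerced if isinstance(v, float))
        else:
            out[col] = pd.array(coerced, dtype=float)
            missing[col] = int(out[col].isna().sum())
    return out, ValidationReport(tuple(issues), missing)
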