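"""Dual-isoform median-split prognostic signature.

Receptor-status molecular subtyping, per-marker median dichotomization,
the 3-group classification (both-low / discordant / both-high) and the
collapsed 2-group dual signature (low only when both markers are low).

Ties at the median are labelled *low*, so *high* always means strictly
above the median.  Medians may be computed on the whole cohort or within
each subtype (``scope``); the median used is always reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUBTYPE_LUMINAL = "Luminal"
SUBTYPE_HER2 = "HER2-enriched"
SUBTYPE_TN = "TripleNegative"
SUBTYPES = (SUBTYPE_LUMINAL, SUBTYPE_HER2, SUBTYPE_TN)

LOW, HIGH = "low", "high"


class SignatureError(ValueError):
    pass


@dataclass(frozen=True)
class ClinicalRecord:
    sample_id: str
    age: float
    sbr_grade: str            # I / II / III
    lymph_node: str           # negative / positive
    tumor_size: float         # mm
    er: str                   # + / -
    pr: str
    her2: str
    rfs_time: float           # months
    event: int                # 1 relapse, 0 censored

    def __post_init__(self) -> None:
        if self.rfs_time < 0:
            raise SignatureError("rfs_time must be non-negative")
        if self.sbr_grade not in ("I", "II", "III"):
            raise SignatureError(f"invalid SBR grade {self.sbr_grade!r}")
        if self.lymph_node not in ("negative", "positive"):
            raise SignatureError(f"invalid lymph_node {self.lymph_node!r}")
        for name in ("er", "pr", "her2"):
            if getattr(self, name) not in ("+", "-"):
                raise SignatureError(f"invalid {name} status {getattr(self, name)!r}")
        if self.event not in (0, 1):
            raise SignatureError("event must be 0 or 1")


@dataclass(frozen=True)
class SignatureAssignment:
    sample_id: str
    wt_label: str
    de4_label: str
    group3: int
    dual: str
    subtype: str | None = None
    e3_label: str | None = None


def assign_subtype(er: str, pr: str, her2: str) -> str:
    """St Gallen-style subtype from receptor statuses.

    Luminal when ER+ and/or PR+ (takes precedence over HER2); HER2-enriched
    when ER-/PR-/HER2+; triple negative when all three are negative.
    """
    for name, status in (("er", er), ("pr", pr), ("her2", her2)):
        if status not in ("+", "-"):
            raise SignatureError(f"unknown {name} status {status!r}")
    if er == "+" or pr == "+":
        return SUBTYPE_LUMINAL
    if her2 == "+":
        return SUBTYPE_HER2
    return SUBTYPE_TN


def median_dichotomize(
    values: Mapping[str, float] | pd.Series,
) -> tuple[dict[str, str], float]:
    """Label each sample high/low against the median of the supplied values.

    ``high`` means strictly above the median; ties at the median are low.
    Returns the labels and the median used.  All-identical values yield all
    low with a warning.
    """
    series = pd.Series(dict(values), dtype=float)
    series = series[np.isfinite(series)]
    if len(series) < 2:
        raise SignatureError("need at least 2 samples with finite values")
    med = float(series.median())
    if series.nunique() == 1:
        warnings.warn("all values identical; every sample labelled low", stacklevel=2)
    labels = {sid: (HIGH if v > med else LOW) for sid, v in series.items()}
    return labels, med


def assign_groups(wt_label: str, de4_label: str) -> tuple[int, str]:
    """Map the two marker labels to (3-group class, dual signature label).

    Group 1 = both low, group 3 = both high, group 2 otherwise; the dual
    signature is low only for group 1.
    """
    for lab in (wt_label, de4_label):
        if lab not in (LOW, HIGH):
            raise SignatureError(f"label must be 'low' or 'high', got {lab!r}")
    if wt_label == LOW and de4_label == LOW:
        return 1, LOW
    if wt_label == HIGH and de4_label == HIGH:
        return 3, HIGH
    return 2, HIGH


def concordance_fraction(assignments: Iterable[SignatureAssignment]) -> float:
    """Fraction of samples whose markers agree (group 1 or group 3)."""
    assignments = list(assignments)
    if not assignments:
        raise SignatureError("no assignments supplied")
    return sum(a.group3 in (1, 3) for a in assignments) / len(assignments)


def build_assignments(
    expression: pd.DataFrame,
    clinical: pd.DataFrame | None = None,
    wt_col: str = "wt_expr",
    de4_col: str = "de4_expr",
    e3_col: str | None = None,
    scope: str = "cohort",
) -> tuple[list[SignatureAssignment], dict]:
    """Dichotomize markers and assign signature groups for a whole table.

    ``expression`` must be indexed by sample id (or carry a ``sample_id``
    column).  With ``scope='subtype'`` the medians are computed within each
    molecular subtype (requires ``clinical`` with er/pr/her2 columns);
    the default ``'cohort'`` uses whole-cohort medians.  Samples with
    missing receptor status get no subtype and are excluded from
    subtype-scoped dichotomization (logged), but still receive cohort-scope
    labels.

    Returns the assignments and a metadata dict recording the scope and the
    median(s) actually used.
    """
    if scope not in ("cohort", "subtype"):
        raise SignatureError(f"scope must be 'cohort' or 'subtype', got {scope!r}")
    expr = expression.copy()
    if "sample_id" in expr.columns:
        expr = expr.set_index("sample_id")

    subtype_by_sample: dict[str, str | None] = {}
    if clinical is not None:
        clin = clinical.copy()
        if "sample_id" in clin.columns:
            clin = clin.set_index("sample_id")
        for sid, row in clin.iterrows():
            try:
                subtype_by_sample[sid] = assign_subtype(row["er"], row["pr"], row["her2"])
            except (SignatureError, KeyError) as exc:
                logger.info("sample %s excluded from subtype analyses: %s", sid, exc)
                subtype_by_sample[sid] = None

    def _labels(col: str) -> tuple[dict[str, str], dict[str, float]]:
        if scope == "cohort":
            labels, med = median_dichotomize(expr[col])
            return labels, {"cohort": med}
        if clinical is None:
            raise SignatureError("subtype scope requires a clinical table")
        labels, medians = {}, {}
        for st in SUBTYPES:
            ids = [s for s in expr.index if subtype_by_sample.get(s) == st]
            if len(ids) < 2:
                continue
            sub_labels, med = median_dichotomize(expr.loc[ids, col])
            labels.update(sub_labels)
            medians[st] = med
        return labels, medians

    wt_labels, wt_medians = _labels(wt_col)
    de4_labels, de4_medians = _labels(de4_col)
    e3_labels: dict[str, str] = {}
    e3_medians: dict[str, float] = {}
    if e3_col is not None:
        e3_labels, e3_medians = _labels(e3_col)

    assignments = []
    for sid in expr.index:
        if sid not in wt_labels or sid not in de4_labels:
            continue
        group3, dual = assign_groups(wt_labels[sid], de4_labels[sid])
        assignments.append(
            SignatureAssignment(
                sample_id=sid,
                wt_label=wt_labels[sid],
                de4_label=de4_labels[sid],
                group3=group3,
                dual=dual,
                subtype=subtype_by_sample.get(sid),
                e3_label=e3_labels.get(sid),
            )
        )
    meta = {
        "dichotomize_scope": scope,
        "medians": {"wt": wt_medians, "de4": de4_medians, **({"e3": e3_medians} if e3_col else {})},
        "n_assigned": len(assignments),
    }
    return assignments, meta


def assignments_to_frame(assignments: Sequence[SignatureAssignment]) -> pd.DataFrame:
    return pd.DataFrame([vars(a) for a in assignments])
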