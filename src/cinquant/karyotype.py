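"""Chromosome-count distributions and cohesion-defect (PCG) classification.

Mitotic spreads are consumed as annotation tables (one row per manually
scored spread), never as images. A primary-constriction gap (PCG) is a
visible separation of sister chromatids at the centromere; spreads are
graded NORMAL, PCG_I (defects in fewer than six chromosomes), PCG_II (six
or more) or PCG_III (cohesion lost entirely, chromatids scattered).
"""

from __future__ import annotations

import enum
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .cinstats import ks_compare, _student_t, significance_code

REQUIRED_SPREAD_COLUMNS = [
    "chromosome_count",
    "defective_chromosomes",
    "severity",
    "severe_spread",
]


class PCGCategory(enum.Enum):
    NORMAL = "NORMAL"
    PCG_I = "PCG_I"
    PCG_II = "PCG_II"
    PCG_III = "PCG_III"


def classify_pcg(
    defective_chromosomes: int,
    severe_spread: bool = False,
    severity: str = "mild",
    rule: str = "count",
) -> PCGCategory:
    """Grade one spread.

    Severe spreads (chromatids scattered) are PCG_III regardless of counts.
    Under the default ``count`` rule, 6 or more defective chromosomes give
    PCG_II and 1-5 give PCG_I irrespective of the mild/moderate adjective
    (the count boundary is authoritative; the adjectives are treated as
    descriptive). The alternative ``severity`` rule lets a 'moderate' label
    promote a sub-6 spread to PCG_II.
    """
    defective = int(defective_chromosomes)
    if defective < 0:
        raise ValueError("defective_chromosomes must be >= 0")
    if severity not in ("mild", "moderate"):
        raise ValueError("severity must be 'mild' or 'moderate'")
    if rule not in ("count", "severity"):
        raise ValueError("rule must be 'count' or 'severity'")
    if severe_spread:
        return PCGCategory.PCG_III
    if defective == 0:
        return PCGCategory.NORMAL
    if rule == "count":
        return PCGCategory.PCG_II if defective >= 6 else PCGCategory.PCG_I
    if severity == "moderate" or defective >= 6:
        return PCGCategory.PCG_II
    return PCGCategory.PCG_I


def classify_spreads(spreads: pd.DataFrame, rule: str = "count") -> pd.Series:
    """Vectorised :func:`classify_pcg` over a spread table."""
    _validate_spreads(spreads)
    return spreads.apply(
        lambda r: classify_pcg(
            r["defective_chromosomes"],
            bool(r["severe_spread"]),
            str(r["severity"]),
            rule=rule,
        ),
        axis=1,
    )


def _validate_spreads(spreads: pd.DataFrame) -> None:
    if spreads.empty:
        raise ValueError("empty spread table")
    missing = [c for c in REQUIRED_SPREAD_COLUMNS if c not in spreads.columns]
    if missing:
        raise ValueError(f"spread table missing columns: {missing}")
    if (spreads["chromosome_count"] < 1).any():
        raise ValueError("chromosome counts must be >= 1")
    if (spreads["defective_chromosomes"] < 0).any():
        raise ValueError("defective_chromosomes must be >= 0")
    bad = spreads["defective_chromosomes"] > spreads["chromosome_count"]
    if bad.any():
        raise ValueError("defective_chromosomes exceeds chromosome_count")


@dataclass
class PCGSummary:
    """Category proportions and defect frequency of one condition vs control."""

    proportions: dict  # category name -> proportion, sums to 1
    defect_frequency_pct: float
    control_defect_frequency_pct: float
    fold_change: float | None  # None when control defect frequency is zero
    p_value: float | None  # replicate t-test; None without >= 2 replicates
    code: str | None
    n_spreads: int
    qc_passed: bool  # n >= min_spreads in both groups

    def as_dict(self) -> dict:
        return asdict(self)


def _defect_pct(spreads: pd.DataFrame, rule: str) -> float:
    cats = classify_spreads(spreads, rule=rule)
    return 100.0 * float((cats != PCGCategory.NORMAL).mean())


def pcg_distribution(
    spreads: pd.DataFrame,
    control_spreads: pd.DataFrame,
    alpha: float = 0.05,
    min_spreads: int = 100,
    rule: str = "count",
) -> PCGSummary:
    """Category proportions, defect frequency and fold change vs control.

    If both tables carry a ``replicate`` column with at least two levels, a
    Student t-test compares per-replicate defect frequencies. Fewer than
    ``min_spreads`` spreads in either group sets the QC flag (analysis still
    runs).
    """
    _validate_spreads(spreads)
    _validate_spreads(control_spreads)
    cats = classify_spreads(spreads, rule=rule)
    proportions = {
        c.value: float((cats == c).mean()) for c in PCGCategory
    }
    defect = 100.0 * (1.0 - proportions[PCGCategory.NORMAL.value])
    control_defect = _defect_pct(control_spreads, rule)
    if defect == 0.0:
        fold: float | None = 0.0
    elif control_defect > 0:
        fold = defect / control_defect
    else:
        fold = None

    p_value = code = None
    if "replicate" in spreads.columns and "replicate" in control_spreads.columns:
        reps = [
            _defect_pct(g, rule) for _, g in spreads.groupby("replicate")
        ]
        ctrl_reps = [
            _defect_pct(g, rule) for _, g in control_spreads.groupby("replicate")
        ]
        if len(reps) >= 2 and len(ctrl_reps) >= 2:
            p_value = _student_t(np.array(reps), np.array(ctrl_reps))
            code = significance_code(p_value)

    return PCGSummary(
        proportions=proportions,
        defect_frequency_pct=defect,
        control_defect_frequency_pct=control_defect,
        fold_change=fold,
        p_value=p_value,
        code=code,
        n_spreads=len(spreads),
        qc_passed=len(spreads) >= min_spreads and len(control_spreads) >= min_spreads,
    )


@dataclass
class KaryotypeStats:
    """Chromosome-count distribution of a condition against its control."""

    modal_count: int
    control_modal_count: int
    counts: list[int]
    ks_d: float
    ks_p: float
    near_tetraploid_fraction: float  # counts > 1.5 x control modal

    def as_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = [int(c) for c in d["counts"]]
        return d


def modal_count(counts) -> int:
    """Most frequent chromosome count; ties resolve to the smallest value."""
    arr = np.asarray(counts, dtype=int)
    if arr.size == 0:
        raise ValueError("empty count list")
    values, freqs = np.unique(arr, return_counts=True)
    return int(values[np.argmax(freqs)])  # np.unique sorts -> first max = smallest


def count_distribution_stats(counts, control_counts) -> KaryotypeStats:
    """Modal number, KS comparison and near-tetraploid fraction.

    Counts above 1.5x the control modal number are scored near-tetraploid
    (consistent with a tetraploidization event followed by chromosome loss).
    """
    arr = np.asarray(counts, dtype=int)
    ctrl = np.asarray(control_counts, dtype=int)
    if arr.size == 0 or ctrl.size == 0:
        raise ValueError("count lists must be non-empty")
    ctrl_mode = modal_count(ctrl)
    ks = ks_compare(arr, ctrl)
    return KaryotypeStats(
        modal_count=modal_count(arr),
        control_modal_count=ctrl_mode,
        counts=[int(c) for c in arr],
        ks_d=ks.d,
        ks_p=ks.p_value,
        near_tetraploid_fraction=float((arr > 1.5 * ctrl_mode).mean()),
    )
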