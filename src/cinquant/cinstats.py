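"""Condition-level CIN statistics.

Micronucleus frequencies per 100 retained nuclei, fold changes with
classical two-sample Student t-tests across replicates, two-sample
Kolmogorov-Smirnov comparison of nuclear-area distributions, western-blot
densitometry normalization, and population-doubling arithmetic.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

SIGNIFICANCE_LEVELS = (
    (0.0001, "****"),
    (0.001, "***"),
    (0.01, "**"),
    (0.05, "*"),
)


def significance_code(p: float) -> str:
    """Map a p-value to the NS/*/**/***/**** convention (NS at p >= 0.05)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p-value must lie in [0, 1]")
    for threshold, code in SIGNIFICANCE_LEVELS:
        if p < threshold:
            return code
    return "NS"


@dataclass
class ConditionSummary:
    """Per-condition micronucleus summary relative to a control."""

    condition: str
    replicate_frequencies: list[float]  # percent, one per replicate
    mean_frequency: float
    sd_frequency: float
    fold_change: float | None  # None when the control mean is zero
    p_value: float
    code: str

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class KSResult:
    """Two-sample KS comparison against a control distribution."""

    d: float
    p_value: float
    direction: int  # sign of median(sample) - median(control)
    n_sample: int
    n_control: int
    small_sample_warning: bool

    def as_dict(self) -> dict:
        return asdict(self)


def micronucleus_frequency(mn: pd.DataFrame, cells: pd.DataFrame) -> float:
    """Micronuclei per 100 retained nuclei for one condition replicate.

    Uses the per-100-nuclei convention (a frequency, not the fraction of
    cells with at least one micronucleus; see the ``per_cell`` variant).
    """
    from .imaging import retained

    n_nuclei = len(retained(cells))
    if n_nuclei == 0:
        raise ValueError("undefined micronucleus frequency: zero retained nuclei")
    return 100.0 * len(mn) / n_nuclei


def micronucleus_frequency_per_cell(mn: pd.DataFrame, cells: pd.DataFrame) -> float:
    """Alternative reading: percent of retained nuclei owning >= 1 micronucleus."""
    from .imaging import retained

    kept = retained(cells)
    if kept.empty:
        raise ValueError("undefined micronucleus frequency: zero retained nuclei")
    owners = set(mn["owner_id"]) if not mn.empty else set()
    with_mn = kept["nucleus_id"].isin(owners).sum()
    return 100.0 * with_mn / len(kept)


def _student_t(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided equal-variance two-sample t-test p-value.

    Degenerate zero-variance inputs: p = 1 when the means agree, 0 otherwise.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    sa2 = a.var(ddof=1) if a.size > 1 else 0.0
    sb2 = b.var(ddof=1) if b.size > 1 else 0.0
    if sa2 == 0.0 and sb2 == 0.0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def fold_change_test(
    condition_freqs,
    control_freqs,
    condition: str = "condition",
    alpha: float = 0.05,
) -> ConditionSummary:
    """Fold change of mean replicate frequencies with a Student t-test.

    Requires at least two replicates per group. A zero control mean leaves
    the fold undefined (``None``) rather than raising.
    """
    cond = np.asarray(condition_freqs, dtype=float)
    ctrl = np.asarray(control_freqs, dtype=float)
    if cond.size < 2 or ctrl.size < 2:
        raise ValueError("need >= 2 replicates per group for a t-test")
    if np.any(cond < 0) or np.any(ctrl < 0):
        raise ValueError("frequencies must be >= 0")
    p = _student_t(cond, ctrl)
    ctrl_mean = ctrl.mean()
    fold = float(cond.mean() / ctrl_mean) if ctrl_mean > 0 else None
    return ConditionSummary(
        condition=condition,
        replicate_frequencies=[float(x) for x in cond],
        mean_frequency=float(cond.mean()),
        sd_frequency=float(cond.std(ddof=1)),
        fold_change=fold,
        p_value=p,
        code=significance_code(p),
    )


def ks_compare(sample, control) -> KSResult:
    """Two-sample KS test of a condition distribution against its control.

    The exact null distribution is used when either sample has fewer than 50
    observations, the asymptotic one otherwise; ``direction`` is the sign of
    the median shift relative to control.
    """
    a = np.asarray(sample, dtype=float)
    b = np.asarray(control, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if min(a.size, b.size) < 50 else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return KSResult(
        d=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        direction=int(np.sign(np.median(a) - np.median(b))),
        n_sample=int(a.size),
        n_control=int(b.size),
        small_sample_warning=bool(min(a.size, b.size) < 10),
    )


def relative_densitometry(
    target_band: float,
    loading_band: float,
    control_target_band: float,
    control_loading_band: float,
) -> float:
    """Loading-normalized band intensity relative to the control lane.

    ``(target / loading) / (control_target / control_loading)``; the control
    applied to itself is identically 1.00.
    """
    bands = (target_band, loading_band, control_target_band, control_loading_band)
    if any(b <= 0 for b in bands):
        raise ValueError("band intensities must be > 0")
    return (target_band / loading_band) / (control_target_band / control_loading_band)


def population_doublings(duration_h: float, doubling_time_h: float) -> float:
    """Number of population doublings over a time course, to one decimal.

    E.g. a 96 h silencing time course with a 22 h doubling time gives 4.4
    doublings; with 36 h, 2.7.
    """
    if duration_h <= 0 or doubling_time_h <= 0:
        raise ValueError("duration and doubling time must be > 0")
    return round(duration_h / doubling_time_h, 1)


def mitotic_event_ratio(doublings_a: float, doublings_b: float) -> float:
    """Ratio of two doubling counts (relative number of mitoses), one decimal."""
    if doublings_a <= 0 or doublings_b <= 0:
        raise ValueError("doubling counts must be > 0")
    return round(doublings_a / doublings_b, 1)
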