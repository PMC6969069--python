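"""Copy-number deletion frequencies and minimal-p survival cutpoint analysis.

Consumes local files only: thresholded gene x sample copy-number matrices in
the cBioPortal discrete coding (-2 deep deletion, -1 shallow deletion, 0,
1, 2) and per-patient survival tables (expression, follow-up months, event
flag). The expression threshold separating "low" from "high" groups is the
value between the 20th and 80th percentiles minimizing the log-rank
p-value — an exploratory minimal-p selection reported without correction
for the search, mirroring common clinical-genomics practice; treat the
selected p-value as descriptive, not confirmatory.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

VALID_CNA_CODES = {-2, -1, 0, 1, 2}


# ---------------------------------------------------------------------------
# CNA matrices
# ---------------------------------------------------------------------------


def validate_cna(matrix: pd.DataFrame) -> None:
    if matrix.empty:
        raise ValueError("empty CNA matrix")
    if matrix.index.duplicated().any():
        raise ValueError("duplicate gene ids")
    if matrix.columns.duplicated().any():
        raise ValueError("duplicate sample ids")
    bad = set(np.unique(matrix.to_numpy())) - VALID_CNA_CODES
    if bad:
        raise ValueError(f"invalid CNA codes present: {sorted(bad)}")


def read_cna(path: str | Path) -> pd.DataFrame:
    """Read a cBioPortal-style discrete CNA TSV (genes as rows).

    Accepts a leading ``Hugo_Symbol`` column (an ``Entrez_Gene_Id`` column,
    if present, is dropped) or any first column of gene identifiers.
    """
    df = pd.read_csv(path, sep="\t")
    gene_col = "Hugo_Symbol" if "Hugo_Symbol" in df.columns else df.columns[0]
    df = df.drop(columns=[c for c in ("Entrez_Gene_Id",) if c in df.columns])
    df = df.set_index(gene_col)
    df.index.name = "gene"
    matrix = df.astype(int)
    validate_cna(matrix)
    return matrix


def write_cna(matrix: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = matrix.copy()
    out.insert(0, "Hugo_Symbol", out.index)
    out.to_csv(path, sep="\t", index=False)
    return path


def deletion_frequency(matrix: pd.DataFrame) -> tuple[pd.Series, float]:
    """Per-gene and cumulative deletion frequencies (percent of samples).

    A sample counts as deleted for a gene when its code is <= -1 (shallow or
    deep loss); the cumulative frequency is the percentage of samples
    deleted in at least one gene.
    """
    validate_cna(matrix)
    deleted = matrix.to_numpy() <= -1
    per_gene = pd.Series(
        100.0 * deleted.mean(axis=1), index=matrix.index, name="deletion_pct"
    )
    cumulative = 100.0 * float(deleted.any(axis=0).mean())
    return per_gene, cumulative


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

SURVIVAL_REQUIRED = ["expression", "time_months", "event"]


def validate_cohort(cohort: pd.DataFrame) -> None:
    missing = [c for c in SURVIVAL_REQUIRED if c not in cohort.columns]
    if missing:
        raise ValueError(f"survival table missing columns: {missing}")
    if (cohort["time_months"] < 0).any():
        raise ValueError("times must be >= 0")
    if not cohort["event"].isin((0, 1)).all():
        raise ValueError("event flags must be 0/1")
    if not np.isfinite(cohort["expression"]).all():
        raise ValueError("expression values must be finite")


def read_cohort(path: str | Path) -> pd.DataFrame:
    cohort = pd.read_csv(path)
    validate_cohort(cohort)
    return cohort


@dataclass
class KMCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    times: list[float]
    survival: list[float]

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class LogrankResult:
    statistic: float | None
    p_value: float | None
    km_low: KMCurve
    km_high: KMCurve
    n_low: int
    n_high: int
    zero_event_group: bool = False

    def as_dict(self) -> dict:
        return asdict(self)


def _km_curve(times, events, label) -> KMCurve:
    kmf = KaplanMeierFitter()
    kmf.fit(times, events, label=label)
    sf = kmf.survival_function_
    return KMCurve(
        times=[float(t) for t in sf.index],
        survival=[float(v) for v in sf[label]],
    )


def km_logrank(group_low: pd.DataFrame, group_high: pd.DataFrame) -> LogrankResult:
    """Kaplan-Meier curves plus the 1-df log-rank test between two groups.

    A group without any observed event leaves the test undefined: curves are
    still returned, the statistic/p are ``None`` and the result is flagged.
    """
    for g in (group_low, group_high):
        validate_cohort(g)
        if g.empty:
            raise ValueError("both groups must be non-empty")
    km_low = _km_curve(group_low["time_months"], group_low["event"], "low")
    km_high = _km_curve(group_high["time_months"], group_high["event"], "high")
    if group_low["event"].sum() == 0 or group_high["event"].sum() == 0:
        return LogrankResult(
            statistic=None,
            p_value=None,
            km_low=km_low,
            km_high=km_high,
            n_low=len(group_low),
            n_high=len(group_high),
            zero_event_group=True,
        )
    res = logrank_test(
        group_low["time_months"],
        group_high["time_months"],
        event_observed_A=group_low["event"],
        event_observed_B=group_high["event"],
    )
    return LogrankResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        km_low=km_low,
        km_high=km_high,
        n_low=len(group_low),
        n_high=len(group_high),
    )


@dataclass
class CutpointResult:
    threshold: float
    percentile: float
    n_low: int
    n_high: int
    statistic: float
    p_value: float
    km_low: KMCurve
    km_high: KMCurve
    grid: list[tuple[float, float]] = field(default_factory=list)  # (pct, p)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = [[float(q), float(p)] for q, p in self.grid]
        return d


def find_cutpoint(
    cohort: pd.DataFrame,
    lower_pct: float = 20.0,
    upper_pct: float = 80.0,
    grid_step: float = 1.0,
) -> CutpointResult:
    """Minimal-p-value expression cutpoint on a percentile grid.

    Every candidate percentile in ``[lower_pct, upper_pct]`` (step
    ``grid_step``) splits the cohort at the corresponding expression value
    ("low" = strictly below the threshold); the candidate with the lowest
    log-rank p-value wins, ties resolving to the lower percentile. The
    selected p-value is exploratory: it is not corrected for the search.
    """
    validate_cohort(cohort)
    n = len(cohort)
    if n < 20:
        raise ValueError("cutpoint search requires n >= 20")
    if cohort["event"].sum() == 0:
        raise ValueError("cutpoint search undefined: all patients are censored")
    if not (0 < lower_pct < upper_pct < 100):
        raise ValueError("need 0 < lower_pct < upper_pct < 100")

    expression = cohort["expression"].to_numpy()
    times = cohort["time_months"].to_numpy()
    events = cohort["event"].to_numpy()
    best = None  # (p, pct, threshold, stat, low_mask)
    grid: list[tuple[float, float]] = []
    q = lower_pct
    while q <= upper_pct + 1e-9:
        threshold = float(np.percentile(expression, q))
        low = expression < threshold
        n_low = int(low.sum())
        if n_low == 0 or n_low == n:
            q += grid_step
            continue
        res = logrank_test(
            times[low],
            times[~low],
            event_observed_A=events[low],
            event_observed_B=events[~low],
        )
        p = float(res.p_value)
        grid.append((float(q), p))
        if best is None or p < best[0]:
            best = (p, float(q), threshold, float(res.test_statistic), low)
        q += grid_step
    if best is None:
        raise ValueError("no valid candidate split in the percentile band")
    p, pct, threshold, stat, low = best
    return CutpointResult(
        threshold=threshold,
        percentile=pct,
        n_low=int(low.sum()),
        n_high=int((~low).sum()),
        statistic=stat,
        p_value=p,
        km_low=_km_curve(times[low], events[low], "low"),
        km_high=_km_curve(times[~low], events[~low], "high"),
        grid=grid,
    )


def plot_km(result, path: str | Path, title: str = "Kaplan-Meier") -> Path:
    """Write a two-group KM plot (low vs high expression) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for curve, label, color in (
        (result.km_low, f"low (n={result.n_low})", "#c0392b"),
        (result.km_high, f"high (n={result.n_high})", "#2c3e50"),
    ):
        ax.step(curve.times, curve.survival, where="post", label=label, color=color)
    p = getattr(result, "p_value", None)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(title + ("" if p is None else f" (log-rank p = {p:.3g})"))
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
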