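"""Feasibility and acceptability analytics for prompt-based studies.

Covers the quantities a pilot of a physiology-triggered experience-sampling
design reports: per-member and pooled engagement (percentage of issued
surveys fully completed), sibling agreement via the one-way random-effects
intraclass correlation ICC(1) with LeBreton–Senter interpretation bands and
an a-priori aggregation cutoff of .51, paired t-tests with the paired
(d_z) form of Cohen's d, emotion/activity endorsement percentage tables,
Pearson correlation tables with significance flags, and ease-of-use /
satisfaction subscale scoring for the USE questionnaire (ease items 7–8
excluded for poor factor loadings).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .survey import TABLE_LABEL_ALIASES

__all__ = [
    "EngagementSummary",
    "AgreementResult",
    "PairedComparison",
    "UseScores",
    "engagement",
    "study_engagement",
    "icc1",
    "aggregate_children",
    "paired_comparison",
    "endorsement_table",
    "render_endorsement",
    "use_scores",
    "correlation_matrix",
]

#: LeBreton–Senter agreement bands for ICC(1), by lower cut point.
ICC_BANDS = (
    (0.91, "very strong"),
    (0.71, "strong"),
    (0.51, "moderate"),
    (0.31, "weak"),
    (-np.inf, "lack"),
)
AGGREGATION_CUTOFF = 0.51

#: Cohen's benchmarks for interpreting d.
D_BENCHMARKS = ((0.80, "large"), (0.50, "medium"), (0.20, "small"), (0.0, "negligible"))


@dataclass(frozen=True)
class EngagementSummary:
    """Response rate for one member and prompt kind (complete / received)."""

    member_id: str
    role: str
    kind: str  # random | deviation | overall
    n_received: int
    n_complete: int
    rate_pct: float  # NaN when undefined
    defined: bool


@dataclass(frozen=True)
class AgreementResult:
    """ICC(1) with its interpretation band and the aggregation decision."""

    icc1: float
    band: str | None
    aggregate: bool
    defined: bool = True
    n_groups: int = 0


@dataclass(frozen=True)
class PairedComparison:
    """Paired t-test with the paired-differences effect size d_z."""

    t_stat: float
    df: int
    p_two_sided: float
    cohens_d: float
    interpretation: str
    defined: bool = True


@dataclass(frozen=True)
class UseScores:
    """USE questionnaire subscale means on the 1–7 Likert metric."""

    ease_of_use: float
    satisfaction: float
    ease_items_used: int
    satisfaction_items_used: int
    has_missing: bool


def engagement(log: pd.DataFrame) -> list[EngagementSummary]:
    """Per-member response rates, separately per prompt kind plus overall.

    ``log`` is a finalized response log (no pending rows) with columns
    member_id, role, kind, status. Incomplete and missed surveys both count
    as non-complete; a member/kind cell with zero received prompts is
    flagged undefined rather than reported as 0%.
    """
    if (log["status"] == "pending").any():
        raise ValueError("response log contains pending surveys; finalize first")
    out: list[EngagementSummary] = []
    kinds = ("random", "deviation", "overall")
    for member_id, grp in log.groupby("member_id", sort=True):
        role = grp["role"].iloc[0]
        for kind in kinds:
            sub = grp if kind == "overall" else grp[grp["kind"] == kind]
            n_recv = int(len(sub))
            n_comp = int((sub["status"] == "complete").sum())
            if n_recv == 0:
                out.append(EngagementSummary(member_id, role, kind, 0, 0, float("nan"), False))
            else:
                out.append(
                    EngagementSummary(
                        member_id, role, kind, n_recv, n_comp, 100.0 * n_comp / n_recv, True
                    )
                )
    return out


def study_engagement(log: pd.DataFrame, method: str = "pooled", kind: str = "overall") -> float:
    """Study-level engagement percentage.

    ``method='pooled'`` pools all prompts (completed / received across every
    member); ``method='member_mean'`` averages the per-member rates. Both are
    provided because published overall rates do not always say which
    aggregation they use.
    """
    summaries = engagement(log)
    rows = [s for s in summaries if s.kind == kind and s.defined]
    if not rows:
        return float("nan")
    if method == "pooled":
        recv = sum(s.n_received for s in rows)
        comp = sum(s.n_complete for s in rows)
        return 100.0 * comp / recv
    if method == "member_mean":
        return float(np.mean([s.rate_pct for s in rows]))
    raise ValueError(f"unknown method {method!r}")


def icc1(values: Sequence[Sequence[float]] | np.ndarray) -> AgreementResult:
    """One-way random-effects intraclass correlation over sibling pairs.

    ``values`` is (n_families, 2): two child scores per family. The estimate
    is ``(MSB - MSW) / (MSB + (k-1) MSW)`` with k = 2, from the one-way
    ANOVA between/within mean squares. Negative estimates are reported as
    computed and banded as a lack of agreement; aggregation is warranted at
    the a-priori cutoff .51.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("each family must contribute exactly 2 child scores")
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 families for a stable ICC(1)")
    if np.any(~np.isfinite(arr)):
        raise ValueError("missing values are not allowed")
    n, k = arr.shape
    grand = arr.mean()
    means = arr.mean(axis=1)
    ssb = k * float(np.sum((means - grand) ** 2))
    ssw = float(np.sum((arr - means[:, None]) ** 2))
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    denom = msb + (k - 1) * msw
    if denom == 0:  # zero total variance
        return AgreementResult(float("nan"), None, False, defined=False, n_groups=n)
    icc = (msb - msw) / denom
    band = next(label for cut, label in ICC_BANDS if icc >= cut)
    return AgreementResult(
        float(icc), band, aggregate=bool(icc >= AGGREGATION_CUTOFF), n_groups=n
    )


def aggregate_children(
    pairs: Sequence[Sequence[float]] | np.ndarray, agreement: AgreementResult
) -> tuple[np.ndarray, bool]:
    """Mean the two child scores per family when agreement warrants it.

    Returns ``(values, aggregated)``: per-family means and True when
    ``agreement.aggregate``; otherwise the original (n, 2) array and False.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("each family must contribute exactly 2 child scores")
    if agreement.aggregate:
        return arr.mean(axis=1), True
    return arr, False


def paired_comparison(a: Sequence[float], b: Sequence[float]) -> PairedComparison:
    """Paired t-test between two matched per-family series.

    t = mean(d)/(sd(d)/sqrt(n)) with sample SD (n-1 denominator), two-sided p
    from Student's t with n-1 df, and Cohen's d in the paired d_z form
    mean(d)/sd(d). Zero-variance differences are flagged undefined (the
    effect size would be infinite) except for the trivial a == b case,
    which is t = 0, d = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired series must be 1-d and of equal length")
    if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
        raise ValueError("pairwise-complete data required")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = float(np.std(d, ddof=1))
    df = n - 1
    if sd == 0:
        if np.allclose(d, 0):
            return PairedComparison(0.0, df, 1.0, 0.0, "negligible")
        return PairedComparison(float("nan"), df, float("nan"), float("nan"),
                                "undefined (zero-variance differences)", defined=False)
    mean_d = float(np.mean(d))
    t = mean_d / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    dz = mean_d / sd
    interp = next(label for cut, label in D_BENCHMARKS if abs(dz) >= cut)
    return PairedComparison(float(t), df, p, float(dz), interp)


def endorsement_table(
    log: pd.DataFrame,
    labels: Sequence[str],
    field: str = "emotion",
    aliases: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Percentage of answered surveys endorsing each label, per role × kind.

    Each column is one (role, prompt-kind) group; cells are 100 × the label
    count over all surveys in the group where ``field`` was answered, so
    every column sums to 100 up to rounding. Zero-count cells are NaN here
    (rendered as "-" by :func:`render_endorsement`). ``aliases`` optionally
    relabels rows for presentation (e.g. relaxed → content as some summary
    tables print it). Empty groups are omitted with a warning.
    """
    answered = log[(log[field].notna()) & (log[field] != "")]
    cols: dict[tuple[str, str], pd.Series] = {}
    for role in ("mother", "father", "child"):
        for kind in ("random", "deviation"):
            grp = answered[(answered["role"] == role) & (answered["kind"] == kind)]
            if len(grp) == 0:
                warnings.warn(f"no answered surveys for {role}/{kind}; column omitted")
                continue
            counts = grp[field].value_counts()
            pct = pd.Series(
                [100.0 * counts.get(lab, 0) / len(grp) for lab in labels], index=list(labels)
            )
            cols[(role, kind)] = pct.where(pct > 0, np.nan)
    table = pd.DataFrame(cols)
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["role", "kind"])
    if aliases:
        table.index = [aliases.get(lab, lab) for lab in table.index]
    return table


def render_endorsement(table: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Human-readable endorsement table: percentages with a dash for zero."""
    return table.map(lambda v: "-" if pd.isna(v) else f"{v:.{decimals}f}%")


_EASE_EXCLUDED = (7, 8)  # 1-based item numbers with poor factor loadings


def use_scores(
    ease_items: Sequence[float | None], satisfaction_items: Sequence[float | None]
) -> UseScores:
    """Score the USE ease-of-use and satisfaction subscales.

    ``ease_items`` are the 11 ease items in order (items 7–8 are dropped
    before averaging, so the subscale mean covers the 9 retained items);
    ``satisfaction_items`` are the 4 satisfaction items. Items are 1–7
    Likert integers; None marks a skipped item, scored as the mean of the
    available retained items with the missing flag set.
    """
    if len(ease_items) != 11:
        raise ValueError("expected the 11 ease-of-use items in order")
    if len(satisfaction_items) != 4:
        raise ValueError("expected the 4 satisfaction items")
    retained = [v for i, v in enumerate(ease_items, start=1) if i not in _EASE_EXCLUDED]

    def _mean(items, label):
        vals = []
        missing = False
        for v in items:
            if v is None or (isinstance(v, float) and np.isnan(v)):
                missing = True
                continue
            if not float(v).is_integer() or not (1 <= v <= 7):
                raise ValueError(f"{label} item {v!r} outside the 1–7 Likert scale")
            vals.append(float(v))
        if not vals:
            raise ValueError(f"all {label} items missing")
        return float(np.mean(vals)), len(vals), missing

    ease, n_ease, miss_e = _mean(retained, "ease-of-use")
    sat, n_sat, miss_s = _mean(satisfaction_items, "satisfaction")
    return UseScores(ease, sat, n_ease, n_sat, miss_e or miss_s)


def correlation_matrix(
    data: pd.DataFrame, alpha_levels: tuple[float, float] = (0.05, 0.01)
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations with significance annotation.

    Returns ``(r, annotated)``: the numeric correlation matrix (NaN where a
    variable is constant on the pairwise-complete subset) and a string
    matrix with ``*``/``**`` at p < .05 / p < .01 and ``†`` marking a
    nonsignificant |r| > .50.
    """
    cols = list(data.columns)
    r = pd.DataFrame(np.nan, index=cols, columns=cols, dtype=float)
    ann = pd.DataFrame("", index=cols, columns=cols, dtype=object)
    for i, ci in enumerate(cols):
        for j, cj in enumerate(cols):
            x, y = data[ci], data[cj]
            mask = x.notna() & y.notna()
            xs, ys = x[mask].to_numpy(float), y[mask].to_numpy(float)
            if i == j:
                r.loc[ci, cj] = 1.0
                ann.loc[ci, cj] = "1"
                continue
            if mask.sum() < 3 or np.std(xs) == 0 or np.std(ys) == 0:
                ann.loc[ci, cj] = "undef"
                continue
            rr, p = stats.pearsonr(xs, ys)
            r.loc[ci, cj] = rr
            star = "**" if p < alpha_levels[1] else "*" if p < alpha_levels[0] else ""
            dagger = "†" if (not star and abs(rr) > 0.50) else ""
            ann.loc[ci, cj] = f"{rr:.2f}{star}{dagger}"
    return r, ann
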