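"""Absolute and relative reliability of window summaries vs the 300 s reference.

Absolute reliability (agreement) is quantified with Bland-Altman statistics
on per-participant relative differences; relative reliability with the
pairwise coefficient of variation and intraclass correlation coefficients
under the two-way absolute-agreement model:

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))
    ICC(A,k) = (MSR - MSE) / (MSR + (MSC - MSE)/n)

with MSR/MSC/MSE the between-subjects, between-raters and residual mean
squares of the subjects x raters table, and F-based 95% confidence intervals
(McGraw-Wong).  The ICC-based sample-size calculation for planning a
reliability study is also provided.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: ICC interpretation bands: [0, .5) poor, [.5, .75) moderate,
#: [.75, .9) good, [.9, 1] excellent.
ICC_CATEGORIES = (
    (0.50, "poor"),
    (0.75, "moderate"),
    (0.90, "good"),
    (math.inf, "excellent"),
)


def icc_category(estimate: float) -> str:
    for upper, name in ICC_CATEGORIES:
        if estimate < upper:
            return name
    return "excellent"


@dataclass(frozen=True)
class BlandAltmanResult:
    n: int
    bias_pct: float
    sd_pct: float
    loa_low_pct: float
    loa_high_pct: float


@dataclass(frozen=True)
class CovResult:
    per_participant_cov_pct: np.ndarray
    mean_cov_pct: float
    sd_cov_pct: float
    median_cov_pct: float


@dataclass(frozen=True)
class IccComponents:
    n_subjects: int
    k_raters: int
    msr: float
    msc: float
    mse: float


@dataclass(frozen=True)
class IccResult:
    form: str  # "single" | "mean"
    estimate: float
    ci_low: float
    ci_high: float
    ci_level: float
    category: str | None
    defined: bool = True


def _paired(short, ref) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(short, dtype=float)
    r = np.asarray(ref, dtype=float)
    if s.shape != r.shape:
        raise ValueError("short and reference values must be paired")
    keep = np.isfinite(s) & np.isfinite(r)
    if keep.sum() < len(s):
        log.warning("dropped %d pairs with a missing side", len(s) - keep.sum())
    return s[keep], r[keep]


def bland_altman(short, ref) -> BlandAltmanResult:
    """Bland-Altman agreement on per-pair relative differences (%).

    Each pair contributes ``100 * (short - ref) / pair mean``; bias is the
    mean, and the 95% limits of agreement are bias +/- 1.96 sample SD.
    Pairs with a zero mean are excluded with a warning.
    """
    s, r = _paired(short, ref)
    mean = 0.5 * (s + r)
    ok = mean != 0
    if (~ok).any():
        log.warning("excluded %d pairs with zero pair mean", (~ok).sum())
    s, r, mean = s[ok], r[ok], mean[ok]
    if len(s) < 2:
        raise ValueError("Bland-Altman needs at least two pairs")
    rel = 100.0 * (s - r) / mean
    bias = float(rel.mean())
    sd = float(rel.std(ddof=1))
    return BlandAltmanResult(
        n=len(s), bias_pct=bias, sd_pct=sd,
        loa_low_pct=bias - 1.96 * sd, loa_high_pct=bias + 1.96 * sd,
    )


def pairwise_cov(short, ref) -> CovResult:
    """Per-participant two-measurement CoV (%) between a window and the reference.

    CoV = 100 * SD(short, ref) / mean(short, ref), with the sample SD of the
    two values, i.e. ``|short - ref| / sqrt(2)`` over the pair mean.  Pairs
    with non-positive mean are excluded with a warning.
    """
    s, r = _paired(short, ref)
    mean = 0.5 * (s + r)
    ok = mean > 0
    if (~ok).any():
        log.warning("excluded %d pairs with non-positive mean from CoV", (~ok).sum())
    s, r, mean = s[ok], r[ok], mean[ok]
    cov = 100.0 * (np.abs(s - r) / math.sqrt(2.0)) / mean
    return CovResult(
        per_participant_cov_pct=cov,
        mean_cov_pct=float(cov.mean()),
        sd_cov_pct=float(cov.std(ddof=1)) if len(cov) > 1 else 0.0,
        median_cov_pct=float(np.median(cov)),
    )


def icc_components(data) -> IccComponents:
    """Two-way ANOVA mean squares of a complete subjects x raters table.

    Subjects with any missing rating are dropped (logged).  Requires at least
    three complete subjects and two raters.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D subjects x raters table")
    complete = np.all(np.isfinite(x), axis=1)
    if (~complete).any():
        log.warning("dropped %d subjects with missing ratings", (~complete).sum())
    x = x[complete]
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError(f"need >= 3 complete subjects and >= 2 raters, got {n} x {k}")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((x - grand) ** 2).sum())
    sse = sst - ssr - ssc
    return IccComponents(
        n_subjects=n, k_raters=k,
        msr=ssr / (n - 1), msc=ssc / (k - 1),
        mse=max(sse, 0.0) / ((n - 1) * (k - 1)),
    )


def _sb(icc: float, k: float) -> float:
    """Spearman-Brown step-up of a single-rating ICC to the mean of k ratings."""
    return k * icc / (1.0 + (k - 1.0) * icc)


def icc_estimate(c: IccComponents, form: str = "single", ci_level: float = 0.95) -> IccResult:
    """Absolute-agreement two-way ICC with an F-based confidence interval.

    ``form='single'`` gives ICC(A,1); ``form='mean'`` gives ICC(A,k).  A table
    with zero variance everywhere has no defined ICC and is flagged rather
    than coerced to 0 or 1.
    """
    if form not in ("single", "mean"):
        raise ValueError("form must be 'single' or 'mean'")
    n, k = c.n_subjects, c.k_raters
    msr, msc, mse = c.msr, c.msc, c.mse
    if msr == 0 and msc == 0 and mse == 0:
        return IccResult(form, math.nan, math.nan, math.nan, ci_level, None, False)

    single = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    estimate = single if form == "single" else (msr - mse) / (msr + (msc - mse) / n)

    if mse == 0 and msc == 0:
        # perfect agreement: the F machinery degenerates
        return IccResult(form, 1.0, 1.0, 1.0, ci_level, icc_category(1.0))

    alpha = 1.0 - ci_level
    r = single
    a = k * r / (n * (1.0 - r)) if r < 1 else math.inf
    b = 1.0 + k * r * (n - 1.0) / (n * (1.0 - r)) if r < 1 else math.inf
    with np.errstate(all="ignore"):
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        nu = num / den if den > 0 else (n - 1) * (k - 1)
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, nu)
    f_u = stats.f.ppf(1 - alpha / 2, nu, n - 1)
    lo = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr)
    if form == "mean":
        lo, hi = _sb(lo, k), _sb(hi, k)
    lo = min(lo, estimate) if np.isfinite(lo) else estimate
    hi = max(hi, estimate) if np.isfinite(hi) else estimate
    return IccResult(form, float(estimate), float(lo), float(hi), ci_level,
                     icc_category(float(estimate)))


@dataclass(frozen=True)
class SampleSizeParams:
    rho0: float  # minimum acceptable reliability
    rho1: float  # expected reliability
    alpha: float = 0.05  # two-sided
    power: float = 0.95
    k: int = 3  # repetitions per participant

    def __post_init__(self) -> None:
        if not (0 < self.rho0 < 1 and 0 < self.rho1 < 1):
            raise ValueError("rho0 and rho1 must lie in (0, 1)")
        if self.rho1 <= self.rho0:
            raise ValueError("expected reliability must exceed the acceptable minimum")
        if self.k < 2:
            raise ValueError("need at least two repetitions per participant")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")


def icc_sample_size(p: SampleSizeParams) -> int:
    """Participants required to show the ICC exceeds ``rho0`` (Walter-Eliasziw-Donner).

    n = ceil( 1 + 2 (z_{alpha/2} + z_power)^2 k / ((ln C0)^2 (k - 1)) ) with
    theta_i = rho_i / (1 - rho_i) and C0 = (1 + k theta0) / (1 + k theta1).
    Alpha is interpreted two-sided.
    """
    theta0 = p.rho0 / (1.0 - p.rho0)
    theta1 = p.rho1 / (1.0 - p.rho1)
    c0 = (1.0 + p.k * theta0) / (1.0 + p.k * theta1)
    z = stats.norm.ppf(1.0 - p.alpha / 2.0) + stats.norm.ppf(p.power)
    n = 1.0 + 2.0 * z**2 * p.k / (math.log(c0) ** 2 * (p.k - 1.0))
    return int(math.ceil(n))


# ---------------------------------------------------------------------------
# full reliability battery

RELIABILITY_COLUMNS = [
    "frequency_hz", "direction", "metric", "comparison", "statistic",
    "estimate", "ci_low", "ci_high", "n",
]


def _rows_for_pair(freq, direction, metric, label, short, ref, ci_level):
    rows = []
    ba = bland_altman(short, ref)
    rows.append((freq, direction, metric, label, "ba_bias_pct",
                 ba.bias_pct, ba.loa_low_pct, ba.loa_high_pct, ba.n))
    cov = pairwise_cov(short, ref)
    rows.append((freq, direction, metric, label, "cov_mean_pct",
                 cov.mean_cov_pct, cov.median_cov_pct, cov.sd_cov_pct,
                 len(cov.per_participant_cov_pct)))
    comp = icc_components(np.column_stack([short, ref]))
    icc = icc_estimate(comp, "single", ci_level)
    rows.append((freq, direction, metric, label, "icc_between_single",
                 icc.estimate, icc.ci_low, icc.ci_high, comp.n_subjects))
    return rows


def reliability_battery(
    summaries: pd.DataFrame,
    transitions: pd.DataFrame | None = None,
    *,
    reference_window_s: float = 300.0,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Bland-Altman, CoV and ICC of every shorter window vs the reference.

    ``summaries`` is the tidy window-summary table (one row per participant x
    frequency x direction x window).  If the per-transition table is supplied,
    within-duration mean-rating ICCs — each transition's ratio against the
    window average, k = transitions per window — are appended.
    """
    rows = []
    metrics = ("ratio_abs", "ratio_rel")
    for (freq, direction), grp in summaries.groupby(["frequency_hz", "direction"]):
        for metric in metrics:
            wide = grp.pivot_table(
                index="participant", columns="window_s",
                values=f"mean_{metric}", aggfunc="first")
            if reference_window_s not in wide.columns:
                raise ValueError(
                    f"reference window {reference_window_s} s missing from summaries")
            ref = wide[reference_window_s]
            for w in sorted(c for c in wide.columns if c != reference_window_s):
                label = f"{int(w)}_vs_{int(reference_window_s)}"
                rows.extend(_rows_for_pair(
                    freq, direction, metric, label, wide[w].to_numpy(),
                    ref.to_numpy(), ci_level))

    if transitions is not None:
        rows.extend(_within_duration_rows(
            transitions, summaries, ci_level=ci_level))
    return pd.DataFrame(rows, columns=RELIABILITY_COLUMNS)


def _within_duration_rows(transitions, summaries, *, ci_level):
    """Within-duration ICC(A,k): subjects x first-k-transition ratio tables."""
    rows = []
    windows = sorted(summaries["window_s"].unique())
    inc = transitions[transitions["included"]]
    for (freq, direction), grp in inc.groupby(["frequency_hz", "direction"]):
        for metric in ("ratio_abs", "ratio_rel"):
            for w in windows:
                sub = grp[grp["map_to_time_s"] <= w]
                lists = {
                    pid: part.sort_values("index")[metric].abs().to_numpy()
                    for pid, part in sub.groupby("participant")
                }
                if not lists:
                    continue
                counts = np.array([len(v) for v in lists.values()])
                k = int(np.bincount(counts).argmax())  # modal transition count
                if k < 2:
                    continue
                table = np.array([v[:k] for v in lists.values() if len(v) >= k])
                if table.shape[0] < 3:
                    continue
                comp = icc_components(table)
                icc = icc_estimate(comp, "mean", ci_level)
                rows.append((freq, direction, metric, f"within_{int(w)}",
                             "icc_within_mean", icc.estimate, icc.ci_low,
                             icc.ci_high, comp.n_subjects))
    return rows
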