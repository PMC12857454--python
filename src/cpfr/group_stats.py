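"""Group-level inference on window summaries.

Two-way fully repeated-measures ANOVA (MAP direction x RSS duration), each
within-subject effect tested against its subject-by-factor interaction, with
Greenhouse-Geisser sphericity correction for factors with more than two
levels; Dunnett-style comparisons of each duration against the 300 s
reference with a seeded max-|t| Monte Carlo family-wise adjustment; and
Friedman rank tests for covariates with signed-rank post hocs under a
Bonferroni-Holm adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class RmAnovaResult:
    effect: str
    f_value: float
    df1: float
    df2: float
    gg_epsilon: float
    df1_corrected: float
    df2_corrected: float
    p_value: float
    ss_effect: float
    ss_error: float


def _orthonormal_contrasts(levels: int) -> np.ndarray:
    """(levels-1) x levels orthonormal contrast matrix (rows sum to zero)."""
    h = np.eye(levels) - np.ones((levels, levels)) / levels
    # orthonormal basis of the centering space via QR
    q, _ = np.linalg.qr(h)
    return q[:, : levels - 1].T


def _gg_epsilon(scores: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from per-subject contrast scores.

    ``scores``: subjects x contrasts matrix (already contrast-transformed);
    epsilon = tr(S)^2 / (d * tr(S^2)) with S the contrast covariance, clipped
    to its theoretical range [1/d, 1].
    """
    d = scores.shape[1]
    if d <= 1:
        return 1.0
    s = np.cov(scores, rowvar=False, ddof=1)
    s = np.atleast_2d(s)
    eps = np.trace(s) ** 2 / (d * float((s * s).sum()))
    return float(np.clip(eps, 1.0 / d, 1.0))


def rm_anova_2way(
    data: np.ndarray,
    factor_a: str = "direction",
    factor_b: str = "duration",
    gg_correction: bool = True,
) -> list[RmAnovaResult]:
    """Two-way fully within-subjects ANOVA on an ``n x a x b`` array.

    One observation per subject per cell; subjects with any missing cell must
    be removed beforehand.  Returns results for factor A, factor B and their
    interaction, in that order.  When ``gg_correction`` is on, any effect
    whose numerator involves a factor with more than two levels has its
    degrees of freedom multiplied by the Greenhouse-Geisser epsilon estimated
    from that effect's contrast covariance.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected an n x a x b array")
    if not np.all(np.isfinite(x)):
        raise ValueError("complete-case data required (drop incomplete subjects first)")
    n, a, b = x.shape
    if n < 3:
        raise ValueError("need at least three complete participants")

    grand = x.mean()
    m_s = x.mean(axis=(1, 2))
    m_a = x.mean(axis=(0, 2))
    m_b = x.mean(axis=(0, 1))
    m_ab = x.mean(axis=0)
    m_sa = x.mean(axis=2)
    m_sb = x.mean(axis=1)

    ss_a = n * b * float(((m_a - grand) ** 2).sum())
    ss_b = n * a * float(((m_b - grand) ** 2).sum())
    ss_ab = n * float(((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum())
    ss_as = b * float(((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum())
    ss_bs = a * float(((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum())
    ss_s = a * b * float(((m_s - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_abs = ss_total - ss_a - ss_b - ss_ab - ss_as - ss_bs - ss_s

    c_a = _orthonormal_contrasts(a)
    c_b = _orthonormal_contrasts(b)
    eps_a = _gg_epsilon(x.mean(axis=2) @ c_a.T)
    eps_b = _gg_epsilon(x.mean(axis=1) @ c_b.T)
    c_ab = np.kron(c_a, c_b)
    eps_ab = _gg_epsilon(x.reshape(n, a * b) @ c_ab.T)

    specs = [
        (factor_a, ss_a, a - 1, ss_as, (n - 1) * (a - 1), eps_a, a),
        (factor_b, ss_b, b - 1, ss_bs, (n - 1) * (b - 1), eps_b, b),
        ("interaction", ss_ab, (a - 1) * (b - 1), ss_abs,
         (n - 1) * (a - 1) * (b - 1), eps_ab, max(a, b)),
    ]
    out = []
    for effect, ss_eff, df1, ss_err, df2, eps, levels in specs:
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        f = ms_eff / ms_err if ms_err > 0 else (0.0 if ms_eff == 0 else np.inf)
        use_eps = eps if (gg_correction and levels > 2) else 1.0
        d1, d2 = df1 * use_eps, df2 * use_eps
        p = float(stats.f.sf(f, d1, d2)) if np.isfinite(f) else 0.0
        out.append(RmAnovaResult(
            effect=effect, f_value=float(f), df1=df1, df2=df2,
            gg_epsilon=use_eps, df1_corrected=d1, df2_corrected=d2,
            p_value=p, ss_effect=ss_eff, ss_error=ss_err,
        ))
    return out


@dataclass(frozen=True)
class ComparisonResult:
    level: float
    reference: float
    mean_difference: float
    t_value: float
    unadjusted_p: float
    adjusted_p: float
    method: str


def dunnett_vs_reference(
    data: np.ndarray,
    levels: list[float],
    reference: float,
    mc_draws: int = 50_000,
    seed: int = 0,
) -> list[ComparisonResult]:
    """Paired comparisons of each level against a reference level.

    ``data`` is an ``n x len(levels)`` complete table.  For each non-reference
    level a paired t statistic of the within-subject difference is computed;
    the family-wise adjusted p-value is P(max_j |T_j| >= |t_obs|) under a
    multivariate-t null (correlation estimated from the difference scores;
    common chi-square scale with n-1 df) evaluated by seeded Monte Carlo.
    With a single comparison this reduces to the exact paired two-sided test
    up to Monte Carlo error.
    """
    x = np.asarray(data, dtype=float)
    if reference not in levels:
        raise ValueError(f"reference level {reference} not among levels {levels}")
    if x.shape[1] != len(levels):
        raise ValueError("data columns must match levels")
    ref_ix = levels.index(reference)
    others = [j for j in range(len(levels)) if j != ref_ix]
    n = x.shape[0]
    d = x[:, others] - x[:, [ref_ix]]
    means = d.mean(axis=0)
    sds = d.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_obs = np.where(sds > 0, means / (sds / np.sqrt(n)), 0.0)
    df = n - 1
    unadj = 2.0 * stats.t.sf(np.abs(t_obs), df)

    m = len(others)
    if m == 1:
        corr = np.eye(1)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(d, rowvar=False)
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)
        # nearest PSD guard for degenerate samples
        w, v = np.linalg.eigh(corr)
        corr = (v * np.clip(w, 1e-10, None)) @ v.T

    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((mc_draws, m)) @ chol.T
    scale = np.sqrt(rng.chisquare(df, mc_draws) / df)
    max_t = np.abs(z).max(axis=1) / scale
    adj = np.array([(max_t >= abs(t)).mean() for t in t_obs])
    adj = np.maximum(adj, unadj)  # adjusted p can never undercut unadjusted

    return [
        ComparisonResult(
            level=levels[j], reference=reference,
            mean_difference=float(means[i]), t_value=float(t_obs[i]),
            unadjusted_p=float(unadj[i]), adjusted_p=float(min(adj[i], 1.0)),
            method="dunnett_mc",
        )
        for i, j in enumerate(others)
    ]


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, ix in enumerate(order):
        running = max(running, (m - rank) * pvals[ix])
        adj[ix] = min(running, 1.0)
    return adj


def friedman_vs_reference(
    data: np.ndarray,
    levels: list[float],
    reference: float,
) -> tuple[float, float, list[ComparisonResult]]:
    """Friedman chi-square across levels plus signed-rank post hocs vs reference.

    Returns ``(chi2, p, comparisons)``.  The post-hoc comparisons are Wilcoxon
    signed-rank tests of each level against the reference with Bonferroni-Holm
    adjustment (the adjustment choice is an interpretation, labelled in the
    ``method`` field).  A table whose rows are all constant yields chi2 = 0,
    p = 1.
    """
    x = np.asarray(data, dtype=float)
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 participants and >= 2 levels")
    if np.all(x == x[:, [0]]):
        chi2, p = 0.0, 1.0
    else:
        chi2, p = stats.friedmanchisquare(*(x[:, j] for j in range(k)))
    ref_ix = levels.index(reference)
    others = [j for j in range(k) if j != ref_ix]
    raw = []
    for j in others:
        diff = x[:, j] - x[:, ref_ix]
        if np.all(diff == 0):
            raw.append(1.0)
        else:
            raw.append(float(stats.wilcoxon(x[:, j], x[:, ref_ix]).pvalue))
    adj = _holm(np.asarray(raw))
    comps = [
        ComparisonResult(
            level=levels[j], reference=reference,
            mean_difference=float((x[:, j] - x[:, ref_ix]).mean()),
            t_value=np.nan, unadjusted_p=raw[i], adjusted_p=float(adj[i]),
            method="friedman_posthoc",
        )
        for i, j in enumerate(others)
    ]
    return float(chi2), float(p), comps
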