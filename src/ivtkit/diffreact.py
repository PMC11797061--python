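"""Position-wise differential SHAPE reactivity between two RNAs.

Normalized reactivities are square-root transformed (a variance-stabilising
transform for the underlying rate differences), a two-group linear model is
fitted per position, and per-position variances are shrunk toward a common
prior with an empirical-Bayes moderated t-test.  The moderation follows the
scaled-F hierarchical model: residual variances s_g^2 on d degrees of
freedom are assumed to be drawn around a prior variance s0^2 with prior
degrees of freedom d0, the posterior variance is

    s~_g^2 = (d0 s0^2 + d s_g^2) / (d0 + d)

and the moderated t statistic is referred to a t distribution on d + d0
degrees of freedom.  (d0, s0^2) are estimated by matching moments of
log s_g^2 through the digamma/trigamma identities; when the trigamma
equation has no positive solution the prior is infinitely informative
(d0 = inf) and every posterior variance equals s0^2.

Per the study's convention, significance is a fixed strict threshold
P < alpha (default 0.001) with no multiplicity correction; a
Benjamini-Hochberg option exists but is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import digamma, polygamma

from .exceptions import InsufficientDataError, ParameterError

MIN_TESTABLE_POSITIONS = 10


@dataclass
class ModeratedTestResult:
    """Per-position moderated test with the global prior estimates."""

    effect: np.ndarray  # mean(A) - mean(B) on the transformed scale
    s2: np.ndarray  # pooled within-group sample variance
    df_residual: float
    s2_post: np.ndarray  # moderated (posterior) variance
    t: np.ndarray
    df_total: float
    p: np.ndarray
    significant: np.ndarray
    d0: float  # prior degrees of freedom
    s02: float  # prior variance
    alpha: float
    testable: np.ndarray  # False where the position could not be tested


def sqrt_transform(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """value -> sqrt(max(value, 0)); returns (transformed, clamp flags).

    Normalized reactivities can be negative (the NAI rate can fall below the
    DMSO background by chance); they are clamped to zero before the square
    root and the affected positions are flagged.
    """
    m = np.asarray(matrix, dtype=float)
    clamped = m < 0
    return np.sqrt(np.where(clamped, 0.0, m)), clamped


def fit_position_models(
    group_a: np.ndarray, group_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int, np.ndarray]:
    """Two-group linear model per position.

    Returns (effect, pooled variance s^2, residual df d, testable mask);
    effect = mean(A) - mean(B), s^2 the pooled within-group variance on
    d = nA + nB - 2 df.  Positions with a non-finite value in any replicate
    are masked from testing.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2:
        raise ParameterError("replicate matrices must be positions x replicates")
    if a.shape[0] != b.shape[0]:
        raise ParameterError("groups cover different position sets")
    n_a, n_b = a.shape[1], b.shape[1]
    df = n_a + n_b - 2
    if df < 1:
        raise InsufficientDataError("need >= 2 residual degrees of freedom")
    testable = np.all(np.isfinite(a), axis=1) & np.all(np.isfinite(b), axis=1)
    effect = a.mean(axis=1) - b.mean(axis=1)
    ss = np.sum((a - a.mean(axis=1, keepdims=True)) ** 2, axis=1) + np.sum(
        (b - b.mean(axis=1, keepdims=True)) ** 2, axis=1
    )
    s2 = ss / df
    effect[~testable] = np.nan
    s2[~testable] = np.nan
    return effect, s2, df, testable


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the near-linear 1/trigamma)."""
    if y <= 0:
        raise ParameterError("trigamma inverse needs y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if -dif / x < 1e-10:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F marginal of the variances.

    With z = log s^2, e = z - digamma(d/2) + log(d/2) has mean
    log s0^2 + digamma(d0/2) - log(d0/2) and excess variance trigamma(d0/2)
    beyond trigamma(d/2); matching the empirical mean and variance of e
    yields (d0, s0^2).  A non-positive excess variance maps to d0 = inf.
    """
    s2 = np.asarray(s2, dtype=float)
    finite = np.isfinite(s2)
    positive = finite & (s2 > 0)
    if positive.sum() < MIN_TESTABLE_POSITIONS:
        raise InsufficientDataError(
            f"only {int(positive.sum())} positions with positive variance; "
            f"need >= {MIN_TESTABLE_POSITIONS}"
        )
    z = np.log(s2[positive])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return d0, s02


def ebayes_moderate(
    effect: np.ndarray,
    s2: np.ndarray,
    df: float,
    n_a: int,
    n_b: int,
    alpha: float = 0.001,
    d0: float | None = None,
    s02: float | None = None,
) -> ModeratedTestResult:
    """Moderated t-test given per-position effects and pooled variances.

    ``d0``/``s02`` may be supplied to override the empirical prior (``d0=0``
    disables moderation and reproduces the classical pooled t-test).  The
    total degrees of freedom d + d0 are capped at the pooled residual df of
    all testable positions.
    """
    effect = np.asarray(effect, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    testable = np.isfinite(effect) & np.isfinite(s2)
    if d0 is None or s02 is None:
        if np.all(np.nan_to_num(s2[testable]) == 0):
            raise InsufficientDataError("all position variances are zero")
        est_d0, est_s02 = estimate_prior(s2, df)
        d0 = est_d0 if d0 is None else d0
        s02 = est_s02 if s02 is None else s02
    if d0 < 0:
        raise ParameterError("prior degrees of freedom must be >= 0")

    if np.isinf(d0):
        s2_post = np.where(testable, s02, np.nan)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        df_total = df + d0
        if d0 > 0:
            df_total = min(df_total, df * int(testable.sum()))  # pooled-df cap

    se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.where(testable, p, np.nan)
    t = np.where(testable, t, np.nan)
    return ModeratedTestResult(
        effect=effect,
        s2=s2,
        df_residual=float(df),
        s2_post=s2_post,
        t=t,
        df_total=float(df_total),
        p=p,
        significant=call_significant(p, alpha),
        d0=float(d0),
        s02=float(s02),
        alpha=alpha,
        testable=testable,
    )


def call_significant(p: np.ndarray, alpha: float = 0.001) -> np.ndarray:
    """Strict threshold flags: significant iff p < alpha (no correction)."""
    p = np.asarray(p, dtype=float)
    if p.size and np.nanmin(p) < 0 or p.size and np.nanmax(p) > 1:
        raise ParameterError("p-values must lie in [0, 1]")
    with np.errstate(invalid="ignore"):
        return (p < alpha) & np.isfinite(p)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional, off by default)."""
    p = np.asarray(p, dtype=float)
    finite = np.isfinite(p)
    q = np.full(p.shape, np.nan)
    pf = p[finite]
    m = pf.size
    order = np.argsort(pf)
    ranked = pf[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[finite] = out
    return q


def moderated_ttest(
    group_a: np.ndarray,
    group_b: np.ndarray,
    alpha: float = 0.001,
    moderate: bool = True,
    transform: bool = True,
) -> ModeratedTestResult:
    """End-to-end comparison of two replicate matrices of reactivities."""
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    if transform:
        a, _ = sqrt_transform(a)
        b, _ = sqrt_transform(b)
    effect, s2, df, _ = fit_position_models(a, b)
    if moderate:
        return ebayes_moderate(effect, s2, df, a.shape[1], b.shape[1], alpha)
    return ebayes_moderate(
        effect, s2, df, a.shape[1], b.shape[1], alpha, d0=0.0, s02=1.0
    )
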