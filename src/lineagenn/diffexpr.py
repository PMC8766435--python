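"""Moderated t-statistics for two-group differential expression ranking.

Per-bifurcation feature selection ranks genes by the absolute moderated
t-statistic between the pooled left-branch and right-branch cells. The
moderation follows the empirical-Bayes scheme of limma-style linear models:
per-gene pooled sample variances s_g^2 (df d) are shrunk toward a common
prior s_0^2 with prior df d_0 estimated from the scaled-F distribution of
the observed variances,

    s_tilde_g^2 = (d_0 s_0^2 + d s_g^2) / (d_0 + d),

and the t denominator uses s_tilde in place of s. Only the ranking is
consumed downstream, so p-values are not computed.
"""
from __future__ import annotations

import numpy as np
from scipy.special import digamma, polygamma


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma is positive on (0, inf)")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate the prior df d0 and prior variance s0^2 from pooled variances.

    Moment estimation on z = log(s2): under the scaled-F model,
    E[z] = log(s0^2) + digamma(d/2) - log(d/2) - digamma(d0/2) + log(d0/2)
    and Var[z] = trigamma(d/2) + trigamma(d0/2). Genes with zero sample
    variance are excluded from the fit. Returns (d0, s0sq); d0 may be inf
    when the observed variances show no excess spread.
    """
    s2 = np.asarray(s2, dtype=np.float64)
    pos = s2[s2 > 0]
    if pos.size < 2:
        s0 = float(pos.mean()) if pos.size else 1e-8
        return np.inf, s0
    z = np.log(pos)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(polygamma(1, df / 2.0))
    if evar <= 0:
        # no excess spread beyond sampling: infinite prior df, plain mean variance
        return np.inf, float(pos.mean())
    d0 = 2.0 * trigamma_inverse(evar)
    s0sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0sq


def moderated_t(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Moderated two-sample t-statistic per gene (rows), left minus right.

    ``left`` is G x n1, ``right`` G x n2; both groups need >= 2 cells so the
    pooled variance has positive degrees of freedom.
    """
    left = np.asarray(left, dtype=np.float64)
    right = np.asarray(right, dtype=np.float64)
    n1, n2 = left.shape[1], right.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("moderated t needs at least two cells per group")
    df = n1 + n2 - 2
    m1, m2 = left.mean(axis=1), right.mean(axis=1)
    v1 = left.var(axis=1, ddof=1)
    v2 = right.var(axis=1, ddof=1)
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    d0, s0sq = squeeze_variances(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
    else:
        s2_post = (d0 * s0sq + df * s2) / (d0 + df)
    denom = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (m1 - m2) / denom, 0.0)
    return t


def mean_difference(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Unmoderated fallback ranking statistic for degenerate tiny groups."""
    return np.asarray(left, dtype=np.float64).mean(axis=1) - np.asarray(
        right, dtype=np.float64
    ).mean(axis=1)
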