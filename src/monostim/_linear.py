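"""Vectorized per-feature least-squares fits for two-group designs with
donor blocking, plus empirical-Bayes variance moderation.

The same machinery backs both the methylation (M-value) and expression
(log-normalized count) models: for each feature,

    response ~ intercept + group + donor

is fit by ordinary least squares across the samples of one comparison, and
the group coefficient is tested with a two-sided t-test.  Moderation
shrinks per-feature residual variances toward a common prior estimated
from their marginal distribution (scaled-F model), which adds prior
degrees of freedom to the t-test -- essential when only a handful of
donors are available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats


class ModelError(ValueError):
    pass


def group_donor_fit(
    y: np.ndarray,
    group: np.ndarray,
    donor_codes: np.ndarray,
    feature_ids,
    block_donor: bool = True,
) -> pd.DataFrame:
    """OLS fit of ``y ~ group (+ donor)`` for every feature at once.

    Parameters
    ----------
    y:
        features x samples response matrix.
    group:
        0/1 indicator per sample (1 = target group).
    donor_codes:
        integer donor code per sample.
    block_donor:
        include donor indicator columns (drop-first coding).

    Returns a DataFrame indexed by feature with columns ``coef`` (group
    effect on the modeling scale), ``se``, ``t``, ``p``, ``s2`` (residual
    variance), ``df`` (residual degrees of freedom) and ``stdev_unscaled``
    (se / sqrt(s2), fixed by the design).
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group, dtype=float)
    n = y.shape[1]
    if group.shape[0] != n:
        raise ModelError("group indicator length mismatch")

    cols = [np.ones(n), group]
    if block_donor:
        donors = np.unique(donor_codes)
        if donors.size < 2:
            raise ModelError("rank-deficiency: donor blocking requires >= 2 donors")
        for d in donors[1:]:
            cols.append((donor_codes == d).astype(float))
    X = np.column_stack(cols)

    rank = np.linalg.matrix_rank(X)
    df = n - rank
    if df < 1:
        raise ModelError("rank-deficiency: no residual degrees of freedom")

    xtx_inv = np.linalg.pinv(X.T @ X)
    beta = y @ X @ xtx_inv.T  # features x params
    resid = y - beta @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    s2 = rss / df
    stdev_unscaled = float(np.sqrt(xtx_inv[1, 1]))

    coef = beta[:, 1]
    se = np.sqrt(s2) * stdev_unscaled
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # Constant features: (numerically) zero residual variance and zero
    # effect -> null identity.
    const = (s2 <= 1e-24) & (np.abs(coef) < 1e-10)
    p = np.where(const, 1.0, p)
    p = np.clip(p, np.nextafter(0, 1), 1.0)

    return pd.DataFrame(
        {
            "coef": coef,
            "se": se,
            "t": np.where(const, 0.0, t),
            "p": p,
            "s2": s2,
            "df": float(df),
            "stdev_unscaled": stdev_unscaled,
        },
        index=pd.Index(feature_ids),
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled-F prior to observed residual variances.

    Under the hierarchical model s2 ~ s0^2 * F(df, d0), log(s2) has known
    digamma/trigamma moments; matching the empirical mean and variance of
    log(s2) yields (d0, s0^2).  Returns ``(prior_df, prior_var)``; the
    prior df is ``inf`` when the observed spread is no wider than the
    chi-square sampling spread alone (no evidence of heterogeneity).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ModelError("not enough positive variances to estimate a prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = np.var(e, ddof=1) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(np.mean(e)))
    if not np.isfinite(s0_2) or s0_2 <= 0:
        # closed-form fallback: plain mean of the variances
        d0, s0_2 = np.inf, float(np.mean(s2[ok]))
    return d0, s0_2


def moderate(
    fits: pd.DataFrame,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderation of a ``group_donor_fit`` result.

    Posterior variance ``(d0*s0^2 + d*s2) / (d0 + d)``; the moderated t
    uses ``d0 + d`` degrees of freedom.  With ``prior_df=0`` the result
    equals the unmoderated fit.
    """
    out = fits.copy()
    s2 = fits["s2"].to_numpy()
    df = float(fits["df"].iloc[0])
    if prior_df is None or (prior_df > 0 and prior_var is None):
        if not (s2 > 0).any():
            # nothing to learn from; moderation is a no-op
            out["s2_post"] = s2
            out["df_total"] = df
            return out
        est_d0, est_s0 = estimate_variance_prior(s2, df)
        if prior_df is None:
            prior_df = est_d0
        if prior_var is None:
            prior_var = est_s0
    if prior_df < 0:
        raise ModelError("prior_df must be non-negative")

    if prior_df == 0:
        s2_post = s2
        df_total = df
    elif np.isinf(prior_df):
        s2_post = np.full_like(s2, prior_var)
        df_total = np.inf
    else:
        s2_post = (prior_df * prior_var + df * s2) / (prior_df + df)
        df_total = prior_df + df

    stdev = fits["stdev_unscaled"].to_numpy()
    se = np.sqrt(s2_post) * stdev
    coef = fits["coef"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    const = (s2_post <= 1e-24) & (np.abs(coef) < 1e-10)
    p = np.where(const, 1.0, p)

    out["s2_post"] = s2_post
    out["df_total"] = df_total
    out["t"] = np.where(const, 0.0, t)
    out["p"] = np.clip(p, np.nextafter(0, 1), 1.0)
    out["se"] = se
    out.attrs["prior_df"] = float(prior_df)
    out.attrs["prior_var"] = float(prior_var) if prior_var is not None else float("nan")
    return out
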