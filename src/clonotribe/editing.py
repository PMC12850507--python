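"""Per-site negative-binomial GLM test and edit-site retention.

Each candidate site contributes one observation per sample: edited count
``k_i`` with coverage ``n_i`` and group label (ADAR fusion = 1, control =
0). Counts are modeled as

    k_i ~ NegBinom(mu_i, theta),   log(mu_i) = b0 + b1 * group_i + log(n_i)

with ``log(n_i)`` as an offset and theta the dispersion estimated by
maximum likelihood (variance mu + mu^2/theta). The group coefficient b1
is tested with a Wald test; p-values are Benjamini-Hochberg adjusted
across all tested sites.

Fitting alternates iteratively reweighted least squares for (b0, b1) at
fixed theta with a one-dimensional ML update of theta, initialized from a
method-of-moments estimate after a Poisson fit, mirroring the classical
``glm.nb`` alternation. Two guards handle the tiny per-site sample size
(six observations):

* non-convergence falls back to a Poisson GLM (theta -> infinity) with a
  ``converged=False`` flag, a conservative but explicit default;
* when every count in one group is zero the group-effect MLE is infinite
  and the Wald statistic collapses (the Hauck-Donner effect), so the
  p-value is computed by a likelihood-ratio test of the group term
  instead; the ``method`` field records which test produced each p.

Group editing frequencies are the no-intercept least-squares slope of k
on n within each group, sum(k*n)/sum(n^2), clipped to [0, 1]; the pooled
ratio sum(k)/sum(n) is carried alongside as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from clonotribe.filtering import SITE_KEY
from clonotribe.simulate import TREATMENT

THETA_MIN, THETA_MAX = 1e-3, 1e6
_MU_FLOOR = 1e-10


@dataclass
class SiteFit:
    """Fit of the per-site negative-binomial GLM."""

    beta0: float
    beta1: float
    theta: float
    se_beta1: float
    p_value: float
    converged: bool
    degenerate: bool = False
    method: str = "wald"


def nb_loglik(k: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """Negative-binomial log-likelihood with mean mu and dispersion theta."""
    mu = np.maximum(mu, _MU_FLOOR)
    return float(
        np.sum(
            gammaln(k + theta)
            - gammaln(theta)
            - gammaln(k + 1)
            + theta * np.log(theta / (theta + mu))
            + k * np.log(mu / (theta + mu))
        )
    )


def _irls(
    k: np.ndarray,
    offset: np.ndarray,
    x: np.ndarray,
    theta: float,
    beta: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """IRLS for a log-link count GLM at fixed dispersion.

    ``theta = np.inf`` gives the Poisson working weights. Returns
    (beta, covariance, converged).
    """
    X = np.column_stack([np.ones_like(k, dtype=float), x]) if x.ndim == 1 else x
    if beta is None:
        mu = np.maximum(k, 0.5)
        eta = np.log(mu)
        # start from a weighted LS fit to the initialized working response
        beta = np.linalg.lstsq(X, eta - offset, rcond=None)[0]
    converged = False
    xtwx = np.eye(X.shape[1])
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu if np.isinf(theta) else mu / (1.0 + mu / theta)
        z = (eta - offset) + (k - mu) / np.maximum(mu, _MU_FLOOR)
        xtwx = X.T @ (w[:, None] * X)
        try:
            beta_new = np.linalg.solve(xtwx, X.T @ (w * z))
        except np.linalg.LinAlgError:
            return beta, np.full_like(xtwx, np.nan), False
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol:
            converged = True
            break
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        cov = np.full_like(xtwx, np.nan)
    return beta, cov, converged


def _theta_mle(k: np.ndarray, mu: np.ndarray, bracket: tuple[float, float] = (THETA_MIN, THETA_MAX)) -> float:
    res = optimize.minimize_scalar(
        lambda lt: -nb_loglik(k, mu, np.exp(lt)),
        bounds=(np.log(bracket[0]), np.log(bracket[1])),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(np.exp(res.x))


def _intercept_only_nb(k: np.ndarray, n: np.ndarray) -> tuple[float, float]:
    """ML fit of an intercept-only NB with offset log n; returns (loglik, theta)."""
    offset = np.log(n.astype(float))
    x = np.ones((len(k), 1))
    beta, _, _ = _irls(k.astype(float), offset, x, np.inf)
    mu = np.exp(np.clip(x @ beta + offset, -30, 30))
    theta = _theta_mle(k, mu)
    for _ in range(25):
        beta, _, _ = _irls(k.astype(float), offset, x, theta, beta=beta)
        mu = np.exp(np.clip(x @ beta + offset, -30, 30))
        theta_new = _theta_mle(k, mu)
        if abs(np.log(theta_new) - np.log(theta)) < 1e-8:
            theta = theta_new
            break
        theta = theta_new
    return nb_loglik(k, mu, theta), theta


def fit_nb_glm(k: np.ndarray, n: np.ndarray, group: np.ndarray) -> SiteFit:
    """Fit the per-site NB GLM and test the group coefficient.

    Parameters
    ----------
    k, n
        Edited counts and coverages per sample (n >= 1 for every row).
    group
        0/1 indicator (1 = ADAR fusion).
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    group = np.asarray(group, dtype=float)
    if np.any(n < 1):
        raise ValueError("all fitted rows need coverage >= 1")
    if len(np.unique(group)) < 2:
        raise ValueError("both groups must be represented")

    if not np.any(k > 0):
        return SiteFit(-np.inf, 0.0, np.inf, np.nan, 1.0, True, degenerate=True)

    offset = np.log(n)

    # Poisson pass for starting values and a method-of-moments dispersion
    beta, cov, _ = _irls(k, offset, group, np.inf)
    mu = np.exp(np.clip(np.column_stack([np.ones_like(k), group]) @ beta + offset, -30, 30))
    denom = np.sum(mu**2)
    alpha_mom = max(np.sum((k - mu) ** 2 - mu) / denom, 1e-8) if denom > 0 else 1e-8
    theta = float(np.clip(1.0 / alpha_mom, THETA_MIN, THETA_MAX))

    converged = False
    ll = -np.inf
    for _ in range(30):
        beta, cov, ok = _irls(k, offset, group, theta, beta=beta)
        mu = np.exp(np.clip(np.column_stack([np.ones_like(k), group]) @ beta + offset, -30, 30))
        theta = _theta_mle(k, mu)
        ll_new = nb_loglik(k, mu, theta)
        if ok and abs(ll_new - ll) < 1e-9:
            converged = True
            break
        ll = ll_new

    method = "wald"
    if not converged:
        # Poisson fallback: theta -> infinity, flagged
        beta, cov, _ = _irls(k, offset, group, np.inf)
        theta = np.inf

    se = float(np.sqrt(cov[1, 1])) if np.isfinite(cov[1, 1]) else np.nan
    zero_trt = not np.any(k[group == 1] > 0)
    zero_ctl = not np.any(k[group == 0] > 0)
    if zero_trt != zero_ctl:
        # one-group separation: infinite group-effect MLE, Wald collapses
        p = _separated_lrt_p(k, n, group)
        method = "lrt"
    elif np.isfinite(se) and se > 0:
        z = beta[1] / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        p = 1.0
    return SiteFit(float(beta[0]), float(beta[1]), float(theta), se, p, converged, method=method)


def _separated_lrt_p(k: np.ndarray, n: np.ndarray, group: np.ndarray) -> float:
    """Likelihood-ratio p for the group term when one group is all-zero.

    The alternative's supremum factorizes: the nonzero group gets its own
    intercept-only NB fit, the all-zero group attains log-likelihood 0 as
    its mean goes to 0.
    """
    ll_null, _ = _intercept_only_nb(k, n)
    live = group == (1.0 if np.any(k[group == 1] > 0) else 0.0)
    ll_live, _ = _intercept_only_nb(k[live], n[live])
    lr = 2.0 * (ll_live - ll_null)
    return float(stats.chi2.sf(max(lr, 0.0), df=1))


def estimate_group_frequencies(
    k: np.ndarray, n: np.ndarray, group: np.ndarray
) -> tuple[float, float]:
    """No-intercept least-squares slope of k on n, per group, clipped to [0, 1].

    The slope sum(k*n)/sum(n^2) is the least-squares estimate of the
    editing frequency under k ~ 0 + n; with a single sample it reduces to
    k/n, and with equal coverages to the mean of per-sample ratios.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    group = np.asarray(group)
    freqs = []
    for g in (1, 0):
        mask = group == g
        if not np.any(mask) or np.sum(n[mask] ** 2) == 0:
            raise ValueError(f"group {g} has no usable coverage")
        slope = np.sum(k[mask] * n[mask]) / np.sum(n[mask] ** 2)
        freqs.append(float(np.clip(slope, 0.0, 1.0)))
    return freqs[0], freqs[1]


def pooled_frequencies(k: np.ndarray, n: np.ndarray, group: np.ndarray) -> tuple[float, float]:
    """Pooled-ratio diagnostic sum(k)/sum(n) per group (treatment, control)."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    out = []
    for g in (1, 0):
        mask = np.asarray(group) == g
        out.append(float(k[mask].sum() / n[mask].sum()) if n[mask].sum() > 0 else np.nan)
    return out[0], out[1]


def test_sites(count_matrix: pd.DataFrame) -> pd.DataFrame:
    """Fit the NB GLM and frequency estimates at every candidate site.

    ``count_matrix`` is the long table from
    :func:`clonotribe.filtering.assemble_count_matrix`; rows flagged
    unusable (n = 0) are excluded from fitting. BH adjustment is applied
    once across all tested sites.
    """
    df = count_matrix if "usable" in count_matrix else count_matrix.assign(usable=count_matrix["n"] > 0)
    rows = []
    for key, site in df[df["usable"]].groupby(SITE_KEY, sort=False):
        g01 = (site["group"] == TREATMENT).astype(int).to_numpy()
        k = site["k"].to_numpy()
        n = site["n"].to_numpy()
        fit = fit_nb_glm(k, n, g01)
        if fit.degenerate:
            f_trt = f_ctl = 0.0
            p_trt = p_ctl = 0.0
        else:
            f_trt, f_ctl = estimate_group_frequencies(k, n, g01)
            p_trt, p_ctl = pooled_frequencies(k, n, g01)
        rows.append(
            dict(
                zip(SITE_KEY, key),
                beta0=fit.beta0,
                beta1=fit.beta1,
                theta=fit.theta,
                se_beta1=fit.se_beta1,
                p_value=fit.p_value,
                freq_treatment=f_trt,
                freq_control=f_ctl,
                pooled_treatment=p_trt,
                pooled_control=p_ctl,
                diff_freq=f_trt - f_ctl,
                converged=fit.converged,
                degenerate=fit.degenerate,
                test_method=fit.method,
            )
        )
    results = pd.DataFrame(rows)
    if not results.empty:
        results["fdr"] = bh_adjust(results["p_value"].to_numpy())
    return results


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(p, method="fdr_bh")[1]


def call_edit_sites(
    results: pd.DataFrame,
    min_diff: float = 0.1,
    max_control_freq: float = 0.02,
    max_fdr: float = 0.05,
) -> pd.DataFrame:
    """Apply the three retention criteria to the per-site test table.

    Retained iff diff_freq >= min_diff (inclusive) AND freq_control <
    max_control_freq (strict) AND fdr < max_fdr (strict). BH adjustment
    must already have been computed over the full test set.
    """
    keep = (
        (results["diff_freq"] >= min_diff)
        & (results["freq_control"] < max_control_freq)
        & (results["fdr"] < max_fdr)
    )
    return results[keep].reset_index(drop=True)
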