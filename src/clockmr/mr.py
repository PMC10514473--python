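"""Two-sample Mendelian randomization estimators on harmonized instruments.

All estimators consume a harmonized table (columns ``beta_x, se_x, beta_y,
se_y``; rows with a ``status`` column are filtered to kept/sign-flipped) and
return an :class:`MREstimate`.  The per-SNP building block is the Wald ratio
theta_j = beta_y_j / beta_x_j; the estimators differ in how they pool the
ratios and which pleiotropy structure they tolerate:

==================  ========================================================
inverse-variance     weighted mean of ratios, weights beta_x^2/se_y^2;
weighted (IVW)       fixed-effect SE or multiplicative random-effects SE
                     inflated by sqrt(max(1, Q/(J-1)))
maximum likelihood   joint normal likelihood over (theta, gamma_1..gamma_J),
                     profiled over the true SNP effects gamma_j
MR-Egger             weighted regression of beta_y on beta_x with a free
                     intercept estimating average directional pleiotropy
weighted median      50% point of the weight-ordered ratios; consistent when
                     at least half the weight is on valid instruments
RAPS                 robust adjusted profile score with overdispersion tau^2
                     and optional Huber score
MR-PRESSO            simulation-based residual-sum-of-squares global test,
                     per-SNP outlier flagging and outlier-corrected IVW
==================  ========================================================

Wald-type standard errors are first order throughout and the 95% interval
multiplier is fixed at 1.959964; odds-ratio reporting is exp(theta).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

Z95 = 1.959964


@dataclass
class MREstimate:
    """A causal-effect estimate with its uncertainty and provenance."""

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    extras: dict = field(default_factory=dict)

    @property
    def odds_ratio(self) -> float:
        """exp(theta); the causal odds ratio when the outcome is binary."""
        return float(np.exp(self.theta))

    @property
    def or_ci_low(self) -> float:
        return float(np.exp(self.ci_low))

    @property
    def or_ci_high(self) -> float:
        return float(np.exp(self.ci_high))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n_snps": self.n_snps,
            "theta": self.theta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "or": self.odds_ratio,
            "or_ci_low": self.or_ci_low,
            "or_ci_high": self.or_ci_high,
        }


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier, and distortion diagnostics."""

    estimate: MREstimate
    global_rss: float
    global_pval: float
    outlier_table: pd.DataFrame
    outliers: list[str]
    distortion_coef: float | None
    distortion_pval: float | None
    n_sim: int
    seed: int


def _extract(pairs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    df = pairs
    if "status" in df.columns:
        df = df[df["status"].isin(("kept", "sign_flipped"))]
    bx = df["beta_x"].to_numpy(float)
    sx = df["se_x"].to_numpy(float)
    by = df["beta_y"].to_numpy(float)
    sy = df["se_y"].to_numpy(float)
    if np.any(sx <= 0) or np.any(sy <= 0):
        raise ValueError("all standard errors must be > 0")
    return bx, sx, by, sy


def _kept(pairs: pd.DataFrame) -> pd.DataFrame:
    if "status" in pairs.columns:
        return pairs[pairs["status"].isin(("kept", "sign_flipped"))].reset_index(drop=True)
    return pairs.reset_index(drop=True)


def _finish(method: str, theta: float, se: float, n: int, extras: dict | None = None) -> MREstimate:
    pval = float(2.0 * stats.norm.sf(abs(theta) / se)) if se > 0 else float("nan")
    return MREstimate(
        method=method,
        theta=float(theta),
        se=float(se),
        ci_low=float(theta - Z95 * se),
        ci_high=float(theta + Z95 * se),
        pval=pval,
        n_snps=int(n),
        extras=extras or {},
    )


def q_statistic(bx: np.ndarray, by: np.ndarray, sy: np.ndarray, theta: float) -> float:
    """Cochran's Q about ``theta``: sum of w_j (ratio_j - theta)^2 with
    w_j = beta_x^2/se_y^2, computed in the equivalent outcome-scale form."""
    return float(np.sum(((by - theta * bx) / sy) ** 2))


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float) -> MREstimate:
    """Single-instrument causal estimate beta_y/beta_x with first-order SE se_y/|beta_x|."""
    if beta_x == 0:
        raise ValueError("wald_ratio undefined for beta_x = 0")
    theta = beta_y / beta_x
    se = se_y / abs(beta_x)
    return _finish("wald", theta, se, 1)


def ivw(pairs: pd.DataFrame, model: str = "random") -> MREstimate:
    """Inverse-variance-weighted estimate.

    ``model="fixed"`` uses SE = 1/sqrt(sum w_j); ``model="random"`` applies
    the multiplicative heterogeneity inflation sqrt(max(1, Q/(J-1))), never
    deflating below the fixed-effect SE.  Extras carry Q, its df and
    p-value, so heterogeneity reporting and the random-effects scaling share
    one computation.
    """
    if model not in ("fixed", "random"):
        raise ValueError("model must be 'fixed' or 'random'")
    bx, sx, by, sy = _extract(pairs)
    J = len(bx)
    if J < 2:
        raise ValueError("ivw needs at least 2 instruments; use wald_ratio for one")
    w_sum = np.sum(bx**2 / sy**2)
    theta = float(np.sum(bx * by / sy**2) / w_sum)
    se_fixed = float(1.0 / np.sqrt(w_sum))
    q = q_statistic(bx, by, sy, theta)
    q_df = J - 1
    scale = np.sqrt(max(1.0, q / q_df))
    se = se_fixed * scale if model == "random" else se_fixed
    extras = {
        "model": model,
        "q": q,
        "q_df": q_df,
        "q_pval": float(stats.chi2.sf(q, q_df)),
        "se_fixed": se_fixed,
    }
    return _finish(f"ivw_{model}", theta, se, J, extras)


def max_likelihood(pairs: pd.DataFrame) -> MREstimate:
    """Maximum-likelihood estimate under jointly normal summary errors.

    The model is beta_x_j ~ N(gamma_j, se_x_j^2), beta_y_j ~ N(theta *
    gamma_j, se_y_j^2); profiling out the nuisance gamma_j leaves

        nll(theta) = 1/2 * sum (beta_y_j - theta beta_x_j)^2
                               / (se_y_j^2 + theta^2 se_x_j^2)

    minimized numerically; the SE comes from the observed information, i.e.
    the profile curvature at the optimum.
    """
    bx, sx, by, sy = _extract(pairs)
    J = len(bx)
    if J < 2:
        raise ValueError("max_likelihood needs at least 2 instruments")

    def nll(theta: float) -> float:
        return 0.5 * float(np.sum((by - theta * bx) ** 2 / (sy**2 + theta**2 * sx**2)))

    start = ivw(pairs, model="fixed").theta
    ratios = by / np.where(bx == 0, np.nan, bx)
    spread = np.nanmax(np.abs(ratios)) if np.isfinite(ratios).any() else abs(start)
    half_width = 5.0 * max(1.0, spread, abs(start))
    res = optimize.minimize_scalar(
        nll,
        bounds=(start - half_width, start + half_width),
        method="bounded",
        options={"xatol": 1e-12},
    )
    if not res.success:
        raise RuntimeError(f"maximum-likelihood optimizer failed: {res.message}")
    theta = float(res.x)
    h = 1e-5 * (1.0 + abs(theta))
    curv = (nll(theta + h) - 2.0 * nll(theta) + nll(theta - h)) / h**2
    if not np.isfinite(curv) or curv <= 0:
        raise RuntimeError(f"profile curvature non-positive at theta={theta}")
    se = float(1.0 / np.sqrt(curv))
    return _finish("max_likelihood", theta, se, J, {"nll": float(res.fun)})


def egger(pairs: pd.DataFrame) -> MREstimate:
    """MR-Egger regression: slope is the causal effect, intercept the
    average directional pleiotropy.

    Instruments are oriented so every exposure beta is non-negative (both
    betas of a pair are negated when beta_x < 0), then beta_y is regressed
    on beta_x with an unconstrained intercept and weights 1/se_y^2.
    Standard errors use the multiplicative overdispersion factor
    max(1, RSS_w/(J-2)).  Extras carry the intercept, its SE and p-value
    (the pleiotropy test).
    """
    bx, sx, by, sy = _extract(pairs)
    J = len(bx)
    if J < 3:
        raise ValueError("egger needs at least 3 instruments")
    sign = np.where(bx < 0, -1.0, 1.0)
    bxo, byo = bx * sign, by * sign
    X = sm.add_constant(bxo)
    fit = sm.WLS(byo, X, weights=1.0 / sy**2).fit()
    phi = max(1.0, float(fit.scale))
    cov = np.asarray(fit.normalized_cov_params) * phi
    intercept, theta = (float(v) for v in fit.params)
    se_int, se_theta = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    extras = {
        "intercept": intercept,
        "intercept_se": se_int,
        "intercept_pval": float(2.0 * stats.norm.sf(abs(intercept) / se_int)),
        "overdispersion": phi,
    }
    return _finish("egger", theta, se_theta, J, extras)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, v))


def weighted_median(pairs: pd.DataFrame, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimate with a seeded parametric-bootstrap SE.

    The point estimate interpolates the weight-ordered Wald ratios at
    cumulative weight 0.5 (weights beta_x^2/se_y^2).  The SE is the standard
    deviation of the estimate over ``n_boot`` datasets resampled from
    Normal(beta_x, se_x^2) and Normal(beta_y, se_y^2).
    """
    bx, sx, by, sy = _extract(pairs)
    J = len(bx)
    if J < 3:
        raise ValueError("weighted_median needs at least 3 instruments")
    if np.any(bx == 0):
        raise ValueError("weighted_median undefined when any beta_x = 0")
    w = bx**2 / sy**2
    if w.sum() <= 0:
        raise ValueError("total instrument weight is zero")
    theta = _weighted_median(by / bx, w)

    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, J))
    by_b = rng.normal(by, sy, size=(n_boot, J))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxi = bx_b[i]
        bxi = np.where(bxi == 0, np.finfo(float).tiny, bxi)
        boots[i] = _weighted_median(by_b[i] / bxi, bxi**2 / sy**2)
    se = float(np.std(boots, ddof=1))
    return _finish("weighted_median", theta, se, J, {"n_boot": n_boot, "seed": seed})


def _huber_psi(t: np.ndarray, k: float) -> np.ndarray:
    return np.clip(t, -k, k)


def raps(
    pairs: pd.DataFrame,
    loss: str = "l2",
    k_huber: float = 1.345,
    max_expand: int = 60,
) -> MREstimate:
    """Robust adjusted profile score estimate with overdispersion.

    Solves the pair of estimating equations in (theta, tau2 >= 0) built
    from the standardized residuals

        t_j = (beta_y_j - theta beta_x_j) / sqrt(se_y_j^2 + theta^2 se_x_j^2 + tau2)

    The theta equation is the profile score sum psi(t_j) * (beta_x_j/sigma_j
    + t_j theta se_x_j^2 / sigma_j^2) = 0 and the tau2 equation matches
    E[psi(T) T] for standard-normal T (1 for the identity score, 2*Phi(k)-1
    for the Huber score), clamped at tau2 = 0 when residuals are
    underdispersed.  The SE is the sandwich form of the profile score.
    """
    if loss not in ("l2", "huber"):
        raise ValueError("loss must be 'l2' or 'huber'")
    bx, sx, by, sy = _extract(pairs)
    J = len(bx)
    if J < 3:
        raise ValueError("raps needs at least 3 instruments")

    if loss == "l2":
        psi = lambda t: t  # noqa: E731
        delta = 1.0
    else:
        psi = lambda t: _huber_psi(t, k_huber)  # noqa: E731
        delta = float(2.0 * stats.norm.cdf(k_huber) - 1.0)

    def score_terms(theta: float, tau2: float) -> np.ndarray:
        sig2 = sy**2 + theta**2 * sx**2 + tau2
        sig = np.sqrt(sig2)
        t = (by - theta * bx) / sig
        return psi(t) * (bx / sig + t * theta * sx**2 / sig2)

    def g_theta(theta: float, tau2: float) -> float:
        return float(np.sum(score_terms(theta, tau2)))

    start = ivw(pairs, model="fixed").theta
    se0 = ivw(pairs, model="random").se

    def solve_theta(tau2: float) -> float:
        lo, hi = start - 4 * se0 - 0.1, start + 4 * se0 + 0.1
        for _ in range(max_expand):
            if g_theta(lo, tau2) * g_theta(hi, tau2) < 0:
                return float(optimize.brentq(g_theta, lo, hi, args=(tau2,), xtol=1e-12))
            lo, hi = lo - (hi - lo), hi + (hi - lo)
        raise RuntimeError(f"raps: no root for theta in bracket [{lo}, {hi}] at tau2={tau2}")

    def g_tau(tau2: float) -> float:
        theta = solve_theta(tau2)
        sig2 = sy**2 + theta**2 * sx**2 + tau2
        t = (by - theta * bx) / np.sqrt(sig2)
        return float(np.sum((psi(t) * t - delta) / sig2))

    if g_tau(0.0) <= 0.0:
        tau2 = 0.0
    else:
        hi = float(np.mean(sy**2))
        for _ in range(max_expand):
            if g_tau(hi) < 0:
                break
            hi *= 4.0
        else:
            raise RuntimeError(f"raps: no root for tau2 in [0, {hi}]")
        tau2 = float(optimize.brentq(g_tau, 0.0, hi, xtol=1e-14))
    theta = solve_theta(tau2)

    terms = score_terms(theta, tau2)
    h = 1e-6 * (1.0 + abs(theta))
    a = (g_theta(theta + h, tau2) - g_theta(theta - h, tau2)) / (2.0 * h)
    b = float(np.sum(terms**2))
    if a == 0:
        raise RuntimeError("raps: singular score derivative")
    se = float(np.sqrt(b) / abs(a))
    return _finish("raps", theta, se, J, {"tau2": tau2, "loss": loss})


def presso(
    pairs: pd.DataFrame,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
    model: str = "random",
) -> PressoResult:
    """MR-PRESSO: global pleiotropy test, outlier flagging, distortion test.

    The observed statistic is the weighted residual sum of squares
    RSS = sum_j (beta_y_j - theta_(-j) beta_x_j)^2 / se_y_j^2 with
    leave-one-out IVW predictions theta_(-j).  ``n_sim`` parametric datasets
    are drawn from Normal(theta_(-j) beta_x_j, se_y_j^2) and
    Normal(beta_x_j, se_x_j^2); the global p-value is the fraction of
    simulated RSS at least as large as observed.  Per-SNP outlier p-values
    compare each observed squared residual with its simulated distribution
    and are Bonferroni-adjusted; flagged SNPs are removed from the reported
    IVW estimate.  The distortion test compares the outlier-corrected
    estimate against estimates obtained by removing equally many SNPs at
    random (reported, never used to veto the corrected estimate).
    """
    kept = _kept(pairs)
    bx, sx, by, sy = _extract(kept)
    J = len(bx)
    if J < 4:
        raise ValueError("presso needs at least 4 instruments")
    snp_ids = (
        kept["snp_id"].astype(str).to_numpy()
        if "snp_id" in kept.columns
        else np.array([f"snp{i}" for i in range(J)])
    )

    w = 1.0 / sy**2
    s1 = np.sum(bx * by * w)
    s2 = np.sum(bx * bx * w)
    th_loo = (s1 - bx * by * w) / (s2 - bx * bx * w)
    resid = by - th_loo * bx
    e_obs = w * resid**2
    rss_obs = float(np.sum(e_obs))

    rng = np.random.default_rng(seed)
    bx_s = rng.normal(bx, sx, size=(n_sim, J))
    by_s = rng.normal(th_loo * bx, sy, size=(n_sim, J))
    s1_s = np.sum(bx_s * by_s * w, axis=1, keepdims=True)
    s2_s = np.sum(bx_s**2 * w, axis=1, keepdims=True)
    th_loo_s = (s1_s - bx_s * by_s * w) / (s2_s - bx_s**2 * w)
    e_s = w * (by_s - th_loo_s * bx_s) ** 2
    rss_s = e_s.sum(axis=1)

    global_pval = float(np.mean(rss_s >= rss_obs))
    p_raw = np.mean(e_s >= e_obs[None, :], axis=0)
    p_adj = np.minimum(1.0, p_raw * J)
    flagged = p_adj < outlier_alpha
    outlier_table = pd.DataFrame(
        {"snp_id": snp_ids, "pval_raw": p_raw, "pval_bonferroni": p_adj, "outlier": flagged}
    )
    outliers = [s for s, f in zip(snp_ids, flagged) if f]

    distortion_coef = distortion_pval = None
    if flagged.any() and J - int(flagged.sum()) >= 2:
        estimate = ivw(kept[~flagged], model=model)
        estimate.method = "presso"
        estimate.extras["outlier_corrected"] = True
        th_all = float(s1 / s2)
        th_corr = estimate.theta
        k = int(flagged.sum())
        n_draw = min(n_sim, 1000)
        th_rand = np.empty(n_draw)
        for i in range(n_draw):
            keep_idx = rng.choice(J, size=J - k, replace=False)
            th_rand[i] = np.sum(bx[keep_idx] * by[keep_idx] * w[keep_idx]) / np.sum(
                bx[keep_idx] ** 2 * w[keep_idx]
            )
        mean_rand = float(np.mean(th_rand))
        if mean_rand != 0:
            distortion_coef = float(100.0 * (th_corr - mean_rand) / abs(mean_rand))
        distortion_pval = float(np.mean(np.abs(th_rand - th_all) >= abs(th_corr - th_all)))
    else:
        estimate = ivw(kept, model=model)
        estimate.method = "presso"
        estimate.extras["outlier_corrected"] = False
    estimate.extras.update(
        {"global_pval": global_pval, "outliers": list(outliers), "n_sim": n_sim}
    )
    return PressoResult(
        estimate=estimate,
        global_rss=rss_obs,
        global_pval=global_pval,
        outlier_table=outlier_table,
        outliers=list(outliers),
        distortion_coef=distortion_coef,
        distortion_pval=distortion_pval,
        n_sim=n_sim,
        seed=seed,
    )
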