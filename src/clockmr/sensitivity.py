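"""Heterogeneity and pleiotropy diagnostics for an instrument set.

Cochran's Q (referenced to the fixed-effect IVW estimate), I^2, the
Egger-intercept pleiotropy test (in :func:`clockmr.mr.egger`), leave-one-out
re-estimation, and funnel-plot coordinates.  The Q computed here is the same
quantity the random-effects IVW uses for its SE inflation: both come from
:func:`clockmr.mr.ivw`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import mr


@dataclass
class HeterogeneityResult:
    """Cochran's Q with its chi-square p-value and the derived I^2."""

    q: float
    df: int
    pval: float
    i2: float


@dataclass
class LeaveOneOutResult:
    """Per-omitted-SNP IVW re-fits plus the all-instrument estimate."""

    table: pd.DataFrame
    full: mr.MREstimate


@dataclass
class FunnelData:
    """Funnel-plot coordinates with IVW and Egger reference lines (no rendering)."""

    points: pd.DataFrame
    ivw_theta: float
    egger_intercept: float | None
    egger_slope: float | None


def cochran_q(pairs: pd.DataFrame, theta_ref: float | None = None) -> HeterogeneityResult:
    """Cochran's Q heterogeneity statistic.

    Q = sum w_j (ratio_j - theta_ref)^2 with w_j = beta_x^2/se_y^2 and
    theta_ref the fixed-effect IVW estimate unless given; p is the upper
    chi-square tail on J-1 degrees of freedom and I^2 = max(0, (Q-df)/Q).
    """
    bx, sx, by, sy = mr._extract(pairs)
    if len(bx) < 2:
        raise ValueError("cochran_q needs at least 2 instruments")
    if theta_ref is None:
        fit = mr.ivw(pairs, model="fixed")
        q = fit.extras["q"]
        df = fit.extras["q_df"]
        pval = fit.extras["q_pval"]
    else:
        q = mr.q_statistic(bx, by, sy, float(theta_ref))
        df = len(bx) - 1
        pval = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return HeterogeneityResult(q=float(q), df=int(df), pval=float(pval), i2=float(i2))


def leave_one_out(pairs: pd.DataFrame, model: str = "random") -> LeaveOneOutResult:
    """Re-estimate IVW leaving out each instrument in turn.

    Flags omissions that move the estimate outside the all-instrument 95%
    interval; exactly J rows for J instruments.
    """
    kept = mr._kept(pairs)
    J = len(kept)
    if J < 3:
        raise ValueError("leave_one_out needs at least 3 instruments")
    full = mr.ivw(kept, model=model)
    rows = []
    ids = (
        kept["snp_id"].astype(str).to_numpy()
        if "snp_id" in kept.columns
        else [f"snp{i}" for i in range(J)]
    )
    for i in range(J):
        sub = kept.drop(kept.index[i])
        est = mr.ivw(sub, model=model)
        rows.append(
            {
                "snp_id": ids[i],
                "theta": est.theta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "outside_full_ci": not (full.ci_low <= est.theta <= full.ci_high),
            }
        )
    return LeaveOneOutResult(table=pd.DataFrame(rows), full=full)


def funnel_data(pairs: pd.DataFrame) -> FunnelData:
    """Per-SNP Wald ratios against their precisions, for funnel asymmetry checks.

    Returns one row per instrument with ``ratio`` = beta_y/beta_x and
    ``precision`` = |beta_x|/se_y (the reciprocal first-order ratio SE),
    plus IVW and Egger reference values.  With fewer than the minimum
    instruments for a reference fit, the reference degenerates to the mean
    ratio and the Egger line is absent.
    """
    kept = mr._kept(pairs)
    bx, sx, by, sy = mr._extract(kept)
    if len(bx) < 1:
        raise ValueError("funnel_data needs at least 1 instrument")
    if np.any(bx == 0):
        raise ValueError("funnel_data undefined when any beta_x = 0")
    ratio = by / bx
    precision = np.abs(bx) / sy
    ids = (
        kept["snp_id"].astype(str).to_numpy()
        if "snp_id" in kept.columns
        else [f"snp{i}" for i in range(len(bx))]
    )
    points = pd.DataFrame({"snp_id": ids, "ratio": ratio, "precision": precision})
    ivw_theta = mr.ivw(kept).theta if len(bx) >= 2 else float(ratio[0])
    eg_int = eg_slope = None
    if len(bx) >= 3:
        eg = mr.egger(kept)
        eg_int, eg_slope = eg.extras["intercept"], eg.theta
    return FunnelData(
        points=points, ivw_theta=float(ivw_theta), egger_intercept=eg_int, egger_slope=eg_slope
    )


def plot_funnel(funnel: FunnelData, path: str) -> None:
    """Render a funnel plot to ``path`` (format from the extension, e.g. SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(funnel.points["ratio"], funnel.points["precision"], s=18, color="#3465a4")
    ax.axvline(funnel.ivw_theta, color="black", lw=1, label="IVW")
    if funnel.egger_slope is not None:
        ax.axvline(funnel.egger_slope, color="firebrick", lw=1, ls="--", label="MR-Egger")
    ax.set_xlabel("per-SNP causal estimate (Wald ratio)")
    ax.set_ylabel("precision  |beta_x| / se_y")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
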