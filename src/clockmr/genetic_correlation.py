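"""Method-of-moments genetic covariance and correlation from paired z-statistics.

For two traits measured in non-overlapping cohorts of sizes N1 and N2, with
M SNPs carrying LD scores l_j, the expected z-statistic moments under a
polygenic additive model are

    E[z1_j^2]    = 1 + N1 h2_1 l_j / M
    E[z1_j z2_j] = sqrt(N1 N2) rho_g l_j / M

which invert to the moment estimators used here:

    h2_hat    = M (mean(z^2) - 1) / (N mean(l))
    rho_g_hat = M mean(z1 z2) / (sqrt(N1 N2) mean(l))
    rg_hat    = rho_g_hat / sqrt(h2_1_hat h2_2_hat)

Uncertainty comes from a leave-one-block-out jackknife over contiguous,
position-ordered SNP blocks (200 by default).  Heritabilities are clipped to
[0, 1] and the reported rg to [-1, 1], with raw values retained; when either
heritability estimate is non-positive rg is undefined and only the genetic
covariance is reported.  No sample-overlap correction is applied: the
estimator assumes disjoint cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class H2Result:
    """SNP-heritability estimate with jackknife uncertainty."""

    h2: float          # clipped to [0, 1]
    h2_raw: float
    se: float
    m_snps: int
    n_blocks: int


@dataclass
class GeneticCorrelationResult:
    """Genetic covariance, per-trait heritabilities, and their correlation."""

    rho_g: float
    h2_1: float
    h2_2: float
    rg: float            # clipped to [-1, 1]; NaN when undefined
    se_rg: float
    pval: float
    m_snps: int
    n_blocks: int
    extras: dict = field(default_factory=dict)

    @property
    def rg_defined(self) -> bool:
        return bool(np.isfinite(self.rg))


def _blocks(m: int, n_blocks: int) -> list[np.ndarray]:
    n_blocks = min(n_blocks, m)
    return np.array_split(np.arange(m), n_blocks)


def _jackknife_se(reps: np.ndarray) -> float:
    b = len(reps)
    return float(np.sqrt((b - 1) / b * np.sum((reps - reps.mean()) ** 2)))


def estimate_h2(
    z, ldscore, n: float, m: int | None = None, n_blocks: int = 200
) -> H2Result:
    """Method-of-moments SNP heritability from one trait's z-statistics.

    ``h2 = M (mean(z^2) - 1) / (N mean(l))``, clipped to [0, 1] with the raw
    value retained; SE by leave-one-block-out jackknife on the raw value.
    """
    z = np.asarray(z, dtype=float)
    l = np.asarray(ldscore, dtype=float)
    if n <= 0:
        raise ValueError("sample size N must be > 0")
    if len(z) < 2:
        raise ValueError("need at least 2 SNPs")
    if np.any(~np.isfinite(z)) or np.any(l < 1):
        raise ValueError("z must be finite and LD scores >= 1")
    m = int(m if m is not None else len(z))

    sz2, sl = float(np.sum(z**2)), float(np.sum(l))
    m_obs = len(z)

    def h2_raw(s2: float, s_l: float, k: int) -> float:
        # mean over the retained k SNPs; M fixed by design
        return m * (s2 / k - 1.0) / (n * (s_l / k))

    point = h2_raw(sz2, sl, m_obs)
    blocks = _blocks(m_obs, n_blocks)
    reps = np.empty(len(blocks))
    for i, idx in enumerate(blocks):
        reps[i] = h2_raw(sz2 - np.sum(z[idx] ** 2), sl - np.sum(l[idx]), m_obs - len(idx))
    return H2Result(
        h2=float(np.clip(point, 0.0, 1.0)),
        h2_raw=float(point),
        se=_jackknife_se(reps),
        m_snps=m_obs,
        n_blocks=len(blocks),
    )


def estimate_rg(
    z1,
    z2,
    ldscore,
    n1: float,
    n2: float,
    m: int | None = None,
    n_blocks: int = 200,
) -> GeneticCorrelationResult:
    """Genetic covariance and correlation between two traits.

    SNP sets must be aligned (same SNP j in ``z1[j]`` and ``z2[j]``),
    position-ordered for the block jackknife, and the cohorts must not
    overlap.  The p-value is a two-sided normal test of the raw rg against
    zero using the jackknife SE (of the covariance when rg is undefined).
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    l = np.asarray(ldscore, dtype=float)
    if not (len(z1) == len(z2) == len(l)):
        raise ValueError("z1, z2 and ldscore must be aligned")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be > 0")
    m_obs = len(z1)
    m = int(m if m is not None else m_obs)

    s11, s22 = float(np.sum(z1**2)), float(np.sum(z2**2))
    s12, sl = float(np.sum(z1 * z2)), float(np.sum(l))

    def stats_from(s11_, s22_, s12_, sl_, k):
        h1 = m * (s11_ / k - 1.0) / (n1 * (sl_ / k))
        h2 = m * (s22_ / k - 1.0) / (n2 * (sl_ / k))
        rho = m * (s12_ / k) / (np.sqrt(n1 * n2) * (sl_ / k))
        rg = rho / np.sqrt(h1 * h2) if h1 > 0 and h2 > 0 else np.nan
        return h1, h2, rho, rg

    h1, h2, rho, rg_raw = stats_from(s11, s22, s12, sl, m_obs)

    blocks = _blocks(m_obs, n_blocks)
    reps_rg = np.empty(len(blocks))
    reps_rho = np.empty(len(blocks))
    for i, idx in enumerate(blocks):
        r = stats_from(
            s11 - np.sum(z1[idx] ** 2),
            s22 - np.sum(z2[idx] ** 2),
            s12 - np.sum(z1[idx] * z2[idx]),
            sl - np.sum(l[idx]),
            m_obs - len(idx),
        )
        reps_rho[i] = r[2]
        reps_rg[i] = r[3]

    defined = np.isfinite(rg_raw) and np.all(np.isfinite(reps_rg))
    if defined:
        se_rg = _jackknife_se(reps_rg)
        pval = float(2.0 * stats.norm.sf(abs(rg_raw) / se_rg)) if se_rg > 0 else float("nan")
        rg = float(np.clip(rg_raw, -1.0, 1.0))
    else:
        se_rg = _jackknife_se(reps_rho)
        pval = float(2.0 * stats.norm.sf(abs(rho) / se_rg)) if se_rg > 0 else float("nan")
        rg = float("nan")
    return GeneticCorrelationResult(
        rho_g=float(rho),
        h2_1=float(h1),
        h2_2=float(h2),
        rg=rg,
        se_rg=float(se_rg),
        pval=pval,
        m_snps=m_obs,
        n_blocks=len(blocks),
        extras={"rg_raw": float(rg_raw), "rg_defined": bool(defined)},
    )
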