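"""Synthetic GWAS summary statistics with a known causal structure.

Two generators cover everything the downstream analysis consumes:

* :func:`simulate_mr_triplet` draws per-SNP association summaries for an
  exposure, a candidate mediator and an outcome under the linear causal
  chain

      exposure --b--> mediator --c--> outcome,   exposure --d--> outcome

  so the total exposure->outcome effect is ``d + b*c``.  Instrument SNPs
  carry true exposure effects gamma_j; optional horizontal pleiotropy adds a
  direct SNP->outcome term alpha_j.  A second set of mediator-specific
  (cis-pQTL-like) SNPs with effects delta_j instruments the mediator itself,
  mirroring how protein mediators are instrumented by variants in or near
  the encoding gene.  SNPs are mutually LD-independent by construction, i.e.
  the tables represent post-clumping instruments.

* :func:`simulate_z_pairs` draws genome-wide z-statistic pairs for two
  traits with given SNP heritabilities, genetic correlation and LD scores,
  with no sample overlap, for the method-of-moments genetic-correlation
  estimator.

Identical config and seed give bitwise-identical tables.

Default magnitudes follow the published HannumAge instrument regime
(per-allele |beta| roughly 0.16-0.54 with SE 0.035-0.073, hence F statistics
around 20-63) and an outcome standard error typical of a lung-cancer
case-control GWAS with tens of thousands of cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import stats

PLEIOTROPY_MODELS = ("none", "balanced", "directional")

_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
_NONPALINDROMIC_PAIRS = (("A", "G"), ("G", "A"), ("A", "C"), ("C", "A"),
                         ("T", "G"), ("G", "T"), ("T", "C"), ("C", "T"))


@dataclass
class SimulationConfig:
    """Conditions for one exposure/mediator/outcome triplet.

    The total causal effect of the exposure on the outcome is
    ``direct_effect + exposure_to_mediator * mediator_to_outcome``; a plain
    (non-mediation) effect theta is specified as ``direct_effect=theta``.

    ``pleiotropy`` selects the SNP-level direct-outcome term alpha_j:
    ``none`` (0), ``balanced`` (Normal(0, pleiotropy_sd^2), violates neither
    IVW on average nor the Egger intercept) or ``directional``
    (Normal(pleiotropy_mean, pleiotropy_sd^2) with nonzero mean, which
    biases IVW but satisfies the InSIDE condition Egger relies on).
    """

    n_snps: int = 50
    gamma_mean: float = 0.25
    gamma_sd: float = 0.10
    random_sign: bool = True
    exposure_to_mediator: float = 0.0   # b
    mediator_to_outcome: float = 0.0    # c
    direct_effect: float = 0.0          # d
    pleiotropy: str = "none"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    se_x: float = 0.04
    se_m: float = 0.03
    se_y: float = 0.02
    n_mediator_snps: int = 25
    delta_mean: float = 0.25
    delta_sd: float = 0.05
    palindromic_fraction: float = 0.2
    n_exposure: int = 13661
    n_mediator: int = 3301
    n_outcome: int = 85449
    seed: int = 0

    @property
    def total_effect(self) -> float:
        """Exposure->outcome effect implied by the path coefficients."""
        return self.direct_effect + self.exposure_to_mediator * self.mediator_to_outcome

    def validate(self) -> None:
        if self.n_snps < 2:
            raise ValueError("n_snps must be >= 2")
        for name in ("se_x", "se_m", "se_y"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.pleiotropy not in PLEIOTROPY_MODELS:
            raise ValueError(
                f"unknown pleiotropy model {self.pleiotropy!r}; "
                f"expected one of {PLEIOTROPY_MODELS}"
            )
        if not 0.0 <= self.palindromic_fraction <= 1.0:
            raise ValueError("palindromic_fraction must lie in [0, 1]")


@dataclass
class ZPairConfig:
    """Conditions for paired genome-wide z-statistics of two traits."""

    n_snps: int = 20_000
    h2_1: float = 0.3
    h2_2: float = 0.3
    rg: float = 0.135
    n1: int = 20_000
    n2: int = 20_000
    ld_shape: float = 2.0
    ld_scale: float = 25.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps < 2:
            raise ValueError("n_snps must be >= 2")
        for name in ("h2_1", "h2_2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if abs(self.rg) > 1.0:
            raise ValueError("rg must lie in [-1, 1]")
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("sample sizes must be positive")


@dataclass
class MRTriplet:
    """Exposure, mediator, and outcome summary tables from one simulation."""

    exposure: pd.DataFrame
    mediator: pd.DataFrame
    outcome: pd.DataFrame
    #: snp_ids of the mediator-specific (cis-like) instruments
    mediator_cis_ids: list[str] = field(default_factory=list)
    config: SimulationConfig | None = None

    def __iter__(self) -> Iterator[pd.DataFrame]:
        return iter((self.exposure, self.mediator, self.outcome))


def _two_sided_p(beta: np.ndarray, se: float | np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    # a p-value of exactly 0 violates the record invariant p in (0, 1]
    return np.clip(p, np.nextafter(0.0, 1.0), 1.0)


def _assign_alleles(rng: np.random.Generator, n: int, palindromic_fraction: float):
    pal = rng.random(n) < palindromic_fraction
    ea = np.empty(n, dtype=object)
    oa = np.empty(n, dtype=object)
    pal_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), size=n)
    non_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=n)
    for i in range(n):
        ea[i], oa[i] = (
            _PALINDROMIC_PAIRS[pal_idx[i]] if pal[i] else _NONPALINDROMIC_PAIRS[non_idx[i]]
        )
    return ea, oa


def _positions(n: int) -> tuple[np.ndarray, np.ndarray]:
    # round-robin over 22 autosomes, 20 Mb apart within a chromosome, so
    # every pair of SNPs is clumping-independent by construction
    idx = np.arange(n)
    chrom = (idx % 22) + 1
    bp = 1_000_000 + (idx // 22) * 20_000_000
    return chrom.astype(str), bp.astype(np.int64)


def simulate_mr_triplet(config: SimulationConfig, seed: int | None = None) -> MRTriplet:
    """Draw one exposure/mediator/outcome triplet of summary tables.

    For instrument SNP j with true exposure effect gamma_j:

    * ``beta_x_j ~ Normal(gamma_j, se_x^2)``
    * ``beta_m_j ~ Normal(b * gamma_j, se_m^2)``
    * ``beta_y_j ~ Normal((d + b*c) * gamma_j + alpha_j, se_y^2)``

    Mediator-specific SNP k with effect delta_k has exposure beta that is
    pure noise, ``beta_m_k ~ Normal(delta_k, se_m^2)`` and
    ``beta_y_k ~ Normal(c * delta_k, se_y^2)``.

    Reported p-values are two-sided normal tail probabilities of beta/se.
    A ``seed`` argument overrides ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    J = config.n_snps
    K = config.n_mediator_snps
    b = config.exposure_to_mediator
    c = config.mediator_to_outcome
    total = config.total_effect

    gamma = rng.normal(config.gamma_mean, config.gamma_sd, J)
    delta = rng.normal(config.delta_mean, config.delta_sd, max(K, 0))

    if config.pleiotropy == "none":
        alpha = np.zeros(J)
    elif config.pleiotropy == "balanced":
        alpha = rng.normal(0.0, config.pleiotropy_sd, J)
    else:  # directional: nonzero mean in the exposure-increasing orientation
        alpha = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, J)

    n = J + K
    snp_id = np.array([f"rs{i + 1:05d}" for i in range(J)] + [f"cis{i + 1:05d}" for i in range(K)])
    chrom, bp = _positions(n)
    ea, oa = _assign_alleles(rng, n, config.palindromic_fraction)
    eaf = rng.uniform(0.05, 0.95, n)

    mean_x = np.concatenate([gamma, np.zeros(K)])
    mean_m = np.concatenate([b * gamma, delta])
    mean_y = np.concatenate([total * gamma + alpha, c * delta])
    if config.random_sign:
        # allele recoding negates every trait's beta for a SNP jointly, so
        # the causal structure (Wald ratios, pleiotropy direction relative
        # to the exposure-increasing allele) is preserved
        sign = rng.choice([-1.0, 1.0], size=n)
        mean_x *= sign
        mean_m *= sign
        mean_y *= sign

    beta_x = rng.normal(mean_x, config.se_x)
    beta_m = rng.normal(mean_m, config.se_m)
    beta_y = rng.normal(mean_y, config.se_y)

    def table(beta: np.ndarray, se: float, n_samples: int) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": snp_id,
                "chrom": chrom,
                "bp": bp,
                "effect_allele": ea,
                "other_allele": oa,
                "eaf": eaf,
                "beta": beta,
                "se": np.full(n, se),
                "pval": _two_sided_p(beta, se),
                "n": n_samples,
            }
        )

    return MRTriplet(
        exposure=table(beta_x, config.se_x, config.n_exposure),
        mediator=table(beta_m, config.se_m, config.n_mediator),
        outcome=table(beta_y, config.se_y, config.n_outcome),
        mediator_cis_ids=[s for s in snp_id[J:]],
        config=replace(config),
    )


def null_mediator_tables(
    triplet: MRTriplet, k: int, seed: int, se_m: float | None = None
) -> dict[str, pd.DataFrame]:
    """Mediator tables with no causal content, on the triplet's SNP scaffold.

    Useful as negative controls in mediator screens: betas are pure noise,
    so such a candidate should survive the exposure->mediator screening step
    only at the nominal false-positive rate, and it offers no genome-wide
    significant instruments of its own.
    """
    scaffold = triplet.mediator
    rng = np.random.default_rng(seed)
    se = float(se_m if se_m is not None else scaffold["se"].iloc[0])
    out: dict[str, pd.DataFrame] = {}
    for i in range(k):
        beta = rng.normal(0.0, se, len(scaffold))
        tab = scaffold.copy()
        tab["beta"] = beta
        tab["se"] = se
        tab["pval"] = _two_sided_p(beta, se)
        out[f"null_mediator_{i + 1}"] = tab
    return out


def simulate_z_pairs(config: ZPairConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw paired z-statistics for two traits with a given genetic correlation.

    For SNP j with LD score l_j, (z1_j, z2_j) is bivariate normal with

        Var(z1_j) = 1 + N1 * h2_1 * l_j / M
        Var(z2_j) = 1 + N2 * h2_2 * l_j / M
        Cov       = sqrt(N1 * N2) * rg * sqrt(h2_1 * h2_2) * l_j / M

    (no sample overlap, so the covariance has no noise term).  LD scores are
    1 + Gamma(ld_shape, ld_scale), position-ordered in the output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    M = config.n_snps
    l = 1.0 + rng.gamma(config.ld_shape, config.ld_scale, M)
    v1 = 1.0 + config.n1 * config.h2_1 * l / M
    v2 = 1.0 + config.n2 * config.h2_2 * l / M
    c12 = np.sqrt(config.n1 * config.n2 * config.h2_1 * config.h2_2) * config.rg * l / M
    resid = v2 - c12**2 / v1
    bad = np.nonzero(resid < 0)[0]
    if bad.size:
        raise ValueError(f"per-SNP covariance not positive semi-definite at SNP index {bad[0]}")
    u1 = rng.standard_normal(M)
    u2 = rng.standard_normal(M)
    z1 = np.sqrt(v1) * u1
    z2 = (c12 / np.sqrt(v1)) * u1 + np.sqrt(resid) * u2
    return pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1:06d}" for i in range(M)],
            "z1": z1,
            "z2": z2,
            "ldscore": l,
        }
    )
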