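"""Instrument selection: significance and MAF filters, LD clumping, F statistics.

Instrumental variants for a two-sample MR analysis must be genome-wide
significant for the exposure, mutually LD-independent, common enough to be
well imputed, free of known confounder associations, and strong.  The
selection here applies, in order: a p-value threshold (default 5e-8), a
minor-allele-frequency floor (default 0.01), a user-supplied exclusion list
(the stand-in for a manual confounder lookup), greedy p-value-ranked LD
clumping (default r^2 < 0.001 within 10,000 kb), and an instrument-strength
floor on the per-SNP F statistic (beta/se)^2 (default F >= 10, the usual
weak-instrument convention).
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def f_statistic(beta, se):
    """Per-SNP instrument-strength F statistic, (beta/se)^2.

    Accepts scalars or arrays; raises ``ValueError`` for any ``se <= 0``.
    Low values (conventionally F < 10) flag instruments whose measurement
    error would bias the causal estimate toward the observational one.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard error must be > 0")
    f = (beta / se) ** 2
    return float(f) if f.ndim == 0 else f


def _ld_lookup(ld_pairs: pd.DataFrame | None) -> dict[tuple[str, str], float]:
    if ld_pairs is None or len(ld_pairs) == 0:
        return {}
    table: dict[tuple[str, str], float] = {}
    for a, b, r2 in zip(ld_pairs["snp_a"], ld_pairs["snp_b"], ld_pairs["r2"]):
        key = (a, b) if a <= b else (b, a)
        table[key] = float(r2)
    return table


def select_instruments(
    table: pd.DataFrame,
    p_threshold: float = 5e-8,
    clump_r2: float = 0.001,
    clump_kb: float = 10_000,
    maf_min: float = 0.01,
    f_min: float = 10.0,
    ld_pairs: pd.DataFrame | None = None,
    exclusion_list: Iterable[str] = (),
    missing_ld: str = "remove",
) -> pd.DataFrame:
    """Select LD-independent, significant, strong instruments.

    Parameters
    ----------
    table:
        Validated summary-statistics table for the exposure.
    p_threshold, maf_min:
        Keep rows with ``pval < p_threshold`` and minor-allele frequency
        ``min(eaf, 1-eaf) > maf_min``; rows without an ``eaf`` column (or
        with missing values) pass the MAF filter, since published
        instrument tables often omit frequencies.
    exclusion_list:
        snp_ids to remove before clumping, e.g. variants known to associate
        with confounders.
    clump_r2, clump_kb, ld_pairs, missing_ld:
        Greedy clumping: survivors are ranked by ascending p-value (ties by
        snp_id); a SNP is accepted unless an already-accepted SNP on the
        same chromosome lies within ``clump_kb`` kilobases and their r^2 is
        at least ``clump_r2``.  When no r^2 is available for a pair within
        the window the behaviour follows ``missing_ld``: ``"remove"``
        (conservative default, as when clumping against an unavailable
        reference panel) or ``"retain"`` (for synthetic data generated
        without LD).
    f_min:
        Minimum per-SNP F statistic; survivors get an ``f_stat`` column.

    Returns the surviving rows (possibly empty, with a logged warning);
    never raises for zero survivors.
    """
    if missing_ld not in ("remove", "retain"):
        raise ValueError("missing_ld must be 'remove' or 'retain'")

    df = table.copy()
    mask = df["pval"].to_numpy(float) < p_threshold
    if "eaf" in df.columns:
        eaf = df["eaf"].to_numpy(float)
        maf = np.minimum(eaf, 1.0 - eaf)
        mask &= np.isnan(maf) | (maf > maf_min)
    excl = set(exclusion_list)
    if excl:
        mask &= ~df["snp_id"].isin(excl).to_numpy(bool)
    df = df[mask]

    # greedy clumping by p-value rank, ties broken lexicographically so the
    # result is invariant to input row order
    df = df.sort_values(["pval", "snp_id"], kind="mergesort")
    ld = _ld_lookup(ld_pairs)
    window_bp = clump_kb * 1000.0
    accepted: list[int] = []
    acc_chrom: list[str] = []
    acc_bp: list[int] = []
    acc_id: list[str] = []
    for idx, snp, chrom, bp in zip(df.index, df["snp_id"], df["chrom"], df["bp"]):
        conflict = False
        for ch, pos, other in zip(acc_chrom, acc_bp, acc_id):
            if ch != chrom or abs(int(bp) - int(pos)) > window_bp:
                continue
            key = (snp, other) if snp <= other else (other, snp)
            r2 = ld.get(key)
            if r2 is None:
                if missing_ld == "remove":
                    conflict = True
            elif r2 >= clump_r2:
                conflict = True
            if conflict:
                break
        if not conflict:
            accepted.append(idx)
            acc_chrom.append(chrom)
            acc_bp.append(int(bp))
            acc_id.append(snp)

    out = df.loc[accepted].copy()
    if len(out):
        out["f_stat"] = f_statistic(out["beta"].to_numpy(), out["se"].to_numpy())
        out = out[out["f_stat"] >= f_min]
    else:
        out["f_stat"] = pd.Series(dtype=float)
    out = out.sort_values(["pval", "snp_id"], kind="mergesort").reset_index(drop=True)
    if len(out) == 0:
        logger.warning("select_instruments: no instruments survived the filters")
    return out
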