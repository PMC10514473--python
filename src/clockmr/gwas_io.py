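"""Reading, validation, writing, and harmonization of GWAS summary statistics.

Summary-statistics tables are plain tab-separated text with a header and one
row per SNP.  In memory they are :class:`pandas.DataFrame` objects with the
canonical columns

    snp_id, chrom, bp, beta, se, pval          (mandatory)
    effect_allele, other_allele, eaf, n        (optional)

``beta`` is the per-allele effect of ``effect_allele`` on the trait scale
(log odds for case-control traits), ``se`` its standard error, ``pval`` the
reported association p-value and ``eaf`` the effect-allele frequency.
Published instrument tables often omit
alleles and frequencies, so those columns are optional here; operations that
genuinely need them (harmonization) raise a clear error when they are absent.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS: tuple[str, ...] = ("snp_id", "chrom", "bp", "beta", "se", "pval")
OPTIONAL_COLUMNS: tuple[str, ...] = ("effect_allele", "other_allele", "eaf", "n")
SUMSTATS_COLUMNS: tuple[str, ...] = MANDATORY_COLUMNS + OPTIONAL_COLUMNS

#: statuses a SNP can receive during harmonization
HARMONY_STATUSES = ("kept", "sign_flipped", "dropped_palindromic", "dropped_incompatible")
KEPT_STATUSES = ("kept", "sign_flipped")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset(_COMPLEMENT)

#: floats are written with 10 significant digits so that a write/read
#: round-trip reproduces every beta and SE at full printed precision
FLOAT_FORMAT = "%.10g"


def read_summary_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> pd.DataFrame:
    """Read and validate a GWAS summary-statistics table.

    Parameters
    ----------
    path:
        Tab-separated text file with a header row.
    column_map:
        Optional mapping from canonical column names (``snp_id`` ...) to the
        names used in the file, for files with non-canonical headers.
    sep:
        Field separator, tab by default.

    Returns
    -------
    pandas.DataFrame
        Validated table with canonical columns.  Rows violating the record
        invariants (non-positive SE, p outside (0, 1], allele frequency
        outside (0, 1), identical or malformed alleles, duplicated snp_id)
        are dropped; the number removed is logged and stored in
        ``df.attrs["n_dropped"]``.

    Raises
    ------
    ValueError
        If a mandatory column is missing (the error names it) or no valid
        rows remain.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    if column_map:
        rename = {src: canon for canon, src in column_map.items()}
        raw = raw.rename(columns=rename)

    for col in MANDATORY_COLUMNS:
        if col not in raw.columns:
            raise ValueError(f"mandatory column {col!r} missing from {path}")

    keep = [c for c in SUMSTATS_COLUMNS if c in raw.columns]
    df = raw[keep].copy()

    df["chrom"] = df["chrom"].astype(str).str.strip()
    for col in ("bp", "beta", "se", "pval", "eaf", "n"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("effect_allele", "other_allele"):
        if col in df.columns:
            df[col] = df[col].astype("string").str.upper().str.strip()

    n_in = len(df)
    ok = (
        df["snp_id"].notna()
        & df["bp"].notna()
        & np.isfinite(df["beta"].to_numpy(float))
        & (df["se"].to_numpy(float) > 0)
        & (df["pval"].to_numpy(float) > 0)
        & (df["pval"].to_numpy(float) <= 1)
    )
    if "eaf" in df.columns:
        eaf = df["eaf"].to_numpy(float)
        ok &= np.isnan(eaf) | ((eaf > 0) & (eaf < 1))
    if "effect_allele" in df.columns and "other_allele" in df.columns:
        ea, oa = df["effect_allele"], df["other_allele"]
        both_missing = ea.isna() & oa.isna()
        valid = ea.isin(_VALID_ALLELES) & oa.isin(_VALID_ALLELES) & (ea != oa)
        ok &= (both_missing | valid).to_numpy(bool)

    df = df[ok]
    df = df[~df["snp_id"].duplicated(keep="first")]
    df = df.reset_index(drop=True)
    df["bp"] = df["bp"].astype(np.int64)

    n_dropped = n_in - len(df)
    if n_dropped:
        logger.info("read_summary_table: dropped %d invalid row(s) from %s", n_dropped, path)
    if len(df) == 0:
        raise ValueError(f"no valid summary-statistics rows in {path}")
    df.attrs["n_dropped"] = n_dropped
    return df


def write_summary_table(table: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write a summary-statistics table as tab-separated text.

    Floats are formatted with 10 significant digits so a subsequent
    :func:`read_summary_table` reproduces betas and SEs exactly as printed.
    """
    table.to_csv(path, sep=sep, index=False, float_format=FLOAT_FORMAT)


def read_ld_scores(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a two-column (snp_id, ldscore) LD-score table.

    LD scores below 1 violate the definition (a SNP is in perfect LD with
    itself); offending rows are dropped and counted in the log.
    """
    df = pd.read_csv(path, sep=sep)
    if not {"snp_id", "ldscore"}.issubset(df.columns):
        raise ValueError(f"LD-score file {path} must have columns snp_id, ldscore")
    n_in = len(df)
    df = df[pd.to_numeric(df["ldscore"], errors="coerce") >= 1].reset_index(drop=True)
    if len(df) < n_in:
        logger.info("read_ld_scores: dropped %d row(s) with ldscore < 1", n_in - len(df))
    return df


def read_ld_pairs(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a three-column (snp_a, snp_b, r2) pairwise-LD table; r2 must lie in [0, 1]."""
    df = pd.read_csv(path, sep=sep)
    if not {"snp_a", "snp_b", "r2"}.issubset(df.columns):
        raise ValueError(f"pairwise-LD file {path} must have columns snp_a, snp_b, r2")
    r2 = pd.to_numeric(df["r2"], errors="coerce")
    bad = ~((r2 >= 0) & (r2 <= 1))
    if bad.any():
        logger.info("read_ld_pairs: dropped %d row(s) with r2 outside [0, 1]", int(bad.sum()))
    return df[~bad].reset_index(drop=True)


def _is_palindromic(a1: pd.Series, a2: pd.Series) -> pd.Series:
    return a2 == a1.map(_COMPLEMENT)


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_eaf_window: float = 0.08,
) -> pd.DataFrame:
    """Align exposure and outcome records onto the exposure's effect allele.

    Two-sample MR requires that, for every instrument, the outcome beta
    refers to the same effect allele as the exposure beta.  For each SNP in
    the intersection of the two tables this assigns exactly one status:

    ``kept``
        outcome alleles already match the exposure orientation (directly or
        after strand complement);
    ``sign_flipped``
        outcome alleles are swapped relative to the exposure, so ``beta_y``
        is negated and ``eaf_y`` replaced by ``1 - eaf_y``;
    ``dropped_palindromic``
        A/T or C/G SNP whose allele frequency lies within
        ``palindrome_eaf_window`` of 0.5 on either trait (or is missing):
        strand cannot be resolved, the SNP is excluded;
    ``dropped_incompatible``
        allele sets that match in neither orientation even allowing strand
        complement, or records with missing alleles.

    Unambiguous palindromic SNPs are oriented by allele frequency (the
    minor/major side must agree between the two studies), because for an A/T
    or C/G SNP the allele letters are identical on both strands.

    Returns a table with columns ``snp_id, chrom, bp, effect_allele,
    other_allele, beta_x, se_x, pval_x, eaf_x, beta_y, se_y, pval_y, eaf_y,
    status``; ``beta_y``/``eaf_y`` are already oriented for kept and flipped
    rows.  Raises ``ValueError`` when the snp_id intersection is empty or a
    table lacks allele columns.
    """
    for name, tab in (("exposure", exposure), ("outcome", outcome)):
        if "effect_allele" not in tab.columns or "other_allele" not in tab.columns:
            raise ValueError(f"{name} table lacks allele columns; cannot harmonize")

    cols = ["snp_id", "chrom", "bp", "effect_allele", "other_allele", "beta", "se", "pval"]
    opt = ["eaf"]
    ex = exposure[[c for c in cols + opt if c in exposure.columns]]
    oc = outcome[[c for c in cols + opt if c in outcome.columns]]
    m = ex.merge(oc, on="snp_id", suffixes=("_x", "_y"))
    if len(m) == 0:
        raise ValueError("exposure and outcome tables share no snp_id")
    for c in ("eaf_x", "eaf_y"):
        if c not in m.columns:
            m[c] = np.nan

    ea_x = m["effect_allele_x"]
    oa_x = m["other_allele_x"]
    ea_y = m["effect_allele_y"]
    oa_y = m["other_allele_y"]
    cea_y = ea_y.map(_COMPLEMENT)
    coa_y = oa_y.map(_COMPLEMENT)

    missing = ea_x.isna() | oa_x.isna() | ea_y.isna() | oa_y.isna()
    pal = _is_palindromic(ea_x, oa_x).fillna(False).to_numpy(bool)

    same = ((ea_y == ea_x) & (oa_y == oa_x)).fillna(False).to_numpy(bool)
    swap = ((ea_y == oa_x) & (oa_y == ea_x)).fillna(False).to_numpy(bool)
    csame = ((cea_y == ea_x) & (coa_y == oa_x)).fillna(False).to_numpy(bool)
    cswap = ((cea_y == oa_x) & (coa_y == ea_x)).fillna(False).to_numpy(bool)
    any_match = same | swap | csame | cswap

    eaf_x = m["eaf_x"].to_numpy(float)
    eaf_y = m["eaf_y"].to_numpy(float)
    near_half = (
        np.isnan(eaf_x)
        | np.isnan(eaf_y)
        | (np.abs(eaf_x - 0.5) < palindrome_eaf_window)
        | (np.abs(eaf_y - 0.5) < palindrome_eaf_window)
    )

    status = np.full(len(m), "dropped_incompatible", dtype=object)
    npal = ~pal & ~missing.to_numpy(bool)
    status[npal & (same | csame)] = "kept"
    status[npal & ~(same | csame) & (swap | cswap)] = "sign_flipped"

    pal_ok = pal & ~missing.to_numpy(bool) & any_match
    status[pal_ok & near_half] = "dropped_palindromic"
    pal_use = pal_ok & ~near_half
    # palindromic orientation by frequency: minor/major side must agree
    agree = (eaf_x < 0.5) == (eaf_y < 0.5)
    status[pal_use & agree] = "kept"
    status[pal_use & ~agree] = "sign_flipped"

    flip = status == "sign_flipped"
    beta_y = m["beta_y"].to_numpy(float).copy()
    beta_y[flip] = -beta_y[flip]
    eaf_y_out = eaf_y.copy()
    eaf_y_out[flip] = 1.0 - eaf_y_out[flip]

    out = pd.DataFrame(
        {
            "snp_id": m["snp_id"],
            "chrom": m["chrom_x"],
            "bp": m["bp_x"],
            "effect_allele": ea_x,
            "other_allele": oa_x,
            "beta_x": m["beta_x"].to_numpy(float),
            "se_x": m["se_x"].to_numpy(float),
            "pval_x": m["pval_x"].to_numpy(float),
            "eaf_x": eaf_x,
            "beta_y": beta_y,
            "se_y": m["se_y"].to_numpy(float),
            "pval_y": m["pval_y"].to_numpy(float),
            "eaf_y": eaf_y_out,
            "status": status,
        }
    )
    counts = out["status"].value_counts().to_dict()
    logger.info("harmonize: %s", counts)
    out.attrs["status_counts"] = counts
    return out


def kept_pairs(harmonized: pd.DataFrame) -> pd.DataFrame:
    """Rows of a harmonized table usable as instruments (kept or sign-flipped)."""
    return harmonized[harmonized["status"].isin(KEPT_STATUSES)].reset_index(drop=True)
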