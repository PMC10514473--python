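"""Packaged reference tables.

The single shipped dataset is the published instrument table for the
HannumAge epigenetic-age-acceleration GWAS: 11 LD-independent, genome-wide
significant SNPs with their per-allele effect sizes, standard errors,
p-values and instrument-strength F statistics as printed.  Alleles and
allele frequencies were not published for this table, so those columns are
absent; the table supports instrument-strength and filtering computations
but not allele harmonization.

Note the printed p-values are reproduced verbatim even where they are not
consistent with a normal Wald test of beta/SE; the pipeline thresholds on
the printed value.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd


def load_hannum_instruments() -> pd.DataFrame:
    """Return the 11-SNP HannumAge instrument table.

    Columns: ``snp_id`` (chr:pos label), ``chrom``, ``bp`` (1-based),
    ``beta``, ``se``, ``pval``, and ``f_reported`` (the F statistic as
    printed in the source table, kept for cross-checking against the
    recomputed (beta/se)^2).
    """
    path = files("clockmr.data").joinpath("hannum_instruments.tsv")
    with path.open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    return df
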