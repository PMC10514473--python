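"""I/O, validation and allele-harmonization behaviour."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clockmr.gwas_io import (
    harmonize,
    kept_pairs,
    read_ld_scores,
    read_summary_table,
    write_summary_table,
)


def _write(tmp_path, rows, header, name="t.tsv", sep="\t"):
    path = tmp_path / name
    lines = [sep.join(header)] + [sep.join(str(v) for v in r) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


HDR = ["snp_id", "chrom", "bp", "beta", "se", "pval"]
ROW1 = ["rs1", "1", "1000", "0.25", "0.05", "1e-10"]
ROW2 = ["rs2", "2", "2000", "-0.30", "0.04", "1e-9"]


class TestReadSummaryTable:
    def test_reads_valid_rows(self, tmp_path):
        df = read_summary_table(_write(tmp_path, [ROW1, ROW2], HDR))
        assert len(df) == 2
        assert df.attrs["n_dropped"] == 0
        assert (df["se"] > 0).all()

    def test_drops_nonpositive_se_and_counts(self, tmp_path):
        bad = ["rs3", "3", "3000", "0.1", "0", "0.5"]
        df = read_summary_table(_write(tmp_path, [ROW1, bad], HDR))
        assert len(df) == 1
        assert df.attrs["n_dropped"] == 1

    def test_column_map_recovers_swapped_order(self, tmp_path):
        canonical = read_summary_table(_write(tmp_path, [ROW1, ROW2], HDR))
        hdr = ["P", "SE", "BETA", "BP", "CHR", "ID"]
        rows = [[r[5], r[4], r[3], r[2], r[1], r[0]] for r in (ROW1, ROW2)]
        mapped = read_summary_table(
            _write(tmp_path, rows, hdr, name="swapped.tsv"),
            column_map={"snp_id": "ID", "chrom": "CHR", "bp": "BP",
                        "beta": "BETA", "se": "SE", "pval": "P"},
        )
        pd.testing.assert_frame_equal(canonical, mapped)

    def test_missing_mandatory_column_names_it(self, tmp_path):
        path = _write(tmp_path, [ROW1[:5]], HDR[:5])
        with pytest.raises(ValueError, match="pval"):
            read_summary_table(path)

    def test_zero_valid_rows_is_hard_error(self, tmp_path):
        bad = ["rs1", "1", "1000", "0.1", "-1", "0.5"]
        with pytest.raises(ValueError, match="no valid"):
            read_summary_table(_write(tmp_path, [bad], HDR))

    def test_duplicate_snp_ids_deduplicated(self, tmp_path):
        df = read_summary_table(_write(tmp_path, [ROW1, ROW1], HDR))
        assert len(df) == 1
        assert df.attrs["n_dropped"] == 1

    def test_round_trip_preserves_full_precision(self, tmp_path):
        rows = [["rs1", "1", "169549040", "0.256626", "0.0526221", "5.38E-17"],
                ["rs2", "10", "49675247", "-0.290248", "0.0364699", "7.26E-11"]]
        df = read_summary_table(_write(tmp_path, rows, HDR))
        out = tmp_path / "roundtrip.tsv"
        write_summary_table(df, out)
        df2 = read_summary_table(out)
        assert (df2["beta"] == df["beta"]).all()
        assert (df2["se"] == df["se"]).all()
        assert (df2["pval"] == df["pval"]).all()

    def test_ld_scores_below_one_dropped(self, tmp_path):
        path = tmp_path / "ld.tsv"
        path.write_text("snp_id\tldscore\nrs1\t5.0\nrs2\t0.5\n")
        assert read_ld_scores(path)["snp_id"].tolist() == ["rs1"]


def _table(rows):
    cols = ["snp_id", "chrom", "bp", "effect_allele", "other_allele", "eaf",
            "beta", "se", "pval"]
    return pd.DataFrame(rows, columns=cols)


EXPOSURE = _table([
    ["rs1", "1", 100, "A", "G", 0.30, 0.20, 0.05, 1e-9],
    ["rs2", "1", 200, "A", "G", 0.30, 0.20, 0.05, 1e-9],
    ["rs3", "1", 300, "A", "T", 0.50, 0.20, 0.05, 1e-9],
    ["rs4", "1", 400, "A", "G", 0.30, 0.20, 0.05, 1e-9],
    ["rs5", "1", 500, "A", "T", 0.20, 0.20, 0.05, 1e-9],
])


class TestHarmonize:
    def test_statuses_and_orientation(self):
        outcome = _table([
            ["rs1", "1", 100, "A", "G", 0.30, 0.10, 0.05, 1e-4],   # identical
            ["rs2", "1", 200, "G", "A", 0.70, 0.10, 0.05, 1e-4],   # swapped
            ["rs3", "1", 300, "A", "T", 0.50, 0.10, 0.05, 1e-4],   # ambiguous palindrome
            ["rs4", "1", 400, "A", "C", 0.30, 0.10, 0.05, 1e-4],   # incompatible alleles
            ["rs5", "1", 500, "A", "T", 0.21, 0.10, 0.05, 1e-4],   # resolvable palindrome
        ])
        h = harmonize(EXPOSURE, outcome).set_index("snp_id")
        assert h.loc["rs1", "status"] == "kept"
        assert h.loc["rs1", "beta_y"] == pytest.approx(0.1)
        assert h.loc["rs2", "status"] == "sign_flipped"
        assert h.loc["rs2", "beta_y"] == pytest.approx(-0.1)
        assert h.loc["rs2", "eaf_y"] == pytest.approx(0.3)
        assert h.loc["rs3", "status"] == "dropped_palindromic"
        assert h.loc["rs4", "status"] == "dropped_incompatible"
        assert h.loc["rs5", "status"] == "kept"

    def test_strand_complement_match_kept(self):
        outcome = _table([["rs1", "1", 100, "T", "C", 0.30, 0.10, 0.05, 1e-4]])
        h = harmonize(EXPOSURE, outcome)
        assert h["status"].tolist() == ["kept"]
        assert h["beta_y"].iloc[0] == pytest.approx(0.1)

    def test_strand_complement_swap_flips(self):
        outcome = _table([["rs1", "1", 100, "C", "T", 0.70, 0.10, 0.05, 1e-4]])
        h = harmonize(EXPOSURE, outcome)
        assert h["status"].tolist() == ["sign_flipped"]
        assert h["beta_y"].iloc[0] == pytest.approx(-0.1)

    def test_missing_eaf_palindrome_dropped(self):
        outcome = _table([["rs5", "1", 500, "A", "T", np.nan, 0.10, 0.05, 1e-4]])
        h = harmonize(EXPOSURE, outcome)
        assert h["status"].tolist() == ["dropped_palindromic"]

    def test_empty_intersection_is_hard_error(self):
        outcome = _table([["rsX", "1", 999, "A", "G", 0.3, 0.1, 0.05, 1e-4]])
        with pytest.raises(ValueError, match="share no snp_id"):
            harmonize(EXPOSURE, outcome)

    def test_idempotent_on_harmonized_output(self):
        outcome = _table([
            ["rs1", "1", 100, "G", "A", 0.70, 0.10, 0.05, 1e-4],
            ["rs2", "1", 200, "A", "G", 0.30, 0.10, 0.05, 1e-4],
        ])
        h1 = harmonize(EXPOSURE, outcome)
        # rebuild an outcome table already oriented to the exposure alleles
        oriented = _table([
            [r.snp_id, "1", 100, r.effect_allele, r.other_allele, r.eaf_y,
             r.beta_y, r.se_y, r.pval_y]
            for r in h1.itertuples()
        ])
        h2 = harmonize(EXPOSURE, oriented)
        assert (h2["status"] == "kept").all()
        assert np.allclose(h2["beta_y"], h1["beta_y"])
        assert np.allclose(h2["eaf_y"], h1["eaf_y"])

    @given(st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_every_snp_gets_exactly_one_status(self, data):
        alleles = ["A", "C", "G", "T"]
        n = data.draw(st.integers(2, 6))
        rows_x, rows_y = [], []
        for i in range(n):
            ea = data.draw(st.sampled_from(alleles), label=f"ea{i}")
            oa = data.draw(st.sampled_from([a for a in alleles if a != ea]), label=f"oa{i}")
            ea2 = data.draw(st.sampled_from(alleles), label=f"ea2{i}")
            oa2 = data.draw(st.sampled_from([a for a in alleles if a != ea2]), label=f"oa2{i}")
            eaf = data.draw(st.floats(0.05, 0.95), label=f"eaf{i}")
            rows_x.append([f"rs{i}", "1", 100 + i, ea, oa, eaf, 0.2, 0.05, 1e-9])
            rows_y.append([f"rs{i}", "1", 100 + i, ea2, oa2, eaf, 0.1, 0.05, 1e-4])
        h = harmonize(_table(rows_x), _table(rows_y))
        assert len(h) == n
        assert h["status"].isin(
            ["kept", "sign_flipped", "dropped_palindromic", "dropped_incompatible"]
        ).all()
        assert len(kept_pairs(h)) + (~h["status"].isin(["kept", "sign_flipped"])).sum() == n
        flipped = h[h["status"] == "sign_flipped"]
        orig = _table(rows_y).set_index("snp_id")
        for r in flipped.itertuples():
            assert r.beta_y == pytest.approx(-orig.loc[r.snp_id, "beta"])
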