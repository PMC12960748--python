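"""Reading, validation and harmonization of summary statistics."""

import numpy as np
import pandas as pd
import pytest

from netmr import gwas_io
from netmr.gwas_io import (ColumnMappingError, EmptyInputError, EmptyOverlapError,
                           harmonize, read_harmonized, read_sumstats,
                           write_harmonized)

from conftest import make_hset, make_table

CANON_HEADER = "snp_id\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn\n"


def _write(tmp_path, rows, header=CANON_HEADER, name="x.tsv"):
    p = tmp_path / name
    p.write_text(header + "".join(rows))
    return p


class TestReadSumstats:
    def test_well_formed_table_read_verbatim(self, tmp_path):
        p = _write(tmp_path, [
            "rs1\t1\t100\ta\tg\t0.2\t0.1\t0.02\t1e-6\t5000\n",
            "rs2\t1\t200\tC\tT\t0.4\t-0.3\t0.05\t1e-8\t5000\n",
            "rs3\t2\t300\tG\tA\t0.5\t0.0\t0.01\t1.0\t5000\n",
        ])
        t = read_sumstats(p, trait_label="prot")
        assert t.n_snp == 3
        # alleles upper-cased
        assert t.df["effect_allele"].tolist() == ["A", "C", "G"]

    def test_invalid_rows_dropped(self, tmp_path):
        p = _write(tmp_path, [
            "rs1\t1\t100\tA\tG\t0.2\t0.1\t0.0\t1e-6\t5000\n",   # se = 0
            "rs2\t1\t200\tC\tC\t0.4\t0.1\t0.05\t1e-8\t5000\n",  # EA == OA
            "rs3\t2\t300\tG\tA\t0.5\t0.2\t0.01\t0.5\t5000\n",
        ])
        t = read_sumstats(p)
        assert t.df["snp_id"].tolist() == ["rs3"]

    def test_zero_pval_clamped_not_dropped(self, tmp_path):
        p = _write(tmp_path, ["rs1\t1\t100\tA\tG\t0.2\t0.9\t0.01\t0\t5000\n"])
        t = read_sumstats(p)
        assert t.n_snp == 1 and 0 < t.df["pval"].iloc[0] < 1e-300

    def test_column_map_aliases_give_identical_table(self, tmp_path):
        p1 = _write(tmp_path, ["rs1\t1\t100\tA\tG\t0.2\t0.1\t0.02\t1e-6\t5000\n"])
        alias = "rsid\tCHR\tBP\tA1\tA2\tfreq\tb\tstderr\tp\tN\n"
        p2 = _write(tmp_path, ["rs1\t1\t100\tA\tG\t0.2\t0.1\t0.02\t1e-6\t5000\n"],
                    header=alias, name="y.tsv")
        t1 = read_sumstats(p1)
        t2 = read_sumstats(p2, column_map={
            "snp_id": "rsid", "chrom": "CHR", "pos": "BP", "effect_allele": "A1",
            "other_allele": "A2", "eaf": "freq", "beta": "b", "se": "stderr",
            "pval": "p", "n": "N"})
        pd.testing.assert_frame_equal(t1.df, t2.df, check_dtype=False)

    def test_missing_mandatory_column_named(self, tmp_path):
        p = _write(tmp_path, ["rs1\t1\t100\tA\t0.2\t0.1\t0.02\t1e-6\t5000\n"],
                   header=CANON_HEADER.replace("other_allele\t", ""))
        with pytest.raises(ColumnMappingError, match="other_allele"):
            read_sumstats(p)

    def test_empty_file_is_input_error(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises(EmptyInputError):
            read_sumstats(p)

    def test_gzip_and_csv_dialects(self, tmp_path):
        import gzip
        body = CANON_HEADER.replace("\t", ",") + "rs1,1,100,A,G,0.2,0.1,0.02,1e-6,5000\n"
        p = tmp_path / "x.csv.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(body)
        assert read_sumstats(p).n_snp == 1


class TestHarmonize:
    def _pair(self, out_ea, out_oa, beta_out=0.3, eaf_out=0.7, exp_eaf=0.3,
              exp_alleles=("A", "G")):
        exp = make_table(["rs1"], [0.1], [0.02], ea=[exp_alleles[0]],
                         oa=[exp_alleles[1]], eaf=[exp_eaf], label="exp")
        out = make_table(["rs1"], [beta_out], [0.05], ea=[out_ea], oa=[out_oa],
                         eaf=[eaf_out], label="out")
        return exp, out

    def test_same_orientation_kept_as_is(self):
        h = harmonize(*self._pair("A", "G"))
        assert h.beta_out[0] == pytest.approx(0.3)

    def test_swapped_orientation_flips_sign(self):
        h = harmonize(*self._pair("G", "A"))
        assert h.beta_out[0] == pytest.approx(-0.3)
        assert h.n_dropped_palindromic == 0 and h.n_dropped_incompatible == 0

    def test_strand_flip_resolved_by_complement(self):
        # exposure A/G; outcome on the other strand is T/C
        h = harmonize(*self._pair("T", "C"))
        assert h.beta_out[0] == pytest.approx(0.3)
        h = harmonize(*self._pair("C", "T"))   # complement + swap
        assert h.beta_out[0] == pytest.approx(-0.3)

    def test_incompatible_alleles_dropped_and_counted(self):
        exp = make_table(["rs1", "rs2"], [0.1, 0.1], [0.02, 0.02], label="exp")
        out = make_table(["rs1", "rs2"], [0.3, 0.3], [0.05, 0.05],
                         ea=["A", "C"], oa=["G", "A"], label="out")
        h = harmonize(exp, out)
        assert h.snp_ids == ["rs1"] and h.n_dropped_incompatible == 1

    @pytest.mark.parametrize("eaf_exp,eaf_out,kept", [
        (0.30, 0.30, True),    # concordant, both clear of 0.5
        (0.70, 0.70, True),
        (0.50, 0.30, False),   # exposure EAF intermediate
        (0.30, 0.44, False),   # outcome EAF inside the 0.42-0.58 window
        (0.30, 0.70, False),   # discordant sides of 0.5
        (np.nan, 0.30, False), # missing EAF
    ])
    def test_palindrome_window_rule(self, eaf_exp, eaf_out, kept):
        exp, out = self._pair("A", "T", eaf_out=eaf_out, exp_eaf=eaf_exp,
                              exp_alleles=("A", "T"))
        if kept:
            h = harmonize(exp, out)
            assert h.n_snp == 1 and h.n_dropped_palindromic == 0
        else:
            with pytest.raises(EmptyOverlapError):
                harmonize(exp, out)

    def test_palindrome_drop_counted(self):
        exp = make_table(["rs1", "rs2"], [0.1, 0.1], [0.02, 0.02],
                         ea=["A", "A"], oa=["T", "G"], eaf=[0.5, 0.3], label="e")
        out = make_table(["rs1", "rs2"], [0.3, 0.3], [0.05, 0.05],
                         ea=["A", "A"], oa=["T", "G"], eaf=[0.5, 0.3], label="o")
        h = harmonize(exp, out)
        assert h.snp_ids == ["rs2"] and h.n_dropped_palindromic == 1

    def test_output_preserves_exposure_order(self):
        exp = make_table(["b", "a", "c"], [0.1] * 3, [0.02] * 3, label="e")
        out = make_table(["c", "a", "b"], [0.1, 0.2, 0.3], [0.05] * 3, label="o")
        h = harmonize(exp, out)
        assert h.snp_ids == ["b", "a", "c"]
        assert h.beta_out.tolist() == [0.3, 0.2, 0.1]

    def test_no_overlap_raises(self):
        exp = make_table(["rs1"], [0.1], [0.02], label="e")
        out = make_table(["rs9"], [0.1], [0.02], label="o")
        with pytest.raises(EmptyOverlapError):
            harmonize(exp, out)

    def test_idempotent_on_aligned_tables(self):
        exp = make_table(["rs1", "rs2"], [0.1, -0.2], [0.02, 0.03],
                         ea=["A", "C"], oa=["G", "T"], label="e")
        out = make_table(["rs1", "rs2"], [0.3, 0.1], [0.05, 0.04],
                         ea=["A", "C"], oa=["G", "T"], label="o")
        h1 = harmonize(exp, out)
        h2 = harmonize(exp, out)  # already consistent: nothing changes
        np.testing.assert_array_equal(h1.beta_out, h2.beta_out)
        np.testing.assert_array_equal(h1.beta_out, out.df["beta"].to_numpy())

    def test_sign_equivariance_under_outcome_allele_flip(self):
        exp = make_table(["rs1", "rs2"], [0.1, -0.2], [0.02, 0.03],
                         ea=["A", "C"], oa=["G", "T"], eaf=[0.3, 0.2], label="e")
        out = make_table(["rs1", "rs2"], [0.3, 0.1], [0.05, 0.04],
                         ea=["A", "C"], oa=["G", "T"], eaf=[0.3, 0.2], label="o")
        flipped = out.df.copy()
        flipped[["effect_allele", "other_allele"]] = \
            flipped[["other_allele", "effect_allele"]].to_numpy()
        flipped["beta"] = -flipped["beta"]
        flipped["eaf"] = 1 - flipped["eaf"]
        h1 = harmonize(exp, out)
        h2 = harmonize(exp, gwas_io.SummaryTable(flipped, "o"))
        np.testing.assert_allclose(h1.beta_out, h2.beta_out)

    def test_drop_counts_partition_exposure_snps(self):
        # 1 kept + 1 palindromic drop + 1 incompatible + 1 not shared = 4
        exp = make_table(["k", "p", "i", "m"], [0.1] * 4, [0.02] * 4,
                         ea=["A", "A", "A", "A"], oa=["G", "T", "G", "G"],
                         eaf=[0.3, 0.5, 0.3, 0.3], label="e")
        out = make_table(["k", "p", "i"], [0.1] * 3, [0.02] * 3,
                         ea=["A", "A", "C"], oa=["G", "T", "A"],
                         eaf=[0.3, 0.5, 0.3], label="o")
        h = harmonize(exp, out)
        n_not_shared = exp.n_snp - sum(
            s in set(out.df["snp_id"]) for s in exp.df["snp_id"])
        assert (h.n_snp + h.n_dropped_palindromic + h.n_dropped_incompatible
                + n_not_shared) == exp.n_snp


class TestWriteHarmonized:
    def test_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(7)
        h = make_hset(rng.normal(size=5), rng.uniform(0.01, 0.1, 5),
                      rng.normal(size=5), rng.uniform(0.01, 0.1, 5))
        p = tmp_path / "new_dir" / "h.tsv"   # directory auto-created
        write_harmonized(h, p)
        back = read_harmonized(p)
        assert back.snp_ids == h.snp_ids
        for f in ("beta_exp", "se_exp", "beta_out", "se_out"):
            np.testing.assert_array_equal(getattr(back, f), getattr(h, f))

    def test_single_snp_file_has_header_and_one_row(self, tmp_path):
        h = make_hset([0.1], [0.02], [0.3], [0.05])
        p = tmp_path / "h.tsv"
        write_harmonized(h, p)
        assert len(p.read_text().strip().splitlines()) == 2
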