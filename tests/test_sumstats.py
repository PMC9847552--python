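"""Summary-statistics reading, harmonization, masks, and the LD reference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import write_sumstats_file
from pleioscan.sumstats import (
    LDReference,
    RegionMask,
    default_masks,
    harmonize_pair,
    load_ld_reference,
    read_sumstats,
    read_results_table,
    tag_masked_regions,
    write_ld_reference,
    write_results_table,
)


def _row(snp, chrom=1, bp=1000, a1="A", a2="G", beta=0.1, se=0.05, p=0.1, n=10000):
    return {"SNP": snp, "CHR": chrom, "BP": bp, "A1": a1, "A2": a2,
            "BETA": beta, "SE": se, "P": p, "N": n}


class TestReadSumstats:
    def test_well_formed_file_sorted_by_position(self, tmp_path):
        path = write_sumstats_file(
            tmp_path / "s.tsv",
            [_row("rs3", bp=3000), _row("rs1", bp=1000), _row("rs2", bp=2000)],
        )
        t = read_sumstats(path, "t")
        assert len(t) == 3
        assert t.table["pos"].tolist() == [1000, 2000, 3000]

    def test_invalid_p_dropped_and_counted(self, tmp_path):
        path = write_sumstats_file(
            tmp_path / "s.tsv", [_row("rs1", p=0.0), _row("rs2", bp=2000)]
        )
        t = read_sumstats(path, "t")
        assert len(t) == 1
        assert t.drop_counts["invalid_p"] == 1

    def test_missing_p_column_filled_from_wald(self, tmp_path):
        path = write_sumstats_file(
            tmp_path / "s.tsv",
            [{"SNP": "rs1", "CHR": 1, "BP": 1000, "A1": "A", "A2": "G",
              "BETA": 1.96, "SE": 1.0, "N": 10000}],
            header=["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "N"],
        )
        t = read_sumstats(path, "t")
        # normal-tail oracle: 2*Phi(-1.96)
        assert t.table["pval"].iloc[0] == pytest.approx(2 * stats.norm.sf(1.96))
        assert t.table["pval"].iloc[0] == pytest.approx(0.05, abs=1e-3)

    def test_missing_required_column_is_hard_error(self, tmp_path):
        path = write_sumstats_file(
            tmp_path / "s.tsv", [_row("rs1")],
            header=["SNP", "CHR", "BP", "A1", "A2", "BETA", "P", "N"],
        )
        with pytest.raises(ValueError, match="SE"):
            read_sumstats(path, "t")

    def test_column_name_remapping(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("rsid\tCHR\tBP\tA1\tA2\tBETA\tSE\tP\tN\n"
                        "rs1\t1\t1000\tA\tG\t0.1\t0.05\t0.1\t10000\n")
        t = read_sumstats(path, "t", column_map={"snp_id": "rsid"})
        assert t.table["snp_id"].tolist() == ["rs1"]

    def test_duplicate_snp_keeps_smaller_se(self, tmp_path):
        path = write_sumstats_file(
            tmp_path / "s.tsv",
            [_row("rs1", se=0.08), _row("rs1", bp=1000, se=0.02)],
        )
        t = read_sumstats(path, "t")
        assert len(t) == 1
        assert t.table["se"].iloc[0] == 0.02
        assert t.drop_counts["duplicate_snp_id"] == 1


class TestHarmonize:
    def _tables(self, tmp_path, rows1, rows2):
        p1 = write_sumstats_file(tmp_path / "t1.tsv", rows1)
        p2 = write_sumstats_file(tmp_path / "t2.tsv", rows2)
        return read_sumstats(p1, "t1"), read_sumstats(p2, "t2")

    def test_swapped_alleles_flip_sign(self, tmp_path):
        t1, t2 = self._tables(
            tmp_path,
            [_row("rs1", a1="A", a2="G", beta=0.1)],
            [_row("rs1", a1="G", a2="A", beta=0.2)],
        )
        pair = harmonize_pair(t1, t2)
        assert pair.table["beta2"].iloc[0] == pytest.approx(-0.2)
        assert not pair.table["concordant"].iloc[0]

    def test_matching_alleles_unchanged(self, tmp_path):
        t1, t2 = self._tables(
            tmp_path, [_row("rs1", beta=0.1)], [_row("rs1", beta=0.2)]
        )
        pair = harmonize_pair(t1, t2)
        assert pair.table["beta2"].iloc[0] == pytest.approx(0.2)
        assert pair.table["concordant"].iloc[0]

    def test_strand_flip_resolved(self, tmp_path):
        # T/C on the other strand is A/G on this one: keep, same orientation
        t1, t2 = self._tables(
            tmp_path,
            [_row("rs1", a1="A", a2="G", beta=0.1)],
            [_row("rs1", a1="T", a2="C", beta=0.2)],
        )
        pair = harmonize_pair(t1, t2)
        assert pair.table["beta2"].iloc[0] == pytest.approx(0.2)

    def test_palindromic_dropped(self, tmp_path):
        t1, t2 = self._tables(
            tmp_path,
            [_row("rs1", a1="A", a2="T"), _row("rs2", bp=2000)],
            [_row("rs1", a1="A", a2="T"), _row("rs2", bp=2000)],
        )
        pair = harmonize_pair(t1, t2)
        assert pair.table["snp_id"].tolist() == ["rs2"]
        assert pair.provenance["palindromic"] == 1

    def test_mismatched_alleles_dropped(self, tmp_path):
        t1, t2 = self._tables(
            tmp_path,
            [_row("rs1", a1="A", a2="G"), _row("rs2", bp=2000)],
            [_row("rs1", a1="A", a2="C"), _row("rs2", bp=2000)],
        )
        pair = harmonize_pair(t1, t2)
        assert pair.table["snp_id"].tolist() == ["rs2"]
        assert pair.provenance["allele_mismatch"] == 1

    def test_no_shared_variants_is_error(self, tmp_path):
        t1, t2 = self._tables(tmp_path, [_row("rs1")], [_row("rs2")])
        with pytest.raises(ValueError):
            harmonize_pair(t1, t2)

    def test_sign_contract(self, tmp_path):
        rows1 = [_row(f"rs{i}", bp=1000 * i, beta=b)
                 for i, b in enumerate([0.1, -0.2, 0.3, -0.4], start=1)]
        rows2 = [_row(f"rs{i}", bp=1000 * i, beta=b)
                 for i, b in enumerate([0.2, 0.1, -0.3, -0.2], start=1)]
        t1, t2 = self._tables(tmp_path, rows1, rows2)
        pair = harmonize_pair(t1, t2)
        tab = pair.table
        np.testing.assert_array_equal(
            tab["concordant"], (tab["z1"] * tab["z2"]) > 0
        )
        np.testing.assert_array_equal(
            tab["concordant"], (tab["beta1"] * tab["beta2"]) > 0
        )

    def test_idempotent_on_own_output(self, tmp_path):
        rows1 = [_row(f"rs{i}", bp=1000 * i, beta=0.1 * i) for i in range(1, 5)]
        rows2 = [_row(f"rs{i}", bp=1000 * i, a1="G", a2="A", beta=-0.05 * i)
                 for i in range(1, 5)]
        t1, t2 = self._tables(tmp_path, rows1, rows2)
        pair = harmonize_pair(t1, t2)
        # re-split the harmonized pair into two tables and re-harmonize
        from pleioscan.sumstats import SummaryStatTable

        def resplit(which):
            tab = pair.table
            return SummaryStatTable(
                trait_label=f"t{which}",
                table=pd.DataFrame({
                    "snp_id": tab["snp_id"], "chrom": tab["chrom"],
                    "pos": tab["pos"], "a1": tab["a1"], "a2": tab["a2"],
                    "beta": tab[f"beta{which}"], "se": tab[f"se{which}"],
                    "pval": tab[f"p{which}"], "n": tab[f"n{which}"],
                }),
            )

        again = harmonize_pair(resplit(1), resplit(2))
        pd.testing.assert_frame_equal(
            again.table.drop(columns=["masked_region"]),
            pair.table.drop(columns=["masked_region"]),
        )

    def test_p_authoritative_when_beta_truncated(self, tmp_path):
        # beta rounded so hard that beta/se disagrees with p by >10% on z-scale
        t1, t2 = self._tables(
            tmp_path,
            [_row("rs1", beta=0.1, se=0.05, p=2 * stats.norm.sf(4.0))],
            [_row("rs1", beta=0.1, se=0.05, p=2 * stats.norm.sf(2.0))],
        )
        pair = harmonize_pair(t1, t2)
        assert pair.table["z1"].iloc[0] == pytest.approx(4.0)
        assert pair.table["z2"].iloc[0] == pytest.approx(2.0)


class TestMasks:
    @pytest.mark.parametrize(
        "chrom,pos,region",
        [
            (6, 30_000_000, "MHC"),
            (6, 28_477_797, "MHC"),
            (6, 28_477_796, "none"),
            (6, 33_448_354, "MHC"),
            (6, 33_448_355, "none"),
            (17, 44_000_000, "MAPT"),
            (17, 43_384_863, "none"),
            (17, 44_913_631, "MAPT"),
            (1, 30_000_000, "none"),
        ],
    )
    def test_default_mask_containment(self, chrom, pos, region):
        from conftest import make_pair

        pair = make_pair([1.0], [1.0], chrom=[chrom], pos=[pos])
        tagged = tag_masked_regions(pair, default_masks())
        assert tagged.table["masked_region"].iloc[0] == region

    def test_every_tagged_variant_inside_its_interval(self):
        from conftest import make_pair

        rng = np.random.default_rng(0)
        chrom = rng.integers(1, 23, size=200)
        pos = rng.integers(1, 60_000_000, size=200)
        pair = make_pair(np.ones(200), np.ones(200), chrom=chrom, pos=pos)
        tagged = tag_masked_regions(pair, default_masks())
        by_name = {m.name: m for m in default_masks()}
        for _, row in tagged.table.iterrows():
            name = row["masked_region"]
            inside = [m.name for m in default_masks()
                      if m.contains(row["chrom"], row["pos"])]
            if name == "none":
                assert not inside
            else:
                assert by_name[name].contains(row["chrom"], row["pos"])


class TestLDReference:
    def test_single_snp_block_ld_score_one(self):
        ld = LDReference([(1, ["rs1"], np.eye(1))])
        assert ld.ld_score["rs1"] == 1.0

    def test_two_snp_block_ld_score(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        ld = LDReference([(1, ["rs1", "rs2"], R)])
        assert ld.ld_score["rs1"] == pytest.approx(1.25)
        assert ld.ld_score["rs2"] == pytest.approx(1.25)

    def test_cross_block_r2_zero(self):
        ld = LDReference([(1, ["rs1"], np.eye(1)), (2, ["rs2"], np.eye(1))])
        assert ld.r2("rs1", "rs2") == 0.0

    def test_duplicate_snp_across_blocks_errors(self):
        with pytest.raises(ValueError, match="more than one"):
            LDReference([(1, ["rs1"], np.eye(1)), (2, ["rs1"], np.eye(1))])

    def test_r_above_one_errors(self):
        R = np.array([[1.0, 1.5], [1.5, 1.0]])
        with pytest.raises(ValueError, match=r"\|r\| > 1"):
            LDReference([(1, ["rs1", "rs2"], R)])

    def test_round_trip_through_text_format(self, tmp_path):
        R = np.array([[1.0, 0.8, 0.64], [0.8, 1.0, 0.8], [0.64, 0.8, 1.0]])
        ld = LDReference([(3, ["rs1", "rs2", "rs3"], R), (4, ["rs4"], np.eye(1))])
        path = tmp_path / "ld.txt"
        write_ld_reference(ld, path)
        back = load_ld_reference(path)
        assert back.n_snps == 4
        assert back.r2("rs1", "rs2") == pytest.approx(0.64, rel=1e-6)
        assert back.ld_score["rs2"] == pytest.approx(ld.ld_score["rs2"], rel=1e-6)


class TestResultsTable:
    def test_round_trip_preserves_values(self, tmp_path):
        df = pd.DataFrame({"snp_id": ["rs1", "rs2"],
                           "conjfdr": [2.34e-08, 0.123456789]})
        path = tmp_path / "out.tsv"
        write_results_table(df, path)
        back = read_results_table(path)
        np.testing.assert_allclose(back["conjfdr"], df["conjfdr"], rtol=1e-9)
        # scientific notation preserved to >= 3 significant digits
        assert "2.34e-08" in path.read_text()

    def test_empty_records_error(self, tmp_path):
        with pytest.raises(ValueError):
            write_results_table(pd.DataFrame(), tmp_path / "out.tsv")


class TestRegionMaskFile:
    def test_bed_style_conversion(self, tmp_path):
        bed = tmp_path / "m.bed"
        bed.write_text("6\t28477796\t33448354\tMHC\n")
        from pleioscan.sumstats import read_region_masks

        masks = read_region_masks(bed)
        assert masks[0].start == 28_477_797
        assert masks[0].end == 33_448_354

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError):
            RegionMask("x", 1, 10, 5)
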