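"""Summary-statistics I/O and allele harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrscreen.exceptions import ConfigurationError, InputError
from mrscreen.gwas_io import (
    ACTIONS,
    SummaryStats,
    harmonize,
    harmonize_multi,
    is_palindromic,
    read_summary_stats,
    write_summary_stats,
)
from mrscreen.simulate import SimulationConfig, simulate_trio

from conftest import make_stats


class TestReadWrite:
    def test_well_formed_tsv_read(self, tmp_path):
        p = tmp_path / "stats.tsv"
        p.write_text(
            "rsid\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn\n"
            "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.02\t1e-6\t5000\n"
            "rs2\t1\t200\tC\tT\t0.4\t-0.2\t0.03\t1e-8\t5000\n"
            "rs3\t2\t300\tG\tA\t0.5\t0.05\t0.01\t1e-5\t5000\n"
        )
        stats = read_summary_stats(p, trait_name="t")
        assert len(stats) == 3

    def test_invalid_rows_dropped_with_remainder_kept(self, tmp_path):
        p = tmp_path / "stats.tsv"
        p.write_text(
            "rsid\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn\n"
            "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.0\t1e-6\t5000\n"  # se = 0
            "rs2\t1\t200\tC\tT\t0.4\t-0.2\t0.03\t1e-8\t5000\n"
            "rs3\t2\t300\tG\tA\t0.5\t0.05\t0.01\t1e-5\t5000\n"
        )
        stats = read_summary_stats(p, trait_name="t")
        assert len(stats) == 2
        assert "rs1" not in stats.rsids

    def test_column_map_and_missing_column_error(self, tmp_path):
        p = tmp_path / "stats.csv"
        p.write_text("SNP,chr,bp,EA,OA,freq,b,stderr,P\nrs1,1,100,A,G,0.3,0.1,0.02,1e-6\n")
        cmap = {
            "rsid": "SNP", "chrom": "chr", "pos": "bp", "effect_allele": "EA",
            "other_allele": "OA", "eaf": "freq", "beta": "b", "se": "stderr",
            "pvalue": "P",
        }
        stats = read_summary_stats(p, column_map=cmap, trait_name="t")
        assert stats.table.loc[0, "beta"] == 0.1
        with pytest.raises(ConfigurationError, match="beta"):
            read_summary_stats(p, column_map={**cmap, "beta": "missing_col"})

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises(InputError):
            read_summary_stats(p)

    def test_write_empty_errors(self, tmp_path):
        stats = make_stats([("rs1", "1", 1, "A", "G", 0.5, 0.1, 0.01, 1e-6, 100)])
        stats.table = stats.table.iloc[:0]
        with pytest.raises(InputError):
            write_summary_stats(stats, tmp_path / "out.tsv")

    def test_single_record_gives_header_plus_row(self, tmp_path):
        stats = make_stats([("rs1", "1", 1, "A", "G", 0.5, 0.1, 0.01, 1e-6, 100)])
        out = tmp_path / "out.tsv"
        write_summary_stats(stats, out)
        assert len(out.read_text().strip().split("\n")) == 2

    def test_simulated_roundtrip_identity(self, tmp_path):
        exp, _, _, _ = simulate_trio(SimulationConfig(n_snps_causal=25, n_snps_null=25), seed=7)
        out = tmp_path / "rt.tsv"
        write_summary_stats(exp, out)
        back = read_summary_stats(out, trait_name=exp.trait_name,
                                  trait_class=exp.trait_class)
        for col in ("beta", "se", "pvalue", "eaf"):
            np.testing.assert_allclose(
                back.table[col].to_numpy(), exp.table[col].to_numpy(), rtol=0, atol=0
            )
        assert back.rsids == exp.rsids

    def test_gzip_transparent(self, tmp_path):
        exp, _, _, _ = simulate_trio(SimulationConfig(n_snps_causal=10), seed=8)
        out = tmp_path / "rt.tsv.gz"
        write_summary_stats(exp, out)
        back = read_summary_stats(out, trait_name="x", sep="\t")
        assert len(back) == len(exp)

    def test_duplicate_rsids_keep_smallest_p(self):
        stats = make_stats(
            [
                ("rs1", "1", 1, "A", "G", 0.5, 0.1, 0.01, 1e-3, 100),
                ("rs1", "1", 1, "A", "G", 0.5, 0.3, 0.01, 1e-8, 100),
            ]
        )
        assert len(stats) == 1
        assert stats.table.loc[0, "beta"] == 0.3


class TestHarmonize:
    def test_identity_alleles_kept(self, simple_pair):
        hset = harmonize(*simple_pair)
        row = hset.table.set_index("rsid").loc["rs1"]
        assert row["action"] == "kept"
        assert row["beta_outcome"] == 0.2

    def test_swapped_alleles_flip_beta_and_eaf(self, simple_pair):
        hset = harmonize(*simple_pair)
        row = hset.table.set_index("rsid").loc["rs2"]
        assert row["action"] == "flipped"
        assert row["beta_outcome"] == -0.05
        assert row["eaf_outcome"] == pytest.approx(0.4)

    def test_palindromic_always_dropped(self, simple_pair):
        hset = harmonize(*simple_pair)
        acts = hset.table.set_index("rsid")["action"]
        assert acts["rs3"] == "dropped_palindromic"
        assert acts["rs4"] == "dropped_palindromic"

    def test_unmatched_dropped(self, simple_pair):
        hset = harmonize(*simple_pair)
        assert hset.table.set_index("rsid").loc["rs5", "action"] == "dropped_unmatched"

    def test_strand_flip_resolves_compatible_alleles(self):
        exposure = make_stats([("rs1", "1", 1, "A", "G", 0.3, 0.1, 0.01, 1e-8, 1000)])
        outcome = make_stats([("rs1", "1", 1, "T", "C", 0.3, 0.2, 0.02, 1e-3, 1000)])
        hset = harmonize(exposure, outcome)
        assert hset.table.loc[0, "action"] == "kept"
        assert hset.table.loc[0, "beta_outcome"] == 0.2

    def test_incompatible_alleles_dropped(self):
        exposure = make_stats([("rs1", "1", 1, "A", "G", 0.3, 0.1, 0.01, 1e-8, 1000)])
        outcome = make_stats([("rs1", "1", 1, "A", "C", 0.3, 0.2, 0.02, 1e-3, 1000)])
        hset = harmonize(exposure, outcome)
        assert hset.table.loc[0, "action"] == "dropped_incompatible"

    def test_rsids_must_exist_in_exposure(self, simple_pair):
        with pytest.raises(InputError):
            harmonize(*simple_pair, rsids=["rs999"])

    def test_self_harmonization_is_identity(self, simple_pair):
        exposure, _ = simple_pair
        hset = harmonize(exposure, exposure)
        kept = hset.kept
        np.testing.assert_allclose(
            kept["beta_outcome"].to_numpy(), kept["beta_exposure"].to_numpy()
        )
        # palindromic variants are still removed even against self
        assert hset.action_counts()["dropped_palindromic"] == 2

    def test_outcome_allele_swap_invariance(self, simple_pair):
        """Swapping EA/OA and negating beta in the outcome leaves results unchanged."""
        exposure, outcome = simple_pair
        swapped = outcome.table.copy()
        swapped[["effect_allele", "other_allele"]] = swapped[
            ["other_allele", "effect_allele"]
        ].to_numpy()
        swapped["beta"] = -swapped["beta"]
        swapped["eaf"] = 1 - swapped["eaf"]
        outcome2 = SummaryStats("outcome_sw", swapped, "outcome", True)
        h1 = harmonize(exposure, outcome).kept.set_index("rsid")["beta_outcome"]
        h2 = harmonize(exposure, outcome2).kept.set_index("rsid")["beta_outcome"]
        pd.testing.assert_series_equal(h1, h2, check_names=False)

    def test_action_counts_partition_input(self, simple_pair):
        hset = harmonize(*simple_pair)
        assert sum(hset.action_counts().values()) == len(simple_pair[0])
        assert set(hset.table["action"]).issubset(set(ACTIONS))


@given(
    a1=st.sampled_from("ACGT"),
    a2=st.sampled_from("ACGT"),
)
def test_palindromic_iff_complementary(a1, a2):
    assert is_palindromic(a1, a2) == ({a1, a2} in ({"A", "T"}, {"C", "G"}))


def test_harmonize_multi_aligns_onto_reference():
    ref = make_stats(
        [
            ("rs1", "1", 1, "A", "G", 0.3, 0.5, 0.02, 1e-4, 1000),
            ("rs2", "1", 2, "C", "T", 0.4, -0.3, 0.02, 1e-3, 1000),
        ],
        trait_name="ref",
        trait_class="outcome",
    )
    t1 = make_stats(
        [
            ("rs1", "1", 1, "G", "A", 0.7, -0.1, 0.01, 1e-8, 500),  # swapped vs ref
            ("rs2", "1", 2, "C", "T", 0.4, 0.2, 0.01, 1e-8, 500),
        ],
        trait_name="t1",
    )
    mset = harmonize_multi(ref, [t1], ["rs1", "rs2"])
    assert mset.n_snp == 2
    np.testing.assert_allclose(mset.y, [0.5, -0.3])
    np.testing.assert_allclose(mset.table["beta_t1"], [0.1, 0.2])
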