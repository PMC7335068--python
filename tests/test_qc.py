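"""QC filters: panel restriction, sample-size cut, MHC exclusion, clumping."""

import numpy as np
import pandas as pd
import pytest

from polyarch import (
    apply_qc,
    exclude_mhc,
    extract_large_effects,
    filter_low_sample_size,
    read_sumstats,
    restrict_to_panel,
    write_sumstats,
)
from polyarch.io import SumstatsFormatError


def _frame(**cols) -> pd.DataFrame:
    base = {
        "SNP": ["rs1"], "CHR": [1], "BP": [1000], "A1": ["A"], "A2": ["G"],
        "MAF": [0.3], "BETA": [0.01], "SE": [0.01], "N": [1000],
    }
    base.update(cols)
    df = pd.DataFrame(base)
    df["Z"] = df["BETA"] / df["SE"]
    df["P"] = 1.0
    return df


class TestReadSumstats:
    def test_well_formed_file(self, tmp_path):
        path = tmp_path / "ss.tsv"
        write_sumstats(_frame(SNP=["rs1", "rs2", "rs3"], CHR=[1, 1, 2],
                              BP=[1, 2, 3], A1=["A"] * 3, A2=["G"] * 3,
                              MAF=[0.3] * 3, BETA=[0.1, 0.2, 0.3],
                              SE=[0.1] * 3, N=[10] * 3), path)
        assert len(read_sumstats(path)) == 3

    def test_zero_se_row_skipped(self, tmp_path):
        path = tmp_path / "ss.tsv"
        write_sumstats(_frame(SNP=["rs1", "rs2"], CHR=[1, 1], BP=[1, 2],
                              A1=["A"] * 2, A2=["G"] * 2, MAF=[0.3] * 2,
                              BETA=[0.1, 0.2], SE=[0.1, 0.0], N=[10] * 2), path)
        out = read_sumstats(path)
        assert list(out["SNP"]) == ["rs1"]

    def test_or_column_converted_to_log(self, tmp_path):
        path = tmp_path / "ss.tsv"
        pd.DataFrame({
            "SNP": ["rs1"], "CHR": [1], "BP": [1], "A1": ["A"], "A2": ["G"],
            "OR": [1.5], "SE": [0.1],
        }).to_csv(path, sep="\t", index=False)
        out = read_sumstats(path)
        assert out["BETA"].iloc[0] == pytest.approx(np.log(1.5))

    def test_missing_mandatory_column_raises(self, tmp_path):
        path = tmp_path / "ss.tsv"
        pd.DataFrame({"SNP": ["rs1"], "CHR": [1], "BP": [1]}).to_csv(
            path, sep="\t", index=False)
        with pytest.raises(SumstatsFormatError):
            read_sumstats(path)

    def test_dialect_mapping(self, tmp_path):
        path = tmp_path / "ss.tsv"
        pd.DataFrame({
            "rsid": ["rs1"], "CHR": [1], "BP": [1], "A1": ["A"], "A2": ["G"],
            "effect": [0.2], "stderr": [0.1],
        }).to_csv(path, sep="\t", index=False)
        out = read_sumstats(path, dialect={"rsid": "SNP", "effect": "BETA",
                                           "stderr": "SE"})
        assert out["Z"].iloc[0] == pytest.approx(2.0)


class TestPanelRestriction:
    def _panel_df(self):
        return pd.DataFrame({
            "SNP": ["rs1", "rs2", "rs3"],
            "A1": ["A", "C", "T"],
            "A2": ["G", "T", "C"],
            "MAF": [0.3, 0.04, 0.2],
        })

    def test_absent_record_dropped(self):
        records = _frame(SNP=["rs_absent"])
        out = restrict_to_panel(records, self._panel_df())
        assert len(out) == 0

    def test_low_maf_dropped(self):
        records = _frame(SNP=["rs2"], A1=["C"], A2=["T"])
        out = restrict_to_panel(records, self._panel_df())
        assert len(out) == 0  # panel MAF 0.04 <= 0.05

    def test_allele_swap_flips_beta(self):
        records = _frame(SNP=["rs3"], A1=["C"], A2=["T"], BETA=[0.02])
        out = restrict_to_panel(records, self._panel_df())
        assert out["BETA"].iloc[0] == pytest.approx(-0.02)
        assert out["Z"].iloc[0] < 0
        assert (out["A1"].iloc[0], out["A2"].iloc[0]) == ("T", "C")

    def test_allele_mismatch_dropped(self):
        records = _frame(SNP=["rs1"], A1=["A"], A2=["C"])
        assert len(restrict_to_panel(records, self._panel_df())) == 0


class TestSampleSizeFilter:
    def test_all_equal_none_removed(self):
        records = _frame(SNP=[f"rs{i}" for i in range(5)], CHR=[1] * 5,
                         BP=list(range(1, 6)), A1=["A"] * 5, A2=["G"] * 5,
                         MAF=[0.3] * 5, BETA=[0.01] * 5, SE=[0.01] * 5,
                         N=[500] * 5)
        assert len(filter_low_sample_size(records)) == 5

    def test_nearest_rank_cutoff(self):
        # n = {100 x9, 50}: Q90 (nearest rank) = 100, cutoff 67 -> drop n=50
        records = _frame(SNP=[f"rs{i}" for i in range(10)], CHR=[1] * 10,
                         BP=list(range(1, 11)), A1=["A"] * 10, A2=["G"] * 10,
                         MAF=[0.3] * 10, BETA=[0.01] * 10, SE=[0.01] * 10,
                         N=[100] * 9 + [50])
        out = filter_low_sample_size(records)
        assert len(out) == 9
        assert (out["N"] == 100).all()

    def test_boundary_strict_inequality(self):
        # n = {67, 100}: cutoff = 0.67*100 = 67; strict < keeps the 67
        records = _frame(SNP=["rs1", "rs2"], CHR=[1, 1], BP=[1, 2],
                         A1=["A"] * 2, A2=["G"] * 2, MAF=[0.3] * 2,
                         BETA=[0.01] * 2, SE=[0.01] * 2, N=[67, 100])
        assert len(filter_low_sample_size(records)) == 2

    def test_all_missing_is_noop_with_warning(self):
        records = _frame(N=[np.nan])
        with pytest.warns(UserWarning):
            out = filter_low_sample_size(records)
        assert len(out) == 1


class TestMhcExclusion:
    @pytest.mark.parametrize("chrom,bp,kept", [
        (6, 30_000_000, False),
        (6, 26_000_000, False),   # inclusive lower bound
        (6, 34_000_000, False),   # inclusive upper bound
        (6, 25_999_999, True),
        (6, 34_000_001, True),
        (7, 30_000_000, True),
    ])
    def test_boundaries(self, chrom, bp, kept):
        records = _frame(CHR=[chrom], BP=[bp])
        assert (len(exclude_mhc(records)) == 1) is kept


class TestLargeEffectExtraction:
    def _records(self, bps, zs, chrom=1):
        k = len(bps)
        df = pd.DataFrame({
            "SNP": [f"rs{i}" for i in range(k)], "CHR": [chrom] * k,
            "BP": bps, "A1": ["A"] * k, "A2": ["G"] * k, "MAF": [0.3] * k,
            "SE": [0.01] * k, "N": [1000] * k, "P": [1.0] * k,
        })
        df["Z"] = zs
        df["BETA"] = df["Z"] * df["SE"]
        return df

    def test_no_extreme_snps_is_identity(self):
        records = self._records([1, 2_000_000], [3.0, -4.0])
        large, residual = extract_large_effects(records)
        assert len(large) == 0
        pd.testing.assert_frame_equal(residual, records)

    def test_nearby_tops_clumped_to_strongest(self):
        # z^2 = 100 and 90, 0.5 Mb apart: only the larger survives
        records = self._records([1_000_000, 1_500_000], [10.0, np.sqrt(90)])
        large, residual = extract_large_effects(records)
        assert list(large.tops["SNP"]) == ["rs0"]
        assert large.removed_neighbors == ["rs1"]
        assert len(residual) == 0

    def test_greedy_fixture_matches_enumeration_oracle(self):
        # brute-force the greedy procedure on 7 SNPs by hand enumeration
        bps = [1_000_000, 1_600_000, 3_000_000, 4_500_000,
               5_200_000, 9_000_000, 9_100_000]
        zs = [9.5, 10.0, 3.0, 9.1, 2.0, -9.2, 5.0]

        def oracle(bps, zs):
            items = sorted(range(len(bps)), key=lambda i: (-zs[i] ** 2, bps[i]))
            alive, tops = set(range(len(bps))), []
            for i in items:
                if i not in alive or zs[i] ** 2 <= 80:
                    continue
                tops.append(i)
                for j in list(alive):
                    if abs(bps[j] - bps[i]) <= 1_000_000:
                        alive.discard(j)
            return tops, sorted(alive)

        exp_tops, exp_alive = oracle(bps, zs)
        records = self._records(bps, zs)
        large, residual = extract_large_effects(records)
        assert list(large.tops["SNP"]) == [f"rs{i}" for i in exp_tops]
        assert list(residual["SNP"]) == [f"rs{i}" for i in exp_alive]
        assert (residual["Z"] ** 2 <= 80).all()

    def test_equal_z2_tie_breaks_to_smaller_coordinate(self):
        records = self._records([2_500_000, 2_000_000], [9.5, -9.5])
        large, _ = extract_large_effects(records)
        assert list(large.tops["SNP"]) == ["rs1"]
        assert large.removed_neighbors == ["rs0"]

    def test_ld_removal_across_distance(self, ):
        # AR(1) panel: block-mates beyond 1 Mb still removed when r^2 > 0.1
        from polyarch import make_reference_panel
        panel = make_reference_panel(10, n_chromosomes=1, block_size=10,
                                     ld_mode="ar1", rho=0.95, seed=1)
        records = panel.df[["SNP", "CHR", "BP", "A1", "A2", "MAF"]].copy()
        records["SE"] = 0.01
        records["N"] = 1000
        records["P"] = 1.0
        records["Z"] = 1.0
        records.loc[0, "Z"] = 10.0
        records["BETA"] = records["Z"] * records["SE"]
        large, residual = extract_large_effects(records, panel)
        # rho^(2k) > 0.1 up to k = 22 >= block span: whole block clumped
        assert len(large) == 1
        assert len(residual) == 0


class TestPipeline:
    def test_idempotence(self, polygenic_records, small_panel):
        for filt in (filter_low_sample_size, exclude_mhc,
                     lambda r: restrict_to_panel(r, small_panel)):
            once = filt(polygenic_records)
            twice = filt(once)
            pd.testing.assert_frame_equal(once, twice)
        _, residual = extract_large_effects(polygenic_records, small_panel)
        _, residual2 = extract_large_effects(residual, small_panel)
        pd.testing.assert_frame_equal(residual, residual2)

    def test_pipeline_equals_composition(self, polygenic_records, small_panel):
        res = apply_qc(polygenic_records, small_panel)
        step = restrict_to_panel(polygenic_records, small_panel)
        step = filter_low_sample_size(step)
        step = exclude_mhc(step)
        large, residual = extract_large_effects(step, small_panel)
        pd.testing.assert_frame_equal(res.records, residual)
        pd.testing.assert_frame_equal(res.large_effects.tops, large.tops)

    def test_conservation_of_records(self, polygenic_records, small_panel):
        res = apply_qc(polygenic_records, small_panel)
        assert len(polygenic_records) == len(res.records) + len(res.drop_report)
        assert (res.records["Z"] ** 2 <= 80).all()
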