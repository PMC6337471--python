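import numpy as np
import pandas as pd
import pytest

from refstab import (
    CtMatrix,
    EfficiencyTable,
    QpcrValidationError,
    SampleSheet,
    assemble_dataset,
    delta_ct_msd,
    read_ct_table,
    read_efficiencies,
    read_sample_sheet,
    write_ranking_table,
)
from refstab.ct_io import write_ct_table


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadCtTable:
    def test_plain_read(self, tmp_path):
        p = _write(
            tmp_path,
            "ct.csv",
            "gene,L1,L2,L3,L4\nA,20,21,22,23\nB,25,26,27,28\nC,20,22,21,24\n",
        )
        ct = read_ct_table(p)
        assert ct.gene_ids == ["A", "B", "C"]
        assert ct.sample_ids == ["L1", "L2", "L3", "L4"]
        assert ct.ct.loc["B", "L3"] == 27.0

    def test_replicates_collapsed_by_mean(self, tmp_path):
        p = _write(
            tmp_path,
            "ct.csv",
            "gene,L1__r1,L1__r2,L1__r3\nA,20.0,20.2,20.4\n",
        )
        ct = read_ct_table(p, replicate_policy="mean")
        assert ct.sample_ids == ["L1"]
        assert ct.ct.loc["A", "L1"] == pytest.approx(20.2)
        # identical replicates collapse to the replicate value exactly
        p2 = _write(tmp_path, "ct2.csv", "gene,X__r1,X__r2\nA,21.5,21.5\n")
        assert read_ct_table(p2).ct.loc["A", "X"] == 21.5

    def test_replicate_policy_median_and_error(self, tmp_path):
        p = _write(tmp_path, "ct.csv", "gene,L1__r1,L1__r2,L1__r3\nA,20,20.2,23\n")
        assert read_ct_table(p, replicate_policy="median").ct.loc["A", "L1"] == 20.2
        with pytest.raises(QpcrValidationError, match="replicate"):
            read_ct_table(p, replicate_policy="error")

    def test_out_of_range_ct_names_the_cell(self, tmp_path):
        p = _write(tmp_path, "ct.csv", "gene,L1,L2\nA,20,48.0\n")
        with pytest.raises(QpcrValidationError, match=r"'A'.*'L2'"):
            read_ct_table(p)

    def test_non_numeric_names_the_cell(self, tmp_path):
        p = _write(tmp_path, "ct.csv", "gene,L1,L2\nA,20,oops\n")
        with pytest.raises(QpcrValidationError, match="oops"):
            read_ct_table(p)

    def test_missing_value_errors_by_default(self, tmp_path):
        p = _write(tmp_path, "ct.csv", "gene,L1,L2\nA,20,\nB,21,22\n")
        with pytest.raises(QpcrValidationError, match="missing"):
            read_ct_table(p)
        ct = read_ct_table(p, drop_incomplete_samples=True)
        assert ct.sample_ids == ["L1"]

    def test_duplicate_ids_rejected(self, tmp_path):
        p = _write(tmp_path, "ct.csv", "gene,L1,L2\nA,20,21\nA,22,23\n")
        with pytest.raises(QpcrValidationError, match="duplicate gene"):
            read_ct_table(p)
        p2 = _write(tmp_path, "ct2.csv", "gene,L1,L1\nA,20,21\n")
        with pytest.raises(QpcrValidationError, match="duplicate sample"):
            read_ct_table(p2)

    def test_round_trip(self, tmp_path, rng):
        from conftest import random_ct

        ct = random_ct(rng, 6, 8)
        p = tmp_path / "ct.csv"
        write_ct_table(ct, p)
        back = read_ct_table(p)
        np.testing.assert_allclose(back.values, ct.values, atol=1e-9)
        assert back.gene_ids == ct.gene_ids and back.sample_ids == ct.sample_ids


class TestSampleSheet:
    def test_groups_in_order_of_appearance(self, tmp_path):
        p = _write(
            tmp_path,
            "samples.csv",
            "sample_id,group,is_control\ns1,control,true\ns2,treat,false\n"
            "s3,control,true\ns4,treat,false\n",
        )
        sheet = read_sample_sheet(p)
        assert sheet.groups == ["control", "treat"]
        assert sheet.control_group == "control"
        assert sheet.samples_in("treat") == ["s2", "s4"]

    def test_two_control_groups_rejected(self, tmp_path):
        p = _write(
            tmp_path,
            "samples.csv",
            "sample_id,group,is_control\ns1,a,true\ns2,b,true\n",
        )
        with pytest.raises(QpcrValidationError, match="control group"):
            read_sample_sheet(p)

    def test_cross_validation_at_assembly(self, toy_ct):
        sheet = SampleSheet(
            pd.DataFrame(
                {
                    "sample_id": ["s1", "s2", "s3"],
                    "group": ["g"] * 3,
                    "is_control": [False] * 3,
                }
            )
        )
        with pytest.raises(QpcrValidationError, match="absent from sample sheet"):
            assemble_dataset(toy_ct, sheet)


class TestEfficiencies:
    def test_read_with_defaults(self, tmp_path):
        p = _write(tmp_path, "eff.csv", "gene,E\nAP-2,2.1419\n")
        eff = read_efficiencies(p, genes=["AP-2", "ACT2"])
        assert eff.for_gene("AP-2") == pytest.approx(2.1419)
        assert eff.for_gene("ACT2") == 2.0  # defaulting rule

    def test_absent_file_all_default(self):
        eff = read_efficiencies(None, genes=["X", "Y"])
        assert list(eff.for_genes(["X", "Y"])) == [2.0, 2.0]

    @pytest.mark.parametrize("bad", [0.9, 1.0, 2.5])
    def test_out_of_range_rejected(self, tmp_path, bad):
        p = _write(tmp_path, "eff.csv", f"gene,E\nX,{bad}\n")
        with pytest.raises(QpcrValidationError):
            read_efficiencies(p)


class TestWriteRankingTable:
    def test_single_and_double(self, tmp_path, toy_ct):
        from refstab import bestkeeper

        r = delta_ct_msd(toy_ct)
        p = tmp_path / "rank.csv"
        write_ranking_table(r, p)
        df = pd.read_csv(p)
        assert list(df.columns) == ["rank", "delta_ct_gene", "delta_ct_mSD"]
        assert df.shape[0] == 3 and df["rank"].iloc[0] == 1

        write_ranking_table([r, bestkeeper(toy_ct).ranking], p)
        assert pd.read_csv(p).shape[1] == 5

    def test_mismatched_universes_rejected(self, tmp_path, toy_ct):
        r = delta_ct_msd(toy_ct)
        other = delta_ct_msd(toy_ct.subset_genes(["A", "B"]))
        with pytest.raises(QpcrValidationError, match="universe"):
            write_ranking_table([r, other], tmp_path / "x.csv")
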