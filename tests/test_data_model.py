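import numpy as np
import pandas as pd
import pytest

from poolmark import (
    DataError,
    ParseError,
    ProbeAnnotation,
    ProbeMatrix,
    build_collection,
    gene_center,
    load_collection,
    read_clinical_table,
    read_expression_matrix,
    read_gene_matrix,
    validate_dataset,
    write_clinical_table,
    write_gene_matrix,
)
from conftest import make_bundle


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestExpressionReader:
    def test_shape_and_ids(self, tmp_path):
        p = _write(
            tmp_path, "e.tsv",
            "probe_id\ts1\ts2\nA_01\t1.5\t2.5\nA_02\tNA\t3.0\nA_03\t0\t-1.25\n",
        )
        pm = read_expression_matrix(p, "d1")
        assert pm.data.shape == (3, 2)
        assert pm.probe_ids == ["A_01", "A_02", "A_03"]
        assert np.isnan(pm.data.loc["A_02", "s1"])

    def test_duplicate_probe_rejected(self, tmp_path):
        p = _write(tmp_path, "e.tsv", "probe_id\ts1\nA_01\t1\nA_01\t2\n")
        with pytest.raises(ParseError, match="A_01"):
            read_expression_matrix(p, "d1")

    def test_empty_file_rejected(self, tmp_path):
        p = _write(tmp_path, "e.tsv", "probe_id\ts1\n")
        with pytest.raises(ParseError, match="no probe"):
            read_expression_matrix(p, "d1")

    def test_non_numeric_cell_named(self, tmp_path):
        p = _write(tmp_path, "e.tsv", "probe_id\ts1\ts2\nA_01\t1.5\toops\n")
        with pytest.raises(ParseError, match="A_01.*s2"):
            read_expression_matrix(p, "d1")


class TestClinicalReader:
    def test_endpoint_presence_and_synonyms(self, tmp_path):
        p = _write(
            tmp_path, "c.tsv",
            "sample_id\ter_status\tdfs_time\tdfs_event\n"
            "s1\tpositive\t60\t1\ns2\t0\t24\tcensored\n",
        )
        ct = read_clinical_table(p)
        assert ct.data.loc["s1", "er_status"] == "pos"
        assert ct.data.loc["s2", "er_status"] == "neg"
        assert ct.endpoint_available("dfs").tolist() == [True, True]
        assert ct.data.loc["s2", "dfs_event"] == 0.0

    def test_half_pair_coerced_to_missing(self, tmp_path, caplog):
        p = _write(
            tmp_path, "c.tsv",
            "sample_id\tdfs_time\tdfs_event\ns1\t\t1\n",
        )
        with caplog.at_level("WARNING"):
            ct = read_clinical_table(p)
        assert not ct.endpoint_available("dfs").any()
        assert "half-pair" in caplog.text

    def test_out_of_range_grade_warns(self, tmp_path, caplog):
        p = _write(tmp_path, "c.tsv", "sample_id\tgrade\ns1\t4\ns2\t2\n")
        with caplog.at_level("WARNING"):
            ct = read_clinical_table(p)
        assert np.isnan(ct.data.loc["s1", "grade"])
        assert ct.data.loc["s2", "grade"] == 2.0
        assert "grade" in caplog.text

    def test_missing_sample_id_column(self, tmp_path):
        p = _write(tmp_path, "c.tsv", "id\tgrade\ns1\t2\n")
        with pytest.raises(ParseError, match="sample_id"):
            read_clinical_table(p)


class TestGeneCenter:
    def test_multi_gene_probe_dropped_and_means(self):
        pm = ProbeMatrix(
            "d1",
            pd.DataFrame(
                {"s1": [2.0, 4.0, 9.0], "s2": [4.0, 6.0, 9.0]},
                index=["A", "B", "C"],
            ),
        )
        ann = ProbeAnnotation(
            {"A": frozenset({"g1"}), "B": frozenset({"g1"}), "C": frozenset({"g1", "g2"})}
        )
        gm = gene_center(pm, ann)
        assert gm.gene_ids == ["g1"]  # C discarded, g2 absent
        assert gm.data.loc["g1"].tolist() == [3.0, 5.0]

    def test_single_probe_identity(self):
        pm = ProbeMatrix("d1", pd.DataFrame({"s1": [1.25], "s2": [7.5]}, index=["A"]))
        gm = gene_center(pm, ProbeAnnotation({"A": frozenset({"g1"})}))
        assert gm.data.loc["g1"].tolist() == [1.25, 7.5]

    def test_mean_skips_missing(self):
        pm = ProbeMatrix(
            "d1",
            pd.DataFrame({"s1": [2.0, 4.0], "s2": [np.nan, 6.0]}, index=["A", "B"]),
        )
        ann = ProbeAnnotation({"A": frozenset({"g1"}), "B": frozenset({"g1"})})
        gm = gene_center(pm, ann)
        assert gm.data.loc["g1"].tolist() == [3.0, 6.0]

    def test_no_mappable_probes(self):
        pm = ProbeMatrix("d1", pd.DataFrame({"s1": [1.0]}, index=["A"]))
        with pytest.raises(DataError, match="no mappable probes"):
            gene_center(pm, ProbeAnnotation({"Z": frozenset({"g1"})}))

    def test_idempotent_under_identity_annotation(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(rng.normal(size=(4, 3)), index=list("abcd"), columns=["s1", "s2", "s3"])
        gm = gene_center(
            ProbeMatrix("d1", data),
            ProbeAnnotation({g: frozenset({g}) for g in data.index}),
        )
        pd.testing.assert_frame_equal(gm.data, data)

    def test_gene_values_within_probe_range(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(rng.normal(size=(6, 4)), index=[f"p{i}" for i in range(6)],
                            columns=[f"s{i}" for i in range(4)])
        ann = ProbeAnnotation({f"p{i}": frozenset({"g1" if i < 4 else "g2"}) for i in range(6)})
        gm = gene_center(ProbeMatrix("d1", data), ann)
        for gene, probes in [("g1", data.iloc[:4]), ("g2", data.iloc[4:])]:
            assert (gm.data.loc[gene] >= probes.min(axis=0) - 1e-12).all()
            assert (gm.data.loc[gene] <= probes.max(axis=0) + 1e-12).all()


class TestValidationAndCollection:
    @pytest.mark.parametrize("n,expected", [(48, True), (47, False)])
    def test_inclusion_boundary(self, n, expected):
        b = make_bundle(
            "d1", ["gA"], {"gA": list(map(float, range(n)))},
            dfs_time=[10.0] * n, dfs_event=[1.0] * n,
        )
        assert validate_dataset(b).passes_inclusion is expected

    def test_no_survival_information(self):
        b = make_bundle("d1", ["gA"], {"gA": [1.0] * 100})
        report = validate_dataset(b)
        assert not report.passes_inclusion
        assert any("no survival" in m for m in report.messages)

    def test_universe_is_union(self, simple_collection):
        assert simple_collection.gene_universe == {"gA", "gB", "gC"}

    def test_duplicate_dataset_id_rejected(self, simple_bundle):
        with pytest.raises(DataError, match="duplicate dataset"):
            build_collection([simple_bundle, simple_bundle])

    def test_enforce_inclusion_drops_small_cohorts(self, simple_bundle):
        big = make_bundle(
            "big", ["gA"], {"gA": list(map(float, range(60)))},
            dfs_time=[5.0] * 60, dfs_event=[1.0] * 60,
        )
        coll = build_collection([simple_bundle, big], enforce_inclusion=True)
        assert coll.dataset_ids == ["big"]


class TestRoundTrip:
    def test_matrix_and_clinical_roundtrip(self, tmp_path, simple_bundle):
        ep = tmp_path / "expr.tsv"
        cp = tmp_path / "clin.tsv"
        write_gene_matrix(simple_bundle.gene_matrix, ep)
        write_clinical_table(simple_bundle.clinical, cp)
        gm = read_gene_matrix(ep, "d1")
        ct = read_clinical_table(cp)
        pd.testing.assert_frame_equal(gm.data, simple_bundle.gene_matrix.data)
        # values and orderings must round-trip exactly; storage dtype of
        # all-missing categorical columns may differ
        pd.testing.assert_frame_equal(ct.data, simple_bundle.clinical.data, check_dtype=False)

    def test_manifest_loading(self, tmp_path, simple_bundle):
        write_gene_matrix(simple_bundle.gene_matrix, tmp_path / "e.tsv")
        write_clinical_table(simple_bundle.clinical, tmp_path / "c.tsv")
        (tmp_path / "manifest.yaml").write_text(
            "datasets:\n- id: d1\n  expression: e.tsv\n  clinical: c.tsv\n"
        )
        coll = load_collection(tmp_path / "manifest.yaml")
        assert coll.dataset_ids == ["d1"]
        pd.testing.assert_frame_equal(
            coll["d1"].gene_matrix.data, simple_bundle.gene_matrix.data
        )
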