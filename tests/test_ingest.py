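import numpy as np
import pytest

from omiclink import ingest
from omiclink.datamodel import ClinicalTable, ClinicalVariable


def write(tmp_path, name, lines):
    p = tmp_path / name
    p.write_text("\n".join(lines) + "\n")
    return p


class TestExpression:
    def test_toy_file_preserves_order(self, tmp_path):
        p = write(tmp_path, "e.tsv", ["gene\ts1\ts2", "g1\t1.5\t2", "g2\t0\t-1",
                                      "g3\t3\t4"])
        m = ingest.read_expression(p, ingest.ExpressionColumns("gene", ["s1", "s2"]))
        assert m.shape == (3, 2) and m.row_ids == ["g1", "g2", "g3"]
        assert m.values[0, 1] == 2.0

    def test_na_cell_becomes_missing(self, tmp_path):
        p = write(tmp_path, "e.tsv", ["gene\ts1\ts2", "g1\tNA\t2"])
        m = ingest.read_expression(p, ingest.ExpressionColumns("gene", ["s1", "s2"]))
        assert int(np.isnan(m.values).sum()) == 1

    def test_absent_column_named_in_error(self, tmp_path):
        p = write(tmp_path, "e.tsv", ["gene\ts1", "g1\t1"])
        with pytest.raises(ValueError, match="foo"):
            ingest.read_expression(p, ingest.ExpressionColumns("gene", ["foo"]))

    def test_duplicate_gene_ids_rejected(self, tmp_path):
        p = write(tmp_path, "e.tsv", ["gene\ts1", "g1\t1", "g1\t2"])
        with pytest.raises(ValueError, match="duplicate"):
            ingest.read_expression(p, ingest.ExpressionColumns("gene", ["s1"]))


class TestStates:
    def test_default_tokens(self, tmp_path):
        p = write(tmp_path, "s.tsv", ["m\ts1\ts2", "m1\t-1\t1", "m2\t0\t0"])
        s = ingest.read_states(p, ingest.StateColumns("m", ["s1", "s2"]))
        assert s.values.tolist() == [[-1.0, 1.0], [0.0, 0.0]]

    def test_configurable_word_encoding(self, tmp_path):
        p = write(tmp_path, "s.tsv", ["m\ts1", "m1\tloss", "m2\tgain", "m3\tnormal"])
        enc = {"loss": -1.0, "normal": 0.0, "gain": 1.0}
        s = ingest.read_states(p, ingest.StateColumns("m", ["s1"], encoding=enc))
        assert s.values.ravel().tolist() == [-1.0, 1.0, 0.0]

    def test_unmapped_token_is_error(self, tmp_path):
        p = write(tmp_path, "s.tsv", ["m\ts1", "m1\t2"])
        with pytest.raises(ValueError, match="outside encoding"):
            ingest.read_states(p, ingest.StateColumns("m", ["s1"]))


class TestFeatures:
    def test_interval_and_point(self, tmp_path):
        p = write(tmp_path, "f.tsv", ["id\tchrom\tstart\tend",
                                      "g1\tchr8\t100\t200"])
        feats = ingest.read_features(
            p, ingest.FeatureColumns("id", "chrom", "start", "end"))
        assert feats[0].chromosome == "8" and (feats[0].start, feats[0].end) == (100, 200)
        q = write(tmp_path, "p.tsv", ["id\tchrom\tpos", "snp1\tX\t500"])
        pts = ingest.read_features(q, ingest.FeatureColumns("id", "chrom", "pos"))
        assert pts[0].is_point and pts[0].end == 500

    def test_inverted_interval_rejected(self, tmp_path):
        p = write(tmp_path, "f.tsv", ["id\tchrom\tstart\tend", "g1\t8\t300\t200"])
        with pytest.raises(ValueError, match="start"):
            ingest.read_features(p, ingest.FeatureColumns("id", "chrom", "start", "end"))


class TestClinical:
    def test_event_and_censoring_parsed(self, tmp_path):
        p = write(tmp_path, "c.tsv", ["sample\tt\tst\tfab",
                                      "s1\t12.0\t1\tM1", "s2\t30.0\t0\tM2",
                                      "s3\t5.5\t1\tM4"])
        t = ingest.read_clinical(p, ingest.ClinicalTypes(
            "sample", {"os": ("time_to_event", "t", "st"), "fab": "categorical"}))
        os = t["os"]
        assert os.values[0] == 12.0 and bool(os.event[0]) is True
        assert os.values[1] == 30.0 and bool(os.event[1]) is False
        assert t["fab"].levels() == ["M1", "M2", "M4"]

    def test_unparseable_status_token(self, tmp_path):
        p = write(tmp_path, "c.tsv", ["sample\tt\tst", "s1\t1.0\tmaybe"])
        with pytest.raises(ValueError, match="status token"):
            ingest.read_clinical(p, ingest.ClinicalTypes(
                "sample", {"os": ("time_to_event", "t", "st")}))

    def test_unknown_type_tag_rejected(self, tmp_path):
        p = write(tmp_path, "c.tsv", ["sample\tx", "s1\t1"])
        with pytest.raises(ValueError, match="type tag"):
            ingest.read_clinical(p, ingest.ClinicalTypes("sample", {"x": "fancy"}))


class TestRoundTrip:
    """Write → read is the identity for every table kind (tolerance 1e-9)."""

    def test_expression(self, tmp_path, study):
        path = tmp_path / "e.tsv"
        ingest.write_expression(study.expression, path)
        back = ingest.read_expression(path, ingest.ExpressionColumns(
            "gene_id", study.expression.col_ids))
        assert back.row_ids == study.expression.row_ids
        np.testing.assert_allclose(back.values, study.expression.values, atol=1e-9)

    def test_states(self, tmp_path, study):
        path = tmp_path / "s.tsv"
        ingest.write_states(study.states, path)
        back = ingest.read_states(path, ingest.StateColumns(
            "marker_id", study.states.col_ids))
        np.testing.assert_array_equal(back.values, study.states.values)

    def test_features(self, tmp_path, study):
        path = tmp_path / "f.tsv"
        ingest.write_features(study.gene_features, path)
        back = ingest.read_features(path, ingest.FeatureColumns(
            "id", "chromosome", "start", "end"))
        assert back == study.gene_features

    def test_clinical(self, tmp_path, study):
        path = tmp_path / "c.tsv"
        ingest.write_clinical(study.clinical, path)
        back = ingest.read_clinical(path, ingest.clinical_typemap(study.clinical))
        assert back.sample_ids == study.clinical.sample_ids
        for name, var in study.clinical.variables.items():
            got = back[name]
            assert got.kind == var.kind
            if var.kind == "categorical":
                assert got.values.tolist() == var.values.tolist()
            else:
                np.testing.assert_allclose(got.values.astype(float),
                                           var.values.astype(float), atol=1e-9)
            if var.kind == "time_to_event":
                np.testing.assert_array_equal(got.event, var.event)


def test_config_roundtrip(tmp_path):
    cfg = {"expression.id_column": "gene", "clinical.types": "a:categorical,b:continuous"}
    p = tmp_path / "cfg.txt"
    ingest.write_config(cfg, p)
    assert ingest.read_config(p) == cfg
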