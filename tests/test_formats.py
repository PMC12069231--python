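"""Reading and writing feature tables, MS2 files, rule tables and networks."""

import numpy as np
import pandas as pd
import pytest

from featlink import (
    AnnotatedFeatureTable,
    AnnotationEdge,
    FormatError,
    ValidationError,
    read_feature_table,
    read_ms2,
    read_rule_tables,
    write_annotated_table,
    write_network,
)

from conftest import make_table, write_mzml


def test_read_basic_csv(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text(
        "feature,mz,rt,sampleA,sampleB\n"
        "F1,181.0707,120.5,100,200\n"
        "F2,203.0526,121.0,50,80\n"
        "F3,435.1291,200.0,10,20\n"
    )
    t = read_feature_table(p)
    assert len(t) == 3 and t.sample_names == ["sampleA", "sampleB"]
    assert t.get("F2").mz == pytest.approx(203.0526)
    assert t.get("F1").rt == pytest.approx(120.5)


def test_tsv_delimiter_sniffed(tmp_path):
    p = tmp_path / "t.tsv"
    p.write_text("feature\tmz\trt\ts1\nF1\t100.0\t120\t5\n")
    assert len(read_feature_table(p)) == 1


def test_mzmine_dialect_converts_minutes(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("row ID,row m/z,row retention time,s1,s2\n1,100.0,2.5,5,6\n")
    t = read_feature_table(p, dialect="mzmine")
    assert t.features[0].rt == pytest.approx(150.0)


def test_auto_dialect_minute_heuristic_warns(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("feature,mz,rt,s1,s2\nF1,100.0,2.5,5,6\n")
    with pytest.warns(UserWarning, match="minutes"):
        t = read_feature_table(p, dialect="auto")
    assert t.features[0].rt == pytest.approx(150.0)
    p2 = tmp_path / "t2.csv"
    p2.write_text("feature,mz,rt,s1,s2\nF1,100.0,250.0,5,6\n")
    assert read_feature_table(p2).features[0].rt == pytest.approx(250.0)


def test_duplicate_ids_rejected(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("feature,mz,rt,s1\nF1,100.0,10,5\nF1,200.0,20,6\n")
    with pytest.raises(ValidationError, match="F1"):
        read_feature_table(p)


def test_missing_mz_column(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("feature,rt,s1\nF1,10,5\n")
    with pytest.raises(FormatError, match="m/z"):
        read_feature_table(p)


def test_non_numeric_mz_names_row(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("feature,mz,rt,s1\nF1,100.0,10,5\nF2,oops,20,6\n")
    with pytest.raises(FormatError, match="1"):
        read_feature_table(p)


def test_no_rows_silently_dropped(tmp_path):
    p = tmp_path / "t.csv"
    rows = "\n".join(f"F{i},{100 + i}.0,{i},1,{i}" for i in range(25))
    p.write_text("feature,mz,rt,s1,s2\n" + rows + "\n")
    assert len(read_feature_table(p)) == 25


def test_missing_id_column_synthesized(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("mz,rt,s1\n100.0,10,5\n200.0,20,6\n")
    assert read_feature_table(p).ids == ["F1", "F2"]


def test_bundled_rule_tables_cover_required_species():
    rules, losses = read_rule_tables()
    names = {r.name for r in rules}
    assert {
        "[M+H]+", "[M+Na]+", "[M+K]+", "[M+NH4]+", "[2M+H]+", "[2M+Na]+",
        "[M+2H]2+", "[M+H-H2O]+", "[M-H]-", "[M+Cl]-", "[M+HCOO]-", "[2M-H]-",
        "[M-2H]2-",
    } <= names
    by_name = {e.name: e for e in losses}
    assert by_name["H2O"].mass == pytest.approx(18.010565, abs=1e-5)
    assert by_name["anhydrohexose"].mass == pytest.approx(162.052824, abs=1e-5)
    assert {"NH3", "CO", "CO2", "HCOOH", "CH2O", "C2H4O2"} <= set(by_name)


def test_custom_rule_tables(tmp_path):
    ap = tmp_path / "a.csv"
    ap.write_text(
        "name,ion_mode,multiplicity,charge,mass_shift\n"
        "[M+H]+,positive,1,1,1.007276\n[M+Na]+,positive,1,1,22.989218\n"
    )
    rules, losses = read_rule_tables(adduct_path=ap)
    assert [r.name for r in rules] == ["[M+H]+", "[M+Na]+"]
    assert losses  # bundled NL fallback still loads


def test_negative_neutral_loss_mass_rejected(tmp_path):
    np_ = tmp_path / "n.csv"
    np_.write_text("name,formula,mass\nbogus,H2O,-5\n")
    with pytest.raises(ValidationError):
        read_rule_tables(nl_path=np_)


def test_read_mgf(tmp_path):
    p = tmp_path / "t.mgf"
    p.write_text(
        "BEGIN IONS\nTITLE=a\nPEPMASS=435.1291\nRTINSECONDS=120.0\n"
        "80.25 20\n50.5 10\nEND IONS\n"
        "BEGIN IONS\nTITLE=b\nPEPMASS=181.0707\n60.0 5\nEND IONS\n"
    )
    specs = read_ms2(p)
    assert len(specs) == 2
    assert specs[0].precursor_rt == pytest.approx(120.0)
    # peaks sorted ascending after load
    assert specs[0].peaks[:, 0].tolist() == [50.5, 80.25]
    assert specs[1].precursor_rt is None


def test_read_mzml_filters_ms1(tmp_path):
    p = tmp_path / "t.mzml"
    write_mzml(
        p,
        [{"ms_level": 1, "mz_array": [100.0 + i], "intensity_array": [1.0], "rt_seconds": 10.0 * i}
         for i in range(5)]
        + [{"ms_level": 2, "mz_array": [50.0, 60.0], "intensity_array": [1.0, 2.0],
            "precursor_mz": 200.0 + i, "rt_seconds": 100.0 + i} for i in range(3)],
    )
    specs = read_ms2(p)
    assert len(specs) == 3
    assert specs[0].precursor_mz == pytest.approx(200.0)
    assert specs[0].precursor_rt == pytest.approx(100.0)


def test_mzml_mgf_equivalence(tmp_path):
    """The same spectra stored as mzML and MGF load identically."""
    content = [
        {"precursor_mz": 435.1291, "rt": 120.0, "mz": [50.5, 80.25, 273.0763],
         "inten": [10.0, 20.0, 900.0]},
        {"precursor_mz": 181.0707, "rt": 60.0, "mz": [89.0, 163.06], "inten": [5.0, 50.0]},
    ]
    mgf_text = []
    for s in content:
        peaks = "\n".join(f"{m} {i}" for m, i in zip(s["mz"], s["inten"]))
        mgf_text.append(
            f"BEGIN IONS\nPEPMASS={s['precursor_mz']}\nRTINSECONDS={s['rt']}\n{peaks}\nEND IONS"
        )
    (tmp_path / "t.mgf").write_text("\n".join(mgf_text) + "\n")
    write_mzml(
        tmp_path / "t.mzml",
        [{"ms_level": 2, "mz_array": s["mz"], "intensity_array": s["inten"],
          "precursor_mz": s["precursor_mz"], "rt_seconds": s["rt"]} for s in content],
    )
    a = read_ms2(tmp_path / "t.mgf")
    b = read_ms2(tmp_path / "t.mzml")
    key = lambda specs: sorted((round(s.precursor_mz, 6), len(s.peaks)) for s in specs)
    assert key(a) == key(b)


def test_empty_ms2_warns(tmp_path):
    p = tmp_path / "t.mgf"
    p.write_text("")
    with pytest.warns(UserWarning, match="no MS2"):
        assert read_ms2(p) == []


def test_annotated_table_round_trip(tmp_path):
    table = make_table(
        [("a", 181.0707123, 120.0, (1.0, 2.0, 3.0)),
         ("b", 203.0526456, 121.0, (4.0, 0.0, 6.0)),
         ("c", 435.1291789, 200.0, (7.0, 8.0, np.nan))]
    )
    ann = pd.DataFrame(
        {"isotope": ["", "[M+1] of a", ""], "group": ["1", "1", ""]},
        index=["a", "b", "c"],
    )
    at = AnnotatedFeatureTable(table=table, annotations=ann)
    out = tmp_path / "annotated.csv"
    write_annotated_table(at, out)
    df = pd.read_csv(out)
    assert list(df["feature"]) == ["a", "b", "c"]
    assert df["mz"].tolist() == pytest.approx([181.0707123, 203.0526456, 435.1291789])
    assert df.loc[1, "s2"] == 0.0  # zeros preserved on write
    # absent annotations are empty, never a literal "NA"
    assert df["adduct"].isna().all()
    back = read_feature_table(out)
    assert back.mz_array().tolist() == pytest.approx(table.mz_array().tolist())
    assert [int(g) for g in df["group"][:2]] == [1, 1]


def test_write_network_edgelist(tmp_path):
    edges = [
        AnnotationEdge("a", "b", "isotope", "[M+1]", 1.0034, 0.5),
        AnnotationEdge("a", "c", "neutral_loss", "H2O", -18.0106, 0.1, correlation=0.93),
    ]
    p = tmp_path / "edges.csv"
    write_network(edges, p)
    df = pd.read_csv(p)
    assert list(df.columns) == ["source", "target", "relation", "detail", "mz_diff", "correlation"]
    assert len(df) == 2
    assert df.loc[0, "relation"] == "isotope" and df.loc[0, "detail"] == "[M+1]"
    write_network([], tmp_path / "empty.csv")
    assert len(pd.read_csv(tmp_path / "empty.csv")) == 0


def test_write_network_graphml(tmp_path):
    import networkx as nx

    edges = [AnnotationEdge("a", "b", "adduct_sibling", "[M+Na]+ of glc", 21.98)]
    p = tmp_path / "net.graphml"
    write_network(edges, p, format="graphml")
    g = nx.read_graphml(p)
    assert set(g.nodes) == {"a", "b"}
    with pytest.raises(ValueError, match="format"):
        write_network(edges, tmp_path / "x", format="dot")
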