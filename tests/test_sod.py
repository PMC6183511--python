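"""SOD file format: layout, round-trips, validation, session bridge."""

import pytest

from raricount import (
    CountSession,
    SODDocument,
    SODFormatError,
    SODValidationError,
    TaxonConfig,
    combined_estimates,
    estimates_from_sod,
    load_definitions,
    read_sod,
    session_to_sod,
    sod_to_long,
    validate_sod,
    write_sod,
)


def minimal_o_doc(n_samples=1, n_taxa=3):
    names = [f"751A-6H-{i + 1}" for i in range(n_samples)]
    return SODDocument(
        file_metadata={
            "SOD version": "1",
            "File type": "O",
            "Fossil group": "radiolarians",
            "Observer": "tester",
            "Site": "751",
            "Hole": "A",
        },
        sample_metadata={
            "Sample": names,
            "Core": ["6H"] * n_samples,
            "Section": [str(i + 1) for i in range(n_samples)],
            "Interval (cm)": ["98-100"] * n_samples,
        },
        taxa_fields=["Genus", "Species", "Author", "Excluded"],
        taxa=[
            {"Genus": "Taxon", "Species": f"sp{r}", "Author": "", "Excluded": "no"}
            for r in range(n_taxa)
        ],
        occurrences=[[10 * r + c for c in range(n_samples)] for r in range(n_taxa)],
    )


class TestWriteRead:
    def test_minimal_grid_shape(self, tmp_path):
        p = tmp_path / "x.sod"
        write_sod(minimal_o_doc(), p)
        lines = p.read_text(encoding="utf-8").splitlines()
        header = [l for l in lines if l.startswith("Genus")]
        assert len(header) == 1
        taxa_rows = lines[lines.index(header[0]) + 1 :]
        assert len(taxa_rows) == 3
        assert all(len(r.split("\t")) == 6 for r in taxa_rows)  # 4 C cols + label + 1 sample

    def test_round_trip_equality(self, tmp_path):
        p = tmp_path / "x.sod"
        doc = minimal_o_doc(n_samples=3, n_taxa=5)
        write_sod(doc, p)
        assert read_sod(p) == doc

    def test_round_trip_bytes_stable(self, tmp_path):
        p1, p2 = tmp_path / "a.sod", tmp_path / "b.sod"
        doc = minimal_o_doc(n_samples=2, n_taxa=4)
        write_sod(doc, p1)
        write_sod(read_sod(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_version_refused(self, tmp_path):
        doc = minimal_o_doc()
        del doc.file_metadata["SOD version"]
        with pytest.raises(SODValidationError):
            write_sod(doc, tmp_path / "x.sod")

    def test_multi_sample_columns_repeat(self, tmp_path):
        p = tmp_path / "x.sod"
        write_sod(minimal_o_doc(n_samples=4), p)
        doc = read_sod(p)
        assert doc.n_samples == 4
        assert doc.sample_names == [f"751A-6H-{i}" for i in range(1, 5)]

    def test_self_description_every_value_labelled(self, tmp_path):
        # Every file/sample metadata value sits next to a ':'-terminated
        # label; every count is addressed by its taxon row and sample column.
        p = tmp_path / "x.sod"
        write_sod(minimal_o_doc(n_samples=2), p)
        rows = [l.split("\t") for l in p.read_text(encoding="utf-8").splitlines()]
        header_idx = next(i for i, r in enumerate(rows) if r[0] == "Genus")
        label_col = rows[header_idx].index("Counts:")
        for r in rows[:header_idx]:
            if len(r) > 1 and r[1]:
                assert r[0].endswith(":")
            for j, cell in enumerate(r[label_col + 1 :]):
                if cell:
                    assert r[label_col].endswith(":")
        for r in rows[header_idx + 1 :]:
            assert r[0] and r[1]  # genus + species label the count row

    def test_unknown_version_rejected(self, tmp_path):
        p = tmp_path / "x.sod"
        doc = minimal_o_doc()
        write_sod(doc, p)
        text = p.read_text(encoding="utf-8").replace("SOD version:\t1", "SOD version:\t99")
        p.write_text(text, encoding="utf-8")
        with pytest.raises(SODFormatError, match="99"):
            read_sod(p)

    def test_shuffled_label_names_offending_cell(self, tmp_path):
        p = tmp_path / "x.sod"
        write_sod(minimal_o_doc(), p)
        text = p.read_text(encoding="utf-8").replace("Site:", "Site")  # drop the colon
        p.write_text(text, encoding="utf-8")
        with pytest.raises(SODFormatError, match=r"row 5 col 1"):
            read_sod(p)

    def test_ragged_count_block_rejected(self, tmp_path):
        p = tmp_path / "x.sod"
        write_sod(minimal_o_doc(), p)
        lines = p.read_text(encoding="utf-8").splitlines()
        lines[-1] = lines[-1].rsplit("\t", 1)[0] + "\tnot_a_number"
        p.write_text("\n".join(lines) + "\n", encoding="utf-8")
        with pytest.raises(SODFormatError, match="not an integer"):
            read_sod(p)


class TestValidate:
    def test_valid_doc_no_findings(self):
        assert validate_sod(minimal_o_doc()) == []

    def test_negative_count_is_error(self):
        doc = minimal_o_doc()
        doc.occurrences[0][0] = -1
        assert any(f.level == "error" and "nonnegative" in f.message for f in validate_sod(doc))

    def test_unknown_optional_label_is_warning(self):
        doc = minimal_o_doc()
        doc.file_metadata["Vessel"] = "JOIDES Resolution"
        findings = validate_sod(doc)
        assert any(f.level == "warning" and f.label == "Vessel" for f in findings)
        assert not any(f.level == "error" for f in findings)

    def test_l_type_fields(self, tmp_path):
        doc = SODDocument(
            file_metadata={
                "SOD version": "1",
                "File type": "L",
                "Fossil group": "radiolarians",
                "Observer": "tester",
                "Region": "Apennines",
                "Section": "Monte dei Corvi",
                "Formation": "",
                "Lithology": "marl",
            },
            sample_metadata={"Sample": ["MC-1"], "Level": ["12.5 m"]},
            taxa_fields=["Genus", "Species"],
            taxa=[{"Genus": "Taxon", "Species": "sp1"}],
            occurrences=[[3]],
        )
        assert validate_sod(doc) == []
        p = tmp_path / "l.sod"
        write_sod(doc, p)
        assert read_sod(p) == doc

    def test_missing_required_sample_field_is_error(self):
        doc = minimal_o_doc()
        del doc.sample_metadata["Core"]
        assert any(f.level == "error" and f.label == "Core" for f in validate_sod(doc))


class TestSessionBridge:
    def make_session(self):
        taxa = [TaxonConfig("A", "a"), TaxonConfig("B", "b"), TaxonConfig("C", "c")]
        s = CountSession(taxa)
        for _ in range(60):
            s.record_count("A a")
        for _ in range(8):
            s.record_count("B b")
        for _ in range(4):
            s.increment_track()
        s.enter_rare_mode({"A a"})
        for _ in range(5):
            s.record_count("B b")
        for _ in range(3):
            s.record_count("C c")
        for _ in range(8):
            s.increment_track()
        return s

    def test_doc_structure(self, o_metadata):
        doc = session_to_sod(self.make_session(), o_metadata, "O", threshold=0.05)
        assert len(doc.taxa) == 3
        assert doc.n_samples == 1
        assert doc.sample_metadata["Tracks (full)"] == ["4"]
        assert doc.sample_metadata["Tracks (rare)"] == ["8"]
        assert doc.sample_metadata["Exclusion threshold (%)"] == ["5"]
        assert doc.taxa[0]["Excluded"] == "yes"

    def test_estimates_recomputable_from_file(self, o_metadata, tmp_path):
        session = self.make_session()
        doc = session_to_sod(session, o_metadata, "O", threshold=0.05)
        p = tmp_path / "x.sod"
        write_sod(doc, p)
        from_file = estimates_from_sod(read_sod(p))
        in_memory = combined_estimates(session)
        assert [e.taxon_id for e in from_file] == [e.taxon_id for e in in_memory]
        for a, b in zip(from_file, in_memory):
            assert a.estimated_count == pytest.approx(b.estimated_count, abs=1e-9)
            assert a.proportion == pytest.approx(b.proportion, abs=1e-9)
            assert a.basis == b.basis

    def test_missing_mandatory_metadata_is_error(self):
        with pytest.raises(SODValidationError):
            session_to_sod(self.make_session(), {"Observer": "x"}, "O")


class TestLongFormat:
    def test_dense_row_count(self):
        df = sod_to_long(minimal_o_doc(n_samples=2, n_taxa=3))
        assert len(df) == 6
        assert set(df.columns) >= {"sample", "taxon_id", "genus", "species", "count"}

    def test_sparse_drops_only_zeros(self):
        doc = minimal_o_doc(n_samples=2, n_taxa=3)
        dense = sod_to_long(doc, keep_zeros=True)
        sparse = sod_to_long(doc, keep_zeros=False)
        assert len(sparse) == (dense["count"] > 0).sum()

    def test_counts_lossless(self):
        doc = minimal_o_doc(n_samples=2, n_taxa=4)
        df = sod_to_long(doc)
        total = sum(sum(row) for row in doc.occurrences)
        assert df["count"].sum() == total


def test_definition_table_loads_both_dialects():
    defs = load_definitions()
    assert ("O", "1") in defs and ("L", "1") in defs
    assert "Interval (cm)" in defs[("O", "1")].labels("B")
    assert "Level" in defs[("L", "1")].labels("B")
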