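import numpy as np
import pytest

from ppiboost import seqio
from ppiboost.seqio import (
    AMINO_ACIDS,
    PSSMatrix,
    PairRecord,
    ProteinRecord,
    read_fasta,
    read_pair_table,
    read_pssm_ascii,
    write_fasta,
    write_pair_table,
    write_pssm_ascii,
)
from conftest import random_protein


class TestFasta:
    def test_single_record(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">p1\nACDE\n")
        (rec,) = read_fasta(path)
        assert (rec.id, rec.sequence, len(rec)) == ("p1", "ACDE", 4)

    def test_multiline_sequences_joined(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">p1\nAC\nDE\n>p2\nKKKK\n")
        recs = read_fasta(path)
        assert [r.id for r in recs] == ["p1", "p2"]
        assert recs[0].sequence == "ACDE"

    def test_roundtrip_50_records(self, tmp_path, rng):
        records = [random_protein(rng, int(rng.integers(20, 120)), f"s{i}") for i in range(50)]
        path = tmp_path / "out.fasta"
        write_fasta(records, path)
        back = read_fasta(path)
        assert [(r.id, r.sequence) for r in back] == [(r.id, r.sequence) for r in records]

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(ValueError, match="no records"):
            read_fasta(path)

    def test_duplicate_id_errors(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">p1\nACDE\n>p1\nKKKK\n")
        with pytest.raises(ValueError, match="p1"):
            read_fasta(path)

    def test_nonstandard_residue_lenient_maps_to_x(self, tmp_path):
        path = tmp_path / "ns.fasta"
        path.write_text(">p1\nACBZU\n")
        (rec,) = read_fasta(path)
        assert rec.sequence == "ACXXX"

    def test_nonstandard_residue_strict_errors_with_position(self, tmp_path):
        path = tmp_path / "ns.fasta"
        path.write_text(">p1\nACBDE\n")
        with pytest.raises(ValueError, match="position 3"):
            read_fasta(path, strict=True)

    def test_truly_invalid_character_always_errors(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">p1\nAC1DE\n")
        with pytest.raises(ValueError, match="position 3"):
            read_fasta(path)


class TestPairTable:
    def test_tab_single_row(self, tmp_path):
        path = tmp_path / "pairs.tsv"
        path.write_text("p1\tp2\t1\n")
        (pair,) = read_pair_table(path)
        assert (pair.id_a, pair.id_b, pair.label) == ("p1", "p2", 1)

    def test_comma_two_rows(self, tmp_path):
        path = tmp_path / "pairs.csv"
        path.write_text("a,b,0\nb,c,1\n")
        pairs = read_pair_table(path, delimiter=",")
        assert [p.label for p in pairs] == [0, 1]

    def test_plus_minus_labels(self, tmp_path):
        path = tmp_path / "pairs.tsv"
        path.write_text("a\tb\t+1\nb\tc\t-1\n")
        assert [p.label for p in read_pair_table(path)] == [1, 0]

    def test_header_autodetected(self, tmp_path):
        path = tmp_path / "pairs.tsv"
        path.write_text("id_a\tid_b\tlabel\np1\tp2\t1\n")
        assert len(read_pair_table(path)) == 1

    def test_invalid_label_errors_with_row(self, tmp_path):
        path = tmp_path / "pairs.tsv"
        path.write_text("p1\tp2\t2\n")
        with pytest.raises(ValueError, match="row 1"):
            read_pair_table(path)

    def test_wrong_column_count_errors_with_row(self, tmp_path):
        path = tmp_path / "pairs.tsv"
        path.write_text("p1\tp2\t1\np3\tp4\n")
        with pytest.raises(ValueError, match="row 2"):
            read_pair_table(path)

    def test_roundtrip(self, tmp_path):
        pairs = [PairRecord("a", "b", 1), PairRecord("c", "d", 0)]
        path = tmp_path / "pairs.tsv"
        write_pair_table(pairs, path)
        assert read_pair_table(path) == pairs


class TestPssm:
    def _make(self, rng, L=5, pid="q"):
        scores = rng.integers(-8, 9, size=(L, 20)).astype(float)
        residues = "".join(rng.choice(list(AMINO_ACIDS), size=L))
        return PSSMatrix(pid, scores, residues=residues)

    def test_roundtrip_scores_and_residues(self, tmp_path, rng):
        pssm = self._make(rng)
        path = tmp_path / "q.pssm"
        write_pssm_ascii(pssm, path)
        back = read_pssm_ascii(path, "q")
        np.testing.assert_array_equal(back.scores, pssm.scores)
        assert back.residues == pssm.residues

    def test_whitespace_and_missing_stats_tolerated(self, tmp_path, rng):
        pssm = self._make(rng)
        path = tmp_path / "q.pssm"
        write_pssm_ascii(pssm, path)
        lines = path.read_text().splitlines()
        body = [ln.replace(" ", "  ", 3) for ln in lines if "Lambda" not in ln and "Standard" not in ln]
        path.write_text("\n".join(body) + "\n")
        back = read_pssm_ascii(path, "q")
        np.testing.assert_array_equal(back.scores, pssm.scores)

    def test_truncated_row_errors(self, tmp_path, rng):
        pssm = self._make(rng)
        path = tmp_path / "q.pssm"
        write_pssm_ascii(pssm, path)
        lines = path.read_text().splitlines()
        for i, ln in enumerate(lines):
            if ln.lstrip().startswith("3 "):
                lines[i] = " ".join(ln.split()[:12])
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="row 3"):
            read_pssm_ascii(path)

    def test_no_data_rows_errors(self, tmp_path):
        path = tmp_path / "q.pssm"
        path.write_text("banner only\n\n")
        with pytest.raises(ValueError, match="no data rows"):
            read_pssm_ascii(path)


class TestModelStore:
    def test_roundtrip_and_schema(self, tmp_path):
        path = tmp_path / "m.model"
        seqio.save_model({"x": 1}, path)
        assert seqio.load_model(path) == {"x": 1}

    def test_rejects_foreign_payload(self, tmp_path):
        import joblib

        path = tmp_path / "m.model"
        joblib.dump([1, 2, 3], path)
        with pytest.raises(ValueError, match="not a ppiboost model"):
            seqio.load_model(path)


class TestRecords:
    def test_protein_record_validation(self):
        with pytest.raises(ValueError):
            ProteinRecord("has space", "ACDE")
        with pytest.raises(ValueError):
            ProteinRecord("p", "AC!E")
        with pytest.raises(ValueError):
            PairRecord("a", "b", 2)

    def test_resolve_pairs(self):
        prots = [ProteinRecord("a", "ACDE"), ProteinRecord("b", "KKKK")]
        seqio.resolve_pairs([PairRecord("a", "b", 1)], prots)
        with pytest.raises(KeyError, match="zzz"):
            seqio.resolve_pairs([PairRecord("a", "zzz", 1)], prots)
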