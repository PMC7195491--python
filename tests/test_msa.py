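import numpy as np
import pytest

from negcon.msa import (
    ALPHABET,
    AlignedSubfamily,
    AlignmentError,
    AsaRecord,
    PositionMap,
    PositionMapEntry,
    assign_interfacial_positions,
    column_frequency_profile,
    extract_interfacial_columns,
    mean_pairwise_identity,
    read_aligned_fasta,
    write_aligned_fasta,
)

from conftest import make_msa


class TestReadAlignedFasta:
    def test_well_formed_records(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\n" + "A" * 33 + "\n>s2\n" + "c" * 33 + "\n")
        msa = read_aligned_fasta(p, "DIP", "blue")
        assert msa.n_sequences == 2
        assert msa.length == 33
        assert msa.rows[1] == "C" * 33  # letters uppercased
        assert msa.sequence_ids == ("s1", "s2")

    def test_ragged_alignment_names_offending_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\n" + "A" * 33 + "\n>s2\n" + "A" * 32 + "\n")
        with pytest.raises(AlignmentError, match="s2"):
            read_aligned_fasta(p, "DIP", "blue")

    def test_non_alphabet_symbol_reports_coordinates(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nAAXA\n>s2\nAAAA\n")
        with pytest.raises(AlignmentError, match=r"'X'") as exc:
            read_aligned_fasta(p, "DIP", "blue")
        assert "s1" in str(exc.value) and "2" in str(exc.value)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("")
        with pytest.raises(AlignmentError, match="no FASTA records"):
            read_aligned_fasta(p, "DIP", "blue")

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nAAAA\n>s1\nCCCC\n")
        with pytest.raises(AlignmentError, match="duplicate"):
            read_aligned_fasta(p, "DIP", "blue")

    def test_roundtrip(self, tmp_path):
        msa = make_msa(["ACD-", "ACDE"])
        p = tmp_path / "rt.fasta"
        write_aligned_fasta(msa, p)
        back = read_aligned_fasta(p, msa.family_side, msa.subgroup_id)
        assert back.rows == msa.rows
        assert back.sequence_ids == msa.sequence_ids


class TestInterfacialAssignment:
    def test_strictly_positive_delta_asa_counts(self):
        recs = [AsaRecord("p", 5, 12.3), AsaRecord("p", 6, 0.0)]
        assert assign_interfacial_positions(recs)["p"] == {5}

    def test_all_zero_gives_empty_set(self):
        recs = [AsaRecord("p", i, 0.0) for i in range(1, 4)]
        assert assign_interfacial_positions(recs)["p"] == set()

    def test_tiny_positive_value_counts(self):
        assert assign_interfacial_positions([AsaRecord("p", 5, 0.001)])["p"] == {5}

    def test_duplicate_record_rejected(self):
        recs = [AsaRecord("p", 5, 1.0), AsaRecord("p", 5, 2.0)]
        with pytest.raises(ValueError, match="duplicate"):
            assign_interfacial_positions(recs)

    def test_negative_delta_asa_rejected_at_parse(self):
        with pytest.raises(ValueError, match=">= 0"):
            AsaRecord("p", 5, -0.1)

    def test_monotone_under_added_positive_records(self, rng):
        recs = [
            AsaRecord("p", i, float(v))
            for i, v in enumerate(rng.choice([0.0, 1.0, 5.0], size=30), start=1)
        ]
        before = assign_interfacial_positions(recs)["p"]
        after = assign_interfacial_positions(recs + [AsaRecord("p", 99, 3.0)])["p"]
        assert before <= after


def identity_map(protein: str, n: int, columns: list[int] | None = None) -> PositionMap:
    cols = columns if columns is not None else list(range(n))
    return PositionMap(entries=tuple(
        PositionMapEntry(fp, protein, fp + 100, col)
        for fp, col in enumerate(cols, start=1)
    ))


class TestExtractInterfacialColumns:
    def test_restricts_to_mapped_columns(self, rng):
        rows = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 100)) for _ in range(5)]
        msa = make_msa(rows, reference_id="seq0")
        pmap = identity_map("seq0", 33, columns=list(range(0, 66, 2)))
        out = extract_interfacial_columns(msa, pmap)
        assert out.length == 33
        assert out.n_sequences == 5

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            PositionMap(entries=())

    def test_output_ordered_by_family_position(self):
        msa = make_msa(["ACDEFGHIKL"], reference_id="seq0")
        # family positions 2,1,3 listed with columns 4,2,9
        pmap = PositionMap(entries=(
            PositionMapEntry(2, "seq0", 102, 4),
            PositionMapEntry(1, "seq0", 101, 2),
            PositionMapEntry(3, "seq0", 103, 9),
        ))
        out = extract_interfacial_columns(msa, pmap)
        src = msa.rows[0]
        assert out.rows[0] == src[2] + src[4] + src[9]

    def test_reference_absent_from_map(self):
        msa = make_msa(["AAAA"], reference_id="seq0")
        pmap = identity_map("other", 2)
        with pytest.raises(ValueError, match="absent"):
            extract_interfacial_columns(msa, pmap)

    def test_mapped_column_beyond_length(self):
        msa = make_msa(["AAAA"], reference_id="seq0")
        pmap = identity_map("seq0", 2, columns=[1, 10])
        with pytest.raises(ValueError, match="beyond"):
            extract_interfacial_columns(msa, pmap)

    def test_commutes_with_frequency_profile(self, rng):
        rows = ["".join(rng.choice(list(ALPHABET), 40)) for _ in range(8)]
        msa = make_msa(rows, reference_id="seq0")
        cols = [3, 17, 25]
        pmap = identity_map("seq0", 3, columns=cols)
        out = extract_interfacial_columns(msa, pmap)
        for new_col, src_col in enumerate(cols):
            np.testing.assert_allclose(
                column_frequency_profile(out, new_col).freqs,
                column_frequency_profile(msa, src_col).freqs,
            )


class TestColumnFrequencyProfile:
    def test_fully_conserved_column(self):
        msa = make_msa(["K", "K", "K", "K"])
        prof = column_frequency_profile(msa, 0)
        assert prof.frequency("K") == 1.0
        assert prof.freqs.sum() == pytest.approx(1.0)

    def test_counting_with_gap_as_symbol(self):
        msa = make_msa(["K", "K", "R", "-"])
        prof = column_frequency_profile(msa, 0)
        assert prof.frequency("K") == 0.5
        assert prof.frequency("R") == 0.25
        assert prof.frequency("-") == 0.25

    def test_random_columns_normalized(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 12))
            rows = ["".join(rng.choice(list(ALPHABET), 10)) for _ in range(n)]
            msa = make_msa(rows)
            col = int(rng.integers(10))
            prof = column_frequency_profile(msa, col)
            assert abs(prof.freqs.sum() - 1.0) < 1e-9
            assert ((prof.freqs >= 0) & (prof.freqs <= 1)).all()

    def test_column_out_of_range(self):
        with pytest.raises(IndexError):
            column_frequency_profile(make_msa(["AA"]), 5)


class TestMeanPairwiseIdentity:
    def test_identical_rows(self):
        assert mean_pairwise_identity(make_msa(["A" * 33, "A" * 33])) == 100.0

    def test_single_mismatch_of_33(self):
        a = "A" * 33
        b = "C" + "A" * 32
        assert mean_pairwise_identity(make_msa([a, b])) == pytest.approx(32 / 33 * 100)

    def test_gap_vs_residue_counts_as_mismatch(self):
        # pairs: (AAAA,AA--)=2/4, (AAAA,AAAA)=4/4, (AA--,AAAA)=2/4
        msa = make_msa(["AAAA", "AA--", "AAAA"])
        assert mean_pairwise_identity(msa) == pytest.approx((50 + 100 + 50) / 3)

    def test_gap_gap_columns_excluded(self):
        # comparable columns: first two only; both match
        msa = make_msa(["AA--", "AA--"])
        assert mean_pairwise_identity(msa) == 100.0

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            mean_pairwise_identity(make_msa(["AAAA"]))

    def test_no_comparable_columns_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            mean_pairwise_identity(make_msa(["--", "--"]))

    def test_invariant_under_row_permutation(self, rng):
        rows = ["".join(rng.choice(list(ALPHABET), 20)) for _ in range(5)]
        base = mean_pairwise_identity(make_msa(rows))
        perm = [rows[i] for i in rng.permutation(5)]
        assert mean_pairwise_identity(make_msa(perm)) == pytest.approx(base)
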