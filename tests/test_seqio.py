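"""FASTA/metadata IO, fragment anchoring, variant calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dloopphylo import seqio, simulate
from dloopphylo.seqio import SequenceRecord

seq_strategy = st.text(alphabet="ACGTN-", min_size=1, max_size=120)


@pytest.fixture(scope="module")
def reference():
    return simulate.make_reference(simulate.SimulationConfig(seed=21))


class TestFasta:
    def test_round_trip_identity(self, tmp_path):
        recs = [SequenceRecord("s1", "ACGTACGTACGT"),
                SequenceRecord("s2", "ACGTNNGTACGT"),
                SequenceRecord("s3", "TTTTACGTAAAA")]
        path = tmp_path / "x.fasta"
        seqio.write_fasta(recs, path)
        assert seqio.read_fasta(path) == recs

    def test_lowercase_and_u_normalized(self, tmp_path):
        path = tmp_path / "x.fasta"
        path.write_text(">s1\nacgu\n")
        assert seqio.read_fasta(path)[0].seq == "ACGT"

    def test_duplicate_ids_rejected_with_name(self, tmp_path):
        path = tmp_path / "x.fasta"
        path.write_text(">dup\nACGT\n>dup\nACGT\n")
        with pytest.raises(seqio.FastaError, match="dup"):
            seqio.read_fasta(path)

    def test_invalid_character_reported_with_position(self, tmp_path):
        path = tmp_path / "x.fasta"
        path.write_text(">s1\nACRT\n")
        with pytest.raises(seqio.FastaError, match="position 3"):
            seqio.read_fasta(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "x.fasta"
        path.write_text("")
        with pytest.raises(seqio.FastaError, match="no FASTA records"):
            seqio.read_fasta(path)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seqs=st.lists(seq_strategy, min_size=1, max_size=8))
    def test_round_trip_arbitrary_records(self, seqs, tmp_path_factory):
        recs = [SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)]
        path = tmp_path_factory.mktemp("fa") / "x.fasta"
        seqio.write_fasta(recs, path)
        assert seqio.read_fasta(path) == recs

    def test_long_sequences_wrapped_at_70(self, tmp_path):
        path = tmp_path / "x.fasta"
        seqio.write_fasta([SequenceRecord("s1", "A" * 200)], path)
        lines = path.read_text().splitlines()
        assert max(len(ln) for ln in lines[1:]) == 70


class TestMetadata:
    def test_valid_table_accepted(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("sample_id\tbreed\tprovince\tpopulation\n"
                        "s1\tTibetan\tTibet\tPT\n")
        df = seqio.read_metadata(path)
        assert df.loc[0, "population"] == "PT"

    def test_unknown_population_label_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("sample_id\tbreed\tprovince\tpopulation\n"
                        "s1\tb\tp\tXX\n")
        with pytest.raises(ValueError, match="XX"):
            seqio.read_metadata(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("sample_id\tbreed\tprovince\ns1\tb\tp\n")
        with pytest.raises(ValueError, match="population"):
            seqio.read_metadata(path)

    def test_metadata_superset_of_fasta_tolerated(self, tmp_path, caplog):
        path = tmp_path / "m.tsv"
        path.write_text("sample_id\tbreed\tprovince\tpopulation\n"
                        "s1\tb\tp\tPT\ns2\tb\tp\tNC\n")
        df = seqio.read_metadata(path, fasta_ids=["s1"])
        assert len(df) == 2  # extras kept in the table, just logged


class TestAnchoring:
    def test_exact_window_recovers_true_start(self, reference):
        frag = SequenceRecord("f", reference.seq[0:431])
        row = seqio.anchor_fragment(reference, frag,
                                    reference_offset=15459)
        assert row.fragment_start == 15459
        assert row.identity == 1.0
        assert row.frag_aln == row.ref_aln

    def test_random_substrings_anchor_at_true_start(self, reference):
        # property: anchoring an exact substring returns its start,
        # over 50 random windows
        rng = np.random.default_rng(17)
        L = len(reference.seq)
        for _ in range(50):
            start = int(rng.integers(0, L - 60))
            length = int(rng.integers(50, min(200, L - start) + 1))
            frag = SequenceRecord("f", reference.seq[start:start + length])
            row = seqio.anchor_fragment(reference, frag,
                                        reference_offset=15459)
            assert row.fragment_start == 15459 + start

    def test_single_deletion_placed_at_correct_column(self, reference):
        # oracle: exhaustively find the leftmost single-deletion
        # placement producing the fragment
        rng = np.random.default_rng(23)
        for _ in range(10):
            start, length = 40, 200
            window = reference.seq[start:start + length]
            del_at = int(rng.integers(5, length - 5))
            frag_seq = window[:del_at] + window[del_at + 1:]
            leftmost = min(
                i for i in range(length)
                if window[:i] + window[i + 1:] == frag_seq)
            row = seqio.anchor_fragment(
                reference, SequenceRecord("f", frag_seq),
                reference_offset=15459)
            aln = seqio.build_alignment(reference, [row],
                                        reference_offset=15459)
            calls = seqio.call_variants(aln)
            assert len(calls) == 1
            assert calls[0].kind == "indel"
            assert calls[0].position == 15459 + start + leftmost

    def test_unrelated_sequence_is_unanchorable(self, reference):
        rng = np.random.default_rng(3)
        junk = "".join(rng.choice(list("ACGT"), 200))
        with pytest.raises(seqio.UnanchorableError):
            seqio.anchor_fragment(reference, SequenceRecord("j", junk))

    def test_short_fragment_rejected(self, reference):
        with pytest.raises(ValueError, match="50"):
            seqio.anchor_fragment(reference, SequenceRecord("f", "ACGT"))


class TestVariantCalling:
    def _anchored(self, reference, seqs):
        rows = [seqio.anchor_fragment(reference, SequenceRecord(f"s{i}", s),
                                      reference_offset=15459)
                for i, s in enumerate(seqs)]
        return seqio.build_alignment(reference, rows,
                                     reference_offset=15459)

    def test_identical_sample_yields_no_calls(self, reference):
        aln = self._anchored(reference, [reference.seq])
        assert seqio.call_variants(aln) == []

    def test_single_transition_called_at_position(self, reference):
        # T -> C at reference coordinate 15,610 (a diagnostic site)
        idx = 15610 - 15459
        mut = reference.seq[:idx] + "C" + reference.seq[idx + 1:]
        aln = self._anchored(reference, [mut])
        calls = seqio.call_variants(aln)
        assert len(calls) == 1
        call = calls[0]
        assert (call.position, call.ref_base, call.alt_base, call.kind) == \
            (15610, "T", "C", "transition")

    def test_k_random_substitutions_all_recovered(self, reference):
        # oracle: the planted mutation list itself
        rng = np.random.default_rng(29)
        others = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
        for k in range(1, 11):
            positions = sorted(rng.choice(431, size=k, replace=False))
            seq = list(reference.seq)
            expected = {}
            for p in positions:
                alt = others[seq[p]][rng.integers(3)]
                seq[p] = alt
                expected[15459 + p] = alt
            aln = self._anchored(reference, ["".join(seq)])
            calls = seqio.call_variants(aln)
            assert {c.position: c.alt_base for c in calls} == expected

    def test_contiguous_gap_run_is_one_indel(self, reference):
        idx = 100
        frag = reference.seq[:idx] + reference.seq[idx + 3:]
        aln = self._anchored(reference, [frag])
        calls = seqio.call_variants(aln)
        indels = [c for c in calls if c.kind == "indel"]
        assert len(indels) == 1
        assert len(calls) == 1

    def test_N_columns_are_skipped(self, reference):
        seq = "N" * 10 + reference.seq[10:]
        aln = self._anchored(reference, [seq])
        assert seqio.call_variants(aln) == []

    def test_transition_transversion_annotation(self):
        assert seqio.substitution_kind("A", "G") == "transition"
        assert seqio.substitution_kind("C", "T") == "transition"
        assert seqio.substitution_kind("A", "C") == "transversion"
        assert seqio.substitution_kind("G", "T") == "transversion"
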