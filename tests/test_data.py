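"""Curation, FASTA I/O, encoding and splitting."""

import numpy as np
import pytest

from prmftp.data import (
    EncodedBatch,
    FastaParseError,
    LabelVocabulary,
    PeptideRecord,
    apply_curation_filters,
    decode_tokens,
    encode_batch,
    merge_multilabel,
    read_multilabel_fasta,
    split_train_test,
    write_multilabel_fasta,
)

from conftest import random_records


class TestFastaIO:
    def test_parses_multilabel_header(self, tmp_path, toy_vocab):
        f = tmp_path / "in.fa"
        f.write_text(">p1|ABP,ACP\nGLFDIIKKIAESF\n")
        recs = read_multilabel_fasta(f, toy_vocab)
        assert len(recs) == 1
        assert recs[0].id == "p1"
        assert recs[0].labels == {"ABP", "ACP"}
        assert recs[0].sequence == "GLFDIIKKIAESF"

    def test_unknown_code_kept_with_warning(self, tmp_path, toy_vocab):
        f = tmp_path / "in.fa"
        f.write_text(">p2|XYZ\nAAAAA\n")
        with pytest.warns(UserWarning, match="XYZ"):
            recs = read_multilabel_fasta(f, toy_vocab)
        assert recs[0].labels == {"XYZ"}

    def test_lowercase_sequence_uppercased(self, tmp_path):
        f = tmp_path / "in.fa"
        f.write_text(">p|ABP\nglfdik\n")
        assert read_multilabel_fasta(f)[0].sequence == "GLFDIK"

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        f = tmp_path / "empty.fa"
        f.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            assert read_multilabel_fasta(f) == []

    def test_malformed_file_cites_line(self, tmp_path):
        f = tmp_path / "bad.fa"
        f.write_text("GLFDIK\n>p|ABP\nAAAAA\n")
        with pytest.raises(FastaParseError, match="line 1"):
            read_multilabel_fasta(f)

    def test_roundtrip_identity(self, tmp_path, rng):
        records = random_records(rng, 20)
        f = tmp_path / "rt.fa"
        write_multilabel_fasta(records, f)
        back = read_multilabel_fasta(f)
        assert [(r.id, r.sequence, r.labels) for r in back] == [
            (r.id, r.sequence, r.labels) for r in records
        ]


class TestMerge:
    def test_union_semantics(self):
        recs = merge_multilabel([("ABP", ["GLFDI", "KKKKK"]), ("ACP", ["KKKKK"])])
        by_seq = {r.sequence: r.labels for r in recs}
        assert by_seq == {"GLFDI": {"ABP"}, "KKKKK": {"ABP", "ACP"}}

    def test_disjoint_sources_sum(self):
        recs = merge_multilabel([("ABP", ["AAAAA", "CCCCC"]), ("ACP", ["DDDDD"])])
        assert len(recs) == 3

    def test_order_independent_and_matches_bruteforce(self, rng):
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        pool = ["".join(rng.choice(letters, size=8)) for _ in range(30)]
        sources = [
            (code, [pool[i] for i in rng.integers(0, 30, size=25)])
            for code in ("ABP", "ACP", "AVP")
        ]
        # brute-force dictionary merge
        expected: dict[str, set] = {}
        for code, seqs in sources:
            for s in seqs:
                expected.setdefault(s, set()).add(code)
        merged = merge_multilabel(sources)
        assert {r.sequence: set(r.labels) for r in merged} == expected
        # permuting sources changes nothing
        merged2 = merge_multilabel(sources[::-1])
        assert [(r.sequence, r.labels) for r in merged] == [
            (r.sequence, r.labels) for r in merged2
        ]


class TestCuration:
    TOY = [
        PeptideRecord("short", "GLFD", {"ABP"}),          # length 4 < 5
        PeptideRecord("long", "A" * 51, {"ABP"}),          # length 51 > 50
        PeptideRecord("odd", "GLBDI", {"ABP"}),            # non-standard 'B'
        PeptideRecord("ok1", "GLFDIIKK", {"ABP"}),
        PeptideRecord("ok2", "KWKLFKKI", {"ABP", "ACP"}),
    ]

    def test_three_rules_on_toy_set(self):
        survivors, vocab = apply_curation_filters(self.TOY, min_class_count=1)
        assert {r.id for r in survivors} == {"ok1", "ok2"}
        assert set(vocab.codes) == {"ABP", "ACP"}

    def test_identity_when_all_valid(self, rng):
        records = random_records(rng, 30)
        out, _ = apply_curation_filters(records, min_class_count=1)
        assert {(r.id, r.sequence, r.labels) for r in out} == {
            (r.id, r.sequence, r.labels) for r in records
        }

    def test_small_class_dropped_at_threshold(self, rng):
        records = random_records(rng, 60, codes=("ABP",))
        records += [
            PeptideRecord(f"avp{i}", r.sequence, {"AVP"})
            for i, r in enumerate(random_records(rng, 45))
        ]
        records += [
            PeptideRecord(f"rare{i}", r.sequence, {"ACP"})
            for i, r in enumerate(random_records(rng, 39))
        ]
        out, vocab = apply_curation_filters(records, min_class_count=40)
        assert "ACP" not in vocab.codes
        assert set(vocab.codes) == {"ABP", "AVP"}
        assert all("ACP" not in r.labels for r in out)

    def test_idempotent(self, rng):
        records = random_records(rng, 80) + self.TOY
        once, v1 = apply_curation_filters(records, min_class_count=10)
        twice, v2 = apply_curation_filters(once, min_class_count=10, vocab=v1)
        assert v1.codes == v2.codes
        assert [(r.id, r.labels) for r in once] == [(r.id, r.labels) for r in twice]

    def test_everything_filtered_raises(self):
        with pytest.raises(ValueError, match="empty dataset"):
            apply_curation_filters([PeptideRecord("x", "GLB", {"ABP"})])


class TestEncoding:
    def test_single_letter_padding(self, toy_vocab):
        rec = PeptideRecord("p", "AAAAA", {"ABP"})
        batch = encode_batch([rec], toy_vocab, L=50)
        assert batch.tokens[0, :5].tolist() == [1] * 5
        assert batch.tokens[0, 5:].tolist() == [0] * 45

    def test_alphabetical_mapping(self, toy_vocab):
        batch = encode_batch([PeptideRecord("p", "ACDE", {"ABP"})], toy_vocab, L=10)
        assert batch.tokens[0].tolist() == [1, 2, 3, 4, 0, 0, 0, 0, 0, 0]

    def test_label_one_hot(self, toy_vocab):
        batch = encode_batch([PeptideRecord("p", "ACDE", {toy_vocab.codes[0]})], toy_vocab)
        assert batch.labels[0].tolist() == [1.0, 0.0, 0.0]

    def test_pad_zeros_trail(self, rng, toy_vocab):
        batch = encode_batch(random_records(rng, 25), toy_vocab, L=50)
        for row in batch.tokens:
            nz = np.flatnonzero(row)
            assert nz.size > 0 and nz.max() == nz.size - 1  # nonzeros precede zeros

    def test_decode_inverts_encode(self, rng, toy_vocab):
        records = random_records(rng, 15)
        batch = encode_batch(records, toy_vocab)
        assert decode_tokens(batch.tokens) == [r.sequence for r in records]

    def test_too_long_and_bad_letter_raise(self, toy_vocab):
        with pytest.raises(ValueError, match="exceeds"):
            encode_batch([PeptideRecord("p", "A" * 11, {"ABP"})], toy_vocab, L=10)
        with pytest.raises(ValueError, match="'B'"):
            encode_batch([PeptideRecord("p", "ABCDE", {"ABP"})], toy_vocab)


class TestSplit:
    def test_sizes(self, rng):
        records = random_records(rng, 10)
        train, test = split_train_test(records, ratio=0.8, seed=0)
        assert len(train) == 8 and len(test) == 2

    def test_deterministic(self, rng):
        records = random_records(rng, 40)
        a = split_train_test(records, seed=7)
        b = split_train_test(records, seed=7)
        assert [r.id for r in a[0]] == [r.id for r in b[0]]
        assert [r.id for r in a[1]] == [r.id for r in b[1]]

    def test_partition_over_random_runs(self, rng):
        records = random_records(rng, 23)
        ids = {r.id for r in records}
        for seed in range(100):
            train, test = split_train_test(records, ratio=0.65, seed=seed)
            tr, te = {r.id for r in train}, {r.id for r in test}
            assert tr | te == ids and not (tr & te)

    def test_too_few_records_raise(self):
        with pytest.raises(ValueError):
            split_train_test([PeptideRecord("a", "AAAAA", {"ABP"})])
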