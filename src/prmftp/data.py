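"""Reading, merging, curating, encoding and splitting multi-label peptide data.

Peptides are short sequences (5-50 residues) of the 20 standard amino acids,
each carrying a *set* of therapeutic function labels (anti-bacterial,
anti-cancer, anti-viral, ...).  Because no standard FASTA dialect exists for
multi-label data, headers are ``>id|CODE1,CODE2,...``; plain single-class
FASTA files (one label supplied externally, e.g. from the filename) are merged
with :func:`merge_multilabel`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from io import StringIO
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "STANDARD_AMINO_ACIDS",
    "DEFAULT_LABEL_CODES",
    "PeptideRecord",
    "LabelVocabulary",
    "EncodedBatch",
    "read_multilabel_fasta",
    "write_multilabel_fasta",
    "write_tsv",
    "merge_multilabel",
    "apply_curation_filters",
    "encode_batch",
    "decode_tokens",
    "split_train_test",
]

#: The 20 standard amino acids in alphabetical order; token i+1 encodes
#: STANDARD_AMINO_ACIDS[i], token 0 is padding.
STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_AA_INDEX = {aa: i + 1 for i, aa in enumerate(STANDARD_AMINO_ACIDS)}

#: The 21 therapeutic function classes of the curated benchmark.
DEFAULT_LABEL_CODES = (
    "AAP", "ABP", "ACP", "ACVP", "ADP", "AEP", "AFP", "AHIVP", "AHP", "AIP",
    "AMRSAP", "APP", "ATP", "AVP", "BBP", "BIP", "CPP", "DPPIP", "QSP", "SBP",
    "THP",
)


class FastaParseError(ValueError):
    """Raised for malformed multi-label FASTA input."""


@dataclass(frozen=True)
class PeptideRecord:
    """One peptide sequence with its set of function labels."""

    id: str
    sequence: str
    labels: frozenset[str]

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        object.__setattr__(self, "labels", frozenset(self.labels))


@dataclass(frozen=True)
class LabelVocabulary:
    """Ordered list of M function codes defining the label-indicator axis.

    The ordering is part of any trained model's contract and is serialized
    with it.
    """

    codes: tuple[str, ...] = DEFAULT_LABEL_CODES

    def __post_init__(self):
        codes = tuple(self.codes)
        if len(set(codes)) != len(codes):
            raise ValueError("label codes must be unique")
        if len(codes) < 2:
            raise ValueError("a label vocabulary needs at least 2 codes")
        object.__setattr__(self, "codes", codes)

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    def index(self, code: str) -> int:
        return self.codes.index(code)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({"codes": list(self.codes)}, indent=1))

    @classmethod
    def from_json(cls, path) -> "LabelVocabulary":
        return cls(tuple(json.loads(Path(path).read_text())["codes"]))


@dataclass
class EncodedBatch:
    """Fixed-length token matrix plus binary label-indicator matrix.

    ``tokens`` is N x L with entries in 0..20 (0 = pad, right-padded);
    ``labels`` is N x M binary.
    """

    tokens: np.ndarray
    labels: np.ndarray
    vocab: LabelVocabulary
    length: int = 50

    def __post_init__(self):
        self.tokens = np.asarray(self.tokens, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.float64)
        if self.tokens.shape[0] != self.labels.shape[0]:
            raise ValueError("tokens and labels disagree on sample count")


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def _parse_header(header: str, lineno: int | None = None) -> tuple[str, frozenset[str]]:
    if "|" in header:
        pid, _, tail = header.partition("|")
        codes = frozenset(c.strip() for c in tail.split(",") if c.strip())
    else:
        pid, codes = header, frozenset()
    if not pid:
        where = f" at line {lineno}" if lineno else ""
        raise FastaParseError(f"empty record id{where}")
    return pid.strip(), codes


def read_multilabel_fasta(path, vocab: LabelVocabulary | None = None) -> list[PeptideRecord]:
    """Read a multi-label FASTA file (``>id|CODE1,CODE2`` headers).

    Unknown label codes (relative to `vocab`, when given) are kept on the
    record but reported with a warning; curation later removes them.
    """
    text = Path(path).read_text()
    if not text.strip():
        warnings.warn(f"{path}: empty FASTA file", stacklevel=2)
        return []
    # locate header lines so parse errors can cite them
    first = text.lstrip()
    if not first.startswith(">"):
        bad = next(i for i, ln in enumerate(text.splitlines(), 1) if ln.strip())
        raise FastaParseError(f"{path}: expected '>' header at line {bad}")
    records = []
    unknown: set[str] = set()
    for entry in SeqIO.parse(StringIO(text), "fasta"):
        pid, codes = _parse_header(entry.description)
        seq = str(entry.seq).upper()
        if not seq:
            raise FastaParseError(f"{path}: record {pid!r} has an empty sequence")
        if vocab is not None:
            unknown |= {c for c in codes if c not in vocab}
        records.append(PeptideRecord(id=pid, sequence=seq, labels=codes))
    if unknown:
        warnings.warn(
            f"{path}: unknown label code(s) {sorted(unknown)} not in vocabulary",
            stacklevel=2,
        )
    return records


def write_multilabel_fasta(records: list[PeptideRecord], path) -> None:
    """Write records in the ``>id|CODE1,CODE2`` dialect (codes sorted)."""
    out = [
        SeqRecord(Seq(r.sequence), id=f"{r.id}|{','.join(sorted(r.labels))}", description="")
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(out, fh, "fasta-2line")


def write_tsv(records: list[PeptideRecord], path) -> None:
    """Export as TSV: id, sequence, comma-joined sorted labels."""
    with open(path, "w") as fh:
        fh.write("id\tsequence\tlabels\n")
        for r in records:
            fh.write(f"{r.id}\t{r.sequence}\t{','.join(sorted(r.labels))}\n")


# ---------------------------------------------------------------------------
# Merging and curation
# ---------------------------------------------------------------------------

def merge_multilabel(sources: list[tuple[str, list[str]]]) -> list[PeptideRecord]:
    """Merge per-class sequence collections into multi-label records.

    Identical sequences appearing under several function classes collapse to
    one record whose label set is the union.  Output order is lexicographic
    by sequence, so the merge is independent of source order.
    """
    by_seq: dict[str, set[str]] = {}
    for code, seqs in sources:
        for seq in set(seqs):  # dedupe within a source
            by_seq.setdefault(seq.upper(), set()).add(code)
    return [
        PeptideRecord(id=f"pep{i + 1}", sequence=seq, labels=frozenset(by_seq[seq]))
        for i, seq in enumerate(sorted(by_seq))
    ]


def apply_curation_filters(
    records: list[PeptideRecord],
    min_len: int = 5,
    max_len: int = 50,
    min_class_count: int = 40,
    vocab: LabelVocabulary | None = None,
) -> tuple[list[PeptideRecord], LabelVocabulary]:
    """Apply the three benchmark curation rules.

    1. drop peptides containing non-standard amino acids;
    2. drop peptides shorter than `min_len` or longer than `max_len`;
    3. drop function classes with fewer than `min_class_count` members
       (counted after rules 1-2), removing them from the vocabulary and from
       every record's label set; records left label-less are dropped too.

    Returns the surviving records and the pruned vocabulary.  Idempotent.
    """
    alphabet = set(STANDARD_AMINO_ACIDS)
    kept = [
        r
        for r in records
        if min_len <= len(r.sequence) <= max_len and set(r.sequence) <= alphabet
    ]
    if vocab is not None:
        kept = [r for r in kept if r.labels & set(vocab.codes)]
        kept = [
            PeptideRecord(r.id, r.sequence, r.labels & set(vocab.codes)) for r in kept
        ]
    counts: dict[str, int] = {}
    for r in kept:
        for c in r.labels:
            counts[c] = counts.get(c, 0) + 1
    order = list(vocab.codes) if vocab is not None else sorted(counts)
    surviving_codes = [c for c in order if counts.get(c, 0) >= min_class_count]
    survivors = []
    for r in kept:
        labels = r.labels & set(surviving_codes)
        if labels:
            survivors.append(PeptideRecord(r.id, r.sequence, labels))
    if not survivors:
        raise ValueError("empty dataset: curation filters removed every record")
    return survivors, LabelVocabulary(tuple(surviving_codes))


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def encode_batch(records: list[PeptideRecord], vocab: LabelVocabulary, L: int = 50) -> EncodedBatch:
    """Encode sequences to right-padded integer tokens and binary labels.

    Residue ``A..Y`` maps to its 1-based alphabetical index (A=1 ... Y=20);
    positions beyond the sequence length are 0.
    """
    n, m = len(records), len(vocab)
    tokens = np.zeros((n, L), dtype=np.int64)
    labels = np.zeros((n, m), dtype=np.float64)
    for i, r in enumerate(records):
        if len(r.sequence) > L:
            raise ValueError(f"record {r.id!r}: sequence length {len(r.sequence)} exceeds L={L}")
        for j, aa in enumerate(r.sequence):
            try:
                tokens[i, j] = _AA_INDEX[aa]
            except KeyError:
                raise ValueError(
                    f"record {r.id!r}: non-standard amino acid {aa!r}"
                ) from None
        for code in r.labels:
            labels[i, vocab.index(code)] = 1.0
    return EncodedBatch(tokens=tokens, labels=labels, vocab=vocab, length=L)


def decode_tokens(tokens: np.ndarray) -> list[str]:
    """Inverse of the token encoding: strip pads, map indices back to letters."""
    out = []
    for row in np.asarray(tokens):
        out.append("".join(STANDARD_AMINO_ACIDS[t - 1] for t in row if t != 0))
    return out


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_train_test(
    records: list[PeptideRecord], ratio: float = 0.8, seed: int = 0
) -> tuple[list[PeptideRecord], list[PeptideRecord]]:
    """Random train/test partition with ``floor(ratio*N)`` training records."""
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    cut = int(np.floor(ratio * n))
    train = [records[i] for i in perm[:cut]]
    test = [records[i] for i in perm[cut:]]
    return train, test
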