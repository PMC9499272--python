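import numpy as np
import pytest

from prmftp.data import LabelVocabulary, PeptideRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_vocab():
    return LabelVocabulary(("ABP", "ACP", "AVP"))


def random_records(rng, n, codes=("ABP", "ACP", "AVP"), min_len=5, max_len=50):
    """Random valid peptide records with non-empty random label subsets."""
    letters = list("ACDEFGHIKLMNPQRSTVWY")
    out = []
    for i in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        seq = "".join(rng.choice(letters, size=length))
        k = int(rng.integers(1, len(codes) + 1))
        labels = frozenset(rng.choice(codes, size=k, replace=False).tolist())
        out.append(PeptideRecord(id=f"r{i}", sequence=seq, labels=labels))
    return out
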