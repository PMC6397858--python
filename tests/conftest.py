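import numpy as np
import pytest

from hairpinmi.seqio import RnaSequence


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_sequences(rng):
    """50 random RNA sequences, lengths 40-120."""
    def make(n=50, lo=40, hi=120, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        out = []
        for i in range(n):
            L = int(r.integers(lo, hi + 1))
            out.append(
                RnaSequence(id=f"r{i}", residues="".join(r.choice(list("ACGU"), size=L)))
            )
        return out

    return make


@pytest.fixture
def fasta_file(tmp_path):
    def write(text, name="in.fa"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return write
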