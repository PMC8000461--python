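"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own vectorized code paths:
canonical k-mers are built with plain string operations so that sketch and
simulation behaviour can be checked against an implementation that shares
nothing with the one under test.
"""

from __future__ import annotations

import numpy as np
import pytest

import linforge as lf

_RC = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def canonical_kmers(seq: str, k: int) -> set[str]:
    """Exact canonical k-mer set via straightforward string handling."""
    out: set[str] = set()
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if any(c not in "ACGT" for c in kmer):
            continue
        out.add(min(kmer, revcomp(kmer)))
    return out


def exact_jaccard(a: str, b: str, k: int) -> float:
    """Brute-force Jaccard over the full canonical k-mer sets."""
    sa, sb = canonical_kmers(a, k), canonical_kmers(b, k)
    union = sa | sb
    return len(sa & sb) / len(union) if union else 0.0


def make_signature_with_shared(m: int, n: int = 2000) -> tuple[lf.Signature, lf.Signature]:
    """Two signatures whose merged-bottom Jaccard is exactly m/n."""
    a = np.arange(1, n + 1, dtype=np.uint64)
    b = np.concatenate([
        np.arange(1, m + 1, dtype=np.uint64),
        np.arange(10 * n + 1, 10 * n + 1 + (n - m), dtype=np.uint64),
    ])
    return (
        lf.Signature("a", 21, n, a),
        lf.Signature("b", 21, n, np.sort(b)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def lin20():
    return lf.get_scheme("lin20")


@pytest.fixture
def small_genome():
    return lf.random_genome(20_400, seed=11)


@pytest.fixture
def tmp_store(tmp_path):
    store = lf.Store.create(tmp_path / "store")
    yield store
    store.close()


def write_genome(tmp_path, name: str, seq: str):
    from linforge.io import write_fasta

    tmp_path.mkdir(parents=True, exist_ok=True)
    path = tmp_path / f"{name}.fasta"
    write_fasta({name: seq}, path)
    return path
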