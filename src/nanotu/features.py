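"""k-mer signature features over homopolymer-compressed reads.

ONT reads systematically miscount homopolymer lengths, so each read is
run-length compressed (every maximal run of one base collapses to a single
base) before k-mer counting; the compressed sequence is used *only* here,
never for consensus building. Each read becomes a vector of counts of all
4^k words (k = 6 by default, 4096 columns). Because k-mer counts are
compositional, the count matrix is centred log-ratio (CLR) transformed
before dimensionality reduction.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_RUN_RE = re.compile(r"(.)\1+")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def compress_homopolymers(seq: str) -> str:
    """Collapse every maximal homopolymer run to a single base.

    ``"GTTTTGGT" -> "GTGT"``; idempotent; empty input yields empty output.
    """
    return _RUN_RE.sub(r"\1", seq)


def kmer_signature(seq: str, k: int = 6) -> np.ndarray | None:
    """Count occurrences of every 4^k k-mer, lexicographic order (A<C<G<T).

    Windows containing a non-ACGT character are skipped. Returns None when
    the sequence is shorter than k (the caller drops the read with a
    warning); otherwise the counts sum to the number of valid windows.
    """
    n = len(seq)
    if n < k:
        return None
    counts = np.zeros(4 ** k, dtype=np.float64)
    # rolling 2-bit encoding; restart after any ambiguous base
    mask = 4 ** k
    code = 0
    run = 0  # valid bases accumulated in the current window
    for ch in seq:
        idx = _BASE_INDEX.get(ch)
        if idx is None:
            code = 0
            run = 0
            continue
        code = (code * 4 + idx) % mask
        run += 1
        if run >= k:
            counts[code] += 1
    return counts


def kmer_labels(k: int) -> list[str]:
    """All 4^k k-mers in lexicographic order (column labels of the matrix)."""
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]


def clr_transform(counts: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Centred log-ratio transform, row-wise, with a pseudocount.

    Each row x becomes ln((x + c) / g(x + c)) with g the geometric mean of
    the pseudocounted row; every output row sums to zero.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    x = np.asarray(counts, dtype=np.float64) + pseudocount
    if np.any(x <= 0):
        raise ValueError("counts must be non-negative")
    logx = np.log(x)
    return logx - logx.mean(axis=1, keepdims=True)


@dataclass
class FeatureMatrix:
    """CLR-transformed N x 4^k k-mer signature matrix with row provenance."""

    values: np.ndarray
    read_ids: list[str]
    k: int
    dropped_ids: list[str] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return self.values.shape[0]


def build_feature_matrix(reads, k: int = 6, pseudocount: float = 1.0) -> FeatureMatrix:
    """Compress, count and CLR-transform a batch of prepared reads.

    Reads whose compressed sequence is shorter than k are dropped with a
    warning and recorded in ``dropped_ids``.
    """
    rows: list[np.ndarray] = []
    ids: list[str] = []
    dropped: list[str] = []
    for read in reads:
        sig = kmer_signature(compress_homopolymers(read.seq), k)
        if sig is None:
            logger.warning("read %s shorter than k=%d after compression; dropped", read.id, k)
            dropped.append(read.id)
            continue
        rows.append(sig)
        ids.append(read.id)
    if not rows:
        return FeatureMatrix(np.zeros((0, 4 ** k)), [], k, dropped)
    return FeatureMatrix(clr_transform(np.vstack(rows), pseudocount), ids, k, dropped)
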