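"""Read preparation: FASTQ input, primer matching/orientation, quality and length filters.

Reads must arrive demultiplexed and barcode-trimmed. Each read is required to
carry the forward primer at its 5' end and the reverse complement of the
reverse primer at its 3' end (in plus orientation); reads lacking either
primer are discarded. Surviving reads are oriented to the plus strand,
primer-trimmed, and then filtered on median base quality and insert length.

Median quality ignores positions reported as Q90: some basecallers clamp
per-base quality at 90 due to reduced-precision arithmetic, and those
positions would otherwise inflate the median.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import edlib
import numpy as np

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

#: IUPAC degeneracy map used to build edlib equality pairs.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes supported)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class RawRead:
    """One basecalled read as parsed from FASTQ."""

    id: str
    seq: str
    qual: np.ndarray  # Phred integers, same length as seq
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.qual = np.asarray(self.qual, dtype=np.int16)
        if len(self.seq) != len(self.qual):
            raise ValueError(f"read {self.id}: seq/qual length mismatch")


@dataclass
class PreparedRead:
    """A plus-oriented, primer-trimmed read ready for feature collection."""

    id: str
    seq: str
    qual: np.ndarray
    sample_id: str = ""
    flipped: bool = False

    @property
    def gc(self) -> float:
        if not self.seq:
            return 0.0
        return (self.seq.count("G") + self.seq.count("C")) / len(self.seq)


@dataclass
class AmpliconConfig:
    """Primer pair and the expected amplicon length/quality window.

    ``min_len``/``max_len`` are the expected insert bounds for the target
    region (e.g. 350-600 bp for 16S V3-V4, 900-1600 bp for V1-V9,
    100-500 bp for ITS1/ITS2, 300-1200 bp for full ITS).
    """

    primer_f: str
    primer_r: str
    min_len: int
    max_len: int
    q_min: float = 20.0
    q_cap_exclude: int = 90
    primer_error_rate: float = 0.1

    def __post_init__(self) -> None:
        if not self.primer_f or not self.primer_r:
            raise ValueError("primers must be non-empty")
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("need 0 < min_len <= max_len")
        for p in (self.primer_f, self.primer_r):
            bad = set(p.upper()) - set(IUPAC)
            if bad:
                raise ValueError(f"non-IUPAC characters in primer: {bad}")


@dataclass
class AttritionLog:
    """Per-reason rejection counts; one increment per input read."""

    no_primer: int = 0
    bad_quality: int = 0
    too_short: int = 0
    too_long: int = 0
    kept: int = 0
    extras: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.no_primer + self.bad_quality + self.too_short + self.too_long + self.kept

    def as_dict(self) -> dict:
        return {
            "no_primer": self.no_primer,
            "bad_quality": self.bad_quality,
            "too_short": self.too_short,
            "too_long": self.too_long,
            "kept": self.kept,
        }


def _equality_pairs() -> list[tuple[str, str]]:
    pairs = []
    for code, bases in IUPAC.items():
        if len(bases) > 1 or code == "N":
            for b in bases:
                pairs.append((code, b))
    # N in the read matches any primer base as well
    for b in "ACGT":
        pairs.append((b, "N"))
    return pairs


_EQUALITIES = _equality_pairs()


def _find_primer(primer: str, seq: str, max_errors: int) -> tuple[int, int] | None:
    """Best infix (semi-global) match of ``primer`` in ``seq``.

    Returns (start, end) of the matched span, end exclusive, or None if no
    match within ``max_errors`` edits exists.
    """
    res = edlib.align(primer.upper(), seq.upper(), mode="HW", task="locations",
                      k=max_errors, additionalEqualities=_EQUALITIES)
    if res["editDistance"] < 0:
        return None
    start, end = res["locations"][0]
    return start, end + 1


def match_and_trim_primers(read: RawRead, cfg: AmpliconConfig) -> PreparedRead | None:
    """Locate both primers, orient the read to the plus strand, trim primers.

    The plus strand carries ``primer_f`` near the 5' end followed by
    ``revcomp(primer_r)`` near the 3' end. Both strands are tried; if
    neither carries both primers in the correct order the read is rejected
    (returns None). Matching is semi-global with IUPAC degeneracy and an
    edit budget of ``primer_error_rate * len(primer)`` per primer.
    """
    kf = int(cfg.primer_error_rate * len(cfg.primer_f))
    kr = int(cfg.primer_error_rate * len(cfg.primer_r))
    r_rc = revcomp(cfg.primer_r)

    for flipped in (False, True):
        seq = revcomp(read.seq) if flipped else read.seq
        hit_f = _find_primer(cfg.primer_f, seq, kf)
        if hit_f is None:
            continue
        hit_r = _find_primer(r_rc, seq[hit_f[1]:], kr)
        if hit_r is None:
            continue
        ins_start = hit_f[1]
        ins_end = hit_f[1] + hit_r[0]
        qual = read.qual[::-1] if flipped else read.qual
        if hit_f[0] > 30:
            logger.warning(
                "read %s: forward primer found %d bp from the end; "
                "reads may not be barcode/adapter trimmed", read.id, hit_f[0])
        return PreparedRead(
            id=read.id,
            seq=seq[ins_start:ins_end],
            qual=qual[ins_start:ins_end].copy(),
            sample_id=read.sample_id,
            flipped=flipped,
        )
    return None


def median_quality(qual: np.ndarray | Iterable[int], q_cap_exclude: int = 90) -> float:
    """Median Phred quality, excluding positions at/above the basecaller cap.

    If every position sits at the cap the full vector's median is returned
    (such reads are pathological; they are not silently dropped here).
    """
    q = np.asarray(qual)
    if q.size == 0:
        raise ValueError("empty quality vector")
    below = q[q < q_cap_exclude]
    if below.size == 0:
        return float(np.median(q))
    return float(np.median(below))


def filter_reads(reads: Iterable[PreparedRead], cfg: AmpliconConfig,
                 log: AttritionLog | None = None) -> tuple[list[PreparedRead], AttritionLog]:
    """Keep reads with median quality >= q_min and length within bounds."""
    log = log or AttritionLog()
    kept: list[PreparedRead] = []
    for read in reads:
        n = len(read.seq)
        if n == 0 or median_quality(read.qual, cfg.q_cap_exclude) < cfg.q_min:
            log.bad_quality += 1
        elif n < cfg.min_len:
            log.too_short += 1
        elif n > cfg.max_len:
            log.too_long += 1
        else:
            log.kept += 1
            kept.append(read)
    return kept, log


def prepare_reads(reads: Iterable[RawRead], cfg: AmpliconConfig) -> tuple[list[PreparedRead], AttritionLog]:
    """Full preparation stage: primer match/orient/trim then quality/length filter."""
    log = AttritionLog()
    trimmed: list[PreparedRead] = []
    for raw in reads:
        prep = match_and_trim_primers(raw, cfg)
        if prep is None:
            log.no_primer += 1
        else:
            trimmed.append(prep)
    kept, log = filter_reads(trimmed, cfg, log)
    return kept, log


# ---------------------------------------------------------------------------
# FASTQ I/O
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path, sample_id: str = "") -> Iterator[RawRead]:
    """Yield RawReads from a FASTQ or gzipped FASTQ file (Sanger Phred+33)."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    sample_id = sample_id or path.name.split(".")[0]
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield RawRead(
                id=rec.id,
                seq=str(rec.seq).upper(),
                qual=np.asarray(rec.letter_annotations["phred_quality"],
                                dtype=np.int16),
                sample_id=sample_id,
            )


def read_sample_sheet(path: str | Path) -> dict[str, Path]:
    """Parse a two-column TSV (sample_id, fastq_path) into a sample map."""
    samples: dict[str, Path] = {}
    base = Path(path).parent
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample_id, fq = line.split("\t")[:2]
            p = Path(fq)
            samples[sample_id] = p if p.is_absolute() else base / p
    return samples
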