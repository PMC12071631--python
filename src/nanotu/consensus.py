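"""Per-cluster multiple alignment and quality-weighted consensus calling.

Each cluster's selected reads are multiple-aligned (MAFFT when the binary is
on PATH, otherwise an internal centre-star aligner with the same contract:
degapping row i reproduces read i). The proto-consensus is then called
column by column:

1. if the gap is the strict plurality symbol, emit '-';
2. otherwise, among letters supported by at least ``min_support`` reads,
   take the letter with the highest average quality over the column (its
   summed Phred score across all reads, i.e. quality-weighted plurality);
   emit it if it is also the (tied-)most frequent letter;
3. if the most frequent letter's column quality is beaten by a less
   frequent supported letter (e.g. 4 reads at Q12 against 3 reads at Q30),
   the evidence is contradictory: emit 'N';
4. if no letter reaches ``min_support``, emit 'N'.

Scoring letters by their total quality mass rather than by the mean over
supporting reads matters: multiple alignments of noisy long reads always
carry a few misplaced high-quality bases per column, and a per-supporting-
read mean would let three such bases outvote dozens of concordant ones.

Gaps are then stripped from the proto-consensus and terminal poly-N runs
trimmed. An external polisher (medaka) can optionally refine the final
sequence; when unavailable the consensus passes through unchanged.

Ties: a plurality tie between '-' and a letter goes to the letter
(deletions dominate ONT errors, so we bias against over-deletion); mean
quality ties go to the higher count, then alphabetical order.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import edlib
import numpy as np

from .ioprep import PreparedRead

logger = logging.getLogger(__name__)

GAP = "-"


@dataclass
class Consensus:
    """Consensus sequence of one read cluster (one OTU)."""

    cluster_label: int
    proto: str
    final_seq: str
    support: int
    polished: bool = False
    sample_id: str = "pooled"


@dataclass
class Alignment:
    """Equal-length aligned rows with qualities lifted to aligned coordinates.

    ``quals[i][j]`` is the Phred score of row i at column j, or -1 at a gap.
    """

    rows: list[str]
    quals: list[np.ndarray]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def _lift_qualities(aligned: list[str], reads: list[PreparedRead]) -> Alignment:
    quals = []
    for row, read in zip(aligned, reads):
        q = np.full(len(row), -1, dtype=np.int16)
        pos = 0
        for j, ch in enumerate(row):
            if ch != GAP:
                q[j] = read.qual[pos]
                pos += 1
        if pos != len(read.qual):
            raise ValueError(f"alignment row does not reconstruct read {read.id}")
        quals.append(q)
    return Alignment(rows=aligned, quals=quals)


def _mafft_align(reads: list[PreparedRead]) -> list[str] | None:
    if shutil.which("mafft") is None:
        return None
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "cluster.fasta"
        with open(fasta, "w") as fh:
            for i, r in enumerate(reads):
                fh.write(f">{i}\n{r.seq}\n")
        try:
            out = subprocess.run(["mafft", "--auto", "--quiet", str(fasta)],
                                 capture_output=True, text=True, check=True)
        except subprocess.CalledProcessError as exc:
            logger.warning("mafft failed (%s); falling back to internal aligner", exc)
            return None
    rows: dict[int, list[str]] = {}
    idx = -1
    for line in out.stdout.splitlines():
        if line.startswith(">"):
            idx = int(line[1:].strip())
            rows[idx] = []
        elif idx >= 0:
            rows[idx].append(line.strip())
    return ["".join(rows[i]).upper() for i in range(len(reads))]


def _center_star_align(reads: list[PreparedRead]) -> list[str]:
    """Centre-star MSA: global pairwise alignments to a centre read, merged
    under the once-a-gap-always-a-gap rule. Used when MAFFT is unavailable."""
    seqs = [r.seq for r in reads]
    center = int(np.argsort([len(s) for s in seqs])[len(seqs) // 2])
    c_seq = seqs[center]
    # pairwise NW alignments of every read against the centre
    pair_aln: list[tuple[str, str]] = []
    for i, s in enumerate(seqs):
        if i == center:
            pair_aln.append((c_seq, c_seq))
            continue
        res = edlib.align(s, c_seq, mode="NW", task="path")
        a_query, a_target = _edlib_pretty(s, c_seq, res["cigar"])
        pair_aln.append((a_query, a_target))
    # merged centre coordinate system: gap count inserted after each centre position
    ins_after = np.zeros(len(c_seq) + 1, dtype=np.int64)
    for a_query, a_target in pair_aln:
        pos = 0
        run = 0
        for ch in a_target:
            if ch == GAP:
                run += 1
            else:
                ins_after[pos] = max(ins_after[pos], run)
                run = 0
                pos += 1
        ins_after[pos] = max(ins_after[pos], run)
    rows = []
    for a_query, a_target in pair_aln:
        out: list[str] = []
        pos = 0
        run_chars: list[str] = []
        for qc, tc in zip(a_query, a_target):
            if tc == GAP:
                run_chars.append(qc)
            else:
                out.append("".join(run_chars) + GAP * (ins_after[pos] - len(run_chars)))
                run_chars = []
                out.append(qc)
                pos += 1
        out.append("".join(run_chars) + GAP * (ins_after[pos] - len(run_chars)))
        rows.append("".join(out))
    return rows


def _edlib_pretty(query: str, target: str, cigar: str) -> tuple[str, str]:
    """Expand an edlib CIGAR into aligned query/target strings."""
    aq: list[str] = []
    at: list[str] = []
    qi = ti = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=X":
            aq.append(query[qi:qi + n]); at.append(target[ti:ti + n])
            qi += n; ti += n
        elif ch == "I":  # insertion to target == consumes query
            aq.append(query[qi:qi + n]); at.append(GAP * n)
            qi += n
        elif ch == "D":
            aq.append(GAP * n); at.append(target[ti:ti + n])
            ti += n
    return "".join(aq), "".join(at)


def align_cluster(reads: list[PreparedRead], use_mafft: bool = True) -> Alignment:
    """Multiple-align a cluster's selected reads, carrying qualities along.

    MAFFT (default parameters) is preferred; the internal centre-star
    aligner is the fallback. Requires at least 3 reads.
    """
    if len(reads) < 3:
        raise ValueError("consensus requires at least 3 reads")
    aligned = _mafft_align(reads) if use_mafft else None
    if aligned is None:
        aligned = _center_star_align(reads)
    return _lift_qualities(aligned, reads)


def call_proto_consensus(aln: Alignment, min_support: int = 3) -> str:
    """Positional consensus over the alignment (see module docstring rules)."""
    rows = aln.rows
    quals = aln.quals
    n_rows = len(rows)
    if n_rows == 0:
        return ""
    out: list[str] = []
    for j in range(aln.n_columns):
        counts: dict[str, int] = {}
        qsums: dict[str, float] = {}
        for i in range(n_rows):
            ch = rows[i][j]
            counts[ch] = counts.get(ch, 0) + 1
            if ch != GAP:
                qsums[ch] = qsums.get(ch, 0.0) + float(quals[i][j])
        letter_counts = {ch: c for ch, c in counts.items() if ch != GAP}
        gap_count = counts.get(GAP, 0)
        max_letter = max(letter_counts.values(), default=0)
        if gap_count > max_letter:
            out.append(GAP)
            continue
        supported = {ch: c for ch, c in letter_counts.items() if c >= min_support}
        if not supported:
            out.append("N")
            continue
        # highest summed quality; ties -> higher count, then alphabetical
        best = max(supported,
                   key=lambda ch: (qsums[ch], supported[ch], -ord(ch)))
        if supported[best] == max_letter:
            out.append(best)
        else:
            out.append("N")
    return "".join(out)


def strip_gaps(proto: str) -> str:
    """Remove all gap symbols from the proto-consensus."""
    return proto.replace(GAP, "")


def trim_polyN(seq: str) -> str:
    """Trim maximal runs of N from both ends; interior Ns are kept."""
    return seq.strip("N")


def polish(cons: Consensus, reads: list[PreparedRead]) -> Consensus:
    """Refine the consensus with medaka when the executable is available.

    Without medaka on PATH (or on polisher failure) the consensus passes
    through unchanged with ``polished=False``; the pipeline never aborts on
    the polisher.
    """
    if shutil.which("medaka_consensus") is None:
        logger.warning("medaka_consensus not found; consensus left unpolished")
        return cons
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        draft = tmp / "draft.fasta"
        fastq = tmp / "reads.fastq"
        draft.write_text(f">draft\n{cons.final_seq}\n")
        with open(fastq, "w") as fh:
            for r in reads:
                qual = "".join(chr(min(q, 93) + 33) for q in r.qual)
                fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")
        try:
            subprocess.run(["medaka_consensus", "-i", str(fastq), "-d", str(draft),
                            "-o", str(tmp / "out"), "-t", "1"],
                           capture_output=True, check=True)
            polished_fa = tmp / "out" / "consensus.fasta"
            seq = "".join(l.strip() for l in polished_fa.read_text().splitlines()
                          if not l.startswith(">"))
        except (subprocess.CalledProcessError, FileNotFoundError) as exc:
            logger.warning("medaka failed (%s); consensus left unpolished", exc)
            return cons
    return Consensus(cons.cluster_label, cons.proto, seq, cons.support,
                     polished=True, sample_id=cons.sample_id)


def build_consensus(reads: list[PreparedRead], cluster_label: int,
                    min_support: int = 3, trim_poly_n: bool = True,
                    do_polish: bool = False, use_mafft: bool = True,
                    sample_id: str = "pooled") -> Consensus:
    """Align a cluster's selected reads and produce its final OTU sequence."""
    aln = align_cluster(reads, use_mafft=use_mafft)
    proto = call_proto_consensus(aln, min_support=min_support)
    final = strip_gaps(proto)
    if trim_poly_n:
        final = trim_polyN(final)
    cons = Consensus(cluster_label=cluster_label, proto=proto, final_seq=final,
                     support=len(reads), sample_id=sample_id)
    if do_polish:
        cons = polish(cons, reads)
    return cons
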