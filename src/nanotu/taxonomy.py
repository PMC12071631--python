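"""Taxonomy assignment from blastn tabular hits.

OTU sequences are searched against a reference database (SILVA for 16S,
UNITE for ITS) with blastn; this module parses the tabular output
(``-outfmt "6 qseqid sseqid pident qcovs bitscore evalue stitle"``) and
keeps, per query, the best hit meeting both a query-coverage and an
identity threshold. Two presets are provided: ``lenient`` (coverage >= 60%,
identity >= 95%) and ``strict`` (coverage >= 98%, identity >= 97%).
Queries without a qualifying hit are reported as "Unclassified".

blastn itself is external: run it yourself or through :func:`run_blastn`.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path

logger = logging.getLogger(__name__)

UNCLASSIFIED = "Unclassified"

#: (min query coverage %, min identity %)
PRESETS = {
    "lenient": (60.0, 95.0),
    "strict": (98.0, 97.0),
}

OUTFMT = "6 qseqid sseqid pident qcovs bitscore evalue stitle"


@dataclass
class BlastHit:
    query_id: str
    subject_id: str
    percent_identity: float
    query_coverage: float
    bitscore: float
    evalue: float
    subject_taxonomy: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.percent_identity <= 100 and 0 <= self.query_coverage <= 100):
            raise ValueError("identity and coverage must lie in [0, 100]")


def parse_blast_tabular(path: str | Path) -> dict[str, list[BlastHit]]:
    """Parse BLAST outfmt-6 lines (qseqid sseqid pident qcovs bitscore evalue
    [stitle]); malformed lines are skipped with a warning."""
    hits: dict[str, list[BlastHit]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                hit = BlastHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    query_coverage=float(fields[3]),
                    bitscore=float(fields[4]),
                    evalue=float(fields[5]),
                    subject_taxonomy=fields[6] if len(fields) > 6 else fields[1],
                )
            except (IndexError, ValueError) as exc:
                logger.warning("skipping malformed BLAST line %d: %s", lineno, exc)
                continue
            hits.setdefault(hit.query_id, []).append(hit)
    return hits


def assign_taxonomy(hits: list[BlastHit], min_qcov: float = 60.0,
                    min_ident: float = 95.0) -> BlastHit | None:
    """Best qualifying hit for one query, or None (-> Unclassified).

    Qualifying means coverage >= min_qcov AND identity >= min_ident; among
    qualifiers the highest bitscore wins, ties broken by lowest e-value and
    then subject id, so the result is independent of input order.
    """
    qualifying = [h for h in hits
                  if h.query_coverage >= min_qcov and h.percent_identity >= min_ident]
    if not qualifying:
        return None
    return min(qualifying, key=lambda h: (-h.bitscore, h.evalue, h.subject_id))


def assign_all(hits_by_query: dict[str, list[BlastHit]], min_qcov: float = 60.0,
               min_ident: float = 95.0,
               query_ids: list[str] | None = None) -> dict[str, BlastHit | None]:
    """Assign every query; queries listed but absent from the hits are None."""
    queries = query_ids if query_ids is not None else list(hits_by_query)
    return {q: assign_taxonomy(hits_by_query.get(q, []), min_qcov, min_ident)
            for q in queries}


def write_taxonomy_table(assignments: dict[str, BlastHit | None], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("otu_id\ttaxonomy\tidentity\tcoverage\tbitscore\n")
        for otu_id, hit in assignments.items():
            if hit is None:
                fh.write(f"{otu_id}\t{UNCLASSIFIED}\t\t\t\n")
            else:
                fh.write(f"{otu_id}\t{hit.subject_taxonomy}\t{hit.percent_identity}"
                         f"\t{hit.query_coverage}\t{hit.bitscore}\n")


def run_blastn(query_fasta: str | Path, db: str, out_path: str | Path,
               evalue: float = 1e-10, threads: int = 1) -> Path:
    """Run external blastn with the expected tabular columns (optional helper)."""
    if shutil.which("blastn") is None:
        raise FileNotFoundError("blastn not found on PATH")
    out_path = Path(out_path)
    subprocess.run(
        ["blastn", "-query", str(query_fasta), "-db", db, "-out", str(out_path),
         "-outfmt", OUTFMT, "-evalue", str(evalue), "-num_threads", str(threads)],
        check=True)
    return out_path
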