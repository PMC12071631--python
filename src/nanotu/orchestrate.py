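"""End-to-end pipeline: read preparation -> features -> clustering -> consensus.

Two operational modes:

* **single** — every sample runs through the whole pipeline independently;
  each sample gets its own OTU set and abundance column.
* **pool** — reads from all samples are clustered jointly (sample provenance
  kept per read), one consensus per pooled cluster, then the per-sample
  composition is restored by counting each sample's reads in each cluster.
  Pooling lets low-abundance taxa that are too sparse in any one sample
  reach the clustering density threshold.

Relative abundances are computed over each sample's clustered (non-noise)
reads; noise reads are reported in the attrition log only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, consensus as consensus_mod, features, ioprep

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline knobs for one run."""

    amplicon: ioprep.AmpliconConfig
    mode: str = "single"
    k: int = 6
    seed: int = 42
    min_cluster_size: int | None = None
    min_support: int = 3
    n_pca_components: int = 30
    umap_n_neighbors: int = 15
    umap_min_dist: float = 0.1
    polish: bool = False
    trim_poly_n: bool = True
    use_mafft: bool = True
    output_dir: Path | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("single", "pool"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class AbundanceTable:
    """OTU x sample read counts with companion relative abundances."""

    counts: pd.DataFrame  # rows: otu ids, columns: sample ids

    @property
    def relative(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=0)
        rel = self.counts.div(totals.where(totals > 0, other=np.nan), axis=1)
        return rel.fillna(0.0)


@dataclass
class RunResult:
    """Everything one pipeline run produces."""

    consensuses: list[consensus_mod.Consensus]
    abundance: AbundanceTable
    attrition: dict[str, ioprep.AttritionLog]
    cluster_sets: dict[str, clustering.ClusterSet] = field(default_factory=dict)
    embeddings: dict[str, np.ndarray] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)


def _load_and_prepare(sample_id: str, fastq: Path, cfg: RunConfig):
    reads = ioprep.read_fastq(fastq, sample_id=sample_id)
    return ioprep.prepare_reads(reads, cfg.amplicon)


def _pipeline_one_batch(prepared: list[ioprep.PreparedRead], cfg: RunConfig,
                        scope: str):
    """Features -> clustering -> consensus for one batch of prepared reads.

    Returns (consensus list, ClusterSet, embedding, read_id -> label map);
    empty results when too few reads survive for clustering.
    """
    if len(prepared) < 2:
        logger.warning("%s: %d prepared reads; skipping clustering", scope, len(prepared))
        return [], None, None, {}
    fm = features.build_feature_matrix(prepared, k=cfg.k)
    if fm.n_reads < 2:
        logger.warning("%s: fewer than 2 reads after feature collection", scope)
        return [], None, None, {}
    by_id = {r.id: r for r in prepared}
    cs, coords = clustering.cluster_reads(
        fm.values, fm.read_ids, by_id, seed=cfg.seed,
        min_cluster_size=cfg.min_cluster_size, n_components=cfg.n_pca_components,
        n_neighbors=cfg.umap_n_neighbors, min_dist=cfg.umap_min_dist,
        min_support=cfg.min_support)
    consensuses = []
    for label in sorted(cs.clusters):
        selected = cs.selected.get(label, [])
        if len(selected) < cfg.min_support:
            continue
        cons = consensus_mod.build_consensus(
            [by_id[r] for r in selected], cluster_label=label,
            min_support=cfg.min_support, trim_poly_n=cfg.trim_poly_n,
            do_polish=cfg.polish, use_mafft=cfg.use_mafft, sample_id=scope)
        consensuses.append(cons)
    labels_by_read = dict(zip(cs.read_ids, (int(l) for l in cs.labels)))
    return consensuses, cs, coords, labels_by_read


def run_single(samples: dict[str, Path], cfg: RunConfig) -> RunResult:
    """Process every sample independently (single mode).

    OTU ids are namespaced per sample (``<sample>/otu_<label>``) so the
    abundance table can hold all samples; a failing or empty sample yields
    an empty column, not an abort.
    """
    result = RunResult([], AbundanceTable(pd.DataFrame()), {})
    columns: dict[str, dict[str, int]] = {}
    for sample_id, fastq in samples.items():
        try:
            prepared, log = _load_and_prepare(sample_id, Path(fastq), cfg)
        except (OSError, ValueError) as exc:
            logger.error("sample %s unreadable: %s", sample_id, exc)
            result.errors[sample_id] = str(exc)
            result.attrition[sample_id] = ioprep.AttritionLog()
            columns[sample_id] = {}
            continue
        result.attrition[sample_id] = log
        consensuses, cs, coords, labels = _pipeline_one_batch(prepared, cfg, sample_id)
        result.consensuses.extend(consensuses)
        if cs is not None:
            result.cluster_sets[sample_id] = cs
            result.embeddings[sample_id] = coords
        called = {c.cluster_label for c in consensuses}
        columns[sample_id] = {
            f"{sample_id}/otu_{label}": len(members)
            for label, members in (cs.clusters.items() if cs else {})
            if label in called}
    all_otus = sorted({otu for col in columns.values() for otu in col})
    counts = pd.DataFrame(0, index=all_otus, columns=list(samples), dtype=np.int64)
    for sample_id, col in columns.items():
        for otu, n in col.items():
            counts.loc[otu, sample_id] = n
    result.abundance = AbundanceTable(counts)
    return result


def run_pool(samples: dict[str, Path], cfg: RunConfig) -> RunResult:
    """Cluster all samples jointly, then restore per-sample composition.

    One feature matrix over every kept read (provenance retained per row),
    one clustering, one consensus per cluster; abundance cell (c, s) counts
    sample-s reads labelled c. Reads the joint clustering marks as noise are
    excluded from the composition.
    """
    result = RunResult([], AbundanceTable(pd.DataFrame()), {})
    prepared_all: list[ioprep.PreparedRead] = []
    for sample_id, fastq in samples.items():
        try:
            prepared, log = _load_and_prepare(sample_id, Path(fastq), cfg)
        except (OSError, ValueError) as exc:
            logger.error("sample %s unreadable: %s", sample_id, exc)
            result.errors[sample_id] = str(exc)
            result.attrition[sample_id] = ioprep.AttritionLog()
            continue
        result.attrition[sample_id] = log
        prepared_all.extend(prepared)
    ids = [r.id for r in prepared_all]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate read ids across pooled samples; pool mode "
                         "requires globally unique read ids")
    consensuses, cs, coords, labels = _pipeline_one_batch(prepared_all, cfg, "pooled")
    result.consensuses = consensuses
    if cs is not None:
        result.cluster_sets["pooled"] = cs
        result.embeddings["pooled"] = coords
    called = {c.cluster_label for c in consensuses}
    sample_of = {r.id: r.sample_id for r in prepared_all}
    otu_ids = [f"otu_{label}" for label in sorted(called)]
    counts = pd.DataFrame(0, index=otu_ids, columns=list(samples), dtype=np.int64)
    for rid, label in labels.items():
        if label >= 0 and label in called:
            counts.loc[f"otu_{label}", sample_of[rid]] += 1
    result.abundance = AbundanceTable(counts)
    return result


def run(samples: dict[str, Path], cfg: RunConfig) -> RunResult:
    """Dispatch on cfg.mode and, when cfg.output_dir is set, write outputs."""
    result = run_single(samples, cfg) if cfg.mode == "single" else run_pool(samples, cfg)
    if cfg.output_dir is not None:
        write_outputs(result, cfg, Path(cfg.output_dir))
    return result


# ---------------------------------------------------------------------------
# Output files
# ---------------------------------------------------------------------------

def write_outputs(result: RunResult, cfg: RunConfig, out_dir: Path) -> None:
    """Write otus.fasta, otu_table(.rel).tsv, attrition.tsv, clusters.tsv,
    run_config.json into ``out_dir``."""
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "otus.fasta", "w") as fh:
        for cons in result.consensuses:
            fh.write(f">otu_{cons.cluster_label} support={cons.support} "
                     f"sample={cons.sample_id}\n{cons.final_seq}\n")
    result.abundance.counts.rename_axis("otu_id").to_csv(out_dir / "otu_table.tsv", sep="\t")
    result.abundance.relative.rename_axis("otu_id").round(6).to_csv(
        out_dir / "otu_table_rel.tsv", sep="\t")
    with open(out_dir / "attrition.tsv", "w") as fh:
        fh.write("sample_id\tno_primer\tbad_quality\ttoo_short\ttoo_long\tkept\n")
        for sample_id, log in result.attrition.items():
            d = log.as_dict()
            fh.write(sample_id + "\t" + "\t".join(str(d[k]) for k in
                     ("no_primer", "bad_quality", "too_short", "too_long", "kept")) + "\n")
    with open(out_dir / "clusters.tsv", "w") as fh:
        fh.write("scope\tread_id\tcluster_label\tselected\tx\ty\n")
        for scope, cs in result.cluster_sets.items():
            coords = result.embeddings[scope]
            sel = {r for ids in cs.selected.values() for r in ids}
            for rid, lab, (x, y) in zip(cs.read_ids, cs.labels, coords):
                fh.write(f"{scope}\t{rid}\t{int(lab)}\t{int(rid in sel)}\t{x:.4f}\t{y:.4f}\n")
    cfg_dict = dataclasses.asdict(cfg)
    cfg_dict["amplicon"] = dataclasses.asdict(cfg.amplicon)
    cfg_dict["output_dir"] = str(cfg.output_dir)
    with open(out_dir / "run_config.json", "w") as fh:
        json.dump(cfg_dict, fh, indent=2)
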