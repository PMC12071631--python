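"""Shared fixtures: simulated communities and full pipeline runs.

The heavyweight pipeline runs (UMAP + HDBSCAN + MAFFT) are session-scoped so
unit and end-to-end tests share a single execution per scenario.
"""

from __future__ import annotations

import numpy as np
import pytest

import edlib

from nanotu.ioprep import AmpliconConfig
from nanotu.orchestrate import RunConfig, run_pool, run_single
from nanotu.simulator import (CommunitySpec, ErrorModel, divergent_templates,
                              simulate_dataset)

# 16S V3-V4 primer pair used throughout the simulations
PRIMER_F = "CCTACGGGNGGCWGCAG"
PRIMER_R = "GACTACHVGGGTATCTAATCC"


def template_of(read_id: str) -> str:
    """Ground-truth template name encoded in a simulated read id."""
    return read_id.split("|")[0].split(":", 1)[1]


def identity(a: str, b: str) -> float:
    """Global alignment identity between two sequences."""
    d = edlib.align(a, b, mode="NW")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def best_template(seq: str, templates: list[tuple[str, str]]) -> tuple[float, str]:
    return max((identity(seq, t), name) for name, t in templates)


def make_community(templates, proportions, n_reads, samples=("s1",), seed=11,
                   error_model=None, **kwargs) -> CommunitySpec:
    kwargs.setdefault("primer_f", PRIMER_F)
    kwargs.setdefault("primer_r", PRIMER_R)
    return CommunitySpec(
        templates=templates, proportions=list(proportions), n_reads=n_reads,
        samples=list(samples), seed=seed,
        error_model=error_model or ErrorModel(), **kwargs)


#: 5% total error (3:2:3 substitution:insertion:deletion split), the error
#: level used for the community-recovery experiments
ERROR_5PCT = ErrorModel(sub_rate=0.01875, ins_rate=0.0125, del_rate=0.01875)


@pytest.fixture(scope="session")
def three_template_setup(tmp_path_factory):
    """3 divergent 500-bp templates at 0.5/0.3/0.2, 600 reads at 5% error."""
    templates = divergent_templates(3, 500, seed=7)
    spec = make_community(templates, [0.5, 0.3, 0.2], 600, seed=11,
                          error_model=ERROR_5PCT)
    out = tmp_path_factory.mktemp("three_template")
    _, truths = simulate_dataset(spec, out_dir=out, gzip_output=False)
    amplicon = AmpliconConfig(PRIMER_F, PRIMER_R, min_len=350, max_len=600)
    return {"templates": templates, "spec": spec, "dir": out,
            "truth": truths["s1"], "amplicon": amplicon,
            "samples": {"s1": out / "s1.fastq"}}


@pytest.fixture(scope="session")
def three_template_single(three_template_setup):
    cfg = RunConfig(amplicon=three_template_setup["amplicon"], mode="single", seed=5)
    return run_single(three_template_setup["samples"], cfg)


@pytest.fixture(scope="session")
def three_template_pool(three_template_setup):
    """Pool-mode run on the same single sample (mode-consistency check)."""
    cfg = RunConfig(amplicon=three_template_setup["amplicon"], mode="pool", seed=5)
    return run_pool(three_template_setup["samples"], cfg)


@pytest.fixture(scope="session")
def short_template_setup(tmp_path_factory):
    """Same community design with 300-bp ITS1-like templates (short amplicons)."""
    templates = divergent_templates(3, 300, seed=17)
    spec = make_community(templates, [0.5, 0.3, 0.2], 600, seed=13,
                          error_model=ERROR_5PCT,
                          primer_f="GGAAGTAAAAGTCGTAACAAGG",
                          primer_r="GCTGCGTTCTTCATCGATGC")
    out = tmp_path_factory.mktemp("short_template")
    _, truths = simulate_dataset(spec, out_dir=out, gzip_output=False)
    amplicon = AmpliconConfig(spec.primer_f, spec.primer_r, min_len=100, max_len=500)
    return {"templates": templates, "spec": spec, "dir": out,
            "truth": truths["s1"], "amplicon": amplicon,
            "samples": {"s1": out / "s1.fastq"}}


@pytest.fixture(scope="session")
def short_template_single(short_template_setup):
    cfg = RunConfig(amplicon=short_template_setup["amplicon"], mode="single", seed=5)
    return run_single(short_template_setup["samples"], cfg)


@pytest.fixture(scope="session")
def minor_taxon_setup(tmp_path_factory):
    """3 major templates plus one at 2%, across 5 samples of 150 reads.

    Per-sample minor counts (~3 reads) sit below the clustering density
    threshold; pooled (~15 reads before attrition) they sit above it.
    """
    templates = divergent_templates(4, 450, seed=21)
    spec = make_community(templates, [0.40, 0.33, 0.25, 0.02], 150,
                          samples=[f"s{i}" for i in range(1, 6)], seed=9)
    out = tmp_path_factory.mktemp("minor_taxon")
    simulate_dataset(spec, out_dir=out, gzip_output=False)
    amplicon = AmpliconConfig(PRIMER_F, PRIMER_R, min_len=350, max_len=600)
    samples = {s: out / f"{s}.fastq" for s in spec.samples}
    return {"templates": templates, "spec": spec, "amplicon": amplicon,
            "samples": samples, "minor": templates[3]}


@pytest.fixture(scope="session")
def minor_taxon_single(minor_taxon_setup):
    cfg = RunConfig(amplicon=minor_taxon_setup["amplicon"], mode="single", seed=5)
    return run_single(minor_taxon_setup["samples"], cfg)


@pytest.fixture(scope="session")
def minor_taxon_pool(minor_taxon_setup):
    cfg = RunConfig(amplicon=minor_taxon_setup["amplicon"], mode="pool", seed=5)
    return run_pool(minor_taxon_setup["samples"], cfg)
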