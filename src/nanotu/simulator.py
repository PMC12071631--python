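"""Synthetic ONT-like amplicon datasets with known ground truth.

Emulates a multi-template amplicon community sequenced on a nanopore
instrument: each read is a template decorated with the primer pair, mutated
with per-base substitution/insertion/deletion errors (indel rates inflated
inside homopolymer runs, the platform's dominant failure mode), given a
per-base Phred quality string, and reverse-complemented with probability
``flip_prob`` to mimic random library orientation.

Two quality artefacts of real basecallers are reproduced: (i) a configurable
fraction of positions is clamped to exactly Q90 (a reduced-precision cap in
the basecaller output), and (ii) erroneous bases (substituted or inserted)
draw their quality from a lower-mean distribution than correct bases, since
basecaller confidence drops at miscalled positions.

Read identifiers encode the source template and realised edit counts so
every downstream stage can be scored against ground truth.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ioprep import RawRead, revcomp

_BASES = np.array(list("ACGT"))


@dataclass
class ErrorModel:
    """Per-base error and quality model for simulated reads.

    Rates are per template base; indel rates are multiplied by
    ``homopolymer_multiplier`` inside homopolymer runs of length >= 3.
    Correct bases draw Phred scores from N(mean_q, sd_q); error bases from
    N(error_mean_q, sd_q); ``q_cap_prob`` of positions are overwritten with
    exactly ``q_cap`` (the basecaller precision artefact).
    """

    sub_rate: float = 0.03
    ins_rate: float = 0.02
    del_rate: float = 0.03
    homopolymer_multiplier: float = 2.0
    mean_q: float = 22.0
    sd_q: float = 5.0
    error_mean_q: float = 10.0
    q_cap: int = 90
    q_cap_prob: float = 0.005

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0 <= r < 1:
                raise ValueError("error rates must lie in [0, 1)")


@dataclass
class CommunitySpec:
    """A mock community: templates, proportions, samples and error model."""

    templates: list[tuple[str, str]]
    proportions: list[float]
    n_reads: int
    samples: list[str] = field(default_factory=lambda: ["sample1"])
    error_model: ErrorModel = field(default_factory=ErrorModel)
    primer_f: str = "CCTACGGGNGGCWGCAG"     # 16S V3-V4 forward
    primer_r: str = "GACTACHVGGGTATCTAATCC"  # 16S V3-V4 reverse
    flip_prob: float = 0.5
    seed: int = 42

    def __post_init__(self) -> None:
        if len(self.templates) != len(self.proportions):
            raise ValueError("one proportion per template required")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        if any(set(seq) - set("ACGT") for _, seq in self.templates):
            raise ValueError("templates must be plain ACGT")


def _homopolymer_mask(seq: str, min_run: int = 3) -> np.ndarray:
    """True at positions inside a homopolymer run of length >= min_run."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    mask = np.zeros(len(arr), dtype=bool)
    i = 0
    while i < len(arr):
        j = i
        while j < len(arr) and arr[j] == arr[i]:
            j += 1
        if j - i >= min_run:
            mask[i:j] = True
        i = j
    return mask


def _resolve_iupac(primer: str, rng: np.random.Generator) -> str:
    """Replace degenerate codes with a concrete base (what a synthesised
    primer pool delivers to any one molecule)."""
    from .ioprep import IUPAC

    return "".join(b if b in "ACGT" else rng.choice(list(IUPAC[b])) for b in primer)


def simulate_read(template_name: str, template: str, spec: CommunitySpec,
                  rng: np.random.Generator, read_index: int = 0,
                  sample_id: str = "sample1") -> RawRead:
    """Simulate one read: decorate with primers, mutate, assign qualities, flip.

    The read id is
    ``<sample>:<template>|<index>|sub=<n>;ins=<n>;del=<n>|flip=<0/1>``;
    the sample prefix keeps ids unique when samples are pooled.
    """
    em = spec.error_model
    molecule = _resolve_iupac(spec.primer_f, rng) + template + revcomp(_resolve_iupac(spec.primer_r, rng))
    hp = _homopolymer_mask(molecule)
    n = len(molecule)

    ins_rates = np.where(hp, em.ins_rate * em.homopolymer_multiplier, em.ins_rate).clip(0, 0.95)
    del_rates = np.where(hp, em.del_rate * em.homopolymer_multiplier, em.del_rate).clip(0, 0.95)
    u_sub = rng.random(n)
    u_ins = rng.random(n)
    u_del = rng.random(n)

    out_bases: list[str] = []
    is_error: list[bool] = []
    n_sub = n_ins = n_del = 0
    for i, base in enumerate(molecule):
        if u_ins[i] < ins_rates[i]:
            out_bases.append(str(rng.choice(_BASES)))
            is_error.append(True)
            n_ins += 1
        if u_del[i] < del_rates[i]:
            n_del += 1
            continue
        if u_sub[i] < em.sub_rate:
            alt = str(rng.choice(_BASES[_BASES != base]))
            out_bases.append(alt)
            is_error.append(True)
            n_sub += 1
        else:
            out_bases.append(base)
            is_error.append(False)

    seq = "".join(out_bases)
    err = np.array(is_error)
    qual = rng.normal(em.mean_q, em.sd_q, size=len(seq))
    qual[err] = rng.normal(em.error_mean_q, em.sd_q / 2, size=int(err.sum()))
    qual = np.clip(np.rint(qual), 1, 60).astype(np.int16)
    capped = rng.random(len(seq)) < em.q_cap_prob
    qual[capped] = em.q_cap

    flipped = rng.random() < spec.flip_prob
    if flipped:
        seq = revcomp(seq)
        qual = qual[::-1].copy()

    rid = (f"{sample_id}:{template_name}|{read_index}"
           f"|sub={n_sub};ins={n_ins};del={n_del}|flip={int(flipped)}")
    return RawRead(id=rid, seq=seq, qual=qual, sample_id=sample_id)


def simulate_sample(spec: CommunitySpec, sample_id: str,
                    rng: np.random.Generator) -> tuple[list[RawRead], dict[str, str]]:
    """Simulate one sample; returns reads plus a read_id -> template map."""
    counts = rng.multinomial(spec.n_reads, spec.proportions)
    reads: list[RawRead] = []
    truth: dict[str, str] = {}
    idx = 0
    for (name, template), k in zip(spec.templates, counts):
        for _ in range(k):
            read = simulate_read(name, template, spec, rng, read_index=idx,
                                 sample_id=sample_id)
            reads.append(read)
            truth[read.id] = name
            idx += 1
    # shuffle so template blocks are not contiguous in the FASTQ
    order = rng.permutation(len(reads))
    return [reads[i] for i in order], truth


def simulate_dataset(spec: CommunitySpec, out_dir: str | Path | None = None,
                     gzip_output: bool = True) -> tuple[dict[str, list[RawRead]], dict[str, dict[str, str]]]:
    """Simulate every sample in the spec; optionally write FASTQ + truth TSV.

    Per-sample read counts per template are multinomial draws with the spec
    proportions. A fixed spec.seed gives byte-identical output; each sample
    uses an independent child RNG stream so samples are distinct but
    individually reproducible.
    """
    root = np.random.default_rng(spec.seed)
    children = root.spawn(len(spec.samples))
    samples: dict[str, list[RawRead]] = {}
    truths: dict[str, dict[str, str]] = {}
    for sample_id, child in zip(spec.samples, children):
        reads, truth = simulate_sample(spec, sample_id, child)
        samples[sample_id] = reads
        truths[sample_id] = truth
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sample_id, reads in samples.items():
            suffix = ".fastq.gz" if gzip_output else ".fastq"
            path = out_dir / f"{sample_id}{suffix}"
            opener = gzip.open if gzip_output else open
            with opener(path, "wt") as fh:
                for r in reads:
                    q = "".join(chr(min(int(x), 93) + 33) for x in r.qual)
                    fh.write(f"@{r.id}\n{r.seq}\n+\n{q}\n")
        with open(out_dir / "truth.tsv", "w") as fh:
            fh.write("sample_id\tread_id\ttemplate\n")
            for sample_id, truth in truths.items():
                for rid, name in truth.items():
                    fh.write(f"{sample_id}\t{rid}\t{name}\n")
        with open(out_dir / "templates.fasta", "w") as fh:
            for name, seq in spec.templates:
                fh.write(f">{name}\n{seq}\n")
    return samples, truths


def random_template(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    """A random DNA template with the given length and expected GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def divergent_templates(n: int, length: int, seed: int = 0,
                        max_identity: float = 0.90) -> list[tuple[str, str]]:
    """Generate n random templates with pairwise identity below max_identity.

    Independent uniform-random sequences sit near 25% identity, far below
    any realistic threshold, so rejection is rare; identity is still checked
    via global edit distance for safety.
    """
    import edlib

    rng = np.random.default_rng(seed)
    templates: list[tuple[str, str]] = []
    attempts = 0
    while len(templates) < n:
        attempts += 1
        if attempts > 100 * n:
            raise RuntimeError("could not generate sufficiently divergent templates")
        cand = random_template(length, rng)
        ok = True
        for _, existing in templates:
            dist = edlib.align(cand, existing, mode="NW")["editDistance"]
            ident = 1 - dist / max(len(cand), len(existing))
            if ident >= max_identity:
                ok = False
                break
        if ok:
            templates.append((f"template{len(templates) + 1}", cand))
    return templates
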