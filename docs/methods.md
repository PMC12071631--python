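# Methods

`nanotu` assembles OTU (operational taxonomic unit) consensus sequences from
demultiplexed, barcode-trimmed Oxford Nanopore amplicon reads. This note
documents the model behind each stage, the parameters that matter, the
numerical choices, and what the simulation-based tests do and do not show.

## Read preparation

Each read must contain the forward primer near its 5' end and the reverse
complement of the reverse primer near its 3' end (in plus orientation).
Matching is semi-global edit-distance alignment (edlib) with IUPAC
degeneracy honoured on both sides, with an edit budget of
`primer_error_rate × primer_length` per primer (default rate 0.1, the
conventional tolerance for primer trimming). Both strands are tried; a read
matching on the reverse strand is reverse-complemented (and its quality
string reversed) so all surviving reads are plus-oriented, and both primer
spans are trimmed. A read lacking either primer at this tolerance is
rejected outright: requiring both anchors is what guarantees the insert
boundaries are known, and single-primer reads are usually truncations or
chimeric fragments. If a forward primer sits more than 30 bp from the read
end a warning is logged, since that pattern indicates untrimmed barcodes or
adapters; the tool deliberately does not attempt automatic adapter
detection.

Quality filtering uses the **median Phred score with Q90 positions
excluded**. Some basecallers emit per-base qualities clamped at Q90 (a
reduced-precision saturation artifact, not a real confidence), and a read
peppered with such positions would pass a naive median. The default
threshold is Q20, inclusive. If *every* position in a read sits at the cap
the full-vector median is used; such reads are pathological and the
fallback simply avoids dividing by an empty set. Length filtering keeps
reads within the expected insert window for the target region; typical
windows are 350–600 bp (16S V3–V4), 900–1600 bp (16S V1–V9), 100–500 bp
(ITS1/ITS2) and 300–1200 bp (full ITS1-5.8S-ITS2). Every input read is
accounted for exactly once in the attrition log
(no_primer / bad_quality / too_short / too_long / kept).

## Feature collection

ONT's dominant systematic error is homopolymer length miscounting, which
would scatter reads of one template across k-mer space. Each read is
therefore run-length compressed (`GTTTTGGT → GTGT`) **only for feature
collection** — consensus building always uses the raw bases. Compressed
reads are converted into k-mer signatures: counts of all 4^k words in
lexicographic order (default k = 6, i.e. 4096 columns; adjustable).
Windows containing an ambiguous base are skipped rather than imputed, and a
read whose compressed length falls below k is dropped with a warning.
Reverse-complement k-mers are *not* collapsed: reads are already
plus-oriented, so canonicalisation would only discard strand-consistent
signal.

K-mer counts are compositional (they scale with read length), so the count
matrix is centred log-ratio transformed row-wise, with a +1 pseudocount to
keep the zero-heavy 4096-dimensional rows finite: x → ln((x+1)/g(x+1)),
g the geometric mean. Every CLR row sums to zero; whether counts are first
normalised to frequencies is immaterial because CLR removes per-row
scaling.

## Clustering

The CLR matrix is reduced by PCA to 30 components (noise suppression and
speed; the effective dimension is min(30, N, 4^k)), then embedded into 2-D
with UMAP (Euclidean metric, `n_neighbors=15`, `min_dist=0.1` — library
defaults, both exposed). A fixed `random_state` makes the embedding
deterministic; the whole PCA→UMAP→HDBSCAN chain is reproducible
bit-for-bit given the input and seed. Standard UMAP is used as the
embedding backend; it satisfies the determinism and shape contracts the
pipeline needs without a deep-learning dependency.

HDBSCAN (scikit-learn implementation) clusters the 2-D embedding with
Euclidean distances. `min_cluster_size` defaults to max(5, 0.1% of reads)
and is exposed as a flag. `allow_single_cluster` is enabled: an amplicon
sample containing a single taxon must come back as one cluster, and the
default excess-of-mass rule would otherwise label the lone cluster as
noise. The trade-off is that structureless garbage input may return one
diffuse cluster rather than pure noise; the per-cluster read selection and
the 3-read consensus floor bound the damage. When `min_cluster_size`
exceeds the number of points, everything is noise by construction. A fully
degenerate input (all feature rows identical, e.g. error-free duplicates)
short-circuits to a single cluster, since UMAP would scatter
indistinguishable points arbitrarily. Cluster labels are renumbered by
decreasing size; −1 is noise. Noise reads join no consensus and no
abundance count.

Within each cluster, reads feeding the consensus are restricted to those
within **±10 bp of the cluster's mean length** and **±2 population standard
deviations of the cluster's mean GC fraction**, both computed over the
cluster's own (uncompressed) members — this removes chimeras, hard-clipped
reads and residual mis-clustered reads before alignment. μ is the
arithmetic mean. A cluster whose selection drops below 3 reads is skipped
with a warning.

## Consensus building

Selected reads are multiple-aligned with MAFFT (default parameters, chosen
for speed) when the binary is on PATH; otherwise an internal centre-star
aligner (pairwise edlib alignments to the median-length read, merged under
once-a-gap-always-a-gap) provides the same contract: degapping row i
reproduces read i, and per-base qualities are carried to aligned
coordinates.

The proto-consensus is called per column:

1. if the gap is the **strict plurality** symbol, emit `-`;
2. otherwise, among letters supported by ≥ `min_support` (default 3)
   reads, the letter with the highest **total quality mass** (summed Phred
   over its supporting reads — equivalently its average quality over all
   reads in the column) wins, provided it is also the (tied-)most frequent
   letter;
3. if a less frequent supported letter carries more quality mass than the
   most frequent one (e.g. 4 reads at Q12 = 48 against 3 reads at Q30 =
   90), the evidence is contradictory and `N` is emitted;
4. if no letter reaches `min_support`, `N` is emitted.

Two choices here are deliberate. A plurality *tie* between gap and letter
goes to the letter: deletions are ONT's dominant error mode, so the caller
is biased against over-deletion. And letters are scored by summed rather
than per-supporting-read mean quality: real multiple alignments of noisy
long reads always contain a few misplaced high-quality bases per column
(alignment jitter around indels), and a mean-based score would let three
such bases outvote dozens of concordant ones — in our simulations that
single change moves consensus identity from ~93% to >99.9%. Quality-mass
ties break by higher count, then alphabetically, so the call is
deterministic and invariant to row order.

Gaps are stripped from the proto-consensus; terminal poly-N runs (typical
of untrimmed, low-quality read ends) are trimmed by default (`--no-trim-polyn`
disables). Medaka, when installed, can polish the final sequence
(`--polish`); it is invoked as an external executable and the pipeline
passes the consensus through unchanged (with a warning) when it is missing
or fails. No test or default depends on it.

## Single and pool modes

*Single* mode runs every sample through the whole pipeline independently.
*Pool* mode builds one feature matrix over all samples' kept reads,
clusters jointly, calls one consensus per pooled cluster, and restores the
per-sample composition by counting each sample's reads per cluster. Pooling
is the right tool when per-sample depth is too low for a taxon to reach
`min_cluster_size` on its own — a taxon at 2% of 150 reads (~3 reads) is
invisible per sample but clusters cleanly at ~15 pooled reads. Reads the
joint clustering marks as noise are excluded from the restored composition.
Relative abundances are computed over each sample's clustered (non-noise)
reads; attrition and noise counts are reported separately so the
denominator is auditable. Pool mode requires globally unique read ids and
fails loudly on duplicates rather than miscounting. On a single sample,
pool and single mode produce identical results for the same seed.

## Taxonomy

OTU sequences are annotated by an external blastn search against a
reference database (e.g. SILVA for 16S, UNITE for ITS); the package parses
the tabular output and keeps, per query, the best hit meeting both a query
coverage and an identity threshold — `lenient` (≥60% / ≥95%) for general
profiling, `strict` (≥98% / ≥97%) for near-exact matching. Best = highest
bitscore, ties broken by e-value then subject id, so assignment is
independent of hit order. Queries with no qualifying hit are
`Unclassified`. Purpose-built classifiers (IDTAXA, MAPSeq, QIIME, SPINGO)
are recommended for serious taxonomic work; this module is a convenience.

## The simulator

The bundled generator emulates a multi-template amplicon community:
per-sample template counts are multinomial in the specified proportions;
each read is primer-decorated (degenerate positions resolved per molecule),
mutated with per-base substitution/insertion/deletion errors, and
reverse-complemented with probability 0.5. Defaults are substitution 0.03,
insertion 0.02, deletion 0.03 (8% total, representative of Guppy-era ONT
reads), with indel rates doubled inside homopolymer runs of length ≥3. Two
basecaller quality artefacts are reproduced: 0.5% of positions are clamped
to exactly Q90, and erroneous bases draw their quality from a lower-mean
distribution (Q≈10 vs Q≈22 for correct bases), reflecting the drop in
basecaller confidence at miscalled positions. Read ids encode sample,
template and realised edit counts, so every stage can be scored against
ground truth. Fixed seeds give byte-identical FASTQ; each sample uses an
independent child RNG stream.

What the simulator does **not** model: signal-level (squiggle) behaviour,
sequence-context-dependent error hotspots beyond homopolymers, chimeras,
barcode cross-talk, or any specific flowcell/basecaller error profile.
Passing tests on simulated data therefore demonstrate the pipeline's
internal correctness and its behaviour under realistic error *rates*, not
performance on any particular real run.

## Problem sizes in the test and acceptance workloads

The simulation experiments use 600-read communities (3 templates at
0.5/0.3/0.2, 500 bp or 300 bp), 100–200-read consensus clusters, and a
5×150-read multi-sample design with a 2% minor taxon; community-recovery
runs use a 5% total error model (3:2:3 sub:ins:del), consensus-accuracy
runs the full 8% default. These sizes give stable clustering and tight
multinomial noise (±0.05 abundance tolerance ≈ 2.2σ at n=600) while keeping
a full run in minutes on one CPU.

## Known limitations

- HDBSCAN with `allow_single_cluster` may return one diffuse cluster on
  structureless input instead of all-noise.
- Consensus columns with genuinely contradictory quality evidence become
  `N` rather than forcing a base call; downstream identity is conservative.
- The centre-star fallback aligner is O(n·L²) per cluster and coarser than
  MAFFT near tandem repeats; MAFFT is strongly recommended.
- Abundances are relative to clustered reads; taxa whose reads are mostly
  labelled noise are under-represented. The attrition log exposes this.
- Primer-based orientation discards reads with a damaged primer on either
  end (~15% at 5% read error, more at higher error rates); this attrition
  is unbiased across templates but reduces effective depth.
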