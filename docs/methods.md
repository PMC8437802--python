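# Methods

## Model and procedure

piRNA clusters are detected as runs of fixed genomic windows whose small-RNA
output collapses in a biogenesis knockout. The unit of signal is the
fractional count: each alignment of a read with `n_hits` genomic alignments
contributes `1/n_hits` to the window containing its 5′-most aligned base
(left edge on "+", right edge on "−"). Assignment by 5′-end containment
rather than overlap splitting is deliberate: reads (≤ 32 nt) are tiny
relative to 1-kb windows, and a containment rule is deterministic and never
double-counts. `n_hits` is trusted from the aligner (NH tag or the tabular
column) rather than recomputed, because a region-subset file no longer
contains all of a read's alignments.

Counts are normalised per sample to RPM, using the number of distinct
19–32-nt reads as the library size, then to RPKM using the window's
*effective length* — its length minus overlap with assembly N-runs. Windows
with zero effective length are dropped; the last, possibly short, window of
each chromosome is kept and handled by the same length normalisation.
Windows below 1 RPKM are removed before classification; the filter is
evaluated on the wild-type samples only (`any_sample` rule), because the
point of the subsequent KO/WT contrast is signal *loss* in the knockout and
a knockout-evaluated filter would delete exactly the windows of interest.
Both the rule and the sample subset are exposed as arguments.

Classification uses the log₂ fold change of knockout over wild-type RPKM,
replicates averaged per genotype × time point, with a pseudocount of
0.01 RPKM added to numerator and denominator. The pseudocount keeps
knockout-zero windows finite (a wild-type-expressed, knockout-silent window
must classify as "lower than −2") while shifting fold changes of expressed
windows by at most log₂((x+p)/x) of the smaller input — negligible above
~0.1 RPKM. Rules, with strict inequalities exactly as worded in the
procedure this reimplements:

- pre-pachytene: log₂FC(9 dpp) < −2 **and** log₂FC(13 dpp) < −2;
- pachytene: log₂FC(21 dpp) < −2 **and** log₂FC(13 dpp) > −2;
- a window at exactly −2 satisfies neither branch.

Adjacent (end == next start) same-stage windows merge into clusters; windows
separated by a filtered-out window do not merge at this step. Clusters of
the same stage at most 2 kb apart (inclusive) merge transitively into
superclusters; mixed-stage merging is forbidden. RPM/RPKM are then
recomputed over each merged interval from the reads, and the wild-type
piRNA density — RPM per gap-corrected kb, averaged over the stage's defining
time points (9 and 13 dpp for pre-pachytene, 21 dpp for pachytene) — must
strictly exceed 10 RPM/kb (pre-pachytene) or 100 RPM/kb (pachytene).
Whether the pachytene "100" is per kb or per cluster is ambiguous in the
source procedure; per-kb is the default and a `per_cluster` mode is
provided. The original workflow included a manual curation pass; that is
reproduced as declarative include/exclude lists of cluster ids, never
interactively.

The oocyte variant seeds windows from PIWIL1/PIWIL3 IP libraries: the same
tiling, fractional counting, RPM/RPKM and RPKM ≥ 1 step (passing in either
IP), then supercluster merging, then retention filters with *inclusive*
bounds ("a minimum of 10 RPM"): PIWIL1 or PIWIL3 cluster RPM ≥ 10, and mean
wild-type oocyte RPM of combined 18–20-nt + 24–32-nt reads ≥ 10, the
21–23-nt miRNA/siRNA-rich population excluded.

Read-level statistics count each read once regardless of multiplicity
(deduplicated by read id). miRNA scaling equalises miRNA RPM across
genotypes: factor = mean(WT miRNA RPM) / KO miRNA RPM, where the miRNA count
comes from overlap with a miRNA annotation when provided, else the 21–23-nt
size class as a proxy. The 1U/10A signature is computed from logo-eligible
reads (primary alignment, unclipped 5′ end, 25–31 nt, 5′ end inside a
cluster; all clusters pooled by default, a per-stage option exists) as a
position frequency matrix indexed from the 5′ end (position 1 = first
nucleotide); N bases are excluded from the per-position denominator.

TE group expression counts a read once per group that any of its alignments
overlaps by ≥ 1 bp — "once per read" plainly addresses within-group
multimapping; cross-group behaviour is unstated in the source procedure, so
per-group multi-assignment is the default and a `unique_global` mode
(assign to the group with most overlapped alignments, ties lexicographic)
is provided. No minimum overlap fraction is imposed (reads are far smaller
than insertions). "Perfectly mapping" in the antisense FLI profiles means
zero mismatches to the genome. Divergence summaries use linear-interpolation
quantiles (the numpy/R default) with whiskers at the most extreme points
within 1.5×IQR of the box; milliDiv is reported as percent.

## The synthetic-data generator

`simulate.SimulationConfig` emits complete studies: a genome with N-run
gaps, a RepeatMasker-style TE annotation with an FLI subset, miRNA loci, and
per-sample sorted alignment tables with truth files and a self-audit.
Libraries are compositional: expression is specified in RPM of 19–32-nt
reads, component counts are Poisson around `rpm × depth / 1e6`, and — unless
`mirna_rpm` is set — a 21–23-nt miRNA population fills the library to
~10⁶ RPM. The filler makes planted RPMs self-consistent and reproduces the
real phenomenon that knockout libraries become relatively miRNA-rich once
piRNAs are gone, which is what makes cross-genotype miRNA scaling
meaningful. Cluster reads carry sequences with exact planted P(U at 1) and
P(A at 10); multimappers emit `n_hits` alignment records (secondaries
non-primary) within their own cluster, or across insertions of their own
subfamily for TE reads. Determinism: one seeded generator for genome
structure and one per library (keyed by seed and the sorted sample index),
with draw order fixed by sorted element lists, so repeated runs are
byte-identical.

The default `hamster_like` configuration is 2 chromosomes × 1 Mb, 2% gaps,
six planted clusters — three pre-pachytene (800–1200 RPM/kb), two pachytene
(4000–5000 RPM/kb), one pre-pachytene decoy at 2 RPM/kb that classifies but
fails the density filter — and four TE subfamilies whose knockout sense-read
upregulation is planted at 20× (MYSERV6), 3.3× (MYSERV), 2× (IAP) and 1.5×
(L1), echoing the magnitudes this kind of study reports; divergence means
differ per subfamily so the boxplot summaries separate young from old
elements. The design is WT/KO × {9, 13, 21 dpp} × 2 replicates at an
expected 200,000 in-range reads per library — scaled so every classification
branch is exercised with stable counting statistics while a full study
simulates in tens of seconds. `oocyte_like` is the IP-seeded analogue with
two supra-threshold oocyte clusters and one weak one.

Two deliberate idealisations, and what they imply:

- The default configuration is **noiseless**: no genome-wide background
  reads (`background_rpm = 0`) and knockout cluster retention 0. Planted
  clusters are therefore recoverable *exactly*, which is what the end-to-end
  tests assert. Background emission exists (and is used in tests) to
  exercise the RPKM < 1 filter, but any Poisson background makes
  boundary-window false merges possible, so exactness claims hold only for
  the noiseless configuration. Real data are not noiseless; on real
  libraries the density and RPKM filters do the probabilistic work that the
  tests here can check only at boundaries.
- Knockout libraries keep TE **antisense** reads at wild-type levels and
  upregulate only sense reads. In a real knockout, TE-antisense piRNAs are
  lost too; the generator routes all knockout piRNA loss through the planted
  clusters so that TE windows are fold-change-neutral-or-up and cannot
  contaminate cluster calls. Passing tests therefore demonstrate the
  classification logic, not robustness to TE-piRNA loss outside annotated
  clusters.

The generator does not simulate sequence-level mapping error, UMI
structure, or bisulfite data; mismatch counts are planted labels, not
realigned differences.

## Numerical choices

- Pseudocounts: 0.01 RPKM in cluster fold changes; 0.1 RPM in TE ranking
  (kept finite and flagged `wt_zero` when the wild type is silent).
- Quantiles: linear interpolation between order statistics, so tests can
  compare against `numpy.percentile` directly.
- Ties in TE ranking: fold change desc, then KO RPM desc, then group name.
- Degenerate inputs: empty chrom.sizes → empty genome with a warning;
  fully-gapped windows/clusters dropped with a log message; zero library
  totals and zero miRNA counts are errors (no silent division).
- Tolerances asserted in tests: conservation identities to 1e-9 relative;
  planted-probability recovery within 3 binomial standard deviations;
  everything rule-shaped (boundaries, merging, recovery) exact.

## Known limitations

Window tables are dense in memory (windows × samples), fine for desk-scale
and single-genome work, not tuned for many large genomes at once. The
interval machinery sweeps vectorised masks per insertion and falls back to
an interval tree for very large annotations, but no BAM random access or
chunked streaming is implemented. The oocyte IP path assumes both IP window
tables share one tiling and errors otherwise. Cross-library batch effects,
adapter artefacts and UMI duplicates are upstream concerns and out of scope.
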