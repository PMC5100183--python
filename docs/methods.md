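# Methods

This note documents the models, conventions and numerical choices behind
`tedyn`, in the spirit of a statistical-software methods appendix. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Overlap alignment and read clustering

Reads are compared with an exact free-end-gap ("overlap") dynamic program.
Scoring is match +1, mismatch 0, gap −1, with deterministic tie-breaking
(diagonal > up > left; the end cell is chosen by score, then matches, then
fewest columns). The gap score matters: with a gap score of 0 the optimum
degenerates to a longest-common-subsequence alignment — a gap+match detour
(+1) always beats a mismatch (0) — which dilutes identity with spurious gap
columns. With gap −1 a detour is never preferred to a mismatch, so on
substitution-only data the optimal alignment is the best ungapped overlap,
which is what the identity thresholds assume. Identity is
matches / alignment columns, gap columns counting as mismatches; `N` never
matches. The reported overlap length is the shorter read span inside the
aligned region, so it cannot exceed either read length. Arguments are
canonicalized (shorter/lexicographically smaller sequence first) so
acceptance is exactly symmetric.

A pair is an edge when overlap length ≥ `min_overlap_frac` × (shorter read)
and identity ≥ `min_identity` (defaults 0.55 and 0.90; the 55 % criterion is
interpreted relative to the shorter read). Clusters are connected components
with ≥ 2 reads. Components are deliberately used instead of graph community
detection: the thresholds define edge admission only, and components are the
simplest consistent clustering rule. Cluster IDs are assigned by descending
read count, ties broken by the lexicographically smallest member read.

**k-mer prefilter.** Before alignment, pairs are screened for a shared exact
8-mer (forward or reverse-complement). This is lossless at the default
thresholds: an accepted alignment has ≥ 69 columns (0.55 × 125) of which at
most ⌊0.1·C⌋ are non-matches, so its longest run of consecutive matched
columns is at least (C − ⌊0.1·C⌋)/(⌊0.1·C⌋ + 1) ≥ 8 over the admissible
range of C — a shared 8-mer. A 16-mer screen would *not* be lossless (the
minimum guaranteed run is 8), hence the smaller k. Tests verify
prefiltered and exhaustive clustering agree exactly.

**Abundance filtering.** Chloroplast-annotated clusters are removed first;
the ≥ 0.2 % read-fraction threshold (inclusive) is then applied against
nuclear reads, i.e. the denominator excludes chloroplast-cluster reads.
Clusters with identical full annotation lineage are merged (bases and
fractions summed; `n_members` preserves per-annotation cluster counts).
The DP inner loops are numba-jitted; a plain-Python transcription of the
same recurrence serves as the test oracle.

## Genome occupancy

Occupancy is computed from read-base *fractions* scaled by the monoploid
genome size: Mb = (cluster bases / total bases) × G with G = 865 Mb, and
%genome = Mb/G × 100. This is the only reading under which a 27.35 %
read-base fraction equals 236.6 Mb; raw read-base sums would depend on
sequencing depth. Report rounding is 2 decimals for Mb and % (1-decimal
style available). The G-test uses the plain likelihood-ratio chi-square
(`scipy.stats.chi2_contingency`, `lambda_="log-likelihood"`) without Yates
or Williams corrections; an all-zero row or column raises an error naming
the offender.

## Cluster-age classification

Pairwise identities of a cluster (same acceptance criteria as clustering, so
the similarity-graph edge identities are exactly the all-vs-all accepted
pairs) are binned on [0.90, 1.00] with bin width 0.001 — matching the 0.1 %
precision at which identity peaks are typically reported — left-closed
right-open, last bin closed, frequencies normalized to sum 1. X is identity
as a fraction and Y relative frequency; whether one fits counts or
frequencies, percent or fraction X, is a convention the source method leaves
open, so both scales are exposed (`bin_width`, and normalization is linear,
so the category is invariant to rescaling raw counts — tested).

Both models are fitted to all bins by OLS (`numpy.linalg.lstsq`; an
explicit normal-equations solve is the test oracle, agreement to 1e-8).
BIC = n ln(RSS/n) + k ln(n) with k = 2 or 3; RSS is floored at 1e-12 for
degenerate exact fits; a BIC tie (within 1e-12) prefers the linear model by
parsimony. Categories: linear winner → 1 / 2 / 3 by b against ±`b_tol`
(0.001 on the normalized scale); quadratic winner → 4 if c > 0, else 6 if
the optimum −b/(2c) exceeds `optimum_cut` (0.99) and 5 otherwise. The
original description phrases curvature as "b² > 0 / b² < 0"; since a literal
square cannot be negative, this is read as the sign of the quadratic
coefficient c. A quadratic winner with c = 0 exactly falls back to the
linear rules. Clusters with fewer than `min_pairs` (20) in-window
identities are reported unclassified rather than forced into a category.

## Synthetic data

The generator defines the study conditions the tests exercise.

* **Genome/reads.** Each family is a random consensus; each copy applies
  i.i.d. substitutions at per-copy rate d (uniform over the three other
  bases), so two copies share per-site identity (1−d)² + d²/3 ≈ 1 − 2d —
  d is the age proxy. No indels, so pairwise identity stays analytically
  checkable and matches the substitution-only assumption of the aligner
  scoring. Reads are uniform 125 bp substrings, reverse-complemented with
  probability 0.5, drawn from background-plus-copies with probability
  proportional to valid start positions; truth labels are emitted for every
  read. Defaults: 5 accessions, 800 reads each (a scaled-down stand-in for
  millions of reads per accession), 60 kb unique background, nine families
  spanning young high-copy LTR families (one with clade-structured copy
  number), an older diverged Gypsy family, DNA transposons, a LINE, rDNA, a
  tandem repeat, a low-copy/high-expression outlier family, and a
  chloroplast contaminant for the exclusion path.
* **Expression.** RNA ~ Poisson(rate × DNA count) per cluster and
  accession; outlier families are simply low-copy specs with a high rate.
* **Methylation.** Per locus and accession a proportion is drawn from
  clearly bimodal bands (low U(0.02, 0.12), high U(0.88, 0.98),
  intermediate U(0.40, 0.60) for planted shifts); coverage ~
  Poisson(`coverage_mean`) truncated to ≥ 1 (avoiding undefined
  proportions), methylated ~ Binomial(coverage, p). Planted true loci mix
  low and high accessions; partial loci shift 1–4 accessions to
  intermediate.

What the generator does **not** model: LTR structural features, insertion
preferences, indels, sequencing error, bisulfite conversion error, genetic
variation confounding methylation calls. Passing recovery tests therefore
demonstrates correctness of the downstream logic under the stated generative
assumptions, not robustness to every artefact of real libraries.

**Classifier benchmark conditions** (`AGE_CONDITIONS`): young clusters use
40 copies at d = 0.0025 (pairwise divergence ≈ 0.005, identities above the
0.99 optimum cut); old clusters use 34 copies at d = 0.03 plus a 6-copy
ancient tail at d = 0.06 (pairwise ≈ 0.06, an identity hump near 0.94 inside
the histogram window — where empirically reported old-family identity peaks
sit — with the tail's pairs mostly below it). Copy number matters: with few
copies a noticeable fraction of read pairs come from the *same* copy and
pile up at identity ≈ 1, biasing old clusters toward young calls; 40 copies
keep that fraction ≈ 2.5 %, as in real high-copy families. Each benchmark
cluster uses 50 reads of 125 bp on a 400 bp consensus (~400–500 accepted
pairs), sizes chosen to keep the 100-cluster-per-condition experiment dense
enough for stable histograms yet quick to simulate.

## Expression and methylation conventions

* Pseudocount ε = 0.1 FPKM in the log ratio (the zero-handling convention is
  not recoverable from the source analysis; exposed in config).
* Regressions run on RPM axes by default (scatter-plot convention), FPKM via
  flag; OLS through `scipy.stats.linregress`, checked against the
  closed-form slope to 1e-10.
* Outlier flag: log ratio > median + k·MAD with raw (unscaled) MAD, k = 3.
  For roughly Gaussian log ratios this sits near the 98th percentile; with
  all ratios equal the MAD is 0 and nothing exceeds the strict inequality.
* Methylation level boundaries 0.25 and 0.75 belong to *intermediate*
  (matching the strict inequalities "< 25 %", "> 75 %").
* DMR means are unweighted across positions (coverage-weighted mean via
  flag); loci whose positions are all filtered out leave the denominator.
* Percentages in methylation summaries are reported to 1 decimal.

## Pipeline and determinism

`PipelineConfig` is a single flat config (YAML) holding every stage
threshold; unknown keys are rejected and ranges validated. All randomness
flows from one integer seed through `numpy.random.default_rng` (stage
streams derive as `[seed, stage]`), outputs are TSV/JSON with fixed float
formatting, and each run writes SHA-256 digests of its outputs; the
determinism test reruns the pipeline and compares digests. Default demo
sizes (800 reads/accession, 300 methylation loci) complete in a few minutes
on one CPU; test configurations use smaller sizes.

## Known limitations

* Connected-component clustering cannot split chimeric components joined by
  a single spurious edge; at the default thresholds such edges require a
  ≥ 69 bp, ≥ 90 % identity overlap between unrelated families and were not
  observed in tests (inter-family identity ~25 %).
* Consensus/contig assembly is out of scope; the cluster representative is
  its longest read, and representative length feeds FPKM only.
* The six-category classifier is a shape heuristic, not a statistical test;
  near-boundary histograms (optimum ≈ 0.99, |b| ≈ b_tol) flip categories
  under resampling noise. Category 4 in particular captures any convex
  histogram, including convex *decay* from the 0.90 edge, so strongly
  left-truncated old families can be mis-called young; dense histograms
  (hundreds of pairs) make this rare.
* The methylation caller consumes per-position count tables; bisulfite
  alignment, strand reconciliation and SNP/methylation disentangling are
  upstream concerns outside this package.
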