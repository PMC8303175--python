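# Methods

## Signal model and detection statistic

A dRNA-seq library is reduced to strand-specific per-position counts of read
5′ ends (the biological 5′ end: leftmost aligned reference base for a
forward alignment, rightmost for a reverse alignment; soft-clipped bases do
not shift the coordinate). Unmapped, secondary and supplementary alignments
are excluded by default. Secondary exclusion is a deliberate simplification:
multi-mapper reassignment is upstream of this package, and exclusion avoids
double counting; a `keep_secondary` escape hatch exists. Mapping-quality
filtering defaults to 0 (off). Replicates of the same treatment are pooled by
position-wise summation; pooling across treatments is refused.

Detection works per position and strand. The null hypothesis is that both
libraries' counts at the position are Poisson draws at their local background
rates, so the count difference follows a Skellam distribution. The local rate
for each library is the mean count over a `background_window` (default
1000 nt) centered on the position, excluding the focal position, with window
counts winsorized at the `winsor_quantile` (default 0.975) empirical
quantile. Winsorization keeps genuine neighboring sites from inflating the
null; exclusion of the focal position keeps the tested signal out of its own
background. The rate is floored at `lambda_floor = 0.01` so the test is
defined in read-free regions. Windows truncate at replicon edges (mean over
available positions). No library-size normalization is applied inside the
test: each library's rate comes from its own window, which absorbs depth
differences and keeps the null self-calibrating.

The upper tail `P(D ≥ d)` is computed by marginalizing over the subtrahend
count: `Σ_k P(N2 = k) · P(N1 ≥ k + d)`, with the inner survival term as a
regularized incomplete gamma. For `d ≤ 0` a complement form is used so that
values below the reachable support give exactly 1.0; when that form returns a
small value it is re-evaluated with the direct sum to avoid cancellation. The
enumeration grid covers the Poisson mass to 10σ plus slack; the test suite
checks agreement with an independent brute-force double-Poisson enumeration
to relative error below 1e-10 over rates 0.01–20 and differences −60…60, and
stability is retained for rates up to ~1e4 and |d| up to 1e5.

Processing-site (TPS) mode treats TEX− as the favored library: candidates
need `n− ≥ min_reads` (default 10) and `p < alpha` (default 1e-9, a raw
per-position cutoff; an optional Benjamini–Hochberg mode over all evaluated
positions exists but is off by default, matching the stringent-raw-cutoff
convention for this assay). TSS mode swaps the library roles symmetrically.
Candidates within `cluster_gap` (default 5 nt) are chained into one site; the
"grouping of at least 5 nt" convention is read as merge-if-gap ≤ 5, which is
one of two defensible readings of the upstream tooling's phrasing. The
representative member is the one with the highest favored-library count, ties
broken 5′-most relative to the strand; the site p-value is the member
minimum.

## CDS-relative placement

For a gene with start-codon coordinate `x_CDSstart` and last-CDS-base
coordinate `x_CDSend`, a site at `x` gets

    D = 100 · σ · (x − x_CDSstart) / |x_CDSstart − x_CDSend|,

σ = +1 for forward genes, −1 for reverse genes. The signed form is the only
reading under which out-of-bound sites land at D < 0 (5′ flank) and D > 100
(3′ flank) on both strands while an absolute-value numerator cannot
distinguish them. The denominator is `length − 1`, so D = 100 falls exactly
on the last coding base, not one past it. Categories partition the line:
UPSTREAM (D < 0), START_PROXIMAL (0 ≤ D ≤ 25), INTERNAL (25 < D < 75,
strict), STOP_PROXIMAL (75 ≤ D ≤ 100), DOWNSTREAM (D > 100); the boundaries
25 and 75 belong to the proximal classes because the internal band is
defined strictly.

Sense assignment uses the gene interval extended by `max_upstream_ext` /
`max_downstream_ext` (default 150 nt each, strand-aware). These extensions
are a package choice, not a literature constant; both halophilic model
archaea are ~70% leaderless, so a modest window is defensible, and both are
configurable. Antisense assignment (aTPS) uses the unextended interval. A
site may annotate several overlapping genes (all assignments are reported;
counts of "genes with sites" deduplicate loci), and unassigned sites are
retained with a null locus.

## Comparative layers

Conservation: all cross combinations of sense sites in an orthologous gene
pair with `|D_a − D_b| < 3` (strict, configurable). The source convention
this implements prints the strict `< 3` inequality while describing it in
prose as "less than two units apart"; the printed inequality is taken as
normative. Only sense annotations enter (D is defined on the orthologous
CDS). Both the combination count and the distinct-site/gene-pair counts are
reported, since a gene pair can contribute several combinations.
Species-specific internal sites: orthologous genes with ≥ 1 strictly internal
sense site in one species and none in the partner. Sense/antisense
coincidence: unordered (TPS, aTPS) pairs on opposite strands of the same
replicon within 5 nt. Antisense conservation is presence-only: both orthologs
carry ≥ 1 aTPS, with no positional requirement.

## Quantitative comparison and Ribo-seq overlap

Two library-scaling conventions: `per_million` (each library's read-start
integral rescaled to 1e6) and `match_max` (shallower libraries scaled up to
the deepest, which keeps factor 1). Site signal is the strand-matched count
sum over ±2 nt around the representative position; gene signal is the mean
count over the CDS. Fold-changes between exactly two conditions use
`log2((b + pseudocount)/(a + pseudocount))` with pseudocount 1; the gene
ratio is computed on CDS count totals so the pseudocount acts on the same
count scale as the site window sum (the reported gene signal remains the
per-nt mean). A site is **discordant** when site and gene fold-changes have
opposite signs and both magnitudes reach the effect floor (default 1 log2
unit). This quantitative rule replaces what is, in the assay's original use,
a visual inspection step; the defaults are conservative and all parameters
are exposed.

Ribo-seq peak calling is a deliberate stand-in for a step with no canonical
method: a summit is a position with depth ≥ `min_height` (5), strictly
greater than everything to its left and ≥ everything to its right within
±window/2 (window 200 nt; ties resolve to the leftmost), and windowed
z-score ≥ `min_z` (2) with an SD floor of 1. Site/peak overlap means a summit
within ±`adjacency` nt (default 10, roughly codon-scale); the per-site table
carries the distance to the nearest summit so the overlap fraction's
sensitivity to this margin can be examined on real data. The fraction is
reported both raw and as a percentage rounded to the nearest integer.

## Synthetic data: what it emulates, and what it does not

The generator exists because the analysis was designed against real archived
libraries with no stated generative model; it implements the model the caller
assumes, so parameter recovery is a meaningful test of the machinery. Counts
are Poisson: background `lambda_bg` per position per strand per library
(default 1), plus site contributions — a TPS adds mean μ to TEX− and
μ·`tex_plus_leak` to TEX+ (leak default 0.02, standing for incomplete
exonuclease digestion; no measured efficiency exists for these datasets, so
it is a convention, and configurable); a TSS adds μ·`tex_enrichment`
(default 3) to TEX+ and μ·`tss_minus_fraction` (default 1) to TEX−. Default
site strength μ = 50 gives unambiguous single-site signals; the recovery
suites use μ = 30 over background 1.

Genes are placed without overlap on either strand (real genomes overlap;
documented simplification), lengths uniform in 300–1500 nt, strands balanced.
TSS are planted at the gene 5′ end (0–5 nt upstream, the leaderless-dominated
regime); TPS uniformly within the CDS; per-gene multiplicities accept a
categorical distribution so mostly-single-site genomes can be emulated.
Same-strand same-kind sites keep ≥ 6 nt spacing (clustering gap + 1) by
rejection, so truth matching at evaluation time is unambiguous; a site that
cannot be placed is skipped with a warning.

The two-species study plants one sense TPS per paired gene. Conserved pairs
get `D_B = D_A + U(−jitter, +jitter)` (re-drawn if integer rounding pushes
|ΔD| past the threshold); **non-conserved pairs are rejection-sampled to
|ΔD| ≥ threshold + 2**, so the planted conserved set is exactly the set
recoverable under the criterion — without that margin, independently placed
sites would occasionally fall inside the threshold by chance and make exact
recovery ill-posed. Jitter ≥ threshold is refused outright. Optionally the
first k pairs get an antisense site in both genes, for testing the
presence-only antisense conservation layer. Ribo-seq coverage is `base`
(10) within CDS plus triangular peaks (summit `peak_height` = 50, half-width
15 nt) at a chosen fraction of planted TPS, so the summit value at a peaked
site is exactly base + height.

What passing these tests does **not** show about real data: no overdispersion
beyond Poisson, no positional read-start correlation, no sequence or
structure bias, no multi-mapping, no overlapping genes, and TEX efficiency is
a single global constant. Recovery rates on synthetic data are therefore an
upper bound on real-data behavior of the machinery, not an estimate of it.

## Numerical and design choices

- p-values are clamped into (0, 1] (smallest positive double) so downstream
  −log10 transforms are total; BED scores cap at 300.
- Determinism: every generator derives independent substreams from one seed
  via seed sequences keyed by (operation, treatment, replicate); identical
  seeds give byte-identical files. The pipeline manifest records SHA-256
  checksums of all outputs, so re-runs are verifiably identical.
- bedGraph I/O uses the format's 0-based half-open intervals, merges
  equal-valued adjacent runs on write, and validates non-negative values and
  non-overlapping intervals on read (first offending line reported).
- Replicon lengths are taken from SAM headers or sequence-region pragmas when
  available; otherwise bounds checks are relaxed and scan windows extend past
  the last observed position.
- Problem sizes in the test suite (1e6-position null genome, 100-site
  recovery on 100 kb, 100-pair ortholog study) are chosen as the smallest
  scales at which the tested guarantees are statistically meaningful.

## Known limitations

- The depletion test is per-position; no joint segmentation across member
  positions beyond gap-chaining, and no replicate-aware dispersion model
  (replicates are pooled).
- Exact numeric agreement with the original TSS-calling tool this test
  stands in for is not claimed; the published parameter semantics (cutoff,
  minimum reads, grouping distance) and recovery of planted truth are the
  contract.
- Headline inventories from the original halophile datasets (thousands of
  sites per genome) require the archived sequencing runs and are full-data
  workflows, not desk-scale results.
- Ortholog inference, UTR/operon reconstruction, RNA structure, GO
  enrichment, and Ribo-seq read processing are out of scope; the pipeline
  starts from alignments or count tracks and an ortholog table.
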