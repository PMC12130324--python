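# Methods

This note documents the models and procedures implemented in `sescout`,
the parameters that matter, the design choices made where the design was
genuinely open, what the synthetic cohorts do and do not emulate, and the
package's known limitations.

## Coordinate model

All coordinates are 0-based half-open (BED convention) everywhere,
including internal types; any 1-based input would be converted at the
reader boundary. A single convention eliminates off-by-one classes of bug.
Strand is stored but ignored in overlap computations — H3K27ac/ATAC signal
is unstranded — and used only to resolve gene TSS positions. Chromosome
names match by exact string equality; readers accept an alias map
(`1 ↔ chr1`) applied at parse time. All deterministic outputs sort
intervals by (chrom lexicographic, start, end); writers emit tab-delimited
UTF-8 with no trailing whitespace, so equal inputs give byte-equal outputs.

Signal tracks are ordered non-overlapping constant-value segments (an
in-memory bedGraph). Region scores are signal *mass* (density × overlapped
bp, summed), which is additive over partitions of the region and invariant
to splitting segments at internal breakpoints.

## Super-enhancer calling

Stitching merges peaks whose consecutive gaps are ≤ `stitch_distance`
(default 12,500 bp) after first unioning overlapping peaks. Peaks whose
centers lie within `tss_exclusion` (default 2,500 bp) of a TSS are withheld
from stitching and kept as singleton regions flagged promoter-proximal;
they still participate in ranking (hockey-stick profiles plot all ranked
enhancers), and excluding them entirely is a configuration switch. Both
defaults follow the established stitched-enhancer convention; both are
exposed as parameters.

Region signal is aggregate mass over the stitched span; when an input-DNA
control track is provided its mass is subtracted and the result floored at
0 per region — negative enrichment is treated as no enrichment. Whether a
control was used is recorded in run metadata; both paths are supported.

The SE/typical cutoff is defined on the min–max-scaled ranked curve
(x_i = (i−1)/(n−1), y_i scaled signal) as argmin(y − x): the standard
discrete surrogate for the tangent-slope-1 point, since exact tangency is
ill-posed on discrete data. Two numerical choices:

- ties in the argmin break toward the larger index (fewer, stronger SEs);
- the top-ranked point is excluded from the argmin (indices 1..n−1 of n).
  The last point always has y − x = 0, so including it would let the
  cutoff swallow the entire curve whenever the minimum is non-negative
  (e.g. any two-point curve); excluding it guarantees a non-empty SE set
  and makes the two-point curve behave sensibly (cutoff at the lower
  point, the higher one called SE).

A sample whose stitched regions all carry the same signal has no
inflection; the caller raises a degenerate-curve error instructing the
caller to skip that sample rather than guessing. SE membership is invariant
to multiplying all signals by a positive constant, and stitching is
idempotent on its own output spans.

## Cohort consensus and lineage specificity

SE identity across samples is transitive ≥ 1 bp overlap (no published
reciprocal-overlap rule exists for this step, so the simplest rule is the
default and a minimum overlap fraction — overlap / min(length) — is
exposed for sensitivity analysis). Merged entries carry support (distinct
contributing samples) and the member list; "unique SEs" of a cohort are
counted after merging. Merging is invariant to sample input order.

Cross-cohort sharing intersects two catalogs on the same genome-build
label; the Venn identity (shared + exclusive = catalog size, per side)
holds on every instance by construction. Presence of an SE in a cohort is
the fraction of that cohort's samples with any overlapping SE call;
lineage specificity is mean presence over target cohorts minus mean
presence over the rest, in [−1, 1], requiring the target set to be a
non-empty proper subset of the cohorts.

## Target assignment

Promoter windows are TSS ± 2,500 bp (mirroring the TSS-exclusion
convention; no window is prescribed by the upstream literature), clipped at
0, strand-aware. A loop nominates (SE, gene) when its FDR is strictly below
0.05 and one anchor overlaps the SE while the other overlaps the promoter
window, in either orientation; the reported FDR per pair is the minimum
over qualifying loops (PET count taken from that best loop, ties to the
higher count). Output is monotone in the FDR threshold.

Gene categorization crosses interaction (appears in loop pairs) with
upregulation (log2FC > `fc_min`, default 0, and FDR < 0.05). Genes absent
from the DE table are labeled `unmeasured` and excluded from the
four-category counts — they are never silently "not upregulated". Nearest-
gene assignment (site midpoint to TSS, ties to the lexicographically
smaller gene id and flagged) is provided both as the loop-free nomination
fallback and for ChIP-site annotation; direct-target lists are the
intersection of a ChIP-bound gene set with significantly changed genes,
split by sign of log2FC (the two sets are disjoint; log2FC exactly 0
belongs to neither).

## Duplication recurrence

A donor counts toward an SE's duplication frequency when at least one of
its DUP calls covers ≥ `min_cover` (default 0.5) of the SE length. The
coverage criterion distinguishes focal amplicons from megabase-scale gains;
0 recovers any-overlap. Only DUP-typed events count (amplification inferred
from copy number is out of scope). Denominators come from a donor manifest,
so donors without any SV still count; each donor counts at most once per
SE, making results invariant to duplicate event records. `recurrent` flags
(SE, cohort) rows with ≥ `min_donors` (default 2) duplicated donors.
Frequencies are monotone non-increasing in `min_cover`.

## Dependency normalization

Per cell line, with m_N and m_E the medians of raw effects over the
non-essential and essential control lists, every score maps through
(x − m_N)/(m_N − m_E). After the map the control medians equal 0 and −1
exactly (to machine precision), and the normalization is invariant to any
per-line affine rescaling of the raw scores. The median is the standard
midpoint-of-two-middle-values median — stated explicitly because control
lists can be even-sized. A line with m_N ≤ m_E cannot be normalized and is
reported by name. Dependency is called strictly below −0.5 — half the
effect expected from knocking out an essential gene.

The expression–dependency association is a Spearman rank correlation (no
specific statistic is prescribed upstream; the choice is recorded in
output metadata). For n ≤ 9 the two-sided p-value is exact, enumerating
all n! pairings of the rank vectors (ties handled by Pearson on midranks);
larger n uses the asymptotic approximation. Constant vectors make rho
undefined; the result is flagged degenerate rather than raising.

## Motif scanning

Log-odds are log2((count + pc·bg)/(column total + pc)/bg) with pseudocount
0.1 distributed by background (configurable; zero pseudocount is legal for
scoring but the exact-p-value machinery requires a finite matrix). The
background defaults to uniform 0.25 and can be estimated 0-order from the
scanned sequence. The exact null is built by discretizing each column onto
a shared integer grid — bin width = total score range / 1000 bins — and
convolving column score distributions under the background; p(s) =
P(score ≥ s) is monotone non-increasing, 1 at the minimum score, and equals
the background probability of the consensus word at the maximum. The DP is
guarded at motif length 25. Scanning evaluates both strands (the minus
strand scores the reverse complement of each window against the same
matrix, so one null serves both), skips windows containing N, and emits
hits with p ≤ 10⁻⁴ sorted by (offset, strand). Reverse-complementing the
input reflects offsets and swaps strands while preserving the score
multiset.

## Synthetic cohorts

The generator emits a complete dataset bundle — per-sample peaks and
signal, per-cohort loops, SV table + donor manifest, DE tables, gene-effect
matrix with control lists, expression, enhancer FASTA and PWM — plus a
truth manifest sufficient to score recall/precision of every stage. Default
scale: 2 chromosomes × 10 Mb, 300 genes, two GI cohorts (COREAD, STAD) of
3 samples sharing 2 planted SEs with 3 private each, a 3-sample
background-only outgroup cohort standing in for non-GI cancer types (so
lineage specificity has a non-target column), and 60 donors per SV cohort —
seconds on one CPU. One pseudo-random stream per output family (peaks,
signal, loops, SVs, expression, dependency, sequence), all spawned from the
master seed, so changing one family's model does not perturb the others;
identical (config, seed) produces a byte-identical bundle.

Signal model: background peaks are 800 bp at density exp(N(0, 0.35));
planted constituent peaks are 1 kb at 60× background density, 5 per cluster
spaced 1.5 kb. These values were fixed by an explicit design-time
calibration of the ranked-curve behavior: they keep the background portion
of the hockey curve sub-inflection (false SE calls ≈ 5·10⁻⁴ per sample)
while reproducing the one-to-two order-of-magnitude signal separation that
ranked H3K27ac profiles show between super-enhancers and typical enhancers.
Signal is written as one constant-value segment per peak — the pipeline
consumes aggregate mass, so per-bp noise would add cost without test
power. Planted peaks drop out independently at rate 0.05 per sample.

Planted loops join each SE's midpoint (±1 kb anchor) to its target gene's
TSS (±1 kb) with FDR ~ U(0, 0.01); decoys anchor at random positions clear
of SEs and promoters with FDR ~ U(0.05, 1), making precision measurable.
One shared SE is recurrently duplicated in 8/60 GI donors (pads 5–20 kb
around the footprint); background SVs (DUP/DEL/INV, 10–200 kb) avoid
planted footprints for DUPs so the planted recurrence structure is
unambiguous. Planted target genes get log2FC ~ N(2, 0.3) (floored at 0.5)
with FDR ≤ 10⁻⁴; null genes draw null log2FC and uniform FDR. The
duplicated SE's target gene carries a graded dependency profile across
lines (−1.25 … −0.62 around the −0.9 center, all below the −0.5 call
cutoff) — the association between expression and dependency needs genuine
line-to-line variation to detect, which is exactly the phenomenon being
modeled (higher-expressing lines are more dependent) — and its expression
is an affine function of dependency strength plus small noise. The raw
gene-effect matrix is a per-line affine distortion of the normalized-space
draws, so the normalization has real work to do. One length-8 consensus
site is planted at a recorded offset in the last enhancer sequence; its
PWM (85/5 counts) is written in JASPAR format.

What the generator does **not** emulate: read-level data, per-bp signal
noise, peak-caller artifacts, copy-number-driven signal inflation,
inter-sample batch effects, realistic SV breakpoint distributions,
karyotype structure, or correlated expression networks. Passing the
planted-truth tests therefore demonstrates the correctness of the
algorithms under clean separation, not their robustness to the full noise
structure of real tumor data.

## Orchestration and the report

The pipeline chains SE calling → cohort consensus → target assignment →
SV recurrence → dependency (if a matrix is supplied) → motif scan (if
FASTA/PWM supplied), logging record counts per stage so filter attrition is
auditable, and aborts on a stage error naming the stage. The final report
ranks the union catalog of target-cohort SEs lexicographically over
(shared across target cohorts, has loop-linked upregulated target,
recurrently duplicated in the focal SV cohort, lineage specificity),
mirroring the narrative funnel from shared SE catalogs to a duplicated,
expression-supported candidate; rank ties resolve by genomic position.
All parameters are echoed into the report header for provenance, and
reruns on identical inputs are byte-identical. When no loop files are
supplied, target assignment degrades to nearest-gene nomination and the
report header notes that interaction evidence is unavailable.

## Known limitations

- The hockey-stick cutoff is sensitive to the largest signal gaps near the
  top of the background distribution; on heavy-tailed real data it calls
  more SEs than planted-truth synthetic data suggests.
- SE identity by ≥ 1 bp transitive overlap can chain distinct elements
  through bridging calls in large cohorts; raise the overlap fraction for
  conservative matching.
- The exact motif p-values are per-window and per-motif; no multiple-
  testing correction across motifs or sequences is applied (deliberately
  out of scope), and only 0-order backgrounds are supported.
- Genome builds are treated as opaque labels that must match; there is no
  coordinate lift-over.
- TRA-typed SVs carry no span and never contribute to recurrence.
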