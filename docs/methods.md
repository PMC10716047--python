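# Methods

This note documents the models, the estimators, the defaults and the
deliberate design choices behind `orfscreen`, and what the synthetic-data
generators do and do not emulate.

## Coordinates and annotation

All internal coordinates are 0-based half-open; GTF is read as 1-based
inclusive (GENCODE dialect), BED as 0-based half-open.  UTRs are derived
per transcript as exon − CDS (split into 5′/3′ by strand relative to the
CDS span) when not explicit, then unioned across transcripts to gene level.
The neighbor filter therefore operates on gene-level CDS/UTR unions — an
isoform-level variant would flag slightly fewer guides; the union is the
conservative choice for an off-target control.  Proximity queries ignore
strand throughout: Cas9 cuts double-stranded DNA, so only physical distance
matters.

Sequence identity for the redundancy collapse is global Needleman–Wunsch
with match +1, mismatch 0 and a linear gap penalty of 1 per gapped base;
identity = matches / alignment columns, gaps counting as non-identical
columns.  Because co-optimal alignments can differ in matches and columns,
the traceback uses a fixed move preference (diagonal, gap in the second
sequence, gap in the first) and arguments are put in canonical order first,
so the reported identity is deterministic and exactly symmetric.

## Ribo-seq model

RPFs are represented by their 5′ ends, grouped by read length; lengths
outside 25–35 nt are excluded from P-site analysis (gel excision selects
~28–30 nt fragments; the band is deliberately tolerant).  The start-codon
metagene sums 5′-end counts over −40..+20 nt across all annotated coding
transcripts.  The P-site offset per read length is the negated argmax of
that profile restricted to −18..−6 (bracketing the canonical ~12–13 nt
distance); ties resolve to the smaller offset, and lengths with no counts
in the window are dropped.

Frame QC uses 5′-end positions from 15 nt upstream of the start codon to
12 nt upstream of the stop codon (half-open), assigns each position's reads
to a frame after the per-length P-site shift, and reports
*f*<sub>d</sub> = max frame count / total, pooled across read lengths and
computed over transcripts with at least one in-range read.

The translation test compares, per ORF, the per-codon P-site counts at
codon base 0 against the pooled counts at bases 1 and 2 (stop codon
excluded) with a one-sided rank-sum test.  Count data are tie-heavy, so the
test enumerates the full permutation null of the midrank sum when the
pooled sample has ≤ 12 values and otherwise uses the tie-corrected normal
approximation with continuity correction.  All-zero input yields *p* = 1,
never NaN.  Candidate ORFs are ATG-initiated in all three frames, one per
stop codon (the longest), and calls use *p* < 0.05.  Identical ORFs found
in several libraries or isoforms (same genomic span, chromosome and
strand) are merged keeping the minimum *p*.

## Screen statistics

**Size factors.**  Ratio-median normalization anchored on the
negative-control guides: factor_j = median over control rows of
count<sub>ij</sub> / geomean<sub>k</sub>(count<sub>ik</sub>), using only
control rows positive in every sample, then divided by the median factor.
The median rescale pins the typical sample at 1 and makes the factors
exactly scale-equivariant (doubling one sample's counts doubles its factor
and leaves the rest untouched, provided that sample is not itself the
median anchor).  A constant rescale of all factors is absorbed by the
normalized condition means, so no downstream statistic depends on it.
With no control set given, every row is a control (the RNA-seq variant).

**Dispersion.**  Per-row method of moments on within-condition residuals of
the normalized counts, α = max(0, (s² − μ)/μ²), pooled across conditions by
residual degrees of freedom, clipped at 0 and floored at 10⁻⁸ (all-zero
rows keep 0).  With only 3 + 6 replicates this per-row estimate is far too
noisy to plug into a Wald test — rows whose dispersion happens to be
underestimated get overconfident standard errors and the type-I error
inflates well above nominal — so the fitted model shrinks each row toward a
pooled moment-ratio estimate, α<sub>i</sub> ← w·α<sub>i</sub> + (1−w)·α̂
with w = resid_df / (resid_df + prior_df) and prior_df = 50.  The pooled
ratio Σw(s²−μ)/Σwμ² is nearly unbiased where averaging per-row estimates is
not.  No mean–dispersion trend is fitted; that (and the absence of
fold-change shrinkage priors) is the main fidelity gap versus the mature
NB frameworks this module parallels, and it is deliberate: every estimator
here is a closed-form expression a reader can recompute.

**Wald test.**  Condition means are fitted on the normalized scale — the
mean of k<sub>j</sub>/s<sub>j</sub> per condition, which is the NB MLE when
samples share a size factor — keeping every statistic an exact function of
the normalized counts.  log₂FC = log₂(q₂₁/q₀); when either condition mean
is 0, 0.5 is added to both before the ratio (and the information is
evaluated at the stabilized means).  The squared standard error is
(1/I₂₁ + 1/I₀)/ln²2 with I = n·q/(1 + αq).  The fitted model refers
z = log₂FC/se to Student's *t* with resid_df + prior_df degrees of freedom
(57 for the 3 + 6 design) rather than the standard normal — the
quasi-likelihood-style acknowledgement that the plug-in dispersion is
estimated; measured on 10,000-guide null screens this brings the type-I
error from ~0.052 (normal reference) to ~0.048 at nominal 0.05.  BH
correction runs over rows with positive base mean only; empty rows are
reported with NaN statistics.

## Hit funnel

Threshold boundary conventions are pinned per filter: depletion is
log₂FC ≤ −log₂(1.5) (equality counts) with *p* < 0.05 strict; the tumor
filter is log₂FC ≥ log₂(1.2) with FDR < 0.01 strict; RNA-seq DE uses
FDR ≤ 0.05 inclusive.  The neighbor window is the symmetric closed ±15 bp
around the cut-site base (the blunt SpCas9 cut 3 bp 5′ of the PAM).  Guides
flagged for both a CDS and an essential-gene UTR conflict are removed once.
A host gene absent from the tumor DE table fails the expression filter
(conservative) with the reason logged.  Redundancy collapse is greedy:
within each host gene, ORFs sorted by ascending translation *p* (ties:
longer ORF, then id) are kept iff ≤ 85 % identical to every already-kept
ORF — one admissible reading of an ambiguous rule, chosen because it keeps
the most significant representative of every dissimilarity class.

## Expression statistics

TPM group comparisons use the two-sided rank-sum machinery (exact
enumeration through 5+5, tie-corrected normal beyond); the TPM fold change
is the ratio of group means with pseudocount 0.01, a choice the funnel is
insensitive to at the planted effect sizes.  Subtype enrichment is
one-vs-rest over tumor samples only; samples with subtype NA are excluded,
"other" stays in the rest; subtypes with < 3 samples are skipped with a
warning.  Gene-level perturbation DE reuses the NB machinery with all-rows
size factors and the basemean ≥ 1, |log₂FC| ≥ log₂(1.5), FDR ≤ 0.05 calls.

## Triage

The DE-overlap test is the one-sided hypergeometric upper tail (the claim
being over-sharing), symmetric in its arguments; the universe is the genes
tested in both perturbation analyses.  Peak-to-gene association is any
overlap between the peak interval and the TSS ± 10 kb window (window
arithmetic keeps the TSS base itself, so the window is
[tss − flank, tss + flank + 1)).  Triage classes are conjunctive and
order-free: co-repressed = shared-up ∧ TSS peak ∧ tumor-down;
co-activated is the mirror; everything else is none, so classes partition
the universe.  The AP–MS filter is ≥ 3 unique bait peptides, zero in both
controls, tumor log₂FC ≥ 0.4 with FDR < 0.01; ≥ 4 bait peptides earns the
"strong" sub-flag.

## Synthetic data

The generators are pure functions of (parameters, seed); regeneration is
byte-identical.  Defaults are the screen design the pipeline targets:
3 day-0 and 6 day-21 replicates, ~500 mean counts per guide, NB dispersion
0.05, 5 guides per ORF, depletion log₂FC = −2, lognormal (σ = 1) baseline
abundances, 500 lncRNA ORFs of which 50 are depleted (10 confounded, 20
with tumor-upregulated hosts), TPM cohorts of 100 tumors and 100 normals
with lognormal noise σ = 0.5 and subtype proportions
CMS1/2/3/4/NA = 0.20/0.30/0.20/0.20/0.10.

Ribo-seq simulation places each read's 5′ end at (P-site − offset) with the
planted per-length offsets {28: 12, 29: 12, 30: 13}, a peaked read-length
distribution centered on 29 nt, per-codon Poisson coverage, a 3× elevated
initiation codon (the ribosome pause at starts that produces the metagene
peak the offset estimator keys on), and uniform background on every
transcript.  Periodicity is the probability a read's P-site falls on codon
base 0; 1/3 is exact null, 0.9 is the strong-signal default.  Planted ORFs
are preceded by an in-frame stop so each is the longest ORF for its stop
codon.  Genes are single-exon and single-transcript; confounded ORFs live
on lncRNAs placed within 200 bp of a coding gene and get all their guides'
cut sites within 15 bp of that gene's CDS, while clean ORF guides cut
inside the ORF body kilobases from any coding feature.

What the simulations do *not* emulate — and hence what passing tests do not
certify about real data: multi-exon and multi-isoform gene structure,
rRNA/multimapper contamination and length-dependent P-site heterogeneity,
guide-efficiency gradients and copy-number effects in the screen, batch
structure and compositional bias in expression cohorts, and any
correlation structure between the omics layers beyond the planted one.

## Problem sizes and numerics

The test suite and the acceptance script run the statistical checks at the
sizes the corresponding claims are stated for: 10,000 null guides for NB
calibration, 400 ORFs for ribo-seq null calibration, 100 coding + 100
lncRNA transcripts for offset/ORF recovery, and the 500-ORF default
scenario (seeds 1–5) for funnel recovery; unit fixtures are smaller.
Newton-free closed forms are used everywhere; the only iteration in the
package is the NW dynamic program.  Degenerate inputs have pinned
behaviors: all-equal rank-sum input → *p* = 1; empty metagene window →
read length dropped; zero-count ORFs → *p* = 1; all-zero count rows →
excluded from testing and BH; constant count rows → dispersion 0 (floored).

## Known limitations

The NB machinery intentionally omits empirical-Bayes dispersion trends and
fold-change shrinkage; borderline guides can therefore differ from what a
shrinkage-based framework would call, which perturbs funnel counts near the
thresholds.  The translation test is a rank-sum on P-site codon counts — a
deliberately simple stand-in for the full generative tests used by
dedicated ORF callers, adequate at the simulated coverage but less powered
for short, low-coverage ORFs.  The expression filter is cohort-agnostic:
the labels define tumor and normal, and no batch correction is applied.
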