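# Methods

## Data model

A single gene of length L (coordinates 1-based inclusive) is present in k
paralogous copies. The copies differ only by substitutions at V
*biologically variable positions*; each such position carries exactly two
nucleotides across the copy set (biallelic by assumption — in the small
bacterial paralogue families this tooling targets, three observed alleles
at one position have not been reported, and a third base in a read is
treated as error). A copy's *variant combination* is the string of its V
bases at the variable positions in ascending order; the multiset of k
combinations is the *gene copy variant combination set*. Multiplicity
greater than one is expected (several copies often share a combination),
which is why proportions cluster near multiples of 1/k. Insertions and
deletions between paralogues are out of scope, as are multi-gene
references: inputs aligned to multi-contig references are rejected.

k = 1 is rejected outright — a single-copy gene admits no variable
position, and the ratio machinery below would be vacuous.

## Extraction

Pileup and combination extraction work from SAM/BAM (via pysam) or from
pre-tabulated TSV counts. Defaults: mapping quality ≥ 20 and base quality
≥ 20 where qualities exist (clone consensus input without qualities passes
through), deletion-spanning and ambiguous calls excluded per site, reads
flagged as duplicates kept (duplicate marking belongs to upstream
pipelines), and a base counted as "end of read" when it lies within E = 5
bp of either aligned read end. All thresholds are configurable; none is
load-bearing for the inference itself.

A read contributes a variant combination only if it has a confident,
non-deleted, canonical base call at *every* site of the window — reads
covering a strict subset are counted as non-spanning, never partially
tallied. This is the honest treatment of short-read platforms: when reads
cannot span the sites, the method reports zero spanning reads rather than
a biased subset. A confident call matching neither site allele rejects the
whole read from combination counting (third alleles are sequencing error
under the biallelic model; they are *not* counted as novel combinations).

## Variant copy ratio estimation

At a variable position the true proportion of the designated allele is
j/k, j ∈ {1..k−1}; j = 0 and j = k are excluded because the position would
then be conserved. With x of n informative reads carrying the designated
allele,

    P(j | x, n) ∝ π(j) · C(n,x) (j/k)^x (1 − j/k)^(n−x),

computed in log space (stable beyond n = 10⁶) with a uniform default prior
π(j) = 1/(k−1). The MAP is reported as the unordered ratio M:m; MAP
probabilities below 0.95 are annotated as low-confidence in the report.
Exact ties (possible when x/n = 1/2) are reported as indeterminate rather
than broken arbitrarily. The model assumes a homogeneous single-organism
sample and unbiased sequencing of the individual copies; per-copy
amplification bias is not modelled.

The copy-number-free companion places a uniform (0,1) prior on the
proportion, giving a Beta(x+1, n−x+1) posterior; the reported interval is
the equal-tailed 95% interval (the plain reading of a central credible
interval; HPD intervals offer no benefit for these unimodal posteriors and
are not computed). The *separation check* classifies the interval against
the two candidate proportions bracketing the observed proportion:
`between` — the interval lies strictly inside the open gap and contains
neither candidate — flags data displaced from every discrete ratio, the
signature of a run- or library-specific artifact rather than sampling
noise. When several datasets are analysed together, the consensus ratio is
the strict majority (> half) of the per-dataset MAP ratios, unordered;
anything else is reported as no-consensus.

## Coverage power analysis

The MAP decision at coverage n assigns each observed count x the candidate
j maximizing Binomial(x; n, j/k). Its exact power at a true ratio is the
binomial probability mass of the x-region mapped to that truth, with
correctness judged on the *unordered* ratio (for a 4:3 truth, MAP j = 4
and j = 3 both count — otherwise a balanced 3:3 truth could never be
"identified" from the half of sample space below 1/2) and MAP ties counted
as failures (conservative).

`required_coverage` defaults to a closed-form design formula. The MAP
decision is asymptotically "nearest candidate proportion", with decision
boundaries half a gap d = 1/(2k) from the true proportion p = j/k.
Requiring the observed proportion to stay within the half-gap with
two-sigma (z = 2) confidence gives

    n = ⌈z² σ² (2k)²⌉,   σ² = p(1−p),

except that ratios adjacent to balanced (|2j−k| ≤ 1, whose unordered
acceptance region straddles 1/2) use the worst-case binomial variance
σ² = 1/4. The formula yields integers: n = 16·j·(k−j) in the regular case
(96× for 6:1 of 7 copies, 80× for 5:1 of 6) and n = 4k² in the
near-balanced case (196× for 4:3 of 7, 144× for 3:3 of 6). Exact unordered
MAP power at those coverages is 0.949, 0.963, 0.975 and 0.963 — the design
numbers are mildly conservative for the harder ratios and essentially
calibrated for the easy ones.

Two exact alternatives are kept behind `method=`: `exact-first` (smallest
n whose exact power meets the target — beware the binomial sawtooth: power
is non-monotone in n, and the first crossing can be followed by dips back
below target) and `exact-stable` (smallest n from which power stays at or
above target for all larger n). For a 6:1 ratio of 7 copies these give 77×
and 97×, bracketing the 96× design value.

## Combination-set inference

Generative model for a read's combination string s over a window of V ≥ 2
sites: with probability 1−c the read descends from one copy chosen
uniformly; with probability c it is a chimera — two ordered parents drawn
uniformly *with replacement* (so self-pairs re-emit a true combination),
one breakpoint over the V−1 inter-site gaps, uniform by default
(gap-width-proportional weights available; plausible for PCR template
switching but not assumed). Emission probability:

    P(s) = (1−c)·mult(s)/k + c·Σ_{i,j,b} 1[chimera(i,j,b) = s]·w_b / k².

Sequencing errors at variable positions are deliberately absorbed into c
rather than modelled separately — at these error rates the two are not
identifiable from combination counts alone, and the estimate of the copy
set is insensitive to the split.

Observed counts are multinomial given P. The estimator searches
exhaustively over all multisets of size k drawn from a candidate alphabet
— by default the observed combinations (keeping the search exhaustive and
deterministic), optionally extended by single-site neighbours to reach a
true copy unobserved at low coverage. For each candidate multiset the
chimera rate is profiled over a grid (0 to 0.2 in 0.001 steps by default;
the grid resolution is far below the statistical uncertainty in c at
realistic read counts). The search is vectorized: per-multiset emission
probabilities at the observed strings decompose as (1−c)A + cB with A the
multiplicity term and B a quadratic form in the multiplicity vector
against a precomputed parent-pair transfer tensor, so the whole
multiset × c-grid likelihood surface is evaluated with dense linear
algebra. A guard caps the candidate-space size (default 500,000 multisets)
with an explicit error. Ties are broken deterministically — higher
likelihood, then fewer distinct combinations, then lexicographically
smallest multiset — and all co-optimal multisets are reported.

Per-combination observed proportions carry exact Clopper–Pearson 95%
intervals from beta quantiles. Counts from several datasets are combined
by plain element-wise summation, deliberately unnormalized: the consensus
is weighted toward the larger (deeper, usually less chimera-ridden)
datasets. Windows must match exactly when combining; the tool never
silently drops unresolvable sites — the caller chooses the window.

## Variant triage

FS is the phred-scaled two-sided Fisher exact test on the 2×2
(ref, alt) × (forward, reverse) table; the two-sided p-value sums all
tables with point probability at most the observed one (stated explicitly
because conventions differ). Flag thresholds — FS > 60, end-of-read
fraction > 0.9, homopolymer run ≥ 4, within 2 bp of a reference end — are
pragmatic screening defaults in line with common hard-filter practice, all
configurable; they are not calibrated significance levels. The homopolymer
statistic is the longest single-base run containing or immediately
adjacent to the position. Non-target regions come either from explicit
untargeted intervals or as the complement of supplied primer-target
intervals. Contaminant identification needs an external database search
and is out of scope; an externally produced annotation is carried through
the report.

## Simulator

`simulate_reads` draws, per read: a source copy (uniform) or, with the
configured chimera probability, an ordered parent pair and a breakpoint
gap with a base-level crossover uniform inside that gap; a read length
(fixed, or truncated-normal from a (mean, min, max) triple with
sd = (max−min)/6); a start uniform over the valid range; a strand
(forward with probability `strand_bias`, default 0.5); and i.i.d.
per-base substitution errors. Emitted SAM records use the true
coordinates (perfect full-match alignments), isolating the inference from
mapper behaviour — mapping bias is real and interesting, but it is an
upstream concern this simulator deliberately excludes. Everything is
reproducible byte-for-byte from the seed.

Presets (`shotgun-short` ~170 bp × 20,000 reads, error 0.005, no
chimeras; `amplicon-454` ~535 bp × 15,000, error 0.005, chimera 0.03;
`sanger-clone` ~850 bp × 90, error 0.001, chimera 0.03) approximate the
read-length/volume/noise regimes of short-read shotgun, long amplicon
pyrosequencing, and Sanger clone libraries for a ~1.5 kb gene. The 3%
chimera rate for amplicon-style presets is a mid-range literature figure
for multi-template PCR; the error rates are order-of-magnitude platform
defaults. They are presets for generating realistic test regimes, not
claims about specific instruments.

`simulate_counts` is the fast path: it draws the same per-read
combination and per-site error process without synthesizing sequence,
assuming full-length reads (every read covers every site). A two-sample
χ² test in the suite confirms it is distributionally indistinguishable
from `simulate_reads` followed by extraction.

What the simulator does *not* emulate — and what passing tests therefore
do not establish about real data: homopolymer indel errors (the dominant
pyrosequencing/semiconductor error mode; the variant model is
substitution-only), quality-score profiles and position-dependent error,
PCR-cycle chimera kinetics and amplification bias between copies,
contamination, and mapper-induced bias. Results on real data inherit all
of those; the simulator establishes correctness of the inference given
its model, not the model's completeness.

## Problem sizes used in validation

The validation suite runs the exact/oracle checks at full prescribed
sizes (all 2×2 tables with margins ≤ 30 for FS; 1,000 random triples up
to n = 10⁴ for the posterior). Stochastic claims use a 6-copy, 3-site,
300 bp gene model: 200 replicates at 2,000 reads (and 3 × 90 reads for
the sample-size contrast) for combination-set recovery, 2,000 binomial
replicates per ratio for MAP recovery at the design coverages, and 400
simulated 96-read datasets for the end-to-end power check. These sizes
put Monte-Carlo error comfortably inside the asserted margins while
keeping the suite quick on one core.
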