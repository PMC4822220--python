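# paracopy

Comparison and inference tools for sequencing data over a **multi-copy
gene** — the situation of the bacterial 16S rRNA gene, which is present in
k paralogous copies (typically 4–10) that are nearly identical but differ
at a handful of *biologically variable positions*. Reads from such a gene
mix the copies together; naive consensus analysis throws the copy-level
signal away, and naive variant calling misreads it as polymorphism.
`paracopy` is aimed at anyone comparing single-organism sequencing runs of
a multi-copy gene across platforms, laboratories, or pipelines.

The package analyses the data at three levels:

1. **Conserved positions** — candidate variants raised against the gene
   reference are triaged with the classical false-positive evidence:
   phred-scaled Fisher strand bias (FS), end-of-read fraction,
   homopolymer context, non-targeted primer regions, and end-of-reference
   artifacts.

2. **Variable positions** — at a variable position the true allele
   proportion can only be j/k for j = 1..k−1. Given x of n reads carrying
   the designated allele, the posterior over the *variant copy ratio* is

       P(j | x, n) ∝ π(j) · Binomial(x; n, j/k),

   reported as the MAP ratio M:m with its posterior probability. A
   copy-number-free companion uses the uniform-prior Beta(x+1, n−x+1)
   posterior and flags data whose 95% credible interval falls strictly
   *between* two candidate proportions — evidence of run-specific bias. An
   exact power analysis gives the coverage needed to call the ratio with
   95% probability (96× for a 6:1 ratio of 7 copies; 196× for 4:3).

3. **Variant combination sets** — each read spanning all variable sites
   carries a *variant combination* (the concatenated bases at those
   sites). The multiset of k combinations carried by the gene copies is
   estimated by exhaustive maximum likelihood under a mixture model with
   PCR **chimera events**: with probability c a read is a hybrid of two
   parent copies split at a breakpoint between consecutive sites,

       P(s) = (1−c)·mult(s)/k + c·Σ_{i,j,b} 1[chimera(i,j,b) = s]·w_b / k².

   The chimera rate c is profiled over a grid; per-combination proportions
   come with exact Clopper–Pearson 95% intervals, and counts from several
   datasets can be pooled (unnormalized) into a consensus estimate.

A seeded simulator (`simulate_reads` / `simulate_counts`) generates reads
and count tables with exactly this statistical structure — k copies,
per-base substitution error, chimeras, platform-like read-length presets —
so every estimator is testable end to end without external data.

## Worked example

```python
import paracopy as pc

ps = pc.demo_paralogue_set()          # 6 copies, 3 variable sites, 5:1 ratios
config = pc.SimulationConfig(paralogue_set=ps, n_reads=2000, read_length=300,
                             per_base_error=0.001, chimera_rate=0.03, seed=7)
obs, cc = pc.simulate_counts(config)

site = ps.sites[0]
x, n = pc.observed_variant_proportion(obs[0], site)
rp = pc.discrete_posterior(x, n, ps.k)
res = pc.required_coverage(ps.k, rp.map_j)
est = pc.infer_combination_set(cc, k=ps.k)
```

This prints (via the obvious `print` statements):

```
site 60: x/n = 1662/1998, MAP ratio 5:1 (posterior 1.0000)
design coverage for 5:1 of 6 copies: 80x (exact power 0.9629)
inferred combination set: ('AAA', 'AAA', 'AAA', 'AAC', 'AGA', 'GAA')
fitted chimera rate: 0.019, log-likelihood -2477.2
AAA observed proportion 0.508 (95% CI 0.486-0.530)
```

Reading the numbers: 1662 of 1998 informative reads carry the A allele at
position 60 (proportion 0.832, nearest candidate 5/6 ≈ 0.833), so the MAP
variant copy ratio is 5:1 with posterior probability ≈ 1 — and 1998×
coverage is far above the 80× design requirement. The combination-set
search recovers the true six-copy multiset, absorbing the injected 3%
chimera rate (fitted 1.9%; sequencing errors and chimeras are deliberately
not distinguished). The `AAA` combination is carried by 3 of 6 copies and
is observed at proportion 0.508 ≈ 3/6.

The same workflow is available from the shell:

```
paracopy power -k 7 --ratio 6:1
paracopy simulate --preset amplicon-454 --seed 1 --outdir sim/
paracopy ratios sim/reads.sam --sites model.json -k 6
paracopy combinations sim/reads.sam --sites model.json -k 6
```

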