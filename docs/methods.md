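# Methods

## The question and the model

An additional stop codon (ASC) is an in-frame stop triplet at codon
position +1..+6 downstream of a gene's primary stop. The fail-safe
hypothesis holds that ASCs are maintained by selection to terminate
ribosomes that read through the primary stop. The testable form of the
hypothesis is compositional: do downstream windows carry more in-frame
stops than their own nucleotide composition predicts?

The central null is a first-order Markov chain over {A,C,G,T}. For one
genome, all qualifying downstream windows are pooled; the chain's initial
vector is the pooled mononucleotide frequency and its transition matrix
comes from overlapping dinucleotide counts taken within each window
(never across gene boundaries — concatenation would fabricate
transitions at the junctions). Conditioning on dinucleotides rather than
mononucleotides matters because stop triplets (TAA, TGA, TAG) are built
from the strongly non-random TA/GA/AG dinucleotides.

## Null distributions and Z-scores

Three equivalent routes to the null are provided:

1. **Monte-Carlo** (`simulate_null`): R replicate pseudo-sets of N
   simulated 21-mers (a pseudo primary stop plus six downstream codons;
   the first codon is generated but never scored). Per replicate, the ASC
   frequency at each position; null mean and sd across replicates. The
   per-sequence text description of "simulating 10,000 UTRs" is read as
   replicate pseudo-sets because a single Bernoulli indicator per
   sequence has no usable standard deviation at the genome level; the
   replicate-set sd converges to the binomial sd below.
2. **Exact marginal** (`analytic_stop_probability`): the chain's marginal
   distribution at the codon's first base (initial vector propagated by
   3k transition steps), times the two transition steps, summed over the
   stop set. The whole-UTR probability `P(≥1 stop at +1..+6)` uses a
   4×4 transfer matrix summing chain probability over non-stop codons.
3. **Binomial fast path** (`analytic_null`): null mean f₀ from route 2
   with sd √(f₀(1−f₀)/N). This is the R→∞ limit of route 1 and is what
   the large calibration runs use.

`Z = (f_obs − μ)/σ`. Whole-UTR frequency is the fraction of genes with at
least one stop at +1..+6, applied identically to observed and simulated
sets. σ = 0 with f_obs = μ gives Z = 0; σ = 0 otherwise flags ±∞.

The geometric first-stop null models the position of the *first*
downstream stop: `P(first stop at codon n) = p(1−p)^(n−1)`, with p the
background per-codon stop rate of the 3' pool (per-gene frames anchored
at each gene's own stop; codons never span gene boundaries).

## Enrichment calls and their calibration

Per-position calls use a 1-df Pearson goodness-of-fit on (stop, non-stop)
counts against N·f₀, no continuity correction. A genome is *enriched*
when any position in +2..+6 has a positive deviation and p < 0.05/5.
Position +1 is excluded by default because the +4T termination motif
(below) inflates it for reasons unrelated to stops. The genome-level null
probability is taken as p₀ = 1 − 0.99⁵ ≈ 0.049, and within-set binomial
tests and the cross-taxa 2×2 chi-square (continuity correction
min(0.5, |O−E|), which reproduces the published 79.6/184.3/242.3 values
exactly) are built on it.

One calibration caveat is inherent to this rule and worth stating
plainly: requiring a *positive* deviation together with a *two-sided*
chi-square p < α yields a positive-call rate of α/2 per position under a
true null, so genuinely null genomes are called enriched at
≈ 1 − 0.995⁵ ≈ 2.5%, not 4.9%. Synthetic-genome calibration (200 genomes
drawn from their own fitted chains) measures ~2–3%, consistent with the
α/2 asymptotics and within the binomial sampling band of p₀ at this
sample size. The rule and the p₀ null are both kept as published; the
discrepancy means the genome-level binomial tests are conservative
against claims of enrichment.

The Z-score genome-level rule calls a genome enriched when any scored
position has Z > 2.33 (one-tailed, Bonferroni-corrected).

Sign-test batteries across genomes use exact binomial tests: #(Z>0)
against 0.5 (two-tailed), #(|Z|>1.96) against 5% (two-tailed), #(Z>1.64)
against 5% (one-tailed, dearth of significant enrichment), #(Z<−1.64)
against 5% (one-tailed, excess depletion), each reported with a 0.05/6
Bonferroni note.

## Codon-switch parsimony

For aligned gapless (outgroup, ingroup1, ingroup2) downstream regions,
the ancestral codon is the outgroup codon when it matches at least one
ingroup codon; a switch is recorded when exactly one ingroup codon
differs from both the other ingroup and the outgroup. Switch classes are
stop→non-stop and non-stop→stop; other substitutions count toward
ancestral denominators only. The null for "in-frame" rates is the same
sequences read with a +1 nucleotide shift: a frame-agnostic substitution
process gives equal rates in both frames, so a frame difference indicates
frame-specific selection. Rates are compared with 2×2 Pearson chi-squares
(no correction), pooled and per position.

## Stop context analyses

"+4" is nucleotide indexing: the first base after the primary stop, i.e.
the first base of codon +1 (elsewhere +k means codon positions). The +4T
motif improves termination via release-factor cross-linking, and because
all stops start with T, +4T enrichment mechanically inflates codon +1
stop frequency. The analyses separate these: +4 base composition by
primary stop (expected order TGA>TAA>TAG if RF2 cross-linking drives the
preference), T-starting codon frequency at +1 vs the +1..+6 mean (all
genes, genes without a +1 ASC, non-stop T-starting codons only), TT/TC
fifth-site variants, and per-codon enrichment scores
`F₁/mean(F₃,F₄,F₅,F₆) − 1` (F₂ excluded from the baseline, following the
published score's definition; the exclusion is taken at face value).

Conditional tests split genes by presence of an ASC at or before +N
(N ≤ +5; +6 has no downstream position left and is rejected) and compare
downstream ASC frequency between groups. Following-base tests compare
P(T | after ASC) against P(T | after primary stop) and P(T | after
non-ASC codon), with a dinucleotide control restricted to non-stop codons
ending in A.

## TT4 versus TT11

TT4 mollicutes read TGA as tryptophan. If TGA is maintained downstream in
TT11 genomes as a fail-safe stop, TT4 genomes should under-use it after
controlling for GC3. Expected frequencies come from a LOESS fit (degree
1, tricube kernel, span = 2/3 as nearest-neighbour fraction, no
robustness iterations, predictions clipped to [0,1], no extrapolation)
of per-position codon frequency on GC3 across TT11 genomes, or from
direct GC3 matching (absolute |ΔGC3| ≤ 0.035 — "within 3.5%" is read as
absolute, GC3 already being a fraction on the percent scale). Deficits
are one-tailed Wilcoxon signed-rank tests of observed − predicted across
TT4 genomes; TT11 mollicutes serve as the negative control, and the same
machinery ranks all 64 codons by deficit p-value.

## Synthetic data: what it emulates and what it does not

The generator draws downstream windows from a configurable chain started
at its stationary distribution, so every codon position shares one null
stop probability and the fitted chain converges to the configured one.
Primary stops follow configurable usage weights (default 0.55/0.30/0.15
for TAA/TGA/TAG, a mid-GC bacterial profile); default GC 0.45 and 500
genes per genome reflect a typical qualifying-gene yield. Enrichment is
injected by drawing a target stop indicator at the flagged position with
probability (1+δ)·p₀ and rejection-resampling whole windows until they
match — overwriting the focal codon in place would distort the
neighbouring dinucleotide transitions that the null is fitted to.
Expression abundances are log-normal (σ = 1); only ranks matter
downstream. Flat-file emission builds gene cassettes (CDS + window +
spacer) on alternating strands with intergenic spacing that clears the
extraction filters, so every generated gene survives the pipeline unless
a filter violation is requested. Triplets evolve chain-drawn ancestors by
independent per-branch per-site substitution (frame-agnostic by default;
an optional boost plants elevated in-frame stop loss); the ledger stores
ancestral and derived sequences so parsimony output can be checked
against exact ground truth.

Synthetic genomes are independent draws with homogeneous composition:
they do not emulate phylogenetic covariance among genomes, operonic gene
overlap, position-dependent composition gradients, or real 3'-UTR motif
structure. Passing calibration therefore shows the statistics behave
correctly *given the null model*, not that the null model captures
everything in real genomes. The `gc3` field of a directly generated UTR
set is the chain's GC content, a synthetic stand-in for the coding-
sequence GC3 the flat-file path computes.

## Numerical and design choices

- Internal coordinates are 0-based half-open; flat-file I/O converts at
  the parse boundary. Intergenic distance runs from the focal 3' end to
  the nearest other-CDS boundary, either strand, in the downstream
  direction; windows wrap only on replicons declared circular.
- The ">100 genes" genome filter counts annotated CDS features (filtering
  precedes window extraction in the pipeline order); genus dedup keeps
  the largest genome; output ordering is deterministic.
- Eukaryote-style windows: 97 nt are extracted, the first 96 (32 codons)
  analysed, keeping windows codon-divisible.
- HEG/LEG are the top/bottom abundance quartiles (n//4 each); ties
  resolved by a single stable ascending sort so the classes stay
  disjoint; a genome is expression-eligible only with >100 genes in each
  class.
- Wilcoxon signed-rank tests drop zero differences and use the exact
  distribution for n ≤ 25 (untied), the normal approximation above.
- A chain row with no observed dinucleotide counts becomes uniform with a
  warning; a zero-probability dead-end under first-base conditioning is
  an error naming the base.
- Chi-square positions with degenerate expected counts (0 or N) are
  skipped with a warning rather than fabricated.
- Default simulation sizes: R = 1000 replicates (configurable), 200
  genomes × 1000 genes for calibration runs, 3000 orthogroups for switch
  recovery, 50 random chains × (200 replicates × 200 sequences) for the
  Monte-Carlo/analytic comparison. These sizes put binomial sampling
  error well below the effect sizes being checked while keeping runs on
  a laptop scale.

## Known limitations

- Only single-span CDS features on one replicon are handled (no joined
  multi-exon locations, no programmed frameshifts); GFF-only annotation
  is out of scope.
- The chain is first-order; higher-order context (trinucleotide and
  beyond) is not modelled, and per-gene nulls are not available.
- Parsimony uses exactly three taxa and undercounts switches where
  multiple branches hit one codon; ledger comparisons bound this error.
- The published pooled switch-rate chi-square of 9.2 is not reproduced by
  a standard 2×2 construction on the published marginals; the standard
  construction is implemented and the printed frequencies, which do
  follow from the marginals, are the quantities checked.
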