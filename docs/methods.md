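# Methods

This note documents the statistical procedures, the defaults and why they
were chosen, the numerical conventions, and what the synthetic cohorts do and
do not establish about real data.

## Data model and conventions

Genotypes are unphased diploid biallelic SNP calls stored as ALT dosage
0/1/2 with −1 for missing; multi-allelic and non-SNP records are skipped at
VCF ingest (the scan operates on MAF-filtered biallelic panels, where split
multi-allelics would be double-counted). Phase is never used: ROH detection
needs only heterozygosity, and haplotype-block estimation works on unphased
genotypes via EM. All coordinates are 1-based inclusive, and every segment
length in the package is `end − start + 1`; the block tables published for
this kind of scan (e.g. a block spanning 31,422,148–31,622,148 listed at
200,001 bp) pin exactly this convention. Chromosome labels are strings, and
QC retains only a configurable autosome set (default "1".."18", the pig
autosomes).

## Quality control

Four steps in a fixed order: (1) drop non-autosomal variants; (2) drop
variants with missingness > 0.1; (3) drop samples with missingness > 0.1,
computed on the surviving variants; (4) drop variants with MAF < 0.05,
computed on the surviving samples. Defaults mirror the standard
`--geno 0.1 --mind 0.1 --maf 0.05` filtering of multi-breed panels. MAF is
always computed from non-missing calls. The filter is idempotent.

LD pruning slides a 50-SNP window advancing by 10 SNPs; within a window,
pairs with dosage-correlation r² > 0.4 (pairwise-complete samples) are
broken greedily. The removal rule is frozen for determinism: violating pairs
are visited in (i, j) index order and the member with smaller MAF is removed
(tie → later position). Tools delegate this tie-break to internal defaults;
any fixed rule is equally defensible, so the package documents one and tests
it against an independent quadratic-time reference.

## Runs of homozygosity

Windows of 50 consecutive SNPs are "hits" when they contain ≤ 3 heterozygous
and ≤ 1 missing call ("1 deletion" in the usual criteria is read as one
missing call). Each SNP gets the fraction of overlapping scored windows that
are hits; windows truncated at chromosome ends are not scored, so terminal
SNPs are covered by fewer windows and the fraction uses the actual count.
SNPs with fraction ≥ 0.05 are eligible; maximal eligible runs are split at
inter-SNP gaps ≥ 250 kb and reported when ≥ 1 Mb long, ≥ 50 SNPs, and at
density ≤ 100 kb/SNP (applied at segment level, `length/n_snps`, matching
the common tool rather than a per-window rule). The hit-proportion step,
minimum SNP count, and minimum length are not part of the published window
criteria; the defaults adopt the conventional tool values (0.05, 50) and a
1 Mb floor because the shortest reported length class starts at 1 Mb. All
are config-exposed.

Length classes partition segments at [1, 5), [5, 10), [10, ∞) Mb.

**Islands.** Per-SNP incidence is the fraction of individuals with at least
one ROH covering the SNP. The island threshold is the k-th largest incidence
over all SNPs with k = ⌈0.01 × n_snps⌉; ties at the cutoff are all selected,
and zero-incidence SNPs are never selected even when the cutoff degenerates
to 0 (a SNP that never occurs in any ROH cannot anchor an island — the
quantile-over-all-SNPs vs nonzero-only choice is otherwise unstated in the
literature this follows). Selected SNPs that are adjacent rows of the matrix
on one chromosome merge into one island.

## Haplotype blocks

Two-locus haplotype frequencies are estimated by EM on the 3×3 unphased
genotype table: all classes except the double heterozygote contribute
determined haplotypes; double heterozygotes are split cis/trans by the
posterior under current frequencies. Convergence at max |Δfreq| < 1e-8,
≤ 1000 iterations; the likelihood is non-decreasing by construction. From
the frequencies: D = p_AB − p_A p_B, D′ = |D|/D_max, r² = D²/(p_A q_A p_B q_B).

The 90% CI on D′ profiles the multinomial likelihood on a deterministic
101-point grid over [0, 1] (sign of D fixed at the MLE, allele frequencies
fixed at their estimates), normalizes the likelihood over the grid, and
takes the bounds at cumulative mass 5% and 95%. This is a transparent,
testable implementation of the confidence-interval approach used by the
standard block-calling tools; it is deterministic and is validated against
degenerate cases (complete LD, independence, tiny n) rather than against any
tool's internal tables.

Blocks follow the CI definition: a pair is strong-LD when CI-low ≥ 0.70 and
CI-high ≥ 0.98, strong-recombination when CI-high < 0.90; other pairs are
uninformative and excluded from denominators. A candidate interval is a
block when its outermost pair is strong-LD and ≥ 95% of its informative
pairs are strong-LD. Candidates are accepted greedily by descending bp
length (ties: leftmost, then smaller span), discarding overlaps. No variant
thresholds for 2–3-SNP candidates are applied (a documented divergence from
tools that special-case small blocks). The cap is 200 kb: pairs farther
apart are never evaluated, so no block exceeds 200,001 bp under the
inclusive length convention. Top blocks are the ⌈1%⌉ longest, cutoff ties
included — tie inclusion is also the parsimonious reading of published
counts slightly above the exact percentile (147 from 14,482).

## Per-SNP F_ST

The two-population Weir–Cockerham variance components a (among populations),
b (among individuals within populations), c (within individuals) are
computed per site from non-missing sample counts, ALT frequencies, and
observed heterozygote frequencies, exactly as in the r = 2 form of the 1984
definitions; θ = a/(a+b+c). Sites with fewer than two non-missing diploids
in either population, or monomorphic in both (zero denominator), are
undefined and excluded from ranking rather than imputed. Ranking uses raw
per-locus θ (negative estimates retained; they cannot reach the top 1%);
the selection takes the ⌈1%⌉ largest defined θ with cutoff ties included.
Multi-locus summaries use the ratio of sums Σa/Σ(a+b+c), which is the
consistent estimator of F under the Balding–Nichols generator.

## Evidence integration

Selected F_ST SNPs become point regions (configurable flank, default 0 —
the most conservative gene assignment; windowed searches can be emulated by
a positive flank), merged when overlapping. Islands and top blocks are
already intervals. A gene is recorded for a source when its span intersects
any region of that source as closed intervals. The candidate set is genes
with ≥ 2 of the four sources {ROH island, haplotype block, F_ST-1, F_ST-2};
the Venn table over source combinations sums to the ledger's gene count and
selection is monotone in the threshold.

## Allele-differentiation follow-up

Fisher's exact test on REF/ALT × population 2×2 tables uses the
minimum-likelihood two-sided convention: the sum of hypergeometric
probabilities ≤ that of the observed table, with a 1e-12 relative tie
tolerance; empty-margin tables return p = 1 by convention. **No
multiple-testing correction is applied anywhere** — the scan reports raw
p < 0.05 throughout, deliberately reproducing the permissive screening style
of this analysis; the intersection across independent evidence sources, not
per-test calibration, is what controls false positives. Per-gene summaries
report the fraction of significant loci per comparison over all QC-surviving
SNPs in the gene span (the denominator is logged; restricting it to other
universes is a caller-side choice). Impact filtering keeps consequence
records at MODERATE or higher on the standard MODIFIER < LOW < MODERATE <
HIGH ordering. Expression correlations are Pearson r per (gene pair, tissue)
across that tissue's samples with the two-sided t-transform (n − 2 df),
retained at p < 0.05; tissues need ≥ 3 samples and zero-variance genes are
dropped.

## Synthetic cohorts

The generator draws ancestral frequencies p ~ U(0.05, 0.95) and population
frequencies Beta(p(1−F)/F, (1−p)(1−F)/F), so F is exactly the expected
differentiation the scan estimates — chosen over coalescent simulation
because it needs no external machinery and yields closed-form recovery
expectations. Defaults emulate a three-group breed panel (focal,
other-indigenous, commercial) at 22/37/31 diploids — about one tenth of a
typical multi-breed resequencing cohort — with 5,000 SNPs on two 50 Mb
chromosomes; these sizes keep every seeded recovery test sharp while running
the whole suite in about a minute. Background loci are independent
(zero LD), so block and ROH false positives are directly measurable.
Plants: autozygous tracts copy one founder haplotype into both of an
individual's gametes (zero heterozygosity by construction); LD regions give
every individual two haplotypes drawn from a small founder pool (founder
columns are forced polymorphic, else a planted SNP would be invisible to
block detection); outlier SNPs override population frequencies. Missingness
is off by default (post-QC panels are near-complete) and configurable.

What passing these tests does **not** show: real cohorts have background LD,
admixture, related individuals, and genotyping error, none of which the
generator emulates. Recovery rates here validate the implementation against
its own model, not the field performance of the scan; dataset-level numbers
from real 891-animal panels (total ROH counts, island counts, empirical θ
thresholds such as 0.723/0.605, intersected gene counts) depend on those
data and are context, not targets.

## Numerical details and edge cases

- Top-percentile selections everywhere use k = ⌈fraction × n⌉ with cutoff
  ties included, so selections can exceed k.
- EM initialization is the uniform simplex point; the double-het split is
  0.5 when both phase products vanish.
- Fisher enumeration runs over the feasible cell range only; p is clipped
  at 1.
- `dprime_ci` raises on monomorphic members; such pairs are skipped in block
  calling and never counted as informative.
- Chromosomes with fewer SNPs than one window produce no ROH calls (logged,
  not an error); QC removing every sample raises an explicit error.
- Pipeline stages are pure functions of (inputs, config, seed); the manifest
  records a config hash, seed, and per-stage row counts, and reruns are
  byte-identical.

## Known limitations

- Block calling evaluates all within-cap pairs with an O(grid) CI each;
  it is intended for focal-breed panels of hundreds of samples and up to a
  few thousand SNPs per chromosome, not for million-SNP genome-wide runs in
  one call.
- The profile-grid CI is coarser (1/100 steps) than analytic intervals;
  bounds are grid values by construction.
- Fisher tests on pooled allele counts treat alleles as independent draws,
  as the published analyses do; family structure within breeds would
  invalidate that assumption.
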