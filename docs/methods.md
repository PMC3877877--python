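# Methods

This note records the models behind each module, the parameters that
matter, the numerical conventions, and what the synthetic data do and do
not establish.

## SNV tables

A table is a pandas DataFrame with fixed columns (chrom, pos, ref, var,
qual) plus per-individual column groups, validated on construction:
genotypes in {−1, 0, 1, 2} (reference-allele copies; −1 uncalled), rows
grouped by chromosome and sorted by position, duplicate (chrom, pos)
rejected at parse (downstream statistics assume unique sites).  Positions
are 1-based inclusive; BED export converts to 0-based half-open.

Header dialect: `#gd_snp` / `#gd_genotype` marker, then
`#individual NAME FIRST_COLUMN [ALIAS]` lines (1-based file columns), then
optional `#column NAME COLUMN` lines declaring appended score columns.  The
written form is canonical: integers bare, floats via `repr`, so
write∘read is the identity on written files (round-trip is byte-exact).

VCF conversion maps GT 0/0→2, 0/1→1, 1/1→0, ./.→−1; the first two AD
values become read counts; missing AD/GQ become −1 placeholders.
Multi-allelic records are skipped with a logged count — the table format is
strictly biallelic.

Filtering is per-individual: depth = ref_reads + var_reads must lie in the
requested range for **every** population member; a −1 read count leaves the
depth undefined and fails any active depth filter (conservative).  The
polymorphism filter drops sites whose called genotypes within the
population are all identical (or absent).

## Diversity and differentiation

Allele counts come from genotypes (a = Σg over called members,
n = 2 × called) or, for pooled samples, from summed reads; the caller
selects the mode (default genotype).

π is the sum over sites of the exact mean pairwise difference
2a(n−a)/(n(n−1)).  θ_W counts segregating sites, each scaled by the
harmonic number of **its own** n−1: with missing genotypes the per-site
sample size varies, so each site contributes with its local a_n rather
than a fixed-n textbook form.  Optional division by a supplied sequence
length L gives per-bp rates; both sums and rates are reported since the
normalisation convention varies between tools.

Three F_ST estimators, all reported per SNV and overall as a
ratio-of-sums (never a mean of per-site ratios, which is biased by
low-information sites):

* **wright** — F = s²_p / p̄(1−p̄) with the unweighted two-deme mean and
  population variance; F ≡ 0 where p̄(1−p̄) = 0.  Bounded in [0, 1].
* **weir_cockerham** — the 1984 two-allele, two-population
  variance-components estimator (a / (a+b+c)) including the heterozygosity
  correction, hence requiring per-individual genotypes; pooled/read mode
  raises.  Sites need pooled sample size > 2.
* **reich** — h_i = a_i(n_i−a_i)/(n_i(n_i−1));
  N = (p̂₁−p̂₂)² − h₁/n₁ − h₂/n₂; D = N + h₁ + h₂; unbiased, negative
  values possible and reported as-is.  Sites need n_i ≥ 2 in both
  populations; failing sites are excluded from per-SNV and overall sums
  with a logged count.

A site scoreable in one population only is unscoreable (NaN in the score
column).  LSBL_A = (F_AB + F_AC − F_BC)/2; negative branches are reported,
not clamped, because they carry signal about estimator noise.

## Remarkable intervals

Scores minus the shift are decomposed per chromosome into all
maximal-scoring subsequences with the linear-time Ruzzo–Tompa algorithm.
Reported intervals are disjoint, have positive total, and extending or
trimming either end cannot increase the total.  Coordinates are the
first/last member SNV positions (SNV-bounded, not round-number windows).
Ties in the ranking break leftmost, then shortest.  A percentile helper
converts "use the 90th percentile" into a concrete shift by linear
interpolation of order statistics.

Raising the shift shortens intervals and nests each new interval inside an
interval of the lower shift; the *count* of intervals can transiently rise
when a long interval splits, so only length/nesting are monotone and only
those are asserted by the tests.

Shuffling for significance permutes scores genome-wide by default
(positions fixed); `within_chrom=True` restricts permutation to each
chromosome.  The empirical p uses the +1 correction, (1 + c)/(K + 1), so
p is never 0.  Gene intersection uses closed 1-based spans with ≥ 1 bp
overlap.

## Admixture painting

States are unordered source pairs: 3 for two sources, 6 for three.
Emissions at a called genotype g use source reference-allele frequencies
clamped into [ε, 1−ε] with ε = 1/(2n+2), n the source alleles observed at
the site — the minimal correction that keeps log-emissions finite when a
source sample is fixed.  Natural logs throughout, so the switch penalty λ
is in nats per switch; λ = 0 reduces to the per-SNV argmax, large λ forces
a single state.  The DP is exact (verified against exhaustive path
enumeration); ties prefer no-switch, then the lowest state index.
Uncalled genotypes are skipped: no emission, no switch opportunity.
Chromosomes are painted independently.

Segment bp spans place boundaries at the midpoint between the SNVs
flanking each switch; SNV positions are also reported.  Ancestry
proportions are emitted both bp-weighted and SNV-weighted, since either
convention is defensible and they differ when marker density varies.

AIM selection keeps SNVs whose per-SNV F_ST between sources (max over
pairs for three sources) exceeds a threshold, then thins to a minimum
spacing with the greedy left-to-right sampler.  Sites unscoreable under
the chosen estimator are never AIMs.

## Trees

A pair's informative sites are those where both genotypes are called (and
both depths reach `min_depth` when read counts exist); the distance is
differing genotypes / informative sites.  A heterozygote–homozygote pair
counts as one full difference by default; `allele_sharing=True` scores
|g₁−g₂|/2 instead — both readings of "genotypic difference" are offered
because the convention is genuinely ambiguous.  Neighbor joining follows
Saitou–Nei with the Q criterion, joining the lowest-index pair on ties;
negative branch lengths are clamped to 0 with a warning (standard
practice).  On additive matrices the implementation reproduces the
generating tree's patristic distances to 1e−9.

## Gene sets and pathways

Fisher enrichment tests the 2×2 table
[[k, n−k], [K−k, N−K−(n−k)]] two-tailed by the method of small p-values
(sum of hypergeometric outcomes no more probable than observed), ranked by
the category fraction k/K then p.  Input genes outside the background are
dropped with a warning.

Pathway disruption enumerates simple source→sink paths (sources: in-degree
0; sinks: out-degree 0, recomputed after node deletion; edge-count
lengths; an isolated node contributes no path).  Enumeration is exhaustive
with a hard cap (default 10⁶) that raises rather than truncates; curated
pathway maps are small enough that the cap is a safety net, not a limit.
Δ values are before − after; when deletion severs all paths the after-mean
counts as 0, so Δ mean length equals the original mean.  Ranking is by
|Δ mean length| then |Δ paths|, descending.

Category clustering is single-linkage with overlap
|A∩B| / min(|A|, |B|) ≥ threshold; the min-size denominator (rather than
Jaccard) lets a small category join a large one it is mostly contained in,
which matches how nested GO terms behave.  Cluster count is non-decreasing
in the threshold.

## Synthetic data

The generator defines the study conditions for all tests:

* **Populations** — Balding–Nichols drift: ancestral frequencies
  ~ Uniform(0.05, 0.95); per-population frequencies ~ Beta with the
  ancestral mean and variance scaled by a drift parameter F ∈ [0, 1);
  genotypes Binomial(2, p).  Defaults: 2 populations × 10 diploids,
  1,000 SNVs on 2 × 10 Mb chromosomes, F = 0.1 — a differentiation level
  typical of conspecific populations.
* **Admixed individuals** — each chromosome copy is tiled with
  exponential-length tracts (memoryless — the simplest generative match to
  the DP's run-length structure) whose sources follow the mix proportions;
  alleles are Bernoulli draws from the tract source's frequency; truth
  tracts record the unordered source pair with equal-state neighbours
  merged.
* **Read counts** — depth ~ Poisson(λ, default 20); each read reports the
  reference allele with probability (g/2)(1−e) + (1−g/2)e, e the
  symmetric error rate (default 0.01).

Everything is reproducible from (config, seed), and generated files parse
through the format layer unchanged.

The generator draws sites independently: no linkage disequilibrium beyond
tract structure, no mutation-rate heterogeneity, no allele-frequency
spectrum realism, no mapping artefacts.  Passing tests therefore establish
algorithmic correctness (oracle equivalence, estimator calibration,
parameter recovery under the stated model), not robustness to the
correlated noise of real resequencing data.

### Problem sizes used by the test suite

Chosen as the smallest sizes at which each check is meaningful:
interval-finder equivalence on 1,000 vectors of ≤ 50 dyadic scores (exact
arithmetic makes tie-breaking well-defined); painting-DP equivalence on
200 instances of ≤ 10 SNVs (2 sources) and ≤ 8 (3 sources, 6⁸ paths);
admixture recovery on 10 × 30 Mb chromosomes, 3,000 SNVs, source drift
F = 0.85, AIMs at F_ST > 0.8, 3 Mb mean tracts, λ = 3, averaged over three
individuals (the span-fraction of a single tract realization has SD ≈ 0.05,
so a single individual would test the tract draw, not the method);
Reich-estimator calibration over 200 no-drift replicates of 300 SNVs;
Fisher enumeration over every 2×2 table with background ≤ 40.

## Known limitations

* No haplotype phase, recombination maps, or admixture-time inference in
  the painting model — it is deliberately simpler than SABER/HAPMIX-class
  models and is meant for datasets too small or noisy to fit them.
* The Weir–Cockerham estimator is genotype-only; pooled data get Wright or
  Reich.
* θ_W with heavy missingness mixes per-site sample sizes; comparisons
  across datasets with different call rates should use π.
* Pathway path enumeration is exponential in the worst case; the cap makes
  failure explicit rather than silent.
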