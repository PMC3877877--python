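# gendiv

Population-genomic analyses on SNV tables for small labs working with
resequencing data from non-model organisms: diversity and differentiation
statistics, window-free selective-sweep scans, admixture painting,
genotype-distance phylogenies, and gene-set/pathway ranking — plus a
synthetic-data generator so every analysis can be exercised end-to-end at
desk scale with known truth.

## Data model

The central object is the **SNV table**: one row per single-nucleotide
variant with five fixed columns (chromosome, 1-based position, reference
and variant allele, site quality) followed by per-individual columns.  Two
tab-delimited dialects are supported:

* **gd_snp** — four columns per individual: reference-read count,
  variant-read count, genotype, genotype quality;
* **gd_genotype** — a single genotype column per individual.

Genotypes count copies of the **reference** allele (0, 1, 2; −1 = uncalled).
VCF files carrying `GT` (and optionally `AD`, `GQ`) convert directly.
Analyses append named numeric columns to the table, so pipelines chain:
aggregate → score → scan.

## Methods at the core

* **Diversity** — per site with `a` reference alleles of `n` called,
  π_site = 2a(n−a)/(n(n−1)); π = Σ π_site; Watterson's
  θ_W = Σ_seg 1/a_n with a_n = Σ_{i<n} 1/i.
* **F_ST** — three estimators between two populations: Wright's
  F = s²_p / p̄(1−p̄); Weir–Cockerham's two-allele variance-components
  estimator; and Reich's unbiased moment estimator
  F = N/D, N = (p̂₁−p̂₂)² − h₁/n₁ − h₂/n₂, D = N + h₁ + h₂, with overall
  values as ratios of summed components (ΣN/ΣD).
* **LSBL** — the locus-specific branch length of population A from pairwise
  F_ST values: (F_AB + F_AC − F_BC)/2.
* **Remarkable intervals** — subtract a single tuning constant (the *shift*)
  from a per-SNV score column and report all maximal-scoring runs
  (Ruzzo–Tompa, linear time): intervals whose summed shifted score cannot
  be improved by trimming or extending.  No windows, no window-size knobs.
  Significance by score shuffling (empirical p).
* **Admixture painting** — partition each chromosome of a test individual
  into *interval genotypes* over 2–3 source populations (3 or 6 states).
  Emission probabilities come from source allele frequencies (p², 2p(1−p),
  (1−p)² for a same-source pair; p·q mixtures for mixed pairs); a dynamic
  program maximizes total log-likelihood minus a per-switch penalty λ
  (nats).
* **Trees** — pairwise distance = differing genotypes / informative sites;
  Saitou–Nei neighbor joining, re-implemented with deterministic
  tie-breaking, Newick output.
* **Gene sets** — two-tailed Fisher exact enrichment, source→sink
  path-disruption ranking of directed pathway graphs, and single-linkage
  clustering of categories by shared genes.

## Worked example

```sh
$ python examples/sweep_scan.py
shift value: 0.9 (score subtracted from each SNV's homozygosity)
rank 1: chr1:31000-130000  score=10.000  n_snvs=100  empirical_p=0.010
rank 2: chr1:1000-10000  score=1.000  n_snvs=10  empirical_p=0.960
```

The toy pooled panel contains a 10-SNV and a 100-SNV run of fully
homozygous sites (pooled counts 30/0, homozygosity (30²+0²)/30² = 1.0)
in a heterozygous background.  At shift 0.9 each such SNV contributes 0.1,
so the runs score 1.0 and 10.0 and the SNV-dense run ranks first — the
signature property of the window-free scan (a fixed-window scan scores
both regions identically).  More examples live in `examples/`
(F_ST/LSBL, admixture painting, NJ trees, pathway ranking), and the same
operations are scriptable via the `gendiv` CLI (`gendiv --help`).

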