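"""Window-free sweep scan on a pooled sample.

Builds a toy pooled panel containing two runs of fully homozygous SNVs
(pooled counts 30/0) embedded in heterozygous background, computes per-SNV
homozygosity, and finds the maximal intervals of shifted scores.
"""

from gendiv import aggregate_population, remarkable_intervals, specify_population
from gendiv.intervals import shuffle_significance
from gendiv.stats import homozygosity_score
from gendiv import synth

table = synth.pooled_chicken_toy()
pop = specify_population(table, ["pool"], "domestic")
agg = aggregate_population(table, pop)
hom = [
    homozygosity_score(r, v)
    for r, v in zip(agg.df["domestic:ref_total"], agg.df["domestic:var_total"])
]
scored = agg.with_extra_column("homozygosity", hom)

shift = 0.9
intervals = remarkable_intervals(scored, "homozygosity", shift)
sig = shuffle_significance(
    scored.df["chrom"].to_numpy(), scored.df["pos"].to_numpy(),
    scored.df["homozygosity"].to_numpy(), shift, n_shuffles=100, seed=1,
)

print(f"shift value: {shift} (score subtracted from each SNV's homozygosity)")
for iv in intervals:
    print(
        f"rank {iv.rank}: {iv.chrom}:{iv.start}-{iv.end}  "
        f"score={iv.score:.3f}  n_snvs={iv.n_snvs}  "
        f"empirical_p={sig.empirical_p(iv.score):.3f}"
    )
print(
    "\nEach interval is a run of SNVs whose summed shifted homozygosity\n"
    "cannot be improved by trimming or extending it; the 100-SNV run\n"
    "outscores the 10-SNV run ten-fold, favouring SNV-dense sweeps.\n"
    f"Shuffle cutoff over 100 permutations: {sig.cutoff:.3f}. Only the\n"
    "100-SNV interval beats it: permutation destroys the clustering of\n"
    "high scores, but with 110 of 150 scores above the shift, runs the\n"
    "size of the 10-SNV interval arise by chance in most shuffles."
)
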