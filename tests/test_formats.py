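import numpy as np
import pytest

from gendiv import (
    GdFormatError,
    GdValidationError,
    aggregate_population,
    convert_vcf,
    coverage_summary,
    filter_snvs,
    read_gd_genotype,
    read_gd_snp,
    sample_uniform,
    specify_population,
)
from gendiv import synth
from conftest import make_genotype_table


GD_SNP_SMALL = """\
#gd_snp
#individual\ta\t6
#individual\tb\t10
chr1\t100\tA\tG\t50\t10\t0\t2\t40\t3\t4\t1\t30
chr1\t250\tC\tT\t60\t0\t12\t0\t45\t5\t5\t1\t35
"""


def test_read_gd_snp_small(tmp_path):
    f = tmp_path / "t.gd_snp"
    f.write_text(GD_SNP_SMALL)
    t = read_gd_snp(f)
    assert t.n_snvs == 2
    assert [i.name for i in t.individuals] == ["a", "b"]
    rr, vr = t.read_counts(["a", "b"])
    assert rr[0, 0] == 10 and vr[1, 1] == 5
    assert t.genotypes(["a"])[:, 0].tolist() == [2, 0]


def test_missing_header_is_format_error(tmp_path):
    f = tmp_path / "bad.gd_snp"
    f.write_text("chr1\t100\tA\tG\t50\t1\t1\t1\t1\n")
    with pytest.raises(GdFormatError):
        read_gd_snp(f)


def test_bad_genotype_names_the_row(tmp_path):
    f = tmp_path / "bad.gd_snp"
    f.write_text(GD_SNP_SMALL.replace("\t2\t40", "\t3\t40"))
    with pytest.raises(GdValidationError, match="row 1"):
        read_gd_snp(f)


def test_duplicate_position_rejected(tmp_path):
    f = tmp_path / "dup.gd_snp"
    f.write_text(GD_SNP_SMALL.replace("250", "100"))
    with pytest.raises(GdValidationError, match="duplicate"):
        read_gd_snp(f)


def test_gd_genotype_reads_absent(tmp_path):
    f = tmp_path / "t.gd_genotype"
    f.write_text(
        "#gd_genotype\n#individual\tx\t6\n"
        "chr1\t10\tA\tC\t-1\t2\nchr1\t20\tA\tC\t-1\t1\nchr1\t30\tG\tT\t-1\t-1\n"
    )
    t = read_gd_genotype(f)
    assert t.n_snvs == 3 and t.mode == "gd_genotype"
    with pytest.raises(GdValidationError):
        t.read_counts(["x"])


def test_empty_body_valid_header(tmp_path):
    f = tmp_path / "empty.gd_genotype"
    f.write_text("#gd_genotype\n#individual\tx\t6\n")
    t = read_gd_genotype(f)
    assert t.n_snvs == 0


@pytest.mark.parametrize("mode", ["gd_genotype", "gd_snp"])
def test_round_trip_byte_identical(tmp_path, mode):
    cfg = synth.SimConfig(n_snvs=80, n_pops=2, n_individuals=3, seed=9)
    table, _ = synth.simulate_populations(cfg)
    if mode == "gd_snp":
        table = synth.attach_read_counts(table, 15, 0.02, 5)
    f1, f2 = tmp_path / "a.gd", tmp_path / "b.gd"
    table.write(f1)
    reader = read_gd_snp if mode == "gd_snp" else read_gd_genotype
    reader(f1).write(f2)
    assert f1.read_bytes() == f2.read_bytes()


# -- populations -----------------------------------------------------------


def test_specify_population_resolves_names(two_pop_table):
    table, *_ = two_pop_table
    pop = specify_population(table, ["pop1_1", "pop1_2"], "north")
    assert pop.name == "north" and len(pop) == 2


def test_specify_population_unknown_name(two_pop_table):
    table, *_ = two_pop_table
    with pytest.raises(KeyError, match="nobody"):
        specify_population(table, ["nobody"], "x")


def test_specify_population_empty_and_duplicates(two_pop_table):
    table, *_ = two_pop_table
    with pytest.raises(GdValidationError):
        specify_population(table, [], "x")
    pop = specify_population(table, ["pop1_1", "pop1_1"], "x")
    assert len(pop) == 1  # deduplicated with warning


# -- filtering / aggregation ----------------------------------------------


def test_filter_by_depth_per_individual(tmp_path):
    t = make_genotype_table([[2], [1], [0]])
    t = synth.attach_read_counts(t, 10, 0.0, 1)
    pop = specify_population(t, ["ind1"], "p")
    rr, vr = t.read_counts(pop)
    depth = (rr + vr)[:, 0]
    kept = filter_snvs(t, pop, min_depth=int(np.median(depth)))
    assert kept.n_snvs == int((depth >= np.median(depth)).sum())
    # identity when nothing active
    assert filter_snvs(t, pop).n_snvs == t.n_snvs


def test_filter_undefined_depth_fails_conservatively():
    t = make_genotype_table([[2, 2]])
    t = synth.attach_read_counts(t, 10, 0.0, 1)
    t.df.loc[0, "ind1:ref_reads"] = -1  # undefined depth
    pop = specify_population(t, ["ind1", "ind2"], "p")
    assert filter_snvs(t, pop, min_depth=1).n_snvs == 0
    assert filter_snvs(t, pop).n_snvs == 1  # no active depth filter


def test_filter_require_polymorphic():
    t = make_genotype_table([[2, 2, 2], [2, 1, 0], [1, 1, -1], [-1, -1, -1]])
    pop = specify_population(t, ["ind1", "ind2", "ind3"], "p")
    kept = filter_snvs(t, pop, require_polymorphic=True)
    assert kept.df["pos"].tolist() == [200]


def test_filter_output_is_ordered_subset(two_pop_table):
    table, p1, *_ = two_pop_table
    kept = filter_snvs(table, p1, require_polymorphic=True)
    pos = kept.df[["chrom", "pos"]].apply(tuple, axis=1).tolist()
    orig = table.df[["chrom", "pos"]].apply(tuple, axis=1).tolist()
    it = iter(orig)
    assert all(p in it for p in pos)  # subsequence check


@pytest.mark.parametrize(
    "genotypes,ref,var",
    [([[2, 1, 0, -1]], 3, 3), ([[2, 2]], 4, 0), ([[-1, -1]], 0, 0)],
)
def test_aggregate_genotype_mode(genotypes, ref, var):
    t = make_genotype_table(genotypes)
    pop = specify_population(t, [f"ind{i+1}" for i in range(len(genotypes[0]))], "p")
    agg = aggregate_population(t, pop)
    assert agg.df["p:ref_total"].iloc[0] == ref
    assert agg.df["p:var_total"].iloc[0] == var


def test_aggregate_read_mode_sums_reads(chicken_toy):
    pop = specify_population(chicken_toy, ["pool"], "dom")
    agg = aggregate_population(chicken_toy, pop)
    assert agg.df["dom:ref_total"].iloc[0] == 30
    assert agg.df["dom:var_total"].iloc[0] == 0


def test_aggregate_totals_conservation(two_pop_table):
    table, p1, *_ = two_pop_table
    agg = aggregate_population(table, p1)
    called = (table.genotypes(p1) >= 0).sum(axis=1)
    tot = agg.df["P1:ref_total"] + agg.df["P1:var_total"]
    assert (tot == 2 * called).all()


# -- coverage / sampling ---------------------------------------------------


def test_coverage_summary_stats():
    t = make_genotype_table([[2], [2], [2]])
    t = synth.attach_read_counts(t, 10, 0.0, 1)
    for i, (r, v) in enumerate([(4, 0), (4, 0), (8, 0)]):
        t.df.loc[i, "ind1:ref_reads"] = r
        t.df.loc[i, "ind1:var_reads"] = v
    pop = specify_population(t, ["ind1"], "p")
    s = coverage_summary(t, pop)
    assert s["mean"].iloc[0] == pytest.approx(16 / 3)
    assert s["median"].iloc[0] == 4
    assert s["histogram"].iloc[0].sum() == 3


def test_coverage_flags_zero_depth_individual():
    t = make_genotype_table([[2, 2]] * 5)
    t = synth.attach_read_counts(t, 20, 0.0, 1)
    for i in range(5):
        t.df.loc[i, "ind2:ref_reads"] = 0
        t.df.loc[i, "ind2:var_reads"] = 0
    pop = specify_population(t, ["ind1", "ind2"], "p")
    s = coverage_summary(t, pop).set_index("individual")
    assert not s.loc["ind1", "low_coverage"]
    assert s.loc["ind2", "low_coverage"]


def test_coverage_rejects_genotype_mode():
    t = make_genotype_table([[2]])
    pop = specify_population(t, ["ind1"], "p")
    with pytest.raises(GdValidationError):
        coverage_summary(t, pop)


def test_sample_uniform_greedy():
    t = make_genotype_table(
        [[2]] * 4, positions=[1, 50_000, 120_000, 260_000]
    )
    kept = sample_uniform(t, 100_000)
    assert kept.df["pos"].tolist() == [1, 120_000, 260_000]
    assert sample_uniform(t, 1).n_snvs == 4  # identity


def test_sample_uniform_spacing_invariant(two_pop_table):
    table, *_ = two_pop_table
    kept = sample_uniform(table, 200_000)
    for _, grp in kept.df.groupby("chrom"):
        assert (np.diff(grp["pos"].to_numpy()) >= 200_000).all()


# -- VCF conversion --------------------------------------------------------

VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1
chr1\t100\t.\tA\tG\t50\tPASS\t.\tGT:AD:GQ\t0/1:7,5:40
chr1\t200\t.\tC\tT\t60\tPASS\t.\tGT:AD:GQ\t./.:.:.
chr1\t300\t.\tG\tA,T\t30\tPASS\t.\tGT:AD:GQ\t1/2:1,2,3:10
chr1\t400\t.\tT\tC\t70\tPASS\t.\tGT:AD:GQ\t1/1:0,9:55
chr1\t500\t.\tA\tC\t80\tPASS\t.\tGT:AD:GQ\t0/0:12,0:60
"""


def test_convert_vcf_mapping(tmp_path):
    f = tmp_path / "t.vcf"
    f.write_text(VCF)
    t = convert_vcf(f)
    assert t.n_snvs == 4  # tri-allelic row skipped
    assert t.n_skipped_multiallelic == 1
    df = t.df
    assert df.loc[0, "s1:gt"] == 1
    assert df.loc[0, "s1:ref_reads"] == 7 and df.loc[0, "s1:var_reads"] == 5
    assert df.loc[0, "s1:gq"] == 40
    assert df.loc[1, "s1:gt"] == -1  # ./. uncalled
    assert df.loc[2, "s1:gt"] == 0  # 1/1 -> zero reference copies
    assert df.loc[3, "s1:gt"] == 2  # 0/0 -> two reference copies


def test_convert_vcf_without_gt_errors(tmp_path):
    f = tmp_path / "nogt.vcf"
    f.write_text(
        VCF.replace("GT:AD:GQ", "AD:GQ")
        .replace("0/1:", "")
        .replace("./.:", "")
        .replace("1/2:", "")
        .replace("1/1:", "")
        .replace("0/0:", "")
        .replace("##FORMAT=<ID=GT,Number=1,Type=String,Description=\"Genotype\">\n", "")
    )
    with pytest.raises(GdFormatError):
        convert_vcf(f)
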