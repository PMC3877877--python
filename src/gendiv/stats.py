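"""Population-genetic statistics on SNV tables.

Per-SNV and aggregate measures: allele frequencies, pooled homozygosity,
nucleotide diversity (pi) and Watterson's theta, three F_ST estimators
(Wright's original definition and the Weir-Cockerham and Reich unbiased
estimators), and the locus-specific branch length (LSBL).

Allele counts use the reference allele: at a site, ``a`` reference alleles
out of ``n`` called alleles.  In genotype mode a = sum of called genotypes
and n = 2 x called diploids; in pooled/read mode a and n come from summed
read counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .formats import Population, SnvTable

log = logging.getLogger(__name__)

ESTIMATORS = ("wright", "weir_cockerham", "reich")

__all__ = [
    "AlleleCounts",
    "FstResult",
    "allele_frequency",
    "homozygosity_score",
    "site_allele_counts",
    "nucleotide_diversity",
    "per_snp_fst",
    "overall_fst",
    "lsbl",
]


@dataclass(frozen=True)
class AlleleCounts:
    """``ref_count`` reference alleles out of ``total`` called alleles."""

    ref_count: int
    total: int

    def __post_init__(self) -> None:
        if not (0 <= self.ref_count <= self.total):
            raise ValueError(f"need 0 <= a <= n, got a={self.ref_count}, n={self.total}")


@dataclass
class FstResult:
    estimator: str
    overall: float
    per_snp: np.ndarray | None = None  # NaN where unscoreable
    n_skipped: int = 0


def allele_frequency(counts: AlleleCounts) -> float:
    """Reference-allele frequency a/n."""
    if counts.total == 0:
        raise ValueError("allele frequency undefined for n = 0")
    return counts.ref_count / counts.total


def homozygosity_score(ref_total: float, var_total: float) -> float:
    """Pooled homozygosity (r^2 + v^2) / (r + v)^2.

    The sum of squared allele frequencies; equals 1 - heterozygosity.
    Symmetric in (r, v), minimum 0.5 at r = v, and 1 iff one count is zero.
    """
    tot = ref_total + var_total
    if tot <= 0:
        raise ValueError("homozygosity undefined when r + v = 0")
    return (ref_total**2 + var_total**2) / tot**2


def site_allele_counts(
    table: SnvTable, pop: Population, mode: str = "genotype"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (a, n) arrays for ``pop``.

    ``mode="genotype"`` counts alleles from called genotypes; ``mode="reads"``
    sums read counts (pooled samples).  Missing values contribute nothing.
    """
    if mode == "genotype":
        gt = table.genotypes(pop)
        called = gt >= 0
        a = np.where(called, gt, 0).sum(axis=1)
        n = 2 * called.sum(axis=1)
    elif mode == "reads":
        rr, vr = table.read_counts(pop)
        a = np.where(rr >= 0, rr, 0).sum(axis=1)
        n = a + np.where(vr >= 0, vr, 0).sum(axis=1)
    else:
        raise ValueError(f"unknown counting mode {mode!r}")
    return a.astype(np.int64), n.astype(np.int64)


# ---------------------------------------------------------------------------
# diversity


def _harmonic(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n)))  # a_n = sum_{i=1}^{n-1} 1/i


def nucleotide_diversity(
    table: SnvTable,
    pop: Population,
    mode: str = "genotype",
    length: float | None = None,
) -> dict:
    """Nucleotide diversity pi and Watterson's theta over the table's SNVs.

    Per site with a reference alleles of n called, pi_site = 2a(n-a)/(n(n-1))
    — the mean pairwise difference over all allele pairs.  pi is the sum of
    pi_site.  theta_W counts segregating sites, each scaled by 1/a_n with
    a_n the harmonic number of its own n-1 (sites vary in call rate, so each
    contributes with its own sample size).  Sites with n < 2 are skipped.
    If ``length`` is given, per-base-pair rates are reported as well.
    """
    a, n = site_allele_counts(table, pop, mode)
    usable = n >= 2
    if not usable.any():
        raise ValueError("no site with >= 2 called alleles")
    a, n = a[usable], n[usable]
    with np.errstate(divide="ignore", invalid="ignore"):
        pi_site = 2.0 * a * (n - a) / (n * (n - 1.0))
    seg = (a > 0) & (a < n)
    theta = float(sum(1.0 / _harmonic(int(nn)) for nn in n[seg]))
    out = {
        "pi": float(pi_site.sum()),
        "theta_w": theta,
        "n_segregating": int(seg.sum()),
        "n_sites_used": int(usable.sum()),
        "pi_site": pi_site,
    }
    if length is not None:
        if length <= 0:
            raise ValueError("length must be positive")
        out["pi_per_bp"] = out["pi"] / length
        out["theta_w_per_bp"] = theta / length
    return out


# ---------------------------------------------------------------------------
# F_ST


def _wright_components(a1, n1, a2, n2):
    """(numerator, denominator) per site for Wright's F_ST on two demes.

    F = s^2_p / (pbar (1-pbar)) with pbar the unweighted mean of the two
    allele frequencies and s^2_p their population variance.
    """
    p1, p2 = a1 / n1, a2 / n2
    pbar = (p1 + p2) / 2.0
    s2 = (p1 - pbar) ** 2 / 2.0 + (p2 - pbar) ** 2 / 2.0
    return s2, pbar * (1.0 - pbar)


def _reich_components(a1, n1, a2, n2):
    """(N, D) per site for the Reich unbiased moment estimator.

    h_i = a_i(n_i - a_i) / (n_i(n_i - 1));
    N = (a1/n1 - a2/n2)^2 - h1/n1 - h2/n2;  D = N + h1 + h2.
    """
    h1 = a1 * (n1 - a1) / (n1 * (n1 - 1.0))
    h2 = a2 * (n2 - a2) / (n2 * (n2 - 1.0))
    N = (a1 / n1 - a2 / n2) ** 2 - h1 / n1 - h2 / n2
    return N, N + h1 + h2


def _wc_components(table: SnvTable, pop1: Population, pop2: Population):
    """(a, a+b+c) variance components of the Weir-Cockerham (1984) estimator.

    Two-allele, two-population form with the heterozygosity correction, so
    per-individual genotypes are required.  Sites need >= 1 called diploid
    in each population and pooled sample size > 2.
    """
    comp = []
    for pop in (pop1, pop2):
        gt = table.genotypes(pop)
        called = gt >= 0
        ni = called.sum(axis=1).astype(float)  # diploids called
        ai = np.where(called, gt, 0).sum(axis=1).astype(float)
        het = ((gt == 1) & called).sum(axis=1).astype(float)
        comp.append((ni, ai, het))
    (n1, a1, het1), (n2, a2, het2) = comp
    r = 2.0
    ok = (n1 >= 1) & (n2 >= 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        p1, p2 = a1 / (2 * n1), a2 / (2 * n2)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (het1 + het2) / (r * nbar)
        qbar = 1.0 - pbar
        A = (nbar / nc) * (
            s2 - (pbar * qbar - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
        )
        B = (nbar / (nbar - 1.0)) * (
            pbar * qbar - s2 * (r - 1.0) / r - hbar * (2 * nbar - 1.0) / (4.0 * nbar)
        )
        C = hbar / 2.0
    ok &= nbar > 1  # nbar - 1 in denominators
    return np.where(ok, A, np.nan), np.where(ok, A + B + C, np.nan)


def _fst_components(
    table: SnvTable,
    pop1: Population,
    pop2: Population,
    estimator: str,
    mode: str,
) -> tuple[np.ndarray, np.ndarray]:
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")
    if estimator == "weir_cockerham":
        if mode != "genotype":
            raise ValueError("weir_cockerham requires genotype mode (het counts)")
        return _wc_components(table, pop1, pop2)
    a1, n1 = site_allele_counts(table, pop1, mode)
    a2, n2 = site_allele_counts(table, pop2, mode)
    a1, n1, a2, n2 = (x.astype(float) for x in (a1, n1, a2, n2))
    if estimator == "wright":
        ok = (n1 >= 1) & (n2 >= 1)
    else:  # reich: h_i needs n_i >= 2
        ok = (n1 >= 2) & (n2 >= 2)
    num = np.full(table.n_snvs, np.nan)
    den = np.full(table.n_snvs, np.nan)
    if ok.any():
        f = _wright_components if estimator == "wright" else _reich_components
        num[ok], den[ok] = f(a1[ok], n1[ok], a2[ok], n2[ok])
    return num, den


def per_snp_fst(
    table: SnvTable,
    pop1: Population,
    pop2: Population,
    estimator: str = "reich",
    mode: str = "genotype",
    column: str | None = None,
) -> tuple[SnvTable, FstResult]:
    """Per-SNV F_ST between two populations, appended as a score column.

    Sites where either population lacks the called alleles the estimator
    needs are unscoreable and carry NaN (they are also excluded from the
    overall ratio-of-sums).  Wright per-SNV values lie in [0, 1]; the
    unbiased estimators may be negative.
    """
    num, den = _fst_components(table, pop1, pop2, estimator, mode)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = num / den
    # a monomorphic shared site has zero variance and zero denominator
    zero_both = np.isfinite(num) & (den == 0)
    if estimator == "wright":
        f[zero_both] = 0.0
    ok = np.isfinite(f)
    n_skipped = int((~ok).sum())
    if n_skipped:
        log.info("per_snp_fst[%s]: %d unscoreable sites", estimator, n_skipped)
    try:
        overall = _overall_from_components(num, den)
    except ValueError:
        overall = float("nan")  # no scoreable site; per-SNP column still appended
    name = column or f"fst_{estimator}:{pop1.name}:{pop2.name}"
    out = table.with_extra_column(name, f)
    return out, FstResult(estimator, overall, per_snp=f, n_skipped=n_skipped)


def _overall_from_components(num: np.ndarray, den: np.ndarray) -> float:
    ok = np.isfinite(num) & np.isfinite(den)
    d = den[ok].sum()
    if not ok.any() or d == 0:
        raise ValueError("overall F_ST undefined: zero denominator sum")
    return float(num[ok].sum() / d)


def overall_fst(
    table: SnvTable,
    pop1: Population,
    pop2: Population,
    estimator: str = "reich",
    mode: str = "genotype",
) -> float:
    """Overall F_ST as the ratio of summed per-site components (not the mean
    of per-site ratios): sum(N)/sum(D) for Reich, and the analogous ratio of
    summed numerator and denominator terms for Wright and Weir-Cockerham."""
    num, den = _fst_components(table, pop1, pop2, estimator, mode)
    return _overall_from_components(num, den)


def lsbl(f_ab: float, f_ac: float, f_bc: float) -> float:
    """Locus-specific branch length of population A.

    Given pairwise F_ST values for (A,B), (A,C) and (B,C), the branch length
    of A is (f_ab + f_ac - f_bc) / 2.  Negative results are reported as-is.
    """
    return (f_ab + f_ac - f_bc) / 2.0
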