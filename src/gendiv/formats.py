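"""SNV tables in the gd_snp / gd_genotype dialects.

A *gd_snp* table is a tab-delimited file with one row per single-nucleotide
variant.  Five fixed columns (chromosome, 1-based position, reference allele,
variant allele, site quality) are followed by four columns per individual:
reference-read count, variant-read count, genotype, and genotype quality.
The genotype counts copies of the **reference** allele (0, 1 or 2; -1 means
uncalled).  The *gd_genotype* variant carries a single genotype column per
individual; read counts and qualities are uniformly -1 (absent).

Header lines start with ``#``.  The dialect used here is::

    #gd_snp
    #individual<TAB>NAME<TAB>FIRST_COLUMN[<TAB>ALIAS]
    #column<TAB>NAME<TAB>COLUMN

``FIRST_COLUMN`` is the 1-based file column of the individual's first data
column.  ``#column`` lines declare extra numeric columns appended by analyses
(per-SNV scores, aggregated allele totals, ...), mirroring the numbered-column
chaining convention of the original toolset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

FIXED_COLUMNS = ("chrom", "pos", "ref", "var", "qual")
VALID_GENOTYPES = frozenset((-1, 0, 1, 2))

__all__ = [
    "GdFormatError",
    "GdValidationError",
    "Individual",
    "Population",
    "SnvTable",
    "read_gd_snp",
    "read_gd_genotype",
    "write_gd_snp",
    "write_gd_genotype",
    "convert_vcf",
    "specify_population",
    "filter_snvs",
    "aggregate_population",
    "coverage_summary",
    "sample_uniform",
]


class GdFormatError(ValueError):
    """Raised when a file does not conform to the gd_snp/gd_genotype dialect."""


class GdValidationError(ValueError):
    """Raised when a structurally valid file violates a table invariant."""


@dataclass(frozen=True)
class Individual:
    """One sample column-group in a gd table.

    ``first_column`` is the 1-based file column of the individual's first
    data column (its ref-read count in gd_snp mode, its genotype in
    gd_genotype mode).
    """

    name: str
    first_column: int
    alias: str | None = None


@dataclass(frozen=True)
class Population:
    """A named, non-empty set of individuals resolved against a table."""

    name: str
    members: tuple[Individual, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise GdValidationError(f"population {self.name!r} is empty")
        names = [m.name for m in self.members]
        if len(set(names)) != len(names):
            raise GdValidationError(f"population {self.name!r} has duplicate members")

    @property
    def member_names(self) -> list[str]:
        return [m.name for m in self.members]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class SnvTable:
    """In-memory gd_snp / gd_genotype table.

    ``df`` holds the fixed columns, then per-individual columns named
    ``{name}:ref_reads``, ``{name}:var_reads``, ``{name}:gt``, ``{name}:gq``
    (gd_snp mode) or ``{name}:gt`` alone (gd_genotype mode), then any extra
    numeric columns in ``extra_columns`` order.
    """

    df: pd.DataFrame
    individuals: list[Individual]
    mode: str = "gd_snp"  # "gd_snp" | "gd_genotype"
    extra_columns: list[str] = field(default_factory=list)

    # -- accessors ---------------------------------------------------------

    def individual(self, name: str) -> Individual:
        for ind in self.individuals:
            if ind.name == name:
                return ind
        raise KeyError(
            f"no individual {name!r}; known: {[i.name for i in self.individuals]}"
        )

    def genotypes(self, who: Population | Sequence[str]) -> np.ndarray:
        """Genotype matrix, shape (n_snvs, n_members), values in {-1,0,1,2}."""
        names = who.member_names if isinstance(who, Population) else list(who)
        return self.df[[f"{n}:gt" for n in names]].to_numpy(dtype=np.int64)

    def read_counts(self, who: Population | Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """(ref_reads, var_reads) matrices; gd_snp mode only."""
        if self.mode != "gd_snp":
            raise GdValidationError("read counts are absent in gd_genotype mode")
        names = who.member_names if isinstance(who, Population) else list(who)
        rr = self.df[[f"{n}:ref_reads" for n in names]].to_numpy(dtype=np.int64)
        vr = self.df[[f"{n}:var_reads" for n in names]].to_numpy(dtype=np.int64)
        return rr, vr

    def geno_qualities(self, who: Population | Sequence[str]) -> np.ndarray:
        names = who.member_names if isinstance(who, Population) else list(who)
        if self.mode != "gd_snp":
            return np.full((len(self.df), len(names)), -1.0)
        return self.df[[f"{n}:gq" for n in names]].to_numpy(dtype=np.float64)

    @property
    def n_snvs(self) -> int:
        return len(self.df)

    def subset_rows(self, mask_or_index) -> "SnvTable":
        """New table with a row subset (boolean mask or positional index)."""
        sel = np.asarray(mask_or_index)
        sub = self.df[sel] if sel.dtype == bool else self.df.iloc[sel]
        return SnvTable(
            df=sub.reset_index(drop=True),
            individuals=list(self.individuals),
            mode=self.mode,
            extra_columns=list(self.extra_columns),
        )

    def with_extra_column(self, name: str, values) -> "SnvTable":
        """Append one named numeric column (analysis-score chaining)."""
        df = self.df.copy()
        df[name] = np.asarray(values, dtype=np.float64)
        return SnvTable(
            df=df,
            individuals=list(self.individuals),
            mode=self.mode,
            extra_columns=list(self.extra_columns) + [name],
        )

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        df = self.df
        names = [i.name for i in self.individuals]
        if len(set(names)) != len(names):
            raise GdValidationError("duplicate individual names")
        gt_cols = [f"{n}:gt" for n in names]
        bad = ~df[gt_cols].isin(VALID_GENOTYPES).all(axis=1)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise GdValidationError(
                f"genotype outside {{-1,0,1,2}} at table row {row + 1} "
                f"({df.iloc[row]['chrom']}:{df.iloc[row]['pos']})"
            )
        if (df["pos"] < 1).any():
            raise GdValidationError("positions must be >= 1")
        if (df["ref"] == df["var"]).any():
            raise GdValidationError("ref_allele == var_allele at some row")
        # rows grouped by chromosome, sorted by position, no duplicates
        for chrom, grp in df.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if (np.diff(pos) < 0).any():
                raise GdValidationError(f"positions not sorted on {chrom}")
            if (np.diff(pos) == 0).any():
                raise GdValidationError(f"duplicate (chrom,pos) on {chrom}")

    def write(self, path: str | Path) -> None:
        if self.mode == "gd_snp":
            write_gd_snp(self, path)
        else:
            write_gd_genotype(self, path)


# ---------------------------------------------------------------------------
# parsing


def _sample_width(mode: str) -> int:
    return 4 if mode == "gd_snp" else 1


def _parse(path: str | Path, mode: str) -> SnvTable:
    path = Path(path)
    individuals: list[Individual] = []
    extra: list[str] = []
    data_lines: list[tuple[int, str]] = []
    saw_mode = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split("\t")
                if parts[0] in ("gd_snp", "gd_genotype"):
                    if parts[0] != mode:
                        raise GdFormatError(
                            f"{path}: file declares {parts[0]}, expected {mode}"
                        )
                    saw_mode = True
                elif parts[0] == "individual":
                    if len(parts) < 3:
                        raise GdFormatError(
                            f"{path}:{lineno}: malformed #individual header"
                        )
                    alias = parts[3] if len(parts) > 3 else None
                    individuals.append(Individual(parts[1], int(parts[2]), alias))
                elif parts[0] == "column":
                    extra.append(parts[1])
                # unknown header lines are ignored
            else:
                data_lines.append((lineno, line))
    if not saw_mode or not individuals:
        raise GdFormatError(
            f"{path}: missing header (need #{mode} marker and #individual lines)"
        )

    width = _sample_width(mode)
    n_fixed = len(FIXED_COLUMNS)
    expected = n_fixed + width * len(individuals) + len(extra)
    # individual column declarations must tile the sample block
    declared = sorted(i.first_column for i in individuals)
    want = list(range(n_fixed + 1, n_fixed + 1 + width * len(individuals), width))
    if declared != want:
        raise GdFormatError(
            f"{path}: #individual first-column declarations {declared} do not "
            f"tile columns {want}"
        )

    rows = []
    for lineno, line in data_lines:
        fields = line.split("\t")
        if len(fields) != expected:
            raise GdFormatError(
                f"{path}:{lineno}: expected {expected} columns, found {len(fields)}"
            )
        try:
            row = [fields[0], int(fields[1]), fields[2], fields[3], float(fields[4])]
            for k in range(len(individuals) * width):
                v = fields[n_fixed + k]
                if mode == "gd_snp" and (k % 4) == 3:
                    row.append(float(v))  # genotype quality may be fractional
                else:
                    row.append(int(v))
            for k in range(len(extra)):
                row.append(float(fields[n_fixed + len(individuals) * width + k]))
        except ValueError as exc:
            raise GdFormatError(f"{path}:{lineno}: {exc}") from exc
        rows.append(row)

    order = sorted(individuals, key=lambda i: i.first_column)
    cols: list[str] = list(FIXED_COLUMNS)
    for ind in order:
        if mode == "gd_snp":
            cols += [
                f"{ind.name}:ref_reads",
                f"{ind.name}:var_reads",
                f"{ind.name}:gt",
                f"{ind.name}:gq",
            ]
        else:
            cols.append(f"{ind.name}:gt")
    cols += extra

    df = pd.DataFrame(rows, columns=cols)
    if len(df) == 0:
        df = pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
        df = df.astype({"pos": np.int64, "qual": np.float64})
    table = SnvTable(df=df, individuals=order, mode=mode, extra_columns=extra)
    try:
        table.validate()
    except GdValidationError as exc:
        raise GdValidationError(f"{path}: {exc}") from exc
    return table


def read_gd_snp(path: str | Path) -> SnvTable:
    """Parse a gd_snp file into a validated :class:`SnvTable`."""
    return _parse(path, "gd_snp")


def read_gd_genotype(path: str | Path) -> SnvTable:
    """Parse a gd_genotype file (one genotype column per individual)."""
    return _parse(path, "gd_genotype")


# ---------------------------------------------------------------------------
# writing


def _fmt_float(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def _write(table: SnvTable, path: str | Path, mode: str) -> None:
    width = _sample_width(mode)
    n_fixed = len(FIXED_COLUMNS)
    with open(path, "w") as fh:
        fh.write(f"#{mode}\n")
        for k, ind in enumerate(table.individuals):
            first = n_fixed + 1 + k * width
            tail = f"\t{ind.alias}" if ind.alias else ""
            fh.write(f"#individual\t{ind.name}\t{first}{tail}\n")
        for k, name in enumerate(table.extra_columns):
            col = n_fixed + width * len(table.individuals) + 1 + k
            fh.write(f"#column\t{name}\t{col}\n")
        df = table.df
        cols: list[list[str]] = [
            [str(x) for x in df["chrom"]],
            [str(int(x)) for x in df["pos"]],
            [str(x) for x in df["ref"]],
            [str(x) for x in df["var"]],
            [_fmt_float(x) for x in df["qual"]],
        ]
        for ind in table.individuals:
            if mode == "gd_snp":
                cols.append([str(int(x)) for x in df[f"{ind.name}:ref_reads"]])
                cols.append([str(int(x)) for x in df[f"{ind.name}:var_reads"]])
                cols.append([str(int(x)) for x in df[f"{ind.name}:gt"]])
                cols.append([_fmt_float(x) for x in df[f"{ind.name}:gq"]])
            else:
                cols.append([str(int(x)) for x in df[f"{ind.name}:gt"]])
        for name in table.extra_columns:
            cols.append([_fmt_float(x) for x in df[name]])
        for fields in zip(*cols):
            fh.write("\t".join(fields) + "\n")


def write_gd_snp(table: SnvTable, path: str | Path) -> None:
    if table.mode != "gd_snp":
        raise GdValidationError("table is not in gd_snp mode")
    _write(table, path, "gd_snp")


def write_gd_genotype(table: SnvTable, path: str | Path) -> None:
    if table.mode != "gd_genotype":
        raise GdValidationError("table is not in gd_genotype mode")
    _write(table, path, "gd_genotype")


# ---------------------------------------------------------------------------
# VCF conversion


def convert_vcf(path: str | Path) -> SnvTable:
    """Convert a VCF (with GT, optionally AD and GQ) into a gd_snp table.

    GT 0/0 -> genotype 2 (two reference copies), 0/1 or 1/0 -> 1, 1/1 -> 0,
    ./. -> -1.  The first AD value becomes the ref-read count and the second
    the var-read count; missing AD or GQ become -1.  Multi-allelic records
    are skipped (gd_snp is strictly biallelic); the skip count is logged and
    stored on the returned table as ``table.n_skipped_multiallelic``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise GdFormatError(f"{path}: VCF has no sample columns")

    rows = []
    n_multi = 0
    for v in vcf:
        if not v.FORMAT or "GT" not in v.FORMAT:
            raise GdFormatError(
                f"{path}: FORMAT field lacks GT at {v.CHROM}:{v.POS}; cannot convert"
            )
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        ad = v.format("AD")
        gq = v.format("GQ")
        qual = float(v.QUAL) if v.QUAL is not None else -1.0
        row = [v.CHROM, int(v.POS), v.REF, v.ALT[0], qual]
        for si in range(len(samples)):
            a, b = v.genotypes[si][0], v.genotypes[si][1]
            gt = -1 if (a < 0 or b < 0) else int(a == 0) + int(b == 0)
            if ad is not None and ad.shape[1] >= 2:
                rr = int(ad[si][0]) if ad[si][0] >= 0 else -1
                vr = int(ad[si][1]) if ad[si][1] >= 0 else -1
            else:
                rr = vr = -1
            g = float(gq[si].item()) if gq is not None and gq[si].item() >= 0 else -1.0
            row += [rr, vr, gt, g]
        rows.append(row)
    if n_multi:
        log.info("convert_vcf: skipped %d multi-allelic records", n_multi)

    individuals = [Individual(name, 6 + 4 * k) for k, name in enumerate(samples)]
    cols: list[str] = list(FIXED_COLUMNS)
    for name in samples:
        cols += [f"{name}:ref_reads", f"{name}:var_reads", f"{name}:gt", f"{name}:gq"]
    df = pd.DataFrame(rows, columns=cols)
    table = SnvTable(df=df, individuals=individuals, mode="gd_snp")
    table.validate()
    table.n_skipped_multiallelic = n_multi  # type: ignore[attr-defined]
    return table


# ---------------------------------------------------------------------------
# populations and row operations


def specify_population(table: SnvTable, names: Iterable[str], pop_name: str) -> Population:
    """Resolve a list of individual names into a named :class:`Population`.

    Duplicate names are dropped with a warning; an unknown name raises with
    the list of known individuals.
    """
    seen: list[str] = []
    for n in names:
        if n in seen:
            log.warning("specify_population: duplicate name %r dropped", n)
            continue
        seen.append(n)
    if not seen:
        raise GdValidationError(f"population {pop_name!r} must be non-empty")
    members = tuple(table.individual(n) for n in seen)
    return Population(pop_name, members)


def _check_pop(table: SnvTable, pop: Population) -> None:
    known = {i.name for i in table.individuals}
    missing = [m.name for m in pop.members if m.name not in known]
    if missing:
        raise GdValidationError(
            f"population {pop.name!r} members not in table: {missing}"
        )


def filter_snvs(
    table: SnvTable,
    pop: Population,
    min_depth: int = 0,
    max_depth: int | None = None,
    min_site_quality: float = 0.0,
    min_geno_quality: float = 0.0,
    require_polymorphic: bool = False,
) -> SnvTable:
    """Discard SNVs failing per-individual coverage/quality thresholds.

    Depth for a member is ref_reads + var_reads; a -1 read count leaves the
    depth undefined and the SNV fails any *active* depth filter for that
    member (conservative).  With ``require_polymorphic``, sites where all
    called genotypes in ``pop`` are identical (or none are called) are
    dropped.  Row order is preserved.
    """
    _check_pop(table, pop)
    if max_depth is not None and max_depth < min_depth:
        raise GdValidationError("max_depth < min_depth")
    n = table.n_snvs
    keep = np.ones(n, dtype=bool)

    depth_active = min_depth > 0 or max_depth is not None
    if depth_active:
        rr, vr = table.read_counts(pop)
        defined = (rr >= 0) & (vr >= 0)
        depth = rr + vr
        ok = defined & (depth >= min_depth)
        if max_depth is not None:
            ok &= depth <= max_depth
        keep &= ok.all(axis=1)
    if min_site_quality > 0:
        keep &= table.df["qual"].to_numpy() >= min_site_quality
    if min_geno_quality > 0:
        gq = table.geno_qualities(pop)
        keep &= (gq >= min_geno_quality).all(axis=1)
    if require_polymorphic:
        gt = table.genotypes(pop)
        called = gt >= 0
        any_called = called.any(axis=1)
        lo = np.where(called, gt, 3).min(axis=1)
        hi = np.where(called, gt, -2).max(axis=1)
        keep &= any_called & (lo != hi)
    return table.subset_rows(keep)


def aggregate_population(table: SnvTable, pop: Population) -> SnvTable:
    """Append summed ref- and var-allele totals for ``pop`` as two columns.

    gd_snp mode sums read counts (a -1 count contributes nothing); in
    gd_genotype mode genotype g contributes g reference alleles and 2-g
    variant alleles, and uncalled genotypes contribute nothing.
    """
    _check_pop(table, pop)
    if table.mode == "gd_snp":
        rr, vr = table.read_counts(pop)
        ref_tot = np.where(rr >= 0, rr, 0).sum(axis=1)
        var_tot = np.where(vr >= 0, vr, 0).sum(axis=1)
    else:
        gt = table.genotypes(pop)
        called = gt >= 0
        ref_tot = np.where(called, gt, 0).sum(axis=1)
        var_tot = np.where(called, 2 - gt, 0).sum(axis=1)
    out = table.with_extra_column(f"{pop.name}:ref_total", ref_tot)
    return out.with_extra_column(f"{pop.name}:var_total", var_tot)


def coverage_summary(table: SnvTable, pop: Population) -> pd.DataFrame:
    """Per-individual read-depth distribution across SNVs (gd_snp only).

    Returns one row per individual with mean/median/quartiles of total depth,
    the depth histogram (integer bins), and a ``low_coverage`` flag for
    individuals whose mean depth is below half the population median of
    mean depths.
    """
    _check_pop(table, pop)
    if table.mode != "gd_snp":
        raise GdValidationError("coverage_summary requires gd_snp mode (read counts)")
    rr, vr = table.read_counts(pop)
    depth = np.where((rr >= 0) & (vr >= 0), rr + vr, 0)
    rows = []
    means = depth.mean(axis=0)
    cohort = float(np.median(means)) if len(means) else 0.0
    for k, ind in enumerate(pop.members):
        d = depth[:, k]
        hist, edges = np.histogram(d, bins=np.arange(0, d.max() + 2))
        rows.append(
            {
                "individual": ind.name,
                "n_snvs": len(d),
                "mean": float(d.mean()),
                "median": float(np.median(d)),
                "q25": float(np.percentile(d, 25)),
                "q75": float(np.percentile(d, 75)),
                "histogram": hist,
                "bin_edges": edges,
                "low_coverage": bool(cohort > 0 and d.mean() < 0.5 * cohort),
            }
        )
    return pd.DataFrame(rows)


def sample_uniform(table: SnvTable, min_spacing: int) -> SnvTable:
    """Thin SNVs to a minimum spacing, greedily left-to-right per chromosome.

    The first SNV of each chromosome is kept; each subsequent SNV is kept iff
    it lies at least ``min_spacing`` bp beyond the last kept SNV.
    """
    if min_spacing <= 0:
        raise GdValidationError("min_spacing must be positive")
    keep = np.zeros(table.n_snvs, dtype=bool)
    pos = table.df["pos"].to_numpy()
    for _, idx in table.df.groupby("chrom", sort=False).indices.items():
        last = None
        for i in idx:
            if last is None or pos[i] - last >= min_spacing:
                keep[i] = True
                last = pos[i]
    return table.subset_rows(keep)
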