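"""Genotype/haplotype containers and VCF + annotation I/O.

The toolkit's substrate is a panel of biallelic SNPs over a set of samples,
stored either phased (a :class:`HaplotypeMatrix`, 2 rows per diploid sample)
or unphased (a :class:`GenotypeMatrix` of alt-allele counts 0/1/2 with
missing cells).  Variants are identified by ``chrom:pos:ref:alt``; the VCF ID
column is ignored for matching so panels with absent or inconsistent rsIDs
still align.

Besides plain reading/writing this module houses two dataset-assembly
procedures used when building a design panel from per-sample sequencing
deliverables: merging single-sample variant-only VCFs into a multi-sample
matrix with hom-ref backfill, and dropping samples while pruning variants
private to them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

MISSING = -1  # sentinel for a missing genotype in GenotypeMatrix.gt

ANNOTATION_COLUMNS = ["id", "maf", "design_score", "on_scaffold", "must_include"]


class VCFParseError(ValueError):
    """Malformed or unsupported VCF content."""


class UnsupportedInputError(ValueError):
    """Input outside the biallelic-SNP diploid data model."""


class InconsistentSiteError(ValueError):
    """Same (chrom, pos) seen with conflicting ref/alt across files."""


class UndefinedMAFError(ValueError):
    """MAF requested for a site with no non-missing calls."""


class MissingAnnotationError(KeyError):
    """Sites lack annotation rows required by a filter."""


@dataclass(frozen=True, order=True)
class Site:
    """A biallelic variant site.

    ``pos`` is 1-based as in VCF; internal matrix coordinates are 0-based
    column indices and never positions.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str = ""

    def __post_init__(self):
        if not self.id:
            object.__setattr__(self, "id", f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def _check_sites(sites: Sequence[Site]) -> None:
    seen: set[str] = set()
    last: dict[str, int] = {}
    for s in sites:
        if s.id in seen:
            raise UnsupportedInputError(f"duplicate site id {s.id!r}")
        seen.add(s.id)
        # non-decreasing: split multiallelics put several sites at one pos
        if s.chrom in last and s.pos < last[s.chrom]:
            raise UnsupportedInputError(
                f"positions not sorted on {s.chrom} at {s.pos}"
            )
        last[s.chrom] = s.pos


@dataclass
class GenotypeMatrix:
    """Diploid genotypes, samples x sites, values in {0, 1, 2, MISSING}."""

    sites: list[Site]
    samples: list[str]
    gt: np.ndarray  # int8, shape (n_samples, n_sites)

    def __post_init__(self):
        self.gt = np.asarray(self.gt, dtype=np.int8)
        if self.gt.shape != (len(self.samples), len(self.sites)):
            raise ValueError("genotype matrix shape does not match samples x sites")
        ok = np.isin(self.gt, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("genotype values must be 0, 1, 2 or missing")
        _check_sites(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_ids(self) -> list[str]:
        return [s.id for s in self.sites]

    def site_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.sites)}

    def subset_sites(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(
            [self.sites[i] for i in idx], list(self.samples), self.gt[:, idx]
        )

    def missing_fraction(self) -> np.ndarray:
        return (self.gt == MISSING).mean(axis=0)


@dataclass
class HaplotypeMatrix:
    """Phased alleles, haplotypes x sites, values in {0, 1}.

    Rows come in consecutive pairs: rows ``2k`` and ``2k+1`` are the two
    chromosome copies of sample ``k``.
    """

    sites: list[Site]
    samples: list[str]
    haps: np.ndarray  # uint8, shape (2 * n_samples, n_sites)

    def __post_init__(self):
        self.haps = np.asarray(self.haps, dtype=np.uint8)
        if self.haps.ndim != 2 or self.haps.shape[0] != 2 * len(self.samples):
            raise ValueError("haplotype matrix must have two rows per sample")
        if self.haps.shape[1] != len(self.sites):
            raise ValueError("haplotype matrix width does not match site count")
        if self.haps.size and self.haps.max() > 1:
            raise ValueError("haplotype alleles must be 0/1")
        _check_sites(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_haplotypes(self) -> int:
        return self.haps.shape[0]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_ids(self) -> list[str]:
        return [s.id for s in self.sites]

    def site_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.sites)}

    def sample_map(self) -> list[tuple[str, int]]:
        """Haplotype row -> (sample label, chromosome copy 0/1)."""
        return [(s, c) for s in self.samples for c in (0, 1)]

    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    def subset_sites(self, idx: Sequence[int]) -> "HaplotypeMatrix":
        idx = list(idx)
        return HaplotypeMatrix(
            [self.sites[i] for i in idx], list(self.samples), self.haps[:, idx]
        )

    def restrict_to_ids(self, ids: Iterable[str]) -> "HaplotypeMatrix":
        wanted = set(ids)
        return self.subset_sites([i for i, s in enumerate(self.sites) if s.id in wanted])

    def to_genotypes(self) -> GenotypeMatrix:
        gt = (self.haps[0::2, :].astype(np.int8) + self.haps[1::2, :].astype(np.int8))
        return GenotypeMatrix(list(self.sites), list(self.samples), gt)


# ---------------------------------------------------------------------------
# VCF I/O (pysam)


def _parse_region(region: str | None) -> tuple[str, int, int] | None:
    if region is None:
        return None
    chrom, _, span = region.partition(":")
    if not span:
        return (chrom, 1, 2**31 - 1)
    lo, _, hi = span.partition("-")
    return (chrom, int(lo), int(hi))


def read_vcf(
    path: str | Path,
    region: str | None = None,
    multiallelic: str = "reject",
):
    """Read a VCF into a :class:`HaplotypeMatrix` or :class:`GenotypeMatrix`.

    If every genotype is phased and non-missing the phased matrix is
    returned; otherwise the data collapse to unphased alt-allele counts.
    ``multiallelic`` is one of ``"reject"`` (error on any multi-alt record,
    the default), ``"split"`` (one biallelic site per alt allele) or
    ``"skip"``.

    ``region`` is ``"chrom"`` or ``"chrom:start-end"`` (1-based inclusive);
    filtering is by streaming, so no index is required.
    """
    if multiallelic not in ("reject", "split", "skip"):
        raise ValueError(f"unknown multiallelic policy {multiallelic!r}")
    reg = _parse_region(region)

    sites: list[Site] = []
    columns: list[np.ndarray] = []
    phased_ok = True
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if reg is not None:
                if rec.chrom != reg[0] or not (reg[1] <= rec.pos <= reg[2]):
                    continue
            alts = rec.alts or ()
            if len(alts) != 1:
                if multiallelic == "reject":
                    raise UnsupportedInputError(
                        f"multiallelic record at {rec.chrom}:{rec.pos} "
                        f"(alts={','.join(alts) or '.'})"
                    )
                if multiallelic == "skip":
                    continue
                split_alts = list(alts)
            else:
                split_alts = [alts[0]]

            for alt in split_alts:
                col = np.empty(len(samples), dtype=np.int8)
                hap_col = np.empty(2 * len(samples), dtype=np.uint8)
                for si, sample in enumerate(rec.samples.values()):
                    gt = sample.get("GT")
                    if gt is None or len(gt) != 2:
                        raise UnsupportedInputError(
                            f"non-diploid genotype at {rec.chrom}:{rec.pos}"
                        )
                    if any(a is None for a in gt):
                        col[si] = MISSING
                        phased_ok = False
                        continue
                    alleles = [1 if rec.alleles[a] == alt else 0 for a in gt]
                    col[si] = sum(alleles)
                    if not sample.phased:
                        phased_ok = False
                    hap_col[2 * si] = alleles[0]
                    hap_col[2 * si + 1] = alleles[1]
                sites.append(Site(rec.chrom, rec.pos, rec.ref, alt))
                columns.append(hap_col if phased_ok else col)

    if phased_ok:
        haps = (
            np.stack(columns, axis=1)
            if columns
            else np.zeros((2 * len(samples), 0), dtype=np.uint8)
        )
        return HaplotypeMatrix(sites, samples, haps.astype(np.uint8))
    # Phasing was broken somewhere: re-read columns as counts (hap columns
    # collected before the first unphased record are still allele pairs).
    gt_cols = []
    for c in columns:
        if c.dtype == np.uint8 and c.shape[0] == 2 * len(samples):
            gt_cols.append((c[0::2].astype(np.int8) + c[1::2].astype(np.int8)))
        else:
            gt_cols.append(c.astype(np.int8))
    gt = (
        np.stack(gt_cols, axis=1)
        if gt_cols
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(sites, samples, gt)


def write_vcf(panel, path: str | Path) -> None:
    """Write a panel back to VCF 4.2 (phased for a HaplotypeMatrix)."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    contigs: dict[str, int] = {}
    for s in panel.sites:
        contigs[s.chrom] = max(contigs.get(s.chrom, 0), s.pos + 1)
    for chrom, length in contigs.items():
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    for sample in panel.samples:
        header.add_sample(sample)

    phased = isinstance(panel, HaplotypeMatrix)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, site in enumerate(panel.sites):
            rec = out.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                stop=site.pos - 1 + len(site.ref),
                alleles=(site.ref, site.alt),
                id=site.id,
            )
            for si in range(len(panel.samples)):
                if phased:
                    a, b = int(panel.haps[2 * si, j]), int(panel.haps[2 * si + 1, j])
                    rec.samples[si]["GT"] = (a, b)
                    rec.samples[si].phased = True
                else:
                    g = int(panel.gt[si, j])
                    if g == MISSING:
                        rec.samples[si]["GT"] = (None, None)
                    else:
                        rec.samples[si]["GT"] = (0, 0) if g == 0 else ((0, 1) if g == 1 else (1, 1))
            out.write(rec)


def merge_single_sample_vcfs(
    paths: Sequence[str | Path], site_universe: Sequence[Site]
) -> GenotypeMatrix:
    """Merge variant-only single-sample VCFs onto a shared site universe.

    Sequencing deliverables often record only non-reference calls per
    sample.  Merging backfills every site absent from a sample's file as a
    homozygous-reference genotype, so per-sample heterozygous and
    homozygous-alternate counts are conserved exactly.

    Raises :class:`InconsistentSiteError` when the same (chrom, pos) carries
    conflicting ref/alt across files or against the universe.
    """
    _check_sites(site_universe)
    by_key = {(s.chrom, s.pos): s for s in site_universe}
    col_of = {s.id: j for j, s in enumerate(site_universe)}

    samples: list[str] = []
    rows: list[np.ndarray] = []
    for path in paths:
        panel = read_vcf(path)
        if isinstance(panel, HaplotypeMatrix):
            panel = panel.to_genotypes()
        if panel.n_samples != 1:
            raise UnsupportedInputError(f"{path}: expected a single-sample VCF")
        row = np.zeros(len(site_universe), dtype=np.int8)
        for j, site in enumerate(panel.sites):
            uni = by_key.get((site.chrom, site.pos))
            if uni is None or uni.key != site.key:
                raise InconsistentSiteError(
                    f"{path}: site {site.chrom}:{site.pos} {site.ref}>{site.alt} "
                    "conflicts with the site universe"
                )
            row[col_of[uni.id]] = panel.gt[0, j]
        samples.append(panel.samples[0])
        rows.append(row)

    gt = (
        np.stack(rows, axis=0)
        if rows
        else np.zeros((0, len(site_universe)), dtype=np.int8)
    )
    return GenotypeMatrix(list(site_universe), samples, gt)


def drop_samples_prune_private(g: GenotypeMatrix, drop: Iterable[str]) -> GenotypeMatrix:
    """Remove samples and prune sites left without any alt allele."""
    drop = set(drop)
    unknown = drop - set(g.samples)
    if unknown:
        raise KeyError(f"unknown sample labels: {sorted(unknown)}")
    keep_rows = [i for i, s in enumerate(g.samples) if s not in drop]
    gt = g.gt[keep_rows, :]
    alt_counts = np.where(gt == MISSING, 0, gt).sum(axis=0)
    keep_cols = np.flatnonzero(alt_counts > 0)
    return GenotypeMatrix(
        [g.sites[j] for j in keep_cols],
        [g.samples[i] for i in keep_rows],
        gt[:, keep_cols],
    )


# ---------------------------------------------------------------------------
# Allele frequencies and filtering


def compute_maf(panel, on_all_missing: str = "error") -> np.ndarray:
    """Per-site minor allele frequency, min(p, 1-p) over non-missing alleles.

    ``on_all_missing``: ``"error"`` raises for a site with no calls,
    ``"nan"`` flags it with NaN instead.
    """
    if isinstance(panel, HaplotypeMatrix):
        p = panel.haps.mean(axis=0) if panel.n_haplotypes else np.zeros(panel.n_sites)
        return np.minimum(p, 1.0 - p)
    gt = panel.gt
    called = gt != MISSING
    n_alleles = 2 * called.sum(axis=0)
    alt = np.where(called, gt, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    if np.isnan(p).any():
        if on_all_missing == "error":
            bad = [panel.sites[j].id for j in np.flatnonzero(np.isnan(p))]
            raise UndefinedMAFError(f"all genotypes missing at: {bad[:5]}")
        if on_all_missing != "nan":
            raise ValueError(f"unknown on_all_missing policy {on_all_missing!r}")
    return np.minimum(p, 1.0 - p)


@dataclass(frozen=True)
class FilterRules:
    """Candidate-pool exclusion rules, applied in fixed precedence order.

    Precedence (first matching reason wins): scaffold membership >
    design score > MAF > explicit exclusion list.
    """

    maf_min: float | None = None
    design_min: float | None = None
    exclude_scaffold: bool = False
    exclude_ids: frozenset[str] = field(default_factory=frozenset)


REASON_SCAFFOLD = "scaffold"
REASON_DESIGN = "design_score"
REASON_MAF = "low_maf"
REASON_EXPLICIT = "excluded"


def filter_sites(panel, ann: pd.DataFrame, rules: FilterRules):
    """Apply exclusion rules; return (retained panel, id -> reason map).

    Every input site lands in exactly one of: retained, or excluded with a
    single reason.  MAF is taken from the annotation table (the column a
    design run fills from :func:`compute_maf` on the target panel).
    """
    ann = ann.set_index("id") if "id" in ann.columns else ann
    missing = [s.id for s in panel.sites if s.id not in ann.index]
    if missing:
        raise MissingAnnotationError(
            f"{len(missing)} sites lack annotation rows, e.g. {missing[:5]}"
        )
    reasons: dict[str, str] = {}
    keep_idx: list[int] = []
    for j, site in enumerate(panel.sites):
        row = ann.loc[site.id]
        if rules.exclude_scaffold and bool(row["on_scaffold"]):
            reasons[site.id] = REASON_SCAFFOLD
        elif (
            rules.design_min is not None
            and not pd.isna(row["design_score"])
            and float(row["design_score"]) < rules.design_min
        ):
            reasons[site.id] = REASON_DESIGN
        elif rules.maf_min is not None and float(row["maf"]) < rules.maf_min:
            reasons[site.id] = REASON_MAF
        elif site.id in rules.exclude_ids:
            reasons[site.id] = REASON_EXPLICIT
        else:
            keep_idx.append(j)
    return panel.subset_sites(keep_idx), reasons


# ---------------------------------------------------------------------------
# Annotation tables


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a per-variant annotation TSV (id, maf, design_score, on_scaffold, must_include)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    df["on_scaffold"] = df["on_scaffold"].astype(bool)
    df["must_include"] = df["must_include"].astype(bool)
    bad = df[(df["maf"] < 0) | (df["maf"] > 0.5)]
    if len(bad):
        raise ValueError(f"maf out of [0, 0.5] for {len(bad)} rows")
    ds = df["design_score"].dropna()
    if ((ds < 0) | (ds > 1)).any():
        raise ValueError("design_score out of [0, 1]")
    return df


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=ANNOTATION_COLUMNS)


def write_exclusion_report(reasons: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(sorted(reasons.items()), columns=["id", "reason"]).to_csv(
        path, sep="\t", index=False
    )
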