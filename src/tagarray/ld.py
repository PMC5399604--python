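"""Pairwise linkage disequilibrium (r-squared) estimation.

Phased haplotypes give r2 by direct counting of two-locus haplotype
frequencies.  Unphased genotypes leave the double-heterozygote phase
ambiguous; those pairs are resolved with the classic two-locus EM over
haplotype frequencies, initialized at linkage equilibrium.  A windowed
all-pairs driver produces the sparse thresholded LD graph consumed by tag
selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, HaplotypeMatrix

logger = logging.getLogger(__name__)

MIN_PAIRWISE_COMPLETE = 10  # pairs with fewer complete samples are skipped in bulk runs


class LDUndefinedError(ValueError):
    """r2 requested for a monomorphic site."""


class EMConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class HapFreqs:
    """Two-locus haplotype frequencies (f_ab = freq of allele a at the first
    site with allele b at the second)."""

    f00: float
    f01: float
    f10: float
    f11: float

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.f00, self.f01, self.f10, self.f11])

    def r2(self) -> float:
        return _r2_from_freqs(self.f00, self.f01, self.f10, self.f11)


def _r2_from_freqs(f00: float, f01: float, f10: float, f11: float) -> float:
    pA = f10 + f11  # allele 1 at first site
    pB = f01 + f11  # allele 1 at second site
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom <= 0:
        raise LDUndefinedError("monomorphic site in r2 computation")
    d = f11 - pA * pB
    return min(1.0, d * d / denom)


def haplotype_freqs(h: HaplotypeMatrix, i: int, j: int) -> HapFreqs:
    a = h.haps[:, i].astype(np.int64)
    b = h.haps[:, j].astype(np.int64)
    n = a.shape[0]
    f11 = float((a & b).sum()) / n
    f10 = float((a & (1 - b)).sum()) / n
    f01 = float(((1 - a) & b).sum()) / n
    return HapFreqs(1.0 - f11 - f10 - f01, f01, f10, f11)


def haplotype_r2(h: HaplotypeMatrix, i: int, j: int) -> float:
    """r2 between two sites by direct haplotype counting.

    Equals the squared Pearson correlation of the two allele columns;
    invariant under allele relabeling at either site and symmetric in (i, j).
    """
    return haplotype_freqs(h, i, j).r2()


def _pair_table(g: GenotypeMatrix, i: int, j: int) -> np.ndarray:
    """3x3 genotype pair counts over pairwise-complete samples."""
    gi = g.gt[:, i]
    gj = g.gt[:, j]
    ok = (gi != MISSING) & (gj != MISSING)
    tab = np.zeros((3, 3), dtype=np.int64)
    np.add.at(tab, (gi[ok], gj[ok]), 1)
    return tab


def _em_loglik(tab: np.ndarray, f: np.ndarray) -> float:
    f00, f01, f10, f11 = f
    # P(g1, g2) under HWE with random pairing of haplotypes
    probs = np.empty((3, 3))
    hap_p = {(0, 0): f00, (0, 1): f01, (1, 0): f10, (1, 1): f11}
    for g1 in range(3):
        for g2 in range(3):
            total = 0.0
            for a1 in range(2):
                for b1 in range(2):
                    a2, b2 = g1 - a1, g2 - b1
                    if a2 in (0, 1) and b2 in (0, 1):
                        total += hap_p[(a1, b1)] * hap_p[(a2, b2)]
            probs[g1, g2] = total
    mask = tab > 0
    with np.errstate(divide="ignore"):
        return float((tab[mask] * np.log(np.maximum(probs[mask], 1e-300))).sum())


def em_haplotype_freqs(
    g: GenotypeMatrix,
    i: int,
    j: int,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> HapFreqs:
    """Two-locus haplotype frequencies from unphased genotypes by EM.

    Only the double-heterozygote class is phase-ambiguous; all other
    genotype pairs contribute known haplotype counts.  The E step splits the
    double-het count between the coupling (00/11) and repulsion (01/10)
    phases by their current relative likelihood; the M step renormalizes.
    Initialization is linkage equilibrium (product of the observed allele
    frequencies), which preserves the single-site marginals at every
    iteration.  Note the all-double-het degenerate dataset is a fixed point
    of this start and returns equilibrium frequencies (r2 = 0).
    """
    tab = _pair_table(g, i, j)
    converged = False
    f = None
    for it, new in enumerate(_em_iterates(tab)):
        if f is not None and np.abs(new - f).max() < tol:
            f = new
            converged = True
            break
        f = new
        if it + 1 >= max_iter:
            break
    if not converged:
        warnings.warn(
            f"two-locus EM did not converge in {max_iter} iterations",
            EMConvergenceWarning,
        )
    return HapFreqs(*f)


def _em_iterates(tab: np.ndarray):
    """Yield EM iterates (f00, f01, f10, f11 arrays), starting at the
    linkage-equilibrium initialization.  Runs forever; the caller stops it."""
    n = int(tab.sum())
    if n < 2:
        raise LDUndefinedError("fewer than 2 pairwise-complete samples")
    # haplotype counts fixed by unambiguous genotype pairs
    k00 = 2 * tab[0, 0] + tab[0, 1] + tab[1, 0]
    k01 = 2 * tab[0, 2] + tab[0, 1] + tab[1, 2]
    k10 = 2 * tab[2, 0] + tab[1, 0] + tab[2, 1]
    k11 = 2 * tab[2, 2] + tab[2, 1] + tab[1, 2]
    c = int(tab[1, 1])  # double heterozygotes: one coupling or one repulsion pair each

    pA = (k10 + k11 + c) / (2.0 * n)
    pB = (k01 + k11 + c) / (2.0 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise LDUndefinedError("monomorphic site among pairwise-complete samples")
    f = np.array([(1 - pA) * (1 - pB), (1 - pA) * pB, pA * (1 - pB), pA * pB])
    yield f
    while True:
        coup = f[0] * f[3]
        rep = f[1] * f[2]
        p_coup = 0.5 if coup + rep == 0 else coup / (coup + rep)
        f = np.array(
            [
                k00 + p_coup * c,
                k01 + (1 - p_coup) * c,
                k10 + (1 - p_coup) * c,
                k11 + p_coup * c,
            ]
        ) / (2.0 * n)
        yield f


def genotype_r2(
    g: GenotypeMatrix, i: int, j: int, tol: float = 1e-8, max_iter: int = 1000
) -> float:
    """r2 from unphased genotypes via EM haplotype frequencies."""
    return em_haplotype_freqs(g, i, j, tol=tol, max_iter=max_iter).r2()


# ---------------------------------------------------------------------------
# Windowed all-pairs LD graph


@dataclass
class LDGraph:
    """Sparse thresholded LD graph: one record per unordered site pair with
    r2 >= r2_min within window_bp."""

    edges: list[tuple[str, str, float]]
    r2_min: float
    window_bp: int
    nodes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.nodes:
            self.nodes = frozenset(x for e in self.edges for x in e[:2])

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> dict[str, dict[str, float]]:
        adj: dict[str, dict[str, float]] = {n: {} for n in self.nodes}
        for a, b, r2 in self.edges:
            adj.setdefault(a, {})[b] = r2
            adj.setdefault(b, {})[a] = r2
        return adj

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["id_i", "id_j", "r2"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, r2_min: float, window_bp: int) -> "LDGraph":
        df = pd.read_csv(path, sep="\t", dtype={"id_i": str, "id_j": str})
        edges = [(a, b, float(r)) for a, b, r in df.itertuples(index=False)]
        return cls(edges, r2_min=r2_min, window_bp=window_bp)


def _window_pairs(sites, window_bp: int) -> Iterator[tuple[int, int]]:
    m = len(sites)
    for i in range(m):
        for j in range(i + 1, m):
            if sites[j].chrom != sites[i].chrom:
                break
            if sites[j].pos - sites[i].pos > window_bp:
                break
            yield i, j


def pairwise_ld(
    panel,
    window_bp: int = 250_000,
    r2_min: float = 0.8,
) -> LDGraph:
    """All intra-window site pairs with r2 >= r2_min, as an :class:`LDGraph`.

    Monomorphic sites are skipped (logged, not fatal); on unphased input,
    pairs with fewer than 10 pairwise-complete samples are skipped too.
    Deterministic for fixed input.
    """
    phased = isinstance(panel, HaplotypeMatrix)
    sites = panel.sites
    edges: list[tuple[str, str, float]] = []

    if phased:
        X = panel.haps.astype(np.float64)
        p = X.mean(axis=0)
        poly = (p > 0) & (p < 1)
        n_mono = int((~poly).sum())
        if n_mono:
            logger.info("pairwise_ld: skipping %d monomorphic sites", n_mono)
        Xc = X - p
        ss = (Xc * Xc).sum(axis=0)
        pos = np.array([s.pos for s in sites], dtype=np.int64)
        chroms = np.array([s.chrom for s in sites])
        m = len(sites)
        for i in range(m):
            if not poly[i]:
                continue
            hi = i + 1
            while (
                hi < m
                and chroms[hi] == chroms[i]
                and pos[hi] - pos[i] <= window_bp
            ):
                hi += 1
            js = np.arange(i + 1, hi)
            js = js[poly[js]]
            if js.size == 0:
                continue
            cov = Xc[:, i] @ Xc[:, js]
            r2 = (cov * cov) / (ss[i] * ss[js])
            keep = np.flatnonzero(r2 >= r2_min)
            for k in keep:
                edges.append((sites[i].id, sites[js[k]].id, float(min(r2[k], 1.0))))
    else:
        n_skipped = 0
        for i, j in _window_pairs(sites, window_bp):
            tab = _pair_table(panel, i, j)
            if tab.sum() < MIN_PAIRWISE_COMPLETE:
                n_skipped += 1
                continue
            try:
                r2 = genotype_r2(panel, i, j)
            except LDUndefinedError:
                continue
            if r2 >= r2_min:
                edges.append((sites[i].id, sites[j].id, r2))
        if n_skipped:
            logger.warning(
                "pairwise_ld: skipped %d pairs with < %d pairwise-complete samples",
                n_skipped,
                MIN_PAIRWISE_COMPLETE,
            )

    return LDGraph(
        edges,
        r2_min=r2_min,
        window_bp=window_bp,
        nodes=frozenset(s.id for s in sites),
    )
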