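"""Panel coverage assessment: how well does a SNP panel tag a target set?

Coverage here is single-marker tagging: a target variant counts as covered
at a threshold when some panel SNP within the window reaches that r2 against
it (a panel member covers itself at r2 = 1).  Reports stratify by MAF bin
and support several panels side by side, including unions, which is how
scaffold-plus-new-array combinations are evaluated.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import HaplotypeMatrix, compute_maf

DEFAULT_THRESHOLDS = (0.5, 0.8, 0.9)
DEFAULT_MAF_BINS = (0.01, 0.02, 0.05, 0.10, 0.50)


def _poly_mask(haps: np.ndarray) -> np.ndarray:
    p = haps.mean(axis=0)
    return (p > 0) & (p < 1)


def best_tag_r2(
    target: str,
    panel: Iterable[str],
    haps: HaplotypeMatrix,
    window_bp: int = 250_000,
) -> float:
    """Max r2 between ``target`` and any panel site within the window.

    Returns 1.0 when the target itself is on the panel, 0.0 when no panel
    site lies in the window (uncovered, not an error).
    """
    return float(
        best_tag_r2_many([target], set(panel), haps, window_bp=window_bp)[0]
    )


def best_tag_r2_many(
    targets: Sequence[str],
    panel: set[str],
    haps: HaplotypeMatrix,
    window_bp: int = 250_000,
) -> np.ndarray:
    """Vectorized :func:`best_tag_r2` over many targets (shared panel)."""
    index = haps.site_index()
    pos = haps.positions()
    X = haps.haps.astype(np.float64)
    p = X.mean(axis=0)
    poly = _poly_mask(haps.haps)
    Xc = X - p
    ss = (Xc * Xc).sum(axis=0)
    chrom = np.array([s.chrom for s in haps.sites])

    panel_idx = np.array(sorted(index[t] for t in panel if t in index), dtype=np.int64)
    panel_poly = panel_idx[poly[panel_idx]] if panel_idx.size else panel_idx

    out = np.zeros(len(targets))
    for k, t in enumerate(targets):
        i = index[t]
        if not poly[i]:
            raise ValueError(f"target {t} is monomorphic")
        if t in panel:
            out[k] = 1.0
            continue
        if panel_poly.size == 0:
            continue
        lo = np.searchsorted(pos, pos[i] - window_bp, side="left")
        hi = np.searchsorted(pos, pos[i] + window_bp, side="right")
        js = panel_poly[(panel_poly >= lo) & (panel_poly < hi)]
        js = js[chrom[js] == chrom[i]]
        if js.size == 0:
            continue
        cov = Xc[:, i] @ Xc[:, js]
        r2 = (cov * cov) / (ss[i] * ss[js])
        out[k] = min(1.0, float(r2.max()))
    return out


def _bin_label(lo: float, hi: float, last: bool) -> str:
    close = "]" if last else ")"
    return f"[{lo:g},{hi:g}{close}"


def _assign_bins(maf: np.ndarray, edges: Sequence[float]) -> list[str | None]:
    """Half-open bins [lo, hi), last bin closed; values outside -> None."""
    labels: list[str | None] = []
    for v in maf:
        lab = None
        for b in range(len(edges) - 1):
            last = b == len(edges) - 2
            if edges[b] <= v < edges[b + 1] or (last and v == edges[b + 1]):
                lab = _bin_label(edges[b], edges[b + 1], last)
                break
        labels.append(lab)
    return labels


def coverage_by_maf(
    targets: Sequence[str],
    panels: Mapping[str, Iterable[str]],
    haps: HaplotypeMatrix,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    maf_bins: Sequence[float] = DEFAULT_MAF_BINS,
    window_bp: int = 250_000,
) -> pd.DataFrame:
    """Coverage table: fraction of targets per MAF bin with best-tag r2 at
    or above each threshold, for each named panel.

    ``panels`` maps a label to a site-id collection; pass the union of two
    id sets under its own label to evaluate a combined array.  An "all" row
    aggregates over bins.  Empty bins are emitted with count 0 and NaN
    fraction.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    maf = compute_maf(haps)
    index = haps.site_index()
    t_maf = np.array([maf[index[t]] for t in targets])
    bins = _assign_bins(t_maf, maf_bins)
    bin_labels = [
        _bin_label(maf_bins[b], maf_bins[b + 1], b == len(maf_bins) - 2)
        for b in range(len(maf_bins) - 1)
    ]

    rows = []
    for label, panel in panels.items():
        best = best_tag_r2_many(targets, set(panel), haps, window_bp=window_bp)
        for bl in bin_labels + ["all"]:
            if bl == "all":
                sel = np.ones(len(targets), dtype=bool)
            else:
                sel = np.array([b == bl for b in bins])
            n = int(sel.sum())
            for th in thresholds:
                frac = float((best[sel] >= th).mean()) if n else float("nan")
                rows.append(
                    {
                        "panel": label,
                        "maf_bin": bl,
                        "r2_threshold": th,
                        "n": n,
                        "fraction_covered": frac,
                    }
                )
    return pd.DataFrame(rows)


def maf_spectrum(
    panel: Iterable[str], ann: pd.DataFrame, bin_width: float = 0.05
) -> pd.DataFrame:
    """MAF histogram of a panel over [0, 0.5]; half-open bins, last closed."""
    a = ann.set_index("id") if "id" in ann.columns else ann
    panel = list(panel)
    missing = [p for p in panel if p not in a.index]
    if missing:
        raise KeyError(f"panel sites missing annotation: {missing[:5]}")
    vals = a.loc[panel, "maf"].to_numpy(dtype=float) if panel else np.array([])
    n_bins = int(np.ceil(0.5 / bin_width))
    edges = [round(b * bin_width, 10) for b in range(n_bins)] + [0.5]
    counts = []
    for b in range(n_bins):
        last = b == n_bins - 1
        lo, hi = edges[b], edges[b + 1]
        if last:
            c = int(((vals >= lo) & (vals <= hi)).sum())
        else:
            c = int(((vals >= lo) & (vals < hi)).sum())
        counts.append({"bin_lo": lo, "bin_hi": hi, "count": c})
    return pd.DataFrame(counts)


def mean_r2_by_maf(
    targets: Sequence[str],
    panel: Iterable[str],
    haps: HaplotypeMatrix,
    maf_grid: Sequence[float] = DEFAULT_MAF_BINS,
    window_bp: int = 250_000,
) -> pd.DataFrame:
    """Mean best-tag r2 per MAF bin — the curve behind coverage-vs-MAF plots."""
    maf = compute_maf(haps)
    index = haps.site_index()
    t_maf = np.array([maf[index[t]] for t in targets])
    bins = _assign_bins(t_maf, maf_grid)
    best = best_tag_r2_many(targets, set(panel), haps, window_bp=window_bp)
    rows = []
    for b in range(len(maf_grid) - 1):
        bl = _bin_label(maf_grid[b], maf_grid[b + 1], b == len(maf_grid) - 2)
        sel = np.array([x == bl for x in bins])
        n = int(sel.sum())
        rows.append(
            {
                "maf_bin": bl,
                "n": n,
                "mean_r2": float(best[sel].mean()) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)
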