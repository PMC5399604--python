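"""End-to-end array design: filters -> imputation screen -> LD -> tag
selection -> capacity trim -> must-include add-back -> manifest.

The pipeline whittles a sequenced target catalog down to a tag-SNP array
that complements an existing scaffold array.  Every input candidate ends up
with exactly one audit disposition, so the funnel is fully accountable:

========================  ====================================================
disposition               meaning
========================  ====================================================
``scaffold``              already on the scaffold array
``design_score``          probe design score below the floor
``low_maf``               below the preliminary MAF cutoff
``excluded``              on an explicit exclusion list
``imputable``             imputable from scaffold + reference at r2 above the
                          screen threshold; needs no tag
``selected_tag``          chosen as a tag and retained on the array
``tagged_by:<id>``        covered by the named tag at r2 >= threshold
``dropped_by_floor``      selected as a tag but removed by the capacity trim
``uncovered``             lost its tag to the capacity trim with no remaining
                          proxy at threshold (accepted coverage loss)
========================  ====================================================
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import coverage as _coverage
from .genotype_io import FilterRules, HaplotypeMatrix, compute_maf, filter_sites
from .imputation_screen import CopyingModelParams, screen_imputable
from .ld import pairwise_ld
from .tagging import TagSelection, apply_capacity, select_tags

logger = logging.getLogger(__name__)


class PanelAlignmentError(ValueError):
    """Study and reference panels disagree where they must agree."""


@dataclass(frozen=True)
class DesignConfig:
    """All tunable knobs of a design run (mirrors the CLI flags).

    The defaults are the classic settings for a low-frequency-targeted
    complement to a common-variant scaffold: preliminary MAF cutoff 1%,
    probe design-score floor 0.5, imputability screen at r2 > 0.8, tag
    selection at r2 >= 0.8, and a capacity-driven MAF floor raised in 0.1%
    steps.
    """

    maf_min: float = 0.01
    design_min: float = 0.5
    imputation_r2_thresh: float = 0.8
    tag_r2_thresh: float = 0.8
    capacity: int | None = None  # None: no trim
    floor_step: float = 0.001
    window_bp: int = 250_000
    exact_cap: int = 15
    must_include: Mapping[str, Sequence[str]] = field(default_factory=dict)
    exclude_ids: frozenset[str] = field(default_factory=frozenset)
    reselect_after_trim: bool = True  # re-cover floor-eligible sites orphaned by the trim
    skip_imputation_screen: bool = False
    imputation_params: CopyingModelParams = field(default_factory=CopyingModelParams)
    seed: int = 0  # recorded for provenance; the pipeline itself is deterministic

    def __post_init__(self):
        for name in ("imputation_r2_thresh", "tag_r2_thresh"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.capacity is not None and self.capacity < 0:
            raise ValueError("capacity must be >= 0")


@dataclass
class ArrayDesign:
    """Result of a design run: the manifest plus a full audit trail."""

    manifest: pd.DataFrame  # id, chrom, pos, category, maf
    audit: dict[str, str]  # candidate id -> disposition
    maf_floor: float
    selection: TagSelection
    quality_table: pd.DataFrame  # imputation screen output
    lost_coverage: pd.DataFrame

    @property
    def tags(self) -> list[str]:
        return self.manifest.loc[self.manifest["category"] == "tag", "id"].tolist()

    def write_manifest(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# array design manifest; category: tag = LD tag SNP, ")
            fh.write("must_include_* = curated add-back content\n")
            self.manifest.to_csv(fh, index=False)

    def write_audit(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.audit.items()), columns=["id", "disposition"]
        ).to_csv(path, sep="\t", index=False)


def design_array(
    study: HaplotypeMatrix,
    reference: HaplotypeMatrix,
    ann: pd.DataFrame,
    cfg: DesignConfig,
) -> ArrayDesign:
    """Run the full design pipeline on a phased study panel.

    ``reference`` is the external imputation reference; ``ann`` must
    annotate every study site.  Returns an :class:`ArrayDesign` whose audit
    partitions the candidate set exhaustively.
    """
    t0 = time.perf_counter()
    ann_idx = ann.set_index("id") if "id" in ann.columns else ann
    audit: dict[str, str] = {}

    # stage 1-3: scaffold / design-score / MAF / explicit-exclusion filters
    rules = FilterRules(
        maf_min=cfg.maf_min,
        design_min=cfg.design_min,
        exclude_scaffold=True,
        exclude_ids=frozenset(cfg.exclude_ids),
    )
    pool, reasons = filter_sites(study, ann, rules)
    audit.update(reasons)
    logger.info(
        "filters: %d candidates -> %d pool (%.1fs)",
        study.n_sites,
        pool.n_sites,
        time.perf_counter() - t0,
    )

    # stage 4: imputation screen against scaffold + reference
    scaffold_ids = set(ann_idx.index[ann_idx["on_scaffold"]]) & set(study.site_ids)
    if cfg.skip_imputation_screen or not scaffold_ids:
        imputable: set[str] = set()
        quality = pd.DataFrame(columns=["id", "r2_hat", "n_eval", "screened"])
    else:
        imputable, quality = screen_imputable(
            pool.site_ids,
            study,
            scaffold_ids,
            reference,
            r2_thresh=cfg.imputation_r2_thresh,
            params=cfg.imputation_params,
        )
        for cid in imputable:
            audit[cid] = "imputable"
    pool = pool.restrict_to_ids(set(pool.site_ids) - imputable)
    logger.info(
        "imputation screen: %d imputable, %d remain (%.1fs)",
        len(imputable),
        pool.n_sites,
        time.perf_counter() - t0,
    )

    # stage 5-6: LD graph and tag selection
    ldg = pairwise_ld(pool, window_bp=cfg.window_bp, r2_min=cfg.tag_r2_thresh)
    maf_map = dict(zip(pool.site_ids, compute_maf(pool)))
    sel = select_tags(ldg, pool.site_ids, exact_cap=cfg.exact_cap, maf=maf_map)
    logger.info(
        "tag selection: %d tags over %d pool sites (%.1fs)",
        sel.n_tags,
        pool.n_sites,
        time.perf_counter() - t0,
    )

    # stage 7: capacity trim by MAF floor
    if cfg.capacity is not None:
        pre_tags = set(sel.tags)
        sel_trimmed, floor, lost = apply_capacity(
            sel,
            ann,
            cfg.capacity,
            floor_step=cfg.floor_step,
            base_floor=cfg.maf_min,
            reselect=cfg.reselect_after_trim,
        )
        dropped = pre_tags - set(sel_trimmed.tags)
        sel = sel_trimmed
    else:
        floor = cfg.maf_min
        dropped = set()
        lost = pd.DataFrame(columns=["id", "old_tag", "old_r2", "new_best_r2"])

    tag_set = set(sel.tags)
    lost_ids = set(lost["id"]) if len(lost) else set()
    for sid in pool.site_ids:
        if sid in tag_set:
            audit[sid] = "selected_tag"
        elif sid in dropped:
            audit[sid] = "dropped_by_floor"
        elif sid in lost_ids:
            audit[sid] = "uncovered"
        else:
            tag, _ = sel.cover[sid]
            audit[sid] = f"tagged_by:{tag}"

    # stage 8: must-include add-back (annotation flag + explicit lists),
    # de-duplicated against selected tags; does not consume tag budget.
    manifest_rows = []
    site_by_id = {s.id: s for s in study.sites}
    maf_all = dict(zip(study.site_ids, compute_maf(study)))
    for t in sel.tags:
        s = site_by_id[t]
        manifest_rows.append(
            {"id": t, "chrom": s.chrom, "pos": s.pos, "category": "tag",
             "maf": maf_all.get(t, float("nan"))}
        )
    included = set(sel.tags)
    add_back: list[tuple[str, str]] = [
        (sid, "must_include")
        for sid in ann_idx.index[ann_idx["must_include"]]
    ]
    for category, ids in cfg.must_include.items():
        add_back.extend((sid, category) for sid in ids)
    for sid, category in add_back:
        if sid in included:
            continue
        included.add(sid)
        s = site_by_id.get(sid)
        manifest_rows.append(
            {
                "id": sid,
                "chrom": s.chrom if s else "",
                "pos": s.pos if s else -1,
                "category": category,
                "maf": maf_all.get(sid, float("nan")),
            }
        )

    manifest = pd.DataFrame(
        manifest_rows, columns=["id", "chrom", "pos", "category", "maf"]
    ).sort_values(["chrom", "pos", "id"], kind="mergesort").reset_index(drop=True)

    missing_audit = set(study.site_ids) - set(audit)
    if missing_audit:  # defensive: the stages above must partition everything
        raise AssertionError(f"audit incomplete for {len(missing_audit)} sites")
    logger.info("design complete: %d manifest rows (%.1fs)",
                len(manifest), time.perf_counter() - t0)

    return ArrayDesign(
        manifest=manifest,
        audit=audit,
        maf_floor=floor,
        selection=sel,
        quality_table=quality,
        lost_coverage=lost,
    )


def audit_report(design: ArrayDesign) -> pd.DataFrame:
    """Funnel summary: candidate counts per disposition (tagged_by:* pooled).

    Counts sum to the number of input candidates.
    """
    counts: dict[str, int] = {}
    for disp in design.audit.values():
        key = "tagged_by" if disp.startswith("tagged_by:") else disp
        counts[key] = counts.get(key, 0) + 1
    df = pd.DataFrame(
        sorted(counts.items()), columns=["disposition", "n"]
    )
    return df


def design_coverage(
    design: ArrayDesign,
    study: HaplotypeMatrix,
    ann: pd.DataFrame,
    thresholds=(0.5, 0.8, 0.9),
    window_bp: int = 250_000,
) -> pd.DataFrame:
    """Coverage of the study catalog by scaffold alone, new tags alone, and
    the combined panels — the standard evaluation of a finished design."""
    ann_idx = ann.set_index("id") if "id" in ann.columns else ann
    scaffold = set(ann_idx.index[ann_idx["on_scaffold"]]) & set(study.site_ids)
    tags = set(design.tags)
    maf = compute_maf(study)
    targets = [
        s for s, m in zip(study.site_ids, maf) if m >= 0.01
    ]
    panels = {
        "scaffold_alone": scaffold,
        "design_alone": tags,
        "combined": scaffold | tags,
    }
    return _coverage.coverage_by_maf(
        targets, panels, study, thresholds=thresholds, window_bp=window_bp
    )
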