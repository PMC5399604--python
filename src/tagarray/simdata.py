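"""Synthetic phased panels with realistic LD structure.

The generator emulates the study design the toolkit targets: a *study*
panel of admixed African-ancestry samples whose variant catalog is skewed
toward low-frequency alleles, an independent *reference* panel drawn from
one of the two ancestral pools (a 1000-Genomes-African-like panel), and a
scaffold array whose membership probability rises with MAF, reproducing the
common-variant bias of commodity GWAS arrays.

Haplotypes come from an msprime coalescent simulation: two ancestral pools
split ``split_time`` generations ago, the study population formed by recent
admixture between them, recombination with hotspots, and binary (strictly
biallelic) mutations.  Everything is reproducible from the single mandatory
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import msprime
import numpy as np
import pandas as pd

from .genotype_io import (
    MISSING,
    ANNOTATION_COLUMNS,
    GenotypeMatrix,
    HaplotypeMatrix,
    Site,
    compute_maf,
)


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Synthetic-panel generation parameters.

    Defaults describe a 2 Mb region with 300 study and 200 reference
    diploids, yielding roughly 5,000 sites segregating in the study panel —
    a desk-scale stand-in for a whole-genome design run.  ``hotspots`` are
    (position fraction of the region, width bp, rate multiplier) triples.
    """

    seed: int  # mandatory; all randomness derives from it
    n_study_samples: int = 300
    n_reference_samples: int = 200
    region_bp: int = 2_000_000
    mutation_rate: float = 6.5e-9
    recomb_rate: float = 1e-8
    hotspots: tuple[tuple[float, int, float], ...] = (
        (0.25, 2_000, 15.0),
        (0.55, 2_000, 15.0),
        (0.80, 2_000, 15.0),
    )
    ne: float = 10_000.0
    split_time: float = 3_000.0  # generations; divergence of the two pools
    admix_time: float = 10.0
    admix_prop: float = 0.8  # study ancestry fraction from the reference-side pool
    scaffold_mid: float = 0.15  # MAF at which scaffold membership odds are even
    scaffold_scale: float = 0.04
    scaffold_max: float = 0.9  # plateau probability for very common variants
    design_beta: tuple[float, float] = (7.0, 1.5)  # Beta params for design scores
    missing_rate: float = 0.0
    chrom: str = "1"

    def validate(self) -> None:
        if self.n_study_samples <= 0 or self.n_reference_samples <= 0:
            raise SimConfigError("sample counts must be positive")
        if self.region_bp <= 0:
            raise SimConfigError("region_bp must be positive")
        if not (0.0 <= self.admix_prop <= 1.0):
            raise SimConfigError("admix_prop must be in [0, 1]")
        if any(r < 0 for r in (self.mutation_rate, self.recomb_rate)):
            raise SimConfigError("rates must be non-negative")
        if not (0.0 <= self.missing_rate < 1.0):
            raise SimConfigError("missing_rate must be in [0, 1)")
        if self.seed is None or not (1 <= int(self.seed) < 2**31):
            raise SimConfigError("seed must be an integer in [1, 2^31)")


def _rate_map(cfg: SimConfig) -> msprime.RateMap:
    breaks = [0.0]
    rates = []
    cursor = 0.0
    for frac, width, mult in sorted(cfg.hotspots):
        lo = max(0.0, min(cfg.region_bp - width, frac * cfg.region_bp))
        hi = lo + width
        if lo <= cursor:
            continue
        breaks.extend([lo, hi])
        rates.extend([cfg.recomb_rate, cfg.recomb_rate * mult])
        cursor = hi
    breaks.append(float(cfg.region_bp))
    rates.append(cfg.recomb_rate)
    return msprime.RateMap(position=breaks, rate=rates)


def _demography(cfg: SimConfig) -> msprime.Demography:
    dem = msprime.Demography()
    dem.add_population(name="POOL_A", initial_size=cfg.ne)  # reference-side pool
    dem.add_population(name="POOL_B", initial_size=cfg.ne)
    dem.add_population(name="STUDY", initial_size=cfg.ne)
    dem.add_population(name="ANC", initial_size=cfg.ne)
    dem.add_admixture(
        time=cfg.admix_time,
        derived="STUDY",
        ancestral=["POOL_A", "POOL_B"],
        proportions=[cfg.admix_prop, 1.0 - cfg.admix_prop],
    )
    dem.add_population_split(
        time=cfg.split_time, derived=["POOL_A", "POOL_B"], ancestral="ANC"
    )
    return dem


def simulate_panels(
    cfg: SimConfig,
) -> tuple[HaplotypeMatrix, HaplotypeMatrix, pd.DataFrame]:
    """Generate (study panel, reference panel, annotation table).

    Both panels are phased.  The study panel keeps sites segregating among
    study samples (its own variant catalog); the reference panel keeps sites
    segregating among reference samples — so some study variants are absent
    from the reference, as with a real external panel.  The annotation table
    covers the study catalog: MAF computed on the study panel, design scores
    drawn Beta(*design_beta*), scaffold membership by a logistic-in-MAF rule,
    must_include all False (callers mark their own).
    """
    cfg.validate()
    ts = msprime.sim_ancestry(
        samples=[
            msprime.SampleSet(cfg.n_study_samples, population="STUDY"),
            msprime.SampleSet(cfg.n_reference_samples, population="POOL_A"),
        ],
        demography=_demography(cfg),
        sequence_length=cfg.region_bp,
        recombination_rate=_rate_map(cfg),
        random_seed=int(cfg.seed),
        discrete_genome=True,
    )
    mts = msprime.sim_mutations(
        ts,
        rate=cfg.mutation_rate,
        random_seed=int(cfg.seed) + 1,
        model=msprime.BinaryMutationModel(),
    )

    n_study_haps = 2 * cfg.n_study_samples
    sites: list[Site] = []
    cols: list[np.ndarray] = []
    last_pos = 0
    for var in mts.variants():
        if len(var.alleles) != 2:
            continue
        g = var.genotypes.astype(np.uint8)
        pos = int(var.site.position) + 1  # 1-based
        if pos <= last_pos:  # duplicate integer position under discrete genome
            continue
        last_pos = pos
        sites.append(Site(cfg.chrom, pos, "A", "G"))
        cols.append(g)
    haps_all = (
        np.stack(cols, axis=1)
        if cols
        else np.zeros((n_study_haps + 2 * cfg.n_reference_samples, 0), dtype=np.uint8)
    )

    study_haps = haps_all[:n_study_haps, :]
    ref_haps = haps_all[n_study_haps:, :]

    study_seg = np.flatnonzero(
        (study_haps.sum(axis=0) > 0) & (study_haps.sum(axis=0) < n_study_haps)
    )
    ref_seg = np.flatnonzero(
        (ref_haps.sum(axis=0) > 0) & (ref_haps.sum(axis=0) < ref_haps.shape[0])
    )

    study_samples = [f"S{i:04d}" for i in range(cfg.n_study_samples)]
    ref_samples = [f"R{i:04d}" for i in range(cfg.n_reference_samples)]
    study = HaplotypeMatrix(
        [sites[j] for j in study_seg], study_samples, study_haps[:, study_seg]
    )
    reference = HaplotypeMatrix(
        [sites[j] for j in ref_seg], ref_samples, ref_haps[:, ref_seg]
    )

    ann = annotate_panel(study, cfg)
    return study, reference, ann


def annotate_panel(study: HaplotypeMatrix, cfg: SimConfig) -> pd.DataFrame:
    """Annotation table for a study catalog under the configured scaffold and
    design-score rules (deterministic given cfg.seed)."""
    rng = np.random.default_rng(int(cfg.seed) + 2)
    maf = compute_maf(study)
    logit = (maf - cfg.scaffold_mid) / max(cfg.scaffold_scale, 1e-9)
    p_scaffold = cfg.scaffold_max / (1.0 + np.exp(-logit))
    on_scaffold = rng.random(study.n_sites) < p_scaffold
    a, b = cfg.design_beta
    design = rng.beta(a, b, size=study.n_sites)
    return pd.DataFrame(
        {
            "id": study.site_ids,
            "maf": maf,
            "design_score": design,
            "on_scaffold": on_scaffold,
            "must_include": np.zeros(study.n_sites, dtype=bool),
        },
        columns=ANNOTATION_COLUMNS,
    )


def unphase(
    h: HaplotypeMatrix, missing_rate: float = 0.0, seed: int | None = None
) -> GenotypeMatrix:
    """Collapse haplotype pairs to genotype counts, optionally masking cells
    missing independently at ``missing_rate``."""
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    g = h.to_genotypes()
    if missing_rate > 0.0:
        rng = np.random.default_rng(seed)
        mask = rng.random(g.gt.shape) < missing_rate
        gt = g.gt.copy()
        gt[mask] = MISSING
        g = GenotypeMatrix(g.sites, g.samples, gt)
    return g
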