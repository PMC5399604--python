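"""Imputation-aware screening of tagging candidates.

A candidate variant that is already imputable from the scaffold array plus
an external reference panel does not need a tag of its own.  The screen
imputes each candidate for every study sample from scaffold-site genotypes
using a Li-Stephens haplotype-copying model (a hidden Markov model whose
states are reference haplotypes, with a per-site copying error ``theta`` and
a distance-scaled switch rate), scores the imputed dosages against the true
sequenced genotypes with an empirical dosage r2, and removes candidates
exceeding the quality threshold from the tagging pool.

All study haplotypes share one forward-backward pass over the scaffold
sites; imputing any individual target then costs a single posterior
interpolation between its flanking scaffold sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotype_io import HaplotypeMatrix

logger = logging.getLogger(__name__)


class ConstantTruthError(ValueError):
    """Imputation quality undefined: held-out genotypes are constant."""


@dataclass(frozen=True)
class CopyingModelParams:
    """Li-Stephens copying model parameters.

    theta
        Per-site copying error (mutation) rate; emission probability of a
        mismatch against the copied reference haplotype.
    ne
        Effective population size scaling the switch rate: the probability
        of switching copying template across an interval of ``d`` bp is
        ``1 - exp(-4 * ne * recomb_rate * d / K)`` for K reference
        haplotypes.
    recomb_rate
        Per-bp per-generation recombination rate.
    window_bp
        Scaffold sites farther than this from a target do not inform it;
        a target with no scaffold site in the window falls back to its
        allele-frequency dosage.
    """

    theta: float = 0.001
    ne: float = 10_000.0
    recomb_rate: float = 1e-8
    window_bp: int = 500_000

    def __post_init__(self):
        if not (0.0 < self.theta < 0.5):
            raise ValueError("theta must be in (0, 0.5)")
        if self.ne <= 0 or self.recomb_rate < 0 or self.window_bp <= 0:
            raise ValueError("invalid copying model parameters")

    def switch_prob(self, dist_bp: np.ndarray | float, n_states: int) -> np.ndarray:
        rho = 4.0 * self.ne * self.recomb_rate * np.asarray(dist_bp, dtype=float)
        return -np.expm1(-rho / max(n_states, 1))


class ImputationEngine:
    """Shared forward-backward machinery for imputing many targets.

    Built once from the study panel restricted to scaffold sites and a
    phased reference panel covering scaffold + target sites.  Scaffold sites
    are aligned between the two panels by variant id; scaffold sites absent
    from the reference are dropped with a log notice.
    """

    def __init__(
        self,
        scaffold_haps: HaplotypeMatrix,
        reference_haps: HaplotypeMatrix,
        params: CopyingModelParams | None = None,
    ):
        self.params = params or CopyingModelParams()
        ref_index = reference_haps.site_index()
        pairs = [
            (j, ref_index[s.id])
            for j, s in enumerate(scaffold_haps.sites)
            if s.id in ref_index
        ]
        n_dropped = scaffold_haps.n_sites - len(pairs)
        if n_dropped:
            logger.info(
                "imputation engine: %d scaffold sites absent from reference, dropped",
                n_dropped,
            )
        self.study = scaffold_haps
        self.reference = reference_haps
        self._study_cols = np.array([p[0] for p in pairs], dtype=np.int64)
        self._ref_cols = np.array([p[1] for p in pairs], dtype=np.int64)
        self.scaffold_pos = np.array(
            [scaffold_haps.sites[j].pos for j in self._study_cols], dtype=np.int64
        )
        self.n_states = reference_haps.n_haplotypes
        self._run_forward_backward()

    # -- HMM internals ------------------------------------------------------

    def _emissions(self, l: int) -> np.ndarray:
        """(H, K) emission matrix at scaffold step l."""
        th = self.params.theta
        obs = self.study.haps[:, self._study_cols[l]].astype(np.int8)  # (H,)
        ref = self.reference.haps[:, self._ref_cols[l]].astype(np.int8)  # (K,)
        match = obs[:, None] == ref[None, :]
        return np.where(match, 1.0 - th, th).astype(np.float32)

    def _run_forward_backward(self) -> None:
        H = self.study.n_haplotypes
        K = self.n_states
        L = self._study_cols.size
        self.L = L
        if L == 0:
            self.alpha = np.zeros((0, H, K), dtype=np.float32)
            self.eb = np.zeros((0, H, K), dtype=np.float32)
            return
        d = np.diff(self.scaffold_pos).astype(float)
        p_sw = self.params.switch_prob(d, K)  # (L-1,)

        alpha = np.empty((L, H, K), dtype=np.float32)
        a = self._emissions(0) / K
        a /= a.sum(axis=1, keepdims=True)
        alpha[0] = a
        for l in range(1, L):
            prior = (1.0 - p_sw[l - 1]) * alpha[l - 1] + p_sw[l - 1] / K
            a = prior * self._emissions(l)
            a /= a.sum(axis=1, keepdims=True)
            alpha[l] = a

        # eb[l] = normalized emission(l) * beta(l): ready for a transition of
        # any length from a query position left of site l.
        eb = np.empty((L, H, K), dtype=np.float32)
        beta = np.ones((H, K), dtype=np.float32) / K
        for l in range(L - 1, -1, -1):
            e = self._emissions(l) * beta
            e /= e.sum(axis=1, keepdims=True)
            eb[l] = e
            if l > 0:
                beta = (1.0 - p_sw[l - 1]) * e + p_sw[l - 1] * e.mean(
                    axis=1, keepdims=True
                )
        self.alpha = alpha
        self.eb = eb

    def state_posterior(self, pos: int) -> np.ndarray | None:
        """(H, K) copying-state posterior at an arbitrary position.

        Returns None when no scaffold site lies within the model window.
        """
        if self.L == 0:
            return None
        K = self.n_states
        idx = int(np.searchsorted(self.scaffold_pos, pos))
        left = idx - 1  # scaffold index strictly left of pos (or at pos-?)
        right = idx
        # exact hit: scaffold site at the same position still treated as flank
        have_left = left >= 0 and pos - self.scaffold_pos[left] <= self.params.window_bp
        have_right = (
            right < self.L and self.scaffold_pos[right] - pos <= self.params.window_bp
        )
        if not have_left and not have_right:
            return None
        post = np.ones((self.study.n_haplotypes, K), dtype=np.float64)
        if have_left:
            p = float(self.params.switch_prob(pos - self.scaffold_pos[left], K))
            post *= (1.0 - p) * self.alpha[left] + p / K
        if have_right:
            p = float(self.params.switch_prob(self.scaffold_pos[right] - pos, K))
            e = self.eb[right]
            post *= (1.0 - p) * e + p * e.mean(axis=1, keepdims=True)
        post /= post.sum(axis=1, keepdims=True)
        return post

    def impute_site(self, target_ref_col: int, pos: int) -> tuple[np.ndarray, bool]:
        """Per-sample dosage in [0, 2] for the reference column at ``pos``.

        Returns (dosages, informed); ``informed`` is False when the model
        fell back to the allele-frequency dosage for lack of scaffold data.
        """
        ref_allele = self.reference.haps[:, target_ref_col].astype(np.float64)
        post = self.state_posterior(pos)
        if post is None:
            logger.warning(
                "no scaffold site within %d bp of position %d; "
                "falling back to allele-frequency dosage",
                self.params.window_bp,
                pos,
            )
            af = float(ref_allele.mean())
            return np.full(self.study.n_samples, 2.0 * af), False
        hap_prob = post @ ref_allele  # (H,)
        dosage = hap_prob[0::2] + hap_prob[1::2]
        return np.clip(dosage, 0.0, 2.0), True


def ls_impute(
    scaffold_haps: HaplotypeMatrix,
    reference_haps: HaplotypeMatrix,
    target_site: int,
    params: CopyingModelParams | None = None,
) -> np.ndarray:
    """Impute one reference site (column index into the reference panel) for
    every study sample; convenience wrapper over :class:`ImputationEngine`."""
    engine = ImputationEngine(scaffold_haps, reference_haps, params)
    pos = reference_haps.sites[target_site].pos
    dosages, _ = engine.impute_site(target_site, pos)
    return dosages


def imputation_r2(dosages: Sequence[float], truth: Sequence[int]) -> float:
    """Squared Pearson correlation between imputed dosage and true genotype.

    A constant dosage vector scores 0 by convention (no information);
    constant truth is an error — the site cannot be evaluated.
    """
    d = np.asarray(dosages, dtype=float)
    t = np.asarray(truth, dtype=float)
    if d.shape != t.shape or d.size < 2:
        raise ValueError("need >= 2 paired (dosage, truth) values")
    if np.ptp(t) == 0:
        raise ConstantTruthError("true genotypes are constant")
    if np.ptp(d) == 0:
        return 0.0
    r = np.corrcoef(d, t)[0, 1]
    return float(min(1.0, r * r))


def screen_imputable(
    candidates: Iterable[str],
    study: HaplotypeMatrix,
    scaffold_ids: Iterable[str],
    reference: HaplotypeMatrix,
    r2_thresh: float = 0.8,
    params: CopyingModelParams | None = None,
) -> tuple[set[str], pd.DataFrame]:
    """Leave-one-out imputability screen over candidate sites.

    Each candidate is imputed from scaffold sites only (the candidate itself
    never enters the model, so masking is implicit) and scored against the
    true study genotypes.  Candidates with empirical dosage r2 strictly
    above ``r2_thresh`` are declared imputable.  Candidates absent from the
    reference panel score 0 (unimputable) and stay in the tagging pool.

    Returns (imputable id set, quality table with columns id, r2_hat,
    n_eval, screened).
    """
    scaffold_ids = set(scaffold_ids)
    candidates = list(candidates)
    overlap = scaffold_ids & set(candidates)
    if overlap:
        raise ValueError(
            f"candidates must be disjoint from the scaffold, e.g. {sorted(overlap)[:5]}"
        )
    scaffold = study.restrict_to_ids(scaffold_ids)
    engine = ImputationEngine(scaffold, reference, params)

    study_index = study.site_index()
    ref_index = reference.site_index()
    truth_gt = study.to_genotypes().gt

    rows = []
    imputable: set[str] = set()
    n_absent = 0
    for cid in candidates:
        n_eval = study.n_samples
        if cid not in ref_index:
            n_absent += 1
            rows.append({"id": cid, "r2_hat": 0.0, "n_eval": n_eval, "screened": 0})
            continue
        pos = reference.sites[ref_index[cid]].pos
        dosages, _ = engine.impute_site(ref_index[cid], pos)
        truth = truth_gt[:, study_index[cid]]
        try:
            r2_hat = imputation_r2(dosages, truth)
        except ConstantTruthError:
            rows.append(
                {"id": cid, "r2_hat": np.nan, "n_eval": n_eval, "screened": 0}
            )
            continue
        screened = int(r2_hat > r2_thresh)
        if screened:
            imputable.add(cid)
        rows.append(
            {"id": cid, "r2_hat": r2_hat, "n_eval": n_eval, "screened": screened}
        )
    if n_absent:
        logger.info(
            "imputation screen: %d candidates absent from reference, retained for tagging",
            n_absent,
        )
    table = pd.DataFrame(rows, columns=["id", "r2_hat", "n_eval", "screened"])
    return imputable, table
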