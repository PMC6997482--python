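"""Bootstrap ensemble of range maps: replicate fitting, AUC filtering,
max-sensitivity-plus-specificity binarization, majority-vote consensus,
population-map union, and temporal change categorization.

Each replicate refits the selected (RM, FC) setting on a random 50% of the
presences, is scored by test AUC against the shared background, binarized at
its own maximum sensitivity-plus-specificity threshold, and the surviving
replicates vote: a cell is suitable in the consensus when strictly more than
the vote fraction (default 60%) of maps agree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .maxent import FeatureSpace, MaxentModel, auc, fit_maxent, predict
from .raster import RasterGrid, RasterStack

logger = logging.getLogger("popsdm")


@dataclass
class Replicate:
    model: MaxentModel
    train_idx: np.ndarray
    test_idx: np.ndarray
    test_auc: float
    threshold: float | None = None   # MSS tau, set at binarization time


@dataclass
class EnsembleResult:
    replicates: list[Replicate]
    retained: list[Replicate]
    consensus: RasterGrid
    vote_fraction: RasterGrid
    auc_cutoff: float
    vote_frac: float
    label: str = ""

    def metrics(self) -> pd.DataFrame:
        return pd.DataFrame({
            "test_auc": [r.test_auc for r in self.replicates],
            "threshold": [r.threshold for r in self.replicates],
            "retained": [r in self.retained for r in self.replicates],
        })


# ---------------------------------------------------------------------------
# Replicates
# ---------------------------------------------------------------------------

def bootstrap_models(presence, background, rm: float, fc: str,
                     feature_space: FeatureSpace | None = None,
                     n_reps: int = 10, split: float = 0.5, seed: int = 0,
                     n_knots: int = 20, max_iter: int = 500,
                     tol: float = 1e-7) -> list[Replicate]:
    """Fit ``n_reps`` models on independent random 50/50 presence splits,
    scoring each by test AUC against the shared background."""
    presence = pd.DataFrame(presence)
    background = pd.DataFrame(background)
    m = len(presence)
    if m < 4:
        raise ValueError("bootstrap needs at least 4 presences")
    rng = np.random.default_rng(seed)
    n_train = int(round(m * split))
    reps = []
    for _ in range(n_reps):
        perm = rng.permutation(m)
        tr_idx, te_idx = perm[:n_train], perm[n_train:]
        model = fit_maxent(presence.iloc[tr_idx], background,
                           feature_space=feature_space, rm=rm, fc=fc,
                           n_knots=n_knots, max_iter=max_iter, tol=tol)
        test_auc = auc(predict(model, presence.iloc[te_idx], output="raw"),
                       predict(model, background, output="raw", clamp=False))
        reps.append(Replicate(model, tr_idx, te_idx, float(test_auc)))
    return reps


def filter_auc(replicates: list[Replicate], cutoff: float = 0.85) -> list[Replicate]:
    """Drop replicates whose test AUC is strictly under the cutoff."""
    kept = [r for r in replicates if r.test_auc >= cutoff]
    if not kept:
        raise ValueError(
            f"all {len(replicates)} replicates fell under test AUC {cutoff}; "
            "revisit the model setting or data"
        )
    if len(kept) < 3:
        logger.warning("filter_auc: only %d replicate(s) retained", len(kept))
    return kept


# ---------------------------------------------------------------------------
# Binarization
# ---------------------------------------------------------------------------

def mss_threshold(presence_scores, background_scores) -> float:
    """Threshold maximizing sensitivity + specificity.

    Candidates are the sorted unique observed scores; sensitivity counts
    presences with score >= tau, specificity counts background with score
    < tau; ties resolve to the smallest tau (the more inclusive map).
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score sets must be nonempty")
    candidates = np.unique(np.concatenate([p, b]))
    sens = (p[None, :] >= candidates[:, None]).mean(axis=1)
    spec = (b[None, :] < candidates[:, None]).mean(axis=1)
    total = sens + spec
    return float(candidates[np.argmax(total)])  # argmax -> first (smallest) tie


def binarize(suitability: RasterGrid, tau: float) -> RasterGrid:
    """cell = 1 iff suitability >= tau; nodata preserved."""
    if not np.isfinite(tau):
        raise ValueError("threshold must be finite")
    vals = np.where(suitability.finite_mask,
                    (suitability.values >= tau).astype(float), np.nan)
    return suitability.copy_with(vals)


# ---------------------------------------------------------------------------
# Consensus and combination
# ---------------------------------------------------------------------------

def majority_vote(binary_maps: list[RasterGrid],
                  vote_frac: float = 0.6) -> tuple[RasterGrid, RasterGrid]:
    """Consensus map (1 where strictly more than ``vote_frac`` of the maps
    are suitable) plus the vote-fraction raster."""
    if not binary_maps:
        raise ValueError("at least one map required")
    first = binary_maps[0]
    for m in binary_maps[1:]:
        if not m.same_geometry(first):
            raise ValueError("majority_vote: geometry mismatch across maps")
    stack = np.stack([m.values for m in binary_maps])
    votes = np.nansum(stack == 1, axis=0) / len(binary_maps)
    any_finite = np.any(np.isfinite(stack), axis=0)
    frac = np.where(any_finite, votes, np.nan)
    consensus = np.where(any_finite, (frac > vote_frac).astype(float), np.nan)
    return first.copy_with(consensus), first.copy_with(frac)


def combine_union(map_a: RasterGrid, map_b: RasterGrid,
                  mode: str = "union") -> RasterGrid:
    """Cellwise combination of two population maps: logical OR by default
    ("suitable for either population"), AND with ``mode='intersection'``.
    Nodata only where both inputs are nodata (union) / where either is
    (intersection)."""
    if not map_a.same_geometry(map_b):
        raise ValueError("combine: geometry mismatch")
    a, b = map_a.values, map_b.values
    fa, fb = np.isfinite(a), np.isfinite(b)
    if mode == "union":
        vals = np.where(fa | fb,
                        ((np.nan_to_num(a) == 1) | (np.nan_to_num(b) == 1)).astype(float),
                        np.nan)
    elif mode == "intersection":
        vals = np.where(fa & fb, ((a == 1) & (b == 1)).astype(float), np.nan)
    else:
        raise ValueError("mode must be 'union' or 'intersection'")
    return map_a.copy_with(vals)


# ---------------------------------------------------------------------------
# Temporal change
# ---------------------------------------------------------------------------

# (current, mid, late) -> category code and name
CHANGE_CATEGORIES: dict[tuple[int, int, int], tuple[int, str]] = {
    (1, 1, 1): (1, "stable-suitable"),
    (1, 1, 0): (2, "lost-from-2070s"),
    (1, 0, 0): (3, "lost-from-2050s"),
    (1, 0, 1): (4, "temporary-loss"),
    (0, 1, 1): (5, "gained-from-2050s"),
    (0, 0, 1): (6, "gained-from-2070s"),
    (0, 1, 0): (7, "temporary-gain"),
    (0, 0, 0): (8, "stable-unsuitable"),
}


@dataclass
class ChangeMap:
    categories: RasterGrid        # integer codes 1..8, NaN = nodata
    legend: dict[int, str] = field(default_factory=lambda: {
        code: name for code, name in CHANGE_CATEGORIES.values()})

    def counts(self) -> pd.Series:
        vals = self.categories.values
        return pd.Series({name: int((vals == code).sum())
                          for code, name in sorted(CHANGE_CATEGORIES.values())})


def change_map(current: RasterGrid, mid: RasterGrid, late: RasterGrid) -> ChangeMap:
    """Assign each cell one of eight suitability-trajectory categories from
    its (current, mid-century, late-century) binary triple."""
    for other in (mid, late):
        if not current.same_geometry(other):
            raise ValueError("change_map: geometry mismatch")
    finite = current.finite_mask & mid.finite_mask & late.finite_mask
    codes = np.full(current.values.shape, np.nan)
    for (c, m_, l), (code, _name) in CHANGE_CATEGORIES.items():
        match = finite & (current.values == c) & (mid.values == m_) & (late.values == l)
        codes[match] = code
    return ChangeMap(current.copy_with(codes))


# ---------------------------------------------------------------------------
# One-call ensemble
# ---------------------------------------------------------------------------

def build_ensemble(presence, background, rm: float, fc: str,
                   current_stack: RasterStack,
                   feature_space: FeatureSpace | None = None,
                   n_reps: int = 10, split: float = 0.5, seed: int = 0,
                   auc_cutoff: float = 0.85, vote_frac: float = 0.6,
                   output: str = "cloglog", n_knots: int = 20,
                   max_iter: int = 500, tol: float = 1e-7,
                   label: str = "") -> EnsembleResult:
    """Bootstrap, filter, binarize (per-replicate MSS on its own test
    presences), and vote — the full consensus-map recipe for one data suite
    on the current climate."""
    presence = pd.DataFrame(presence)
    reps = bootstrap_models(presence, background, rm, fc,
                            feature_space=feature_space, n_reps=n_reps,
                            split=split, seed=seed, n_knots=n_knots,
                            max_iter=max_iter, tol=tol)
    retained = filter_auc(reps, cutoff=auc_cutoff)
    maps = []
    for rep in retained:
        test_scores = predict(rep.model, presence.iloc[rep.test_idx], output=output)
        bg_scores = predict(rep.model, background, output=output, clamp=False)
        rep.threshold = mss_threshold(test_scores, bg_scores)
        suit = predict(rep.model, current_stack, output=output)
        maps.append(binarize(suit, rep.threshold))
    consensus, frac = majority_vote(maps, vote_frac=vote_frac)
    return EnsembleResult(reps, retained, consensus, frac, auc_cutoff, vote_frac, label)


def project_ensemble(result: EnsembleResult, stack: RasterStack,
                     vote_frac: float | None = None,
                     output: str = "cloglog") -> tuple[RasterGrid, RasterGrid]:
    """Project the retained replicates onto another climate stack, reusing
    each replicate's fitted threshold; returns (consensus, vote fraction)."""
    maps = [binarize(predict(rep.model, stack, output=output), rep.threshold)
            for rep in result.retained]
    return majority_vote(maps, vote_frac=result.vote_frac if vote_frac is None else vote_frac)
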