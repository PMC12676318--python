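"""Enrichment validation: ROC curve and AUC over active-vs-decoy docking
scores, plus a simplified property-matched decoy generator.

Scores are docking affinities in kcal/mol where *lower is better*; the
threshold sweep internally negates scores so the usual "higher = more
active" ROC machinery applies.  The AUC equals the Mann–Whitney
probability that a random active outscores a random decoy, with ties
counted one half.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chem_filters import DescriptorSet
from .io_model import CompoundRecord

__all__ = ["ScoredSet", "roc_curve", "auc", "generate_decoys"]


@dataclass
class ScoredSet:
    """Active and decoy docking scores under a declared convention."""

    active_scores: Sequence[float]
    decoy_scores: Sequence[float]
    lower_is_better: bool = True

    def __post_init__(self):
        self.active_scores = np.asarray(self.active_scores, dtype=float)
        self.decoy_scores = np.asarray(self.decoy_scores, dtype=float)
        if not (np.all(np.isfinite(self.active_scores)) and np.all(np.isfinite(self.decoy_scores))):
            raise ValueError("scores must be finite")


def _oriented(s: ScoredSet):
    sign = -1.0 if s.lower_is_better else 1.0
    return sign * s.active_scores, sign * s.decoy_scores


def roc_curve(s: ScoredSet) -> list[tuple[float, float]]:
    """ROC points from the best-to-worst threshold sweep.

    Equal scores are grouped into a single step, so the curve has one point
    per distinct score plus the (0,0) origin; it always ends at (1,1).
    """
    if len(s.active_scores) == 0 or len(s.decoy_scores) == 0:
        raise ValueError("both actives and decoys must be non-empty")
    act, dec = _oriented(s)
    thresholds = np.unique(np.concatenate([act, dec]))[::-1]
    n_a, n_d = len(act), len(dec)
    points = [(0.0, 0.0)]
    for th in thresholds:
        tpr = float(np.sum(act >= th)) / n_a
        fpr = float(np.sum(dec >= th)) / n_d
        points.append((fpr, tpr))
    return points


def auc(s: ScoredSet) -> float:
    """Trapezoidal area under the ROC curve, in [0, 1]."""
    pts = roc_curve(s)
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    return float(np.trapezoid(ys, xs))


def generate_decoys(
    active: DescriptorSet,
    n: int,
    seed: int,
    strict: bool = True,
    prefix: str = "decoy",
) -> list[CompoundRecord]:
    """Property-matched decoys: MW and logP within ±10% of the active.

    A light stand-in for a decoy web service — decoys carry matched bulk
    properties and a distinct structure key (id), not real chemistry.
    Deterministic under ``seed``.
    """
    if n < 1:
        if strict:
            raise ValueError("n must be >= 1")
        return []
    rng = np.random.default_rng(seed)
    mws = active.mw * rng.uniform(0.9, 1.1, size=n)
    logps = active.logp * rng.uniform(0.9, 1.1, size=n) if active.logp != 0 else rng.uniform(-0.1, 0.1, size=n)
    out = []
    for k in range(n):
        out.append(
            CompoundRecord(
                id=f"{prefix}-{seed}-{k:04d}",
                affinity=0.0,  # unscored until docked
                wlogp=float(logps[k]),
                tpsa=float(active.tpsa),
                mw=float(mws[k]),
            )
        )
    return out
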