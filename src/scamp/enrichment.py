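"""Enrichment-curve evaluation of a ranked candidate list.

Given a ranking with known active/inactive labels, the enrichment curve
tracks the fraction of actives recovered as the list is screened from the
top.  Under the default "roc" convention the x axis is the fraction of
INACTIVES screened, so an ideal ranking (all actives first) has an area
under the curve of exactly 1.0 and a random ranking 0.5 in expectation,
for any finite list.  The "screened" convention (x = fraction of the whole
database screened) is provided for comparison; with it an ideal ranking
reaches 1 - n_active / (2n).

Candidates sharing a score are treated as one diagonal segment (the
average over their permutations), so the AUC does not depend on how a
sorting routine happened to break ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["LabeledRanking", "EnrichmentCurve", "enrichment_curve", "auc"]


@dataclass
class LabeledRanking:
    """A ranked candidate list with active labels (rank 1 first).

    ``scores`` is optional; when given, equal scores mark tied blocks that
    are averaged in the curve.  Requires at least one active and one
    inactive candidate — otherwise recovery has no denominator.
    """

    ids: Sequence
    active: np.ndarray
    scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.active = np.asarray(self.active, dtype=bool)
        if len(self.ids) != self.active.size:
            raise ValueError("one active flag per candidate required")
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float)
            if self.scores.size != self.active.size:
                raise ValueError("one score per candidate required")
            if np.any(np.diff(self.scores) > 0):
                raise ValueError("scores must be non-increasing down the ranking")
        if self.n_active == 0 or self.n_inactive == 0:
            raise ValueError("ranking needs at least one active and one inactive")

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    @property
    def n_inactive(self) -> int:
        return int((~self.active).sum())


@dataclass
class EnrichmentCurve:
    """Piecewise-linear recovery curve from (0,0) to (1,1) and its AUC."""

    x: np.ndarray
    y: np.ndarray
    auc: float
    convention: str = "roc"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("curve points must be matching 1-D arrays")
        if np.any(np.diff(self.x) < 0) or np.any(np.diff(self.y) < 0):
            raise ValueError("curve must be non-decreasing in both axes")
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must lie in [0, 1]")


def _tie_blocks(r: LabeledRanking) -> list[np.ndarray]:
    """Indices of consecutive equal-score blocks (singletons without scores)."""
    n = r.active.size
    if r.scores is None:
        return [np.array([i]) for i in range(n)]
    blocks, start = [], 0
    for i in range(1, n + 1):
        if i == n or r.scores[i] != r.scores[start]:
            blocks.append(np.arange(start, i))
            start = i
    return blocks


def enrichment_curve(r: LabeledRanking, convention: str = "roc") -> EnrichmentCurve:
    """Walk the ranking from rank 1 and accumulate the recovery curve.

    Under "roc", x advances by 1/n_inactive per inactive and y by
    1/n_active per active; under "screened", x advances by 1/n per
    candidate.  The curve is anchored at (0,0) and ends at (1,1).
    """
    if convention not in ("roc", "screened"):
        raise ValueError(f"unknown enrichment convention {convention!r}")
    n = r.active.size
    xs, ys = [0.0], [0.0]
    seen = seen_active = seen_inactive = 0
    for block in _tie_blocks(r):
        n_act = int(r.active[block].sum())
        seen += block.size
        seen_active += n_act
        seen_inactive += block.size - n_act
        # integer cumulative counts keep the curve exactly monotone
        ys.append(seen_active / r.n_active)
        xs.append(seen_inactive / r.n_inactive if convention == "roc"
                  else seen / n)
    curve_auc = float(np.trapezoid(ys, xs))
    return EnrichmentCurve(np.array(xs), np.array(ys),
                           min(max(curve_auc, 0.0), 1.0), convention)


def auc(curve: EnrichmentCurve) -> float:
    """Trapezoidal area under an enrichment curve over x in [0, 1]."""
    return float(np.trapezoid(curve.y, curve.x))
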