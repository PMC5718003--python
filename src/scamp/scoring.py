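"""The three mass-activity correlation scores and candidate ranking.

Score 1 is the correlation coefficient C_j: the dot product of the
unit-normalized activity profile A0 and the unit-normalized mass profile
M_j0 of bin j, reported on a 0-100 scale (100 = the profiles are
proportional).  Score 2 = C_j x I adds concentration dependence through
the bin's summed raw intensity I.  Score 3 = C_j sigma^2 I / N_f^2 is
computed per chromatographic group — a maximal contiguous run of fractions
whose intensity exceeds the bin-profile mean — so that structural isomers
sharing an m/z but eluting in different fraction windows are scored as
separate candidates, and broad featureless profiles are penalized.

The 0-100 C_j scale is used because the unit-norm dot product of
non-negative profiles lies in [0, 1] while the method's working values
(e.g. a speed-filter threshold above 30) only make sense multiplied by
100; all published working values are consistent with that convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fraction_io import ActivityProfile
from .preprocess import BinnedMatrix

__all__ = [
    "Group",
    "ScoredCandidate",
    "normalize_vector",
    "correlation_cj",
    "total_intensity",
    "score2",
    "find_groups",
    "group_statistics",
    "score3",
    "rank_candidates",
]


@dataclass(frozen=True)
class Group:
    """A contiguous run of fractions within one bin's profile.

    ``start``/``end`` are inclusive 1-based fraction indices.  ``sigma`` is
    the population standard deviation and ``intensity`` the sum of the raw
    in-group intensities; ``n_f`` the number of fractions in the group.
    """

    bin_index: int
    start: int
    end: int
    n_f: int
    sigma: float
    intensity: float

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError("group bounds must satisfy 1 <= start <= end")
        if self.n_f != self.end - self.start + 1:
            raise ValueError("n_f must equal end - start + 1")
        if self.sigma < 0 or self.intensity < 0:
            raise ValueError("sigma and intensity must be non-negative")


@dataclass
class ScoredCandidate:
    """One ranked candidate: a bin (methods 1-2) or one group of a bin
    (method 3), with all three scores and the active method's score."""

    mz: float
    start: int
    end: int
    cj: float
    intensity: float
    sigma: float
    n_f: int
    score2: float
    score3: float
    score: float
    rank: int = 0
    name: str | None = field(default=None)

    @property
    def score1(self) -> float:
        return self.cj


def normalize_vector(v) -> np.ndarray:
    """Scale a vector to unit Euclidean norm (all-zero maps to all-zero)."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("vector contains non-finite entries")
    peak = float(np.max(np.abs(v))) if v.size else 0.0
    if peak == 0.0:
        return v.copy()
    scaled = v / peak  # pre-scale so the squared sum cannot underflow
    return scaled / float(np.linalg.norm(scaled))


def correlation_cj(profile, activity) -> float:
    """Correlation coefficient C_j on the 0-100 scale.

    100 x sum_k a_k0 m_kj0 over the unit-normalized vectors.  Either input
    being all-zero (a degenerate bin or flat assay) yields 0.
    """
    m = np.asarray(profile, dtype=float)
    a = activity.values if isinstance(activity, ActivityProfile) else np.asarray(
        activity, dtype=float)
    if m.shape != a.shape:
        raise ValueError(f"profile length {m.size} != activity length {a.size}")
    return 100.0 * float(np.dot(normalize_vector(a), normalize_vector(m)))


def total_intensity(profile) -> float:
    """Summed raw intensity I of a bin over all fractions."""
    return float(np.sum(np.asarray(profile, dtype=float)))


def score2(cj: float, intensity: float) -> float:
    """Score 2 = C_j x I."""
    return cj * intensity


def find_groups(profile, bin_index: int = 0) -> list[Group]:
    """Split a bin profile into chromatographic groups.

    The mean of all N intensities is computed; maximal contiguous runs of
    fractions strictly above the mean become groups (left to right).
    Fractions at or below the mean belong to no group, so a constant
    profile yields no groups.
    """
    m = np.asarray(profile, dtype=float)
    if m.ndim != 1 or m.size == 0:
        raise ValueError("profile must be a non-empty 1-D vector")
    mean = float(m.mean())
    above = m > mean
    groups: list[Group] = []
    k = 0
    while k < m.size:
        if above[k]:
            start = k
            while k < m.size and above[k]:
                k += 1
            segment = m[start:k]
            groups.append(Group(
                bin_index=bin_index, start=start + 1, end=k,
                n_f=k - start, sigma=float(segment.std()),
                intensity=float(segment.sum()),
            ))
        else:
            k += 1
    return groups


def group_statistics(profile, group: Group) -> tuple[float, float, int]:
    """(sigma, I, N_f) over the raw in-group intensities.

    sigma is the population (divide-by-N_f) standard deviation, so a
    single-fraction group has sigma = 0 rather than being undefined.
    """
    m = np.asarray(profile, dtype=float)
    if not 1 <= group.start <= group.end <= m.size:
        raise ValueError("group window outside profile bounds")
    segment = m[group.start - 1:group.end]
    return float(segment.std()), float(segment.sum()), int(segment.size)


def score3(cj: float, sigma: float, intensity: float, n_f: int) -> float:
    """Score 3 = C_j sigma^2 I / N_f^2."""
    if n_f < 1:
        raise ValueError("group must contain at least one fraction")
    return cj * sigma**2 * intensity / n_f**2


def _masked_profile(profile: np.ndarray, group: Group) -> np.ndarray:
    masked = np.zeros_like(profile)
    masked[group.start - 1:group.end] = profile[group.start - 1:group.end]
    return masked


def rank_candidates(
    matrix: BinnedMatrix,
    activity: ActivityProfile,
    method: int = 3,
    min_cj: float | None = None,
) -> list[ScoredCandidate]:
    """Score every bin against the activity profile and rank descending.

    Methods 1 and 2 score each bin's whole profile.  Method 3 first splits
    every bin into chromatographic groups; each group becomes its own
    candidate whose C_j is computed on the masked full-length profile
    (out-of-group fractions zeroed) against the full activity vector, and
    whose Score 3 uses the group's raw sigma, I, N_f.  Masking rather than
    truncating keeps every C_j on one comparable scale.

    Candidates with C_j <= ``min_cj`` (when given) are dropped — the
    speed filter used to thin very large peak lists.  Ties are broken by
    ascending m/z then ascending start fraction; ranks are 1..n.
    """
    if method not in (1, 2, 3):
        raise ValueError(f"unknown scoring method {method!r}")
    if matrix.n_fractions != activity.n_fractions:
        raise ValueError(
            f"matrix has {matrix.n_fractions} fractions, "
            f"activity has {activity.n_fractions}"
        )
    a0 = activity.normalize().values
    candidates: list[ScoredCandidate] = []
    for j in range(matrix.n_bins):
        profile = matrix.profile(j)
        mz = float(matrix.bin_centers[j])
        if method in (1, 2):
            cj = 100.0 * float(np.dot(a0, normalize_vector(profile)))
            intensity = total_intensity(profile)
            sigma = float(profile.std())
            n_f = profile.size
            s2 = score2(cj, intensity)
            s3 = score3(cj, sigma, intensity, n_f)
            candidates.append(ScoredCandidate(
                mz=mz, start=1, end=int(profile.size), cj=cj,
                intensity=intensity, sigma=sigma, n_f=int(n_f),
                score2=s2, score3=s3, score=cj if method == 1 else s2,
            ))
        else:
            for group in find_groups(profile, bin_index=j):
                masked = _masked_profile(profile, group)
                cj = 100.0 * float(np.dot(a0, normalize_vector(masked)))
                sigma, intensity, n_f = group_statistics(profile, group)
                s3 = score3(cj, sigma, intensity, n_f)
                candidates.append(ScoredCandidate(
                    mz=mz, start=group.start, end=group.end, cj=cj,
                    intensity=intensity, sigma=sigma, n_f=n_f,
                    score2=score2(cj, intensity), score3=s3, score=s3,
                ))
    if min_cj is not None:
        candidates = [c for c in candidates if c.cj > min_cj]
    candidates.sort(key=lambda c: (-c.score, c.mz, c.start))
    for rank, c in enumerate(candidates, start=1):
        c.rank = rank
    return candidates
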